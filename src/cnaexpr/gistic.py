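"""Recurrent copy-number region detection via a G-score permutation test.

A transparent, simplified take on the frequency x amplitude scoring used for
recurrent-aberration discovery in tumour cohorts: each marker (here a gene)
gets G = f x a-bar, the fraction of aberrant samples times the mean absolute
log2 ratio among them — equivalently the sample-mean of the masked
amplitude.  Significance comes from permuting each sample's markers within
chromosomes, p-values are Benjamini-Hochberg corrected, and significant runs
are reduced to their maximal-G peak intervals.

No peel-off of secondary peaks and no boundary confidence intervals; this is
deliberately a minimal recurrent-region caller, not a reimplementation of
any particular release of the original method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .copy_number import GeneCN

__all__ = ["compute_gscore", "permutation_significance", "find_peaks"]

_DIRECTION_STATUSES = {"del": ("DEL", "HOMDEL"), "gain": ("GAIN", "AMP")}


def _masked_amplitude(genecn: GeneCN, direction: str) -> np.ndarray:
    """|log2 ratio| where the sample is aberrant in ``direction``, else 0."""
    statuses = _DIRECTION_STATUSES[direction]
    if genecn.status is None:
        raise ValueError("statuses not called")
    if genecn.ratios.shape[1] == 0:
        raise ValueError("no samples")
    aberrant = genecn.status.isin(statuses).to_numpy()
    amp = np.abs(np.nan_to_num(genecn.ratios.to_numpy(), nan=0.0))
    return np.where(aberrant, amp, 0.0)


def compute_gscore(
    genecn: GeneCN, annotation: pd.DataFrame, direction: str
) -> pd.DataFrame:
    """Per-marker G-score track for one direction ('del' or 'gain').

    Returns a DataFrame indexed by gene with chrom, start, end, freq,
    mean_amp and G.  G = freq x mean_amp; markers no sample hits get G = 0.
    """
    masked = _masked_amplitude(genecn, direction)
    n_samples = masked.shape[1]
    n_ab = (masked > 0).sum(axis=1)
    freq = n_ab / n_samples
    with np.errstate(invalid="ignore"):
        mean_amp = np.where(n_ab > 0, masked.sum(axis=1) / np.maximum(n_ab, 1), 0.0)
    track = annotation.loc[genecn.ratios.index, ["chrom", "start", "end"]].copy()
    track["freq"] = freq
    track["mean_amp"] = mean_amp
    track["G"] = masked.mean(axis=1)  # == freq * mean_amp
    return track


def permutation_significance(
    genecn: GeneCN,
    annotation: pd.DataFrame,
    direction: str,
    n_perm: int = 1000,
    seed: int = 0,
    null: str = "marker",
    q_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Permutation p and BH q values for the G-score track.

    The null permutes each sample's markers independently within each
    chromosome, breaking recurrence while preserving every sample's
    aberration load and per-chromosome marker counts.  ``null='marker'``
    (default) pools permuted G-scores across markers and permutations;
    ``null='max'`` compares each marker against the permuted genome-wide
    maximum (more conservative).  Both use add-one smoothing and are
    deterministic for a fixed seed.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    track = compute_gscore(genecn, annotation, direction)
    masked = _masked_amplitude(genecn, direction)
    n_markers, n_samples = masked.shape
    chrom = annotation.loc[genecn.ratios.index, "chrom"].to_numpy()
    blocks = [np.flatnonzero(chrom == c) for c in dict.fromkeys(chrom)]
    obs = track["G"].to_numpy()

    if null == "marker":
        # empirical CDF of the pooled null, evaluated by sorted search
        pool = np.empty(n_perm * n_markers)
        for p in range(n_perm):
            perm = np.empty_like(masked)
            for idx in blocks:
                for s in range(n_samples):
                    perm[idx, s] = masked[rng.permutation(idx), s]
            pool[p * n_markers : (p + 1) * n_markers] = perm.mean(axis=1)
        pool.sort()
        # count of null values >= obs via searchsorted on the sorted pool
        ge = len(pool) - np.searchsorted(pool, obs - 1e-12, side="left")
        pvals = (1.0 + ge) / (len(pool) + 1.0)
    elif null == "max":
        maxima = np.empty(n_perm)
        for p in range(n_perm):
            perm = np.empty_like(masked)
            for idx in blocks:
                for s in range(n_samples):
                    perm[idx, s] = masked[rng.permutation(idx), s]
            maxima[p] = perm.mean(axis=1).max()
        maxima.sort()
        ge = n_perm - np.searchsorted(maxima, obs - 1e-12, side="left")
        pvals = (1.0 + ge) / (n_perm + 1.0)
    else:
        raise ValueError("null must be 'marker' or 'max'")

    track["p_value"] = pvals
    track["q_value"] = multipletests(pvals, method=q_method)[1]
    return track


def find_peaks(
    track: pd.DataFrame,
    q_threshold: float = 0.25,
    annotation: pd.DataFrame | None = None,
    direction: str = "del",
) -> pd.DataFrame:
    """Reduce significant runs to their maximal-G peak intervals.

    A run is a maximal stretch of contiguous markers (within one chromosome)
    with q <= threshold; its peak is the contiguous sub-interval attaining
    the run's maximum G (a plateau of equal maxima spans the whole plateau).
    Peaks are annotated with the symbols of overlapping genes when an
    annotation is supplied.
    """
    peaks = []
    for chrom in dict.fromkeys(track["chrom"]):
        sub = track[track["chrom"] == chrom]
        sig = (sub["q_value"] <= q_threshold).to_numpy()
        g = sub["G"].to_numpy()
        i = 0
        while i < len(sig):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            run = np.arange(i, j + 1)
            gmax = g[run].max()
            at_max = run[np.isclose(g[run], gmax, rtol=0.0, atol=1e-12)]
            # maximal contiguous plateau containing the first maximum
            a = b = at_max[0]
            while b + 1 in at_max:
                b += 1
            start = int(sub.iloc[a]["start"])
            end = int(sub.iloc[b]["end"])
            qmin = float(sub.iloc[run]["q_value"].min())
            peaks.append((chrom, start, end, direction, qmin, gmax))
            i = j + 1
    out = pd.DataFrame(
        peaks, columns=["chrom", "start", "end", "direction", "q_value", "G"]
    )
    genes_col = []
    if annotation is not None:
        for _, pk in out.iterrows():
            hit = annotation[
                (annotation["chrom"] == pk["chrom"])
                & (annotation["end"] >= pk["start"])
                & (annotation["start"] <= pk["end"])
            ]
            genes_col.append(",".join(hit.index))
        out["genes"] = genes_col
    return out
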