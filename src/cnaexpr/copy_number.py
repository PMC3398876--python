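"""Probe-level log2 ratios -> segments -> gene-level copy-number calls.

The copy-number stack mirrors the classic SNP-array workflow for tumour
biopsies whose DNA was whole-genome amplified before hybridisation:

1. ``correct_amplification`` removes the probe-specific bias introduced by
   amplification, using amplified normal-copy-number controls.
2. ``center_median`` recentres each sample to median log2 ratio zero.
3. ``combine_enzyme_sets`` merges the two restriction-enzyme array halves.
4. ``segment_cbs`` partitions each chromosome into constant-mean segments by
   circular binary segmentation with a permutation test.
5. ``assign_gene_values`` maps segment means onto genes by base-pair overlap.
6. ``call_copy_status`` thresholds assigned ratios into categorical calls.

All genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "STATUSES",
    "CNThresholds",
    "ProbeRatioMatrix",
    "GeneCN",
    "correct_amplification",
    "center_median",
    "combine_enzyme_sets",
    "segment_cbs",
    "segment_series",
    "assign_gene_values",
    "call_copy_status",
    "deletion_frequency",
    "gain_frequency",
    "compute_concordance",
    "chrom_sort_key",
]

STATUSES = ("HOMDEL", "DEL", "NEUTRAL", "GAIN", "AMP", "MISSING")

#: Collapse of fine-grained statuses into the three classes used for
#: concordance between call sets: deleted / gained / normal.
COLLAPSE = {
    "HOMDEL": "deleted",
    "DEL": "deleted",
    "NEUTRAL": "normal",
    "GAIN": "gained",
    "AMP": "gained",
}

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "seg_mean"]


def chrom_sort_key(chrom: str):
    """Natural ordering for chromosome names (chr2 < chr10 < chrX)."""
    m = re.match(r"(?:chr)?(\d+)$", str(chrom))
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, str(chrom))


@dataclass(frozen=True)
class CNThresholds:
    """Log2-ratio boundaries for categorical copy-number calls.

    Defaults correspond to 1.5 copies (deletion), 2.5 copies (gain),
    0.5 copies (homozygous deletion) and 5 copies (high-level
    amplification) on a diploid baseline.  All comparisons are strict:
    a ratio exactly at a boundary is NEUTRAL.
    """

    del_threshold: float = math.log2(1.5 / 2)
    gain_threshold: float = math.log2(2.5 / 2)
    homdel_threshold: float = math.log2(0.5 / 2)
    amp_threshold: float = math.log2(5 / 2)

    def __post_init__(self):
        if not (
            self.homdel_threshold
            < self.del_threshold
            < 0
            < self.gain_threshold
            < self.amp_threshold
        ):
            raise ValueError(
                "thresholds must satisfy homdel < del < 0 < gain < amp; got "
                f"{self}"
            )


@dataclass
class ProbeRatioMatrix:
    """Ordered probe-level log2 ratios for a set of samples.

    Parameters
    ----------
    probes
        DataFrame with columns ``probe_id``, ``chrom``, ``pos`` (1-based bp)
        and ``enzyme_set`` (``"A"`` or ``"B"``), sorted by (chrom, pos).
    ratios
        DataFrame of log2 ratios, one row per probe (aligned with
        ``probes``), one column per sample.
    control_samples
        Names of the amplified normal-copy-number control samples; a subset
        of the ratio columns.
    controls_consumed
        Set once the amplification correction has been applied.
    """

    probes: pd.DataFrame
    ratios: pd.DataFrame
    control_samples: tuple = ()
    controls_consumed: bool = False

    def __post_init__(self):
        self.control_samples = tuple(self.control_samples)
        required = {"probe_id", "chrom", "pos", "enzyme_set"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")
        if len(self.probes) != len(self.ratios):
            raise ValueError("probes and ratios row counts differ")
        unknown = set(self.control_samples) - set(self.ratios.columns)
        if unknown:
            raise ValueError(f"unknown control samples: {sorted(unknown)}")
        for chrom, grp in self.probes.groupby("chrom", sort=False):
            if grp["pos"].duplicated().any():
                raise ValueError(f"duplicate probe positions on {chrom}")
        self._sort()

    def _sort(self):
        key = self.probes["chrom"].map(chrom_sort_key)
        order = (
            pd.DataFrame({"k": key, "pos": self.probes["pos"]})
            .sort_values(["k", "pos"])
            .index
        )
        self.probes = self.probes.loc[order].reset_index(drop=True)
        self.ratios = self.ratios.loc[order].reset_index(drop=True)

    @property
    def samples(self) -> list:
        return list(self.ratios.columns)

    @property
    def tumour_samples(self) -> list:
        ctrl = set(self.control_samples)
        return [s for s in self.ratios.columns if s not in ctrl]


@dataclass
class GeneCN:
    """Gene x sample assigned log2 ratios and categorical statuses."""

    ratios: pd.DataFrame
    status: pd.DataFrame | None = None
    thresholds: CNThresholds | None = None

    @property
    def genes(self) -> pd.Index:
        return self.ratios.index

    @property
    def samples(self) -> list:
        return list(self.ratios.columns)


# ---------------------------------------------------------------------------
# pre-segmentation corrections


def correct_amplification(matrix: ProbeRatioMatrix) -> ProbeRatioMatrix:
    """Subtract the per-probe median of the amplified-normal controls.

    Whole-genome amplification distorts individual probes reproducibly; the
    same distortion appears in amplified normal-diploid DNA, so the per-probe
    median over controls estimates the bias and is subtracted from every
    tumour sample.  Control columns pass through unchanged.
    """
    if not matrix.control_samples:
        raise ValueError("amplification correction requires >=1 control sample")
    ctrl = matrix.ratios[list(matrix.control_samples)]
    bias = ctrl.median(axis=1)
    all_missing = ctrl.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} probes have no control values; "
            "correction 0 applied there",
            stacklevel=2,
        )
        bias = bias.fillna(0.0)
    out = matrix.ratios.copy()
    for s in matrix.tumour_samples:
        out[s] = out[s] - bias
    return replace(matrix, ratios=out, controls_consumed=True)


def center_median(matrix: ProbeRatioMatrix) -> ProbeRatioMatrix:
    """Centre every sample to a median log2 ratio of zero."""
    out = matrix.ratios.copy()
    for s in out.columns:
        med = out[s].median()
        if pd.isna(med):
            raise ValueError(f"sample {s!r} has no non-missing ratios")
        out[s] = out[s] - med
    return replace(matrix, ratios=out)


def combine_enzyme_sets(
    a: ProbeRatioMatrix, b: ProbeRatioMatrix
) -> ProbeRatioMatrix:
    """Merge the two restriction-enzyme array halves of each sample."""
    if set(a.samples) != set(b.samples):
        raise ValueError("enzyme-set matrices cover different samples")
    dup = set(a.probes["probe_id"]) & set(b.probes["probe_id"])
    if dup:
        raise ValueError(f"duplicate probe ids across enzyme sets: {sorted(dup)[:5]}")
    probes = pd.concat([a.probes, b.probes], ignore_index=True)
    ratios = pd.concat(
        [a.ratios, b.ratios[a.ratios.columns]], ignore_index=True
    )
    controls = tuple(dict.fromkeys(a.control_samples + b.control_samples))
    return ProbeRatioMatrix(probes=probes, ratios=ratios, control_samples=controls)


# ---------------------------------------------------------------------------
# circular binary segmentation


def _arc_t_stats(x: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Two-sample t statistics comparing arc x[i:j] with its complement.

    Uses the pooled within-group variance.  Arcs with zero pooled variance
    but a non-zero mean difference get +/-inf; fully constant windows get 0.
    """
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    q = np.concatenate([[0.0], np.cumsum(x * x)])
    k = (j - i).astype(float)
    m = n - k
    sum_arc = s[j] - s[i]
    m1 = sum_arc / k
    m2 = (s[n] - sum_arc) / m
    ss_within = q[n] - k * m1 * m1 - m * m2 * m2
    ss_within = np.maximum(ss_within, 0.0)
    dof = max(n - 2, 1)
    denom = np.sqrt((ss_within / dof) * (1.0 / k + 1.0 / m))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(np.abs(diff) > 1e-12, np.inf * np.sign(diff), 0.0))
    return t


def _candidate_arcs(n: int, min_width: int):
    """Index pairs (i, j) of candidate arcs x[i:j] honouring min_width.

    Every piece a split would produce (the arc and its flanks) must span at
    least ``min_width`` probes.
    """
    i, j = np.triu_indices(n + 1, k=1)
    k = j - i
    ok = (k >= min_width) & (k <= n - min_width)
    # interior arcs additionally need both flanks wide enough
    ok &= (i == 0) | (i >= min_width)
    ok &= (j == n) | (j <= n - min_width)
    return i[ok], j[ok]


def _max_abs_t(x: np.ndarray, i: np.ndarray, j: np.ndarray):
    t = np.abs(_arc_t_stats(x, i, j))
    a = int(np.argmax(t))
    return float(t[a]), int(i[a]), int(j[a])


def _test_split(x, alpha, n_perm, min_width, rng):
    """Permutation test for the best circular split of window ``x``.

    Returns the accepted cut indices (i, j) or None.  The p-value uses
    add-one smoothing, p = (1 + #{perm >= obs}) / (n_perm + 1), and the
    permutation loop stops early once significance is unreachable.
    """
    n = len(x)
    if n < 2 * min_width:
        return None
    i_idx, j_idx = _candidate_arcs(n, min_width)
    if len(i_idx) == 0:
        return None
    obs, bi, bj = _max_abs_t(x, i_idx, j_idx)
    if obs <= 0:
        return None
    allowed = int(math.floor(alpha * (n_perm + 1))) - 1
    if allowed < 0:
        return None
    exceed = 0
    xp = x.copy()
    for _ in range(n_perm):
        rng.shuffle(xp)
        tmax, _, _ = _max_abs_t(xp, i_idx, j_idx)
        if tmax >= obs - 1e-12:
            exceed += 1
            if exceed > allowed:
                return None
    return bi, bj


def segment_series(
    values: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 200,
    min_width: int = 2,
    rng: np.random.Generator | None = None,
) -> list:
    """Segment one ordered ratio series; returns [(start_idx, end_idx), ...].

    End indices are exclusive.  A series with fewer than two probes (or too
    short to split under ``min_width``) yields a single trivial segment.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(values, dtype=float)
    segs = []

    def recurse(lo: int, hi: int):
        cut = _test_split(x[lo:hi], alpha, n_perm, min_width, rng)
        if cut is None:
            segs.append((lo, hi))
            return
        i, j = cut
        bounds = sorted({0, i, j, hi - lo})
        for a, b in zip(bounds[:-1], bounds[1:]):
            recurse(lo + a, lo + b)

    if len(x) == 0:
        return []
    recurse(0, len(x))
    return sorted(segs)


def segment_cbs(
    matrix: ProbeRatioMatrix,
    alpha: float = 0.01,
    n_perm: int = 200,
    min_width: int = 2,
    seed: int = 0,
    samples=None,
) -> pd.DataFrame:
    """Circular binary segmentation of every (sample, chromosome) series.

    Each chromosome is recursively split at the arc maximising the circular
    two-sample t statistic; a split is kept when its within-window
    permutation p-value is <= ``alpha``.  Deterministic for a fixed seed
    regardless of sample order (child seeds are spawned per series).

    Returns a SEG-style DataFrame with columns
    sample, chrom, start, end, n_probes, seg_mean.
    """
    if samples is None:
        samples = matrix.tumour_samples
    chroms = list(dict.fromkeys(matrix.probes["chrom"]))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(samples) * len(chroms))
    rows = []
    idx = 0
    for sample in samples:
        for chrom in chroms:
            mask = (matrix.probes["chrom"] == chrom).to_numpy()
            pos = matrix.probes.loc[mask, "pos"].to_numpy()
            vals = matrix.ratios.loc[mask, sample].to_numpy(dtype=float)
            keep = ~np.isnan(vals)
            pos, vals = pos[keep], vals[keep]
            rng = np.random.default_rng(children[idx])
            idx += 1
            if len(vals) == 0:
                continue
            if len(vals) < 2:
                segs = [(0, len(vals))]
            else:
                segs = segment_series(vals, alpha, n_perm, min_width, rng)
            for lo, hi in segs:
                rows.append(
                    (
                        sample,
                        chrom,
                        int(pos[lo]),
                        int(pos[hi - 1]),
                        hi - lo,
                        float(np.mean(vals[lo:hi])),
                    )
                )
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


# ---------------------------------------------------------------------------
# gene-level assignment and calls


def assign_gene_values(segments: pd.DataFrame, annotation: pd.DataFrame) -> GeneCN:
    """Assign each gene the mean log2 ratio of its best-overlapping segment.

    The winning segment has the largest base-pair overlap with the gene;
    ties go to the segment containing the gene midpoint, then to the
    leftmost.  Genes overlapping no segment get a missing ratio.
    Coordinates are 1-based inclusive on both sides.
    """
    genes = annotation.index
    samples = list(dict.fromkeys(segments["sample"])) if len(segments) else []
    out = pd.DataFrame(np.nan, index=genes, columns=samples, dtype=float)
    if len(annotation) == 0 or len(segments) == 0:
        return GeneCN(ratios=out)
    g_chrom = annotation["chrom"].to_numpy()
    g_start = annotation["start"].to_numpy()
    g_end = annotation["end"].to_numpy()
    g_mid = (g_start + g_end) // 2
    for (sample, chrom), seg in segments.groupby(["sample", "chrom"], sort=False):
        gsel = np.flatnonzero(g_chrom == chrom)
        if len(gsel) == 0:
            continue
        s_start = seg["start"].to_numpy()
        s_end = seg["end"].to_numpy()
        s_mean = seg["seg_mean"].to_numpy()
        order = np.argsort(s_start)
        s_start, s_end, s_mean = s_start[order], s_end[order], s_mean[order]
        # overlap matrix genes x segments (few segments per chromosome)
        ov = np.maximum(
            0,
            np.minimum(g_end[gsel, None], s_end[None, :])
            - np.maximum(g_start[gsel, None], s_start[None, :])
            + 1,
        )
        best = np.zeros(len(gsel), dtype=int)
        for gi in range(len(gsel)):
            row = ov[gi]
            mx = row.max()
            if mx <= 0:
                best[gi] = -1
                continue
            cand = np.flatnonzero(row == mx)
            if len(cand) > 1:
                mid = g_mid[gsel[gi]]
                holds = cand[(s_start[cand] <= mid) & (mid <= s_end[cand])]
                cand = holds if len(holds) else cand
            best[gi] = cand[0]  # leftmost (segments sorted by start)
        vals = np.where(best >= 0, s_mean[np.clip(best, 0, None)], np.nan)
        out.loc[genes[gsel], sample] = vals
    return GeneCN(ratios=out)


def call_copy_status(
    genecn: GeneCN, thresholds: CNThresholds | None = None
) -> GeneCN:
    """Threshold assigned ratios into HOMDEL/DEL/NEUTRAL/GAIN/AMP calls.

    All comparisons are strict; a ratio exactly at a boundary stays NEUTRAL.
    Missing ratios become MISSING.
    """
    thr = thresholds or CNThresholds()
    r = genecn.ratios.to_numpy()
    status = np.full(r.shape, "NEUTRAL", dtype=object)
    status[r < thr.del_threshold] = "DEL"
    status[r < thr.homdel_threshold] = "HOMDEL"
    status[r > thr.gain_threshold] = "GAIN"
    status[r > thr.amp_threshold] = "AMP"
    status[np.isnan(r)] = "MISSING"
    status_df = pd.DataFrame(
        status, index=genecn.ratios.index, columns=genecn.ratios.columns
    )
    return GeneCN(ratios=genecn.ratios, status=status_df, thresholds=thr)


def deletion_frequency(genecn: GeneCN) -> pd.Series:
    """Per-gene count of samples called DEL or HOMDEL."""
    if genecn.status is None:
        raise ValueError("statuses not called; run call_copy_status first")
    return genecn.status.isin(["DEL", "HOMDEL"]).sum(axis=1)


def gain_frequency(genecn: GeneCN) -> pd.Series:
    """Per-gene count of samples called GAIN or AMP."""
    if genecn.status is None:
        raise ValueError("statuses not called; run call_copy_status first")
    return genecn.status.isin(["GAIN", "AMP"]).sum(axis=1)


def compute_concordance(status_a: pd.Series, status_b: pd.Series):
    """Fraction of genes with the same collapsed call in two call vectors.

    Statuses are collapsed to deleted / gained / normal before comparison
    (MISSING in either vector excludes the gene).  Returns
    (fraction, n_concordant, n_compared).
    """
    if not status_a.index.equals(status_b.index):
        if set(status_a.index) != set(status_b.index):
            raise ValueError("gene sets differ between call vectors")
        status_b = status_b.reindex(status_a.index)
    a = status_a.map(COLLAPSE)
    b = status_b.map(COLLAPSE)
    valid = a.notna() & b.notna()
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no genes with calls in both vectors")
    conc = int((a[valid] == b[valid]).sum())
    return conc / n, conc, n
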