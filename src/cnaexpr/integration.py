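"""Copy-number vs expression: per-gene rank correlation and call cross-tabs.

Across matched samples, each gene's assigned copy-number log2 ratio is
correlated with its expression signal by Spearman's rank correlation; the
cohort is then summarised by how many genes fall below a "well-correlated"
cutoff (default 0.65, strict inequality).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .copy_number import GeneCN

__all__ = [
    "spearman_rho",
    "correlate_all",
    "summarize_correlation",
    "crosstab_calls",
]

WELL_CORRELATED_CUTOFF = 0.65
MIN_PAIRS = 3


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors differ in length")
    if len(x) < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def correlate_all(
    genecn: GeneCN,
    signals: pd.DataFrame,
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-gene Spearman rho between assigned ratio and expression.

    Samples are matched by name; a gene is reported only when at least
    three samples have both a non-missing ratio and a signal (complete
    pairs, no imputation).  Returns a DataFrame indexed by gene with
    columns rho and n.
    """
    shared = [s for s in genecn.ratios.columns if s in signals.columns]
    if not shared:
        raise ValueError("no shared samples between copy number and expression")
    if genes is None:
        genes = genecn.ratios.index
    genes = pd.Index(genes).intersection(genecn.ratios.index).intersection(
        signals.index
    )
    r = genecn.ratios.loc[genes, shared].to_numpy()
    e = signals.loc[genes, shared].to_numpy()
    rows = []
    for gi, gene in enumerate(genes):
        ok = ~(np.isnan(r[gi]) | np.isnan(e[gi]))
        n = int(ok.sum())
        if n < MIN_PAIRS:
            continue
        rows.append((gene, spearman_rho(r[gi, ok], e[gi, ok]), n))
    return pd.DataFrame(rows, columns=["gene", "rho", "n"]).set_index("gene")


def summarize_correlation(
    records: pd.DataFrame, cutoff: float = WELL_CORRELATED_CUTOFF
) -> dict:
    """Count genes with rho strictly below the cutoff.

    NaN correlations (constant vectors) are excluded from both numerator
    and denominator and tallied separately.  Returns a dict with n_below,
    n_total, n_na and fraction.
    """
    if len(records) == 0:
        raise ValueError("no correlation records")
    rho = records["rho"]
    na = rho.isna()
    valid = rho[~na]
    n_below = int((valid < cutoff).sum())
    n_total = int(len(valid))
    return {
        "n_below": n_below,
        "n_total": n_total,
        "n_na": int(na.sum()),
        "fraction": n_below / n_total if n_total else float("nan"),
    }


def crosstab_calls(
    genecn: GeneCN,
    freq: pd.DataFrame,
    genes: pd.Index | None = None,
    k: int = 4,
) -> pd.DataFrame:
    """Cross-tabulate aberration against regulation over a gene set.

    A gene counts as "deleted" if called DEL/HOMDEL in >= 1 sample and as
    "down" if down-called in >= k tumours (default 4, i.e. the 25% tier of a
    16-tumour cohort); symmetrically for gained/up.  Returns a DataFrame
    with rows deleted/gained and columns changed/unchanged.
    """
    if genecn.status is None:
        raise ValueError("statuses not called")
    if genes is None:
        genes = genecn.status.index
    genes = pd.Index(genes).intersection(genecn.status.index).intersection(freq.index)
    deleted = genecn.status.loc[genes].isin(["DEL", "HOMDEL"]).any(axis=1)
    gained = genecn.status.loc[genes].isin(["GAIN", "AMP"]).any(axis=1)
    down = freq.loc[genes, "n_down"] >= k
    up = freq.loc[genes, "n_up"] >= k
    return pd.DataFrame(
        {
            "changed": [int((deleted & down).sum()), int((gained & up).sum())],
            "unchanged": [int((deleted & ~down).sum()), int((gained & ~up).sum())],
        },
        index=["deleted", "gained"],
    )
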