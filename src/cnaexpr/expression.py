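"""Per-tumour differential-expression calls and IHC validation scoring.

Cohort-mean comparisons miss changes confined to a few tumours, so each
tumour is compared individually against the mean of the normal samples:

* UP   — the tumour's detection call is present (P) and its signal exceeds
         ``fold`` times the mean of the normals;
* DOWN — the gene is present in *all* normals and the tumour signal is more
         than ``fold``-fold below the normal mean;
* NC   — otherwise.

Marginal (M) detection calls are treated as not-present.  The false-positive
rate of the rules is estimated from the normals alone by leave-one-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "call_regulation",
    "call_regulation_all",
    "summarize_frequency",
    "filter_changed",
    "estimate_fpr",
    "ihc_score",
    "ihc_log_ratio",
    "ihc_paired_test",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample signals with P/M/A detection calls and sample groups."""

    signals: pd.DataFrame
    calls: pd.DataFrame
    tumours: list
    normals: list

    def __post_init__(self):
        if (self.signals.to_numpy() < 0).any():
            raise ValueError("expression signals must be non-negative")
        if not self.signals.index.equals(self.calls.index) or list(
            self.signals.columns
        ) != list(self.calls.columns):
            raise ValueError("signals and calls must share genes and samples")
        both = set(self.tumours) & set(self.normals)
        if both:
            raise ValueError(f"samples in both groups: {sorted(both)}")
        missing = (set(self.tumours) | set(self.normals)) - set(self.signals.columns)
        if missing:
            raise ValueError(f"grouped samples absent from matrix: {sorted(missing)}")

    def rescale_to_target(self, target: float = 100.0) -> "ExpressionMatrix":
        """Globally rescale each sample so its trimmed mean signal is ``target``."""
        sig = self.signals.copy()
        for s in sig.columns:
            v = sig[s].to_numpy()
            lo, hi = np.percentile(v, [2, 98])
            trimmed = v[(v >= lo) & (v <= hi)]
            sig[s] = v * (target / trimmed.mean())
        return ExpressionMatrix(sig, self.calls, self.tumours, self.normals)


def _rule_calls(
    signal: np.ndarray,
    present: bool,
    normal_mean: np.ndarray | float,
    normals_all_present: np.ndarray | bool,
    fold: float,
) -> np.ndarray:
    up = present & (signal > fold * normal_mean)
    down = normals_all_present & (signal < normal_mean / fold)
    out = np.full(np.shape(signal), "NC", dtype=object)
    out[np.asarray(down)] = "DOWN"
    out[np.asarray(up)] = "UP"  # mutually exclusive by fold direction
    return out


def call_regulation(
    expr: ExpressionMatrix,
    gene: str,
    tumour: str,
    fold: float = 2.0,
    require_tumour_present_for_down: bool = False,
) -> str:
    """UP/DOWN/NC call for one gene in one tumour (see module docstring)."""
    if gene not in expr.signals.index:
        raise KeyError(f"unknown gene {gene!r}")
    if tumour not in expr.tumours:
        raise KeyError(f"unknown tumour sample {tumour!r}")
    table = call_regulation_all(
        expr, fold=fold,
        require_tumour_present_for_down=require_tumour_present_for_down,
    )
    return table.at[gene, tumour]


def call_regulation_all(
    expr: ExpressionMatrix,
    fold: float = 2.0,
    require_tumour_present_for_down: bool = False,
) -> pd.DataFrame:
    """UP/DOWN/NC calls for every gene in every tumour.

    ``require_tumour_present_for_down`` additionally demands a present call
    in the tumour for DOWN (off by default: the quoted rule conditions DOWN
    only on the normals).
    """
    if len(expr.normals) < 2:
        raise ValueError("calling requires >= 2 normal samples")
    nm = expr.signals[expr.normals].mean(axis=1).to_numpy()[:, None]
    all_p = (expr.calls[expr.normals] == "P").all(axis=1).to_numpy()[:, None]
    sig = expr.signals[expr.tumours].to_numpy()
    pres = (expr.calls[expr.tumours] == "P").to_numpy()
    up = pres & (sig > fold * nm)
    down = all_p & (sig < nm / fold)
    if require_tumour_present_for_down:
        down &= pres
    out = np.full(sig.shape, "NC", dtype=object)
    out[down] = "DOWN"
    out[up] = "UP"
    return pd.DataFrame(out, index=expr.signals.index, columns=expr.tumours)


def summarize_frequency(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts (n_up, n_nc, n_down) over tumours."""
    return pd.DataFrame(
        {
            "n_up": (table == "UP").sum(axis=1),
            "n_nc": (table == "NC").sum(axis=1),
            "n_down": (table == "DOWN").sum(axis=1),
        },
        index=table.index,
    )


def filter_changed(freq: pd.DataFrame, direction: str, k: int) -> pd.Index:
    """Genes changed in >= k tumours in the given direction ('up'/'down')."""
    col = {"up": "n_up", "down": "n_down"}[direction]
    n_tumours = int(freq[["n_up", "n_nc", "n_down"]].sum(axis=1).iloc[0]) if len(freq) else 0
    if k > n_tumours:
        warnings.warn(
            f"cutoff k={k} exceeds the {n_tumours} tumours; empty result",
            stacklevel=2,
        )
        return freq.index[:0]
    return freq.index[freq[col] >= k]


def estimate_fpr(expr: ExpressionMatrix, fold: float = 2.0):
    """False-positive rates of the call rules, from the normals alone.

    Leave-one-out: each normal in turn plays the tumour against the mean
    (and the all-present requirement) of the remaining normals.  Returns
    (fpr_up, fpr_down), each the fraction of gene x pseudo-tumour
    combinations called in that direction.
    """
    normals = expr.normals
    if len(normals) < 3:
        raise ValueError("FPR estimation needs >= 3 normals for leave-one-out")
    sig = expr.signals[normals].to_numpy()
    pres = (expr.calls[normals] == "P").to_numpy()
    n = len(normals)
    n_up = n_down = 0
    for j in range(n):
        rest = [i for i in range(n) if i != j]
        rest_mean = sig[:, rest].mean(axis=1)
        rest_all_p = pres[:, rest].all(axis=1)
        n_up += int((pres[:, j] & (sig[:, j] > fold * rest_mean)).sum())
        n_down += int((rest_all_p & (sig[:, j] < rest_mean / fold)).sum())
    denom = sig.shape[0] * n
    return n_up / denom, n_down / denom


# ---------------------------------------------------------------------------
# immunohistochemistry validation

_INTENSITIES = (0, 1, 2, 3)
_PROPORTION_CLASSES = (1, 2, 3)
IHC_CLAMP = 4.0


def ihc_score(intensity: int, proportion_class: int) -> int:
    """Semiquantitative IHC score: staining intensity x proportion class.

    Intensity: 0 negative, 1 weak, 2 moderate, 3 strong.  Proportion of
    positive cells: 1 (<=30%), 2 (30-70%), 3 (>70%).  Scores span 0-9.
    """
    if intensity not in _INTENSITIES:
        raise ValueError(f"intensity must be in {_INTENSITIES}")
    if proportion_class not in _PROPORTION_CLASSES:
        raise ValueError(f"proportion_class must be in {_PROPORTION_CLASSES}")
    return intensity * proportion_class


def ihc_log_ratio(tumour_score: float, normal_score: float) -> float:
    """log2(tumour/normal) IHC score ratio, clamped to +/-4 at zero scores.

    A zero score in exactly one member of the pair would give an infinite
    ratio; it is represented as +4 or -4.  Both zero -> NaN (undefined).
    """
    if tumour_score < 0 or normal_score < 0:
        raise ValueError("IHC scores are non-negative")
    if tumour_score == 0 and normal_score == 0:
        return float("nan")
    if normal_score == 0:
        return IHC_CLAMP
    if tumour_score == 0:
        return -IHC_CLAMP
    return float(np.log2(tumour_score / normal_score))


def ihc_paired_test(tumour_scores, normal_scores) -> float:
    """Exact two-sided Wilcoxon signed-rank p on paired IHC scores.

    Tied pairs (difference 0) are dropped; all-tied input returns NaN.
    """
    t = np.asarray(tumour_scores, dtype=float)
    n = np.asarray(normal_scores, dtype=float)
    if t.shape != n.shape:
        raise ValueError("paired score vectors differ in length")
    diff = t - n
    diff = diff[diff != 0]
    if len(diff) == 0:
        return float("nan")
    if len(diff) < 5:
        raise ValueError("need >= 5 informative (non-tied) pairs")
    return float(stats.wilcoxon(diff, alternative="two-sided", method="exact").pvalue)
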