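"""One-sided exact binomial enrichment of gene classes in selected sets.

Given a background universe of genes with copy-number information in which a
class (e.g. curated tumour-suppressor genes) occupies proportion p0, the
number of class members among n selected genes (deleted, gained,
homozygously deleted, or peak-resident) is tested against Binomial(n, p0)
with the upper-tail alternative "class over-represented".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassBackground",
    "binomial_enrichment",
    "frequency_profile",
    "per_sample_enrichment",
    "subset_enrichment",
    "fisher_crosscheck",
]


@dataclass(frozen=True)
class ClassBackground:
    """Class prevalence in the gene universe with copy-number data."""

    n_class: int
    n_total: int

    def __post_init__(self):
        if not (0 < self.n_class <= self.n_total):
            raise ValueError("need 0 < n_class <= n_total")

    @property
    def p0(self) -> float:
        return self.n_class / self.n_total


def binomial_enrichment(k: int, n: int, background: ClassBackground) -> float:
    """Exact upper-tail P(X >= k), X ~ Binomial(n, p0).

    Evaluated through the regularised incomplete beta function (scipy's
    survival function), which stays accurate far below 1e-15.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError(f"k must lie in [0, n]; got k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, background.p0))


def frequency_profile(
    counts: pd.Series,
    class_members: pd.Index,
    background: ClassBackground,
    cutoffs=range(5, 15),
) -> pd.DataFrame:
    """Enrichment rows across minimum-recurrence cutoffs.

    ``counts`` holds, per gene, the number of samples sharing the aberration;
    at each cutoff the selected set is the genes with count >= cutoff.
    Cutoffs selecting no genes are omitted with a warning.  Columns mirror
    the canonical frequency-profile table: cutoff, n_selected, n_class,
    fraction, p_value.
    """
    if len(counts) != background.n_total:
        raise ValueError(
            f"counts cover {len(counts)} genes but background universe has "
            f"{background.n_total}"
        )
    is_class = counts.index.isin(class_members)
    rows = []
    for cutoff in cutoffs:
        sel = counts >= cutoff
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"no genes at cutoff {cutoff}; row omitted", stacklevel=2)
            continue
        k = int((sel & is_class).sum())
        rows.append(
            (cutoff, n, k, k / n, binomial_enrichment(k, n, background))
        )
    return pd.DataFrame(
        rows, columns=["cutoff", "n_selected", "n_class", "fraction", "p_value"]
    )


def per_sample_enrichment(
    status: pd.DataFrame,
    class_members: pd.Index,
    background: ClassBackground,
    direction: str = "loss",
    alpha: float = 0.05,
):
    """Per-sample test: are class genes over-represented among that
    sample's aberrant genes?

    ``direction`` 'loss' selects DEL/HOMDEL calls, 'gain' selects GAIN/AMP.
    Returns (DataFrame indexed by sample with k, n, p_value, significant;
    count of significant samples at ``alpha``).
    """
    sel_statuses = {"loss": ("DEL", "HOMDEL"), "gain": ("GAIN", "AMP")}[direction]
    is_class = status.index.isin(class_members)
    rows = []
    for sample in status.columns:
        aberrant = status[sample].isin(sel_statuses).to_numpy()
        n = int(aberrant.sum())
        if n == 0:
            warnings.warn(f"sample {sample} has no {direction} calls; p=1",
                          stacklevel=2)
            rows.append((sample, 0, 0, 1.0))
            continue
        k = int((aberrant & is_class).sum())
        rows.append((sample, k, n, binomial_enrichment(k, n, background)))
    out = pd.DataFrame(rows, columns=["sample", "k", "n", "p_value"]).set_index("sample")
    out["significant"] = out["p_value"] < alpha
    return out, int(out["significant"].sum())


def subset_enrichment(
    selected: pd.Index, class_members: pd.Index, background: ClassBackground
):
    """Class fraction and upper-tail binomial p for one selected gene set.

    Used for recurrent-peak gene sets and homozygous-deletion sets.
    Returns (fraction, p_value, k, n).
    """
    n = len(selected)
    if n == 0:
        raise ValueError("selected gene set is empty")
    k = int(pd.Index(selected).isin(class_members).sum())
    return k / n, binomial_enrichment(k, n, background), k, n


def fisher_crosscheck(k: int, n: int, background: ClassBackground) -> float:
    """One-sided Fisher exact p for the same 2x2 table (sanity cross-check).

    Not the headline statistic; the binomial test conditions only on the
    background proportion, Fisher on both margins.
    """
    table = [
        [k, n - k],
        [background.n_class - k, (background.n_total - background.n_class) - (n - k)],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])
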