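"""Absolute genomic copy number from qPCR standard curves.

Ct is linear in log10 of starting template copies.  A calibrator dilution
series (10..1e5 gene copies, from the convention that one diploid cell
contains 6.6 pg of DNA) yields a least-squares standard curve per target;
unknown Ct values are inverted through the curve and normalised to a
diploid reference locus (CYP7A1 by default in plate workflows).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardCurve",
    "MassConvention",
    "fit_standard_curve",
    "ct_to_copies",
    "normalize_to_reference",
    "copies_from_mass",
    "quantify_plate",
]

#: Slope window corresponding to 90-110% amplification efficiency.
GOOD_SLOPE_RANGE = (-3.6, -3.1)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Ct = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency; 1.0 means perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class MassConvention:
    """DNA mass to locus-copy conversion constants."""

    pg_per_diploid_cell: float = 6.6
    copies_per_cell_per_locus: float = 2.0

    def __post_init__(self):
        if self.pg_per_diploid_cell <= 0 or self.copies_per_cell_per_locus <= 0:
            raise ValueError("mass-convention constants must be positive")


def fit_standard_curve(copies, ct) -> StandardCurve:
    """Fit the standard curve from calibrator (copies, Ct) pairs.

    Requires at least three distinct dilution levels with determined Ct.
    Warns when the slope falls outside the 90-110% efficiency window or is
    non-negative (invalid curve).
    """
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    ok = ~np.isnan(ct)
    if not ok.any():
        raise ValueError("no determined Ct values in the dilution series")
    copies, ct = copies[ok], ct[ok]
    if len(np.unique(copies)) < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    x = np.log10(copies)
    slope, intercept = np.polyfit(x, ct, 1)
    pred = intercept + slope * x
    ss_res = float(np.sum((ct - pred) ** 2))
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope >= -1e-9:
        slope = 0.0 if abs(slope) < 1e-9 else slope
        warnings.warn(
            f"non-negative standard-curve slope {slope:.3f}: curve invalid",
            stacklevel=2,
        )
    elif not (GOOD_SLOPE_RANGE[0] <= slope <= GOOD_SLOPE_RANGE[1]):
        warnings.warn(
            f"slope {slope:.3f} outside {GOOD_SLOPE_RANGE} "
            "(efficiency outside 90-110%)",
            stacklevel=2,
        )
    return StandardCurve(float(slope), float(intercept), r2)


def ct_to_copies(curve: StandardCurve, ct):
    """Invert the standard curve: copies = 10**((Ct - intercept)/slope).

    NaN (undetermined) Ct propagates as NaN.  Accepts scalars or arrays.
    """
    if curve.slope >= 0:
        raise ValueError("cannot invert a curve with non-negative slope")
    ct_arr = np.asarray(ct, dtype=float)
    out = 10.0 ** ((ct_arr - curve.intercept) / curve.slope)
    if np.isscalar(ct) or ct_arr.ndim == 0:
        return float(out)
    return out


def normalize_to_reference(
    target_copies: float, reference_copies: float, reference_ploidy: float = 2.0
) -> float:
    """Copy-number estimate: reference_ploidy x target / reference.

    Any common multiplicative bias (input mass, amplification) cancels.
    NA or zero reference gives NaN with a warning.
    """
    if target_copies is None or (isinstance(target_copies, float) and math.isnan(target_copies)):
        return float("nan")
    if not reference_copies or (
        isinstance(reference_copies, float) and math.isnan(reference_copies)
    ):
        warnings.warn("reference copies missing or zero; estimate undefined",
                      stacklevel=2)
        return float("nan")
    return reference_ploidy * target_copies / reference_copies


def copies_from_mass(mass_pg: float, convention: MassConvention | None = None) -> float:
    """Expected autosomal locus copies in a given mass of genomic DNA."""
    conv = convention or MassConvention()
    if mass_pg < 0:
        raise ValueError("mass must be >= 0")
    return conv.copies_per_cell_per_locus * mass_pg / conv.pg_per_diploid_cell


def quantify_plate(
    plate: pd.DataFrame,
    reference: str = "CYP7A1",
    average_scale: str = "ct",
) -> pd.DataFrame:
    """Per-sample, per-target copy-number estimates from one plate table.

    Expects columns sample, target, replicate, Ct, calibrator_copies with
    the calibrator series rows under sample == 'calibrator'.  Duplicates are
    averaged on the Ct scale by default (geometric mean of copies);
    ``average_scale='copies'`` averages after conversion instead.  Each
    target's estimate is normalised to the same sample's ``reference``
    locus.  Returns DataFrame (sample, target, copies, copy_number).
    """
    if average_scale not in ("ct", "copies"):
        raise ValueError("average_scale must be 'ct' or 'copies'")
    curves = {}
    cal = plate[plate["sample"] == "calibrator"]
    for target, grp in cal.groupby("target"):
        curves[target] = fit_standard_curve(
            grp["calibrator_copies"].to_numpy(), grp["Ct"].to_numpy()
        )
    unk = plate[plate["sample"] != "calibrator"]
    rows = []
    for (sample, target), grp in unk.groupby(["sample", "target"]):
        if target not in curves:
            raise ValueError(f"no calibrator series for target {target!r}")
        ct = grp["Ct"].to_numpy(dtype=float)
        if average_scale == "ct":
            mean_ct = float(np.nanmean(ct)) if (~np.isnan(ct)).any() else float("nan")
            copies = ct_to_copies(curves[target], mean_ct) if not math.isnan(mean_ct) else float("nan")
        else:
            per_well = ct_to_copies(curves[target], ct)
            copies = float(np.nanmean(per_well))
        rows.append((sample, target, copies))
    out = pd.DataFrame(rows, columns=["sample", "target", "copies"])
    ref = out[out["target"] == reference].set_index("sample")["copies"]
    cn = []
    for _, row in out.iterrows():
        r = ref.get(row["sample"], float("nan"))
        cn.append(normalize_to_reference(row["copies"], r))
    out["copy_number"] = cn
    return out
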