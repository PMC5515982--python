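"""Urinary-dilution adjustments and the hair-pigmentation slope analysis.

Urinary concentrations depend on how dilute the urine is; two standard
corrections are compared against the raw concentration by their squared
Pearson correlation with the exposure rate:

* volume adjustment — concentration (ng/mL) × 24-h urine volume (mL) gives
  the amount excreted over 24 h (ng);
* creatinine adjustment — concentration / urinary creatinine (mg/mL) gives
  ng per mg creatinine.

Pigmentation: white and pigmented hair from the same animal are regressed
(white on black, through the origin by default); a slope close to 1
indicates that melanin content has little influence on incorporation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .association import pearson, select_for_association
from .study import AnimalCovariates, ConcentrationTable, StudyDesign, StudyError

__all__ = [
    "AdjustmentComparison",
    "PigmentationFit",
    "amount_24h",
    "creatinine_adjust",
    "compare_adjustments",
    "pigmentation_slope",
]


@dataclass(frozen=True)
class AdjustmentComparison:
    compound: str
    status: str  # ok | NA | ND
    r2_unadjusted: float | None = None
    r2_volume_adjusted: float | None = None
    r2_creatinine_adjusted: float | None = None

    def direction(self, which: str) -> str | None:
        """'improved' or 'worsened' for adjustment ``which`` vs raw."""
        adj = {
            "volume": self.r2_volume_adjusted,
            "creatinine": self.r2_creatinine_adjusted,
        }[which]
        if adj is None or self.r2_unadjusted is None:
            return None
        return "improved" if adj >= self.r2_unadjusted else "worsened"


@dataclass(frozen=True)
class PigmentationFit:
    compound: str
    slope_white_vs_black: float
    n_pairs: int


def amount_24h(concentration, volume):
    """ng excreted over 24 h = concentration (ng/mL) × volume (mL)."""
    c = np.asarray(concentration, dtype=float)
    v = np.asarray(volume, dtype=float)
    if np.any(c <= 0) or np.any(v <= 0):
        raise StudyError("amount_24h needs positive concentration and volume")
    out = c * v
    return float(out) if out.ndim == 0 else out


def creatinine_adjust(concentration, creatinine):
    """ng per mg creatinine = concentration (ng/mL) / creatinine (mg/mL)."""
    c = np.asarray(concentration, dtype=float)
    k = np.asarray(creatinine, dtype=float)
    if np.any(k <= 0):
        raise StudyError("creatinine must be positive")
    out = c / k
    return float(out) if out.ndim == 0 else out


def compare_adjustments(
    table: ConcentrationTable,
    covariates: Sequence[AnimalCovariates],
    compound: str,
    design: StudyDesign,
) -> AdjustmentComparison:
    """Squared dose correlation of raw vs volume- vs creatinine-adjusted
    urinary values.

    All three r² use the same detected-only inclusion rule as the
    association statistics, so the comparison is not confounded with a
    change of sample set.  NA/ND statuses propagate.
    """
    detected, status, _ = select_for_association(table, compound, "urine")
    if status != "ok":
        return AdjustmentComparison(compound, status)
    cov = pd.DataFrame(
        {
            "animal_id": [c.animal_id for c in covariates],
            "volume": [c.urine_volume_24h for c in covariates],
            "creatinine": [c.creatinine for c in covariates],
        }
    )
    merged = detected.merge(cov, on="animal_id", how="left")
    if merged["volume"].isna().any():
        missing = merged.loc[merged["volume"].isna(), "animal_id"].iloc[0]
        raise StudyError(f"no covariates for animal {missing}")
    rate = np.asarray(design.exposure_rate(merged["dose"].to_numpy()))
    raw = merged["value"].to_numpy()
    r2 = lambda y: pearson(rate, y)[0] ** 2
    return AdjustmentComparison(
        compound,
        "ok",
        r2_unadjusted=r2(raw),
        r2_volume_adjusted=r2(amount_24h(raw, merged["volume"].to_numpy())),
        r2_creatinine_adjusted=r2(
            creatinine_adjust(raw, merged["creatinine"].to_numpy())
        ),
    )


def pigmentation_slope(
    black: Sequence[float],
    white: Sequence[float],
    compound: str = "",
    through_origin: bool = True,
) -> PigmentationFit:
    """Least-squares slope of white-hair on black-hair concentration.

    Origin-forced by default: two measurements of the same analyte in the
    same animal have no physical intercept.  ``through_origin=False`` fits
    an ordinary line and reports its slope.
    """
    b = np.asarray(black, dtype=float)
    w = np.asarray(white, dtype=float)
    if len(b) < 3:
        raise StudyError("pigmentation fit needs >= 3 pairs")
    if np.any(b <= 0) or np.any(w <= 0):
        raise StudyError("pigmentation pairs must be positive")
    if through_origin:
        slope = float(b @ w / (b @ b))
    else:
        bc = b - b.mean()
        slope = float(bc @ (w - w.mean()) / (bc @ bc))
    return PigmentationFit(compound, slope, len(b))
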