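"""Dose-concentration association per compound and matrix.

For every analyte in every matrix the pipeline reports the slope of an
ordinary least-squares line of concentration on exposure rate (mg/kg per
day), the Pearson product-moment correlation (with its two-sided p-value),
and the Spearman rank correlation (midranks for ties, which are pervasive
because doses repeat within groups).

Inclusion rules:

* only *detected* records enter (non-detects are never imputed here);
  control animals therefore contribute exactly when the compound was
  detected in them;
* the statistics are not computed when the compound was detected in fewer
  than four dose levels (status ``NA``), or never (status ``ND``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study import CompoundSpec, ConcentrationTable, StudyDesign, StudyError

__all__ = [
    "AssociationResult",
    "select_for_association",
    "fit_slope",
    "pearson",
    "spearman",
    "summarize_associations",
    "associations_frame",
]

MIN_LEVELS = 4  # dose levels with detection required for association


@dataclass(frozen=True)
class AssociationResult:
    """One Table-style row: association statistics for compound × matrix."""

    compound: str
    matrix: str
    status: str  # ok | NA | ND
    slope: float | None = None          # matrix units per (mg/kg per day)
    r_pearson: float | None = None
    p_pearson: float | None = None
    r_spearman: float | None = None
    n_used: int = 0
    levels_detected: int = 0
    concentration_range: tuple[float, float] | None = None  # group means


def select_for_association(
    table: ConcentrationTable, compound: str, matrix: str
) -> tuple[pd.DataFrame, str, int]:
    """Apply the detected-only inclusion rule.

    Returns ``(subset, status, levels_detected)`` where ``subset`` holds all
    detected records for the compound/matrix (controls included iff detected
    in controls — which the detected-only rule enforces by construction),
    ``status`` is ``ok``/``NA``/``ND`` and ``levels_detected`` counts dose
    levels with at least one detected animal.
    """
    sub = table.subset(compound, matrix)
    detected = sub[sub["detected"]]
    levels = int(detected["dose"].nunique())
    if len(detected) == 0:
        return detected, "ND", 0
    if levels < MIN_LEVELS:
        return detected, "NA", levels
    return detected, "ok", levels


def fit_slope(rate: np.ndarray, conc: np.ndarray) -> float:
    """OLS slope of concentration on exposure rate, intercept included."""
    rate = np.asarray(rate, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(rate) < 2 or np.ptp(rate) == 0:
        raise StudyError("slope undefined: need >= 2 distinct exposure values")
    xc = rate - rate.mean()
    return float(xc @ (conc - conc.mean()) / (xc @ xc))


def pearson(rate: np.ndarray, conc: np.ndarray) -> tuple[float, float]:
    """Product-moment r and two-sided p (t distribution, n-2 df)."""
    rate = np.asarray(rate, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(rate) < 3:
        raise StudyError("pearson undefined: need n >= 3")
    if np.ptp(rate) == 0 or np.ptp(conc) == 0:
        raise StudyError("pearson undefined: zero variance")
    res = stats.pearsonr(rate, conc)
    return float(res.statistic), float(res.pvalue)


def spearman(rate: np.ndarray, conc: np.ndarray) -> float:
    """Spearman rank correlation with midranks for ties."""
    rate = np.asarray(rate, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(rate) < 3:
        raise StudyError("spearman undefined: need n >= 3")
    r_rate = stats.rankdata(rate)
    r_conc = stats.rankdata(conc)
    if np.ptp(r_rate) == 0 or np.ptp(r_conc) == 0:
        raise StudyError("spearman undefined: zero rank variance")
    return float(stats.spearmanr(rate, conc).statistic)


def _group_mean_range(detected: pd.DataFrame) -> tuple[float, float]:
    means = detected.groupby("dose")["value"].mean()
    return float(means.min()), float(means.max())


def summarize_associations(
    table: ConcentrationTable,
    registry: Sequence[CompoundSpec],
    design: StudyDesign,
) -> list[AssociationResult]:
    """One :class:`AssociationResult` per registry compound × table matrix.

    The concentration range reports the smallest and largest *group mean*
    over detected values.  The input table must not be ½-LOD-imputed.
    """
    results = []
    matrices = table.matrices
    for spec in registry:
        for matrix in matrices:
            if len(table.subset(spec.name, matrix)) == 0:
                continue
            detected, status, levels = select_for_association(
                table, spec.name, matrix
            )
            if status != "ok":
                rng = _group_mean_range(detected) if len(detected) else None
                results.append(
                    AssociationResult(
                        spec.name,
                        matrix,
                        status,
                        n_used=len(detected),
                        levels_detected=levels,
                        concentration_range=rng,
                    )
                )
                continue
            rate = np.asarray(design.exposure_rate(detected["dose"].to_numpy()))
            conc = detected["value"].to_numpy()
            slope = fit_slope(rate, conc)
            r_p, p_p = pearson(rate, conc)
            r_s = spearman(rate, conc)
            results.append(
                AssociationResult(
                    spec.name,
                    matrix,
                    "ok",
                    slope=slope,
                    r_pearson=r_p,
                    p_pearson=p_p,
                    r_spearman=r_s,
                    n_used=len(detected),
                    levels_detected=levels,
                    concentration_range=_group_mean_range(detected),
                )
            )
    return results


def associations_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.concentration_range or (np.nan, np.nan)
        rows.append(
            {
                "compound": r.compound,
                "matrix": r.matrix,
                "status": r.status,
                "slope": r.slope if r.slope is not None else np.nan,
                "r_pearson": r.r_pearson if r.r_pearson is not None else np.nan,
                "p_pearson": r.p_pearson if r.p_pearson is not None else np.nan,
                "r_spearman": r.r_spearman if r.r_spearman is not None else np.nan,
                "n_used": r.n_used,
                "levels_detected": r.levels_detected,
                "range_low": lo,
                "range_high": hi,
            }
        )
    return pd.DataFrame(rows)
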