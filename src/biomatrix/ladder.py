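"""Sequential inter-group difference testing ("the ladder").

Each pairwise comparison uses a pooled-variance t test when both groups pass
Shapiro-Wilk normality and a median-centered Levene equal-variance test (all
at the 0.05 gate), and a two-sided Mann-Whitney rank-sum test otherwise.
Concentrations are expected ½-LOD-imputed so every animal contributes.

The walk maintains a reference group.  Top-down it starts at the highest
dose and tests against the next lower group: a significant difference is
recorded as a bracket and the reference moves down to that group; a
non-significant one keeps the reference and skips to the next lower group.
The procedure is then re-applied down-top starting from the control group,
and the two passes are merged (per pair, the smaller p is kept) so that all
groups are covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .study import ConcentrationTable, StudyDesign, StudyError

__all__ = ["Comparison", "LadderResult", "compare_two_groups", "run_ladder"]

GATE_ALPHA = 0.05       # Shapiro-Wilk / Levene gate for the t-test branch
MARGINAL_UPPER = 0.10   # "p slightly greater than 0.05" band


@dataclass(frozen=True)
class Comparison:
    dose_high: float
    dose_low: float
    test_used: str  # "t" | "mann_whitney"
    p: float
    category: str   # "significant" | "marginal" | "ns"

    @property
    def stars(self) -> str:
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


@dataclass
class LadderResult:
    compound: str
    matrix: str
    alpha: float
    comparisons: list[Comparison] = field(default_factory=list)

    @property
    def brackets(self) -> list[Comparison]:
        """The significant comparisons (the figure's bracket annotations)."""
        return [c for c in self.comparisons if c.category == "significant"]


def _categorize(p: float, alpha: float) -> str:
    if p <= alpha:
        return "significant"
    if p <= MARGINAL_UPPER:
        return "marginal"
    return "ns"


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    gate: float = GATE_ALPHA,
    force_test: str | None = None,
) -> tuple[str, float]:
    """Two-sided two-sample test with automatic parametric/nonparametric
    selection.

    Returns ``(test_used, p)``.  The t branch requires both groups to pass
    Shapiro-Wilk at ``gate`` and the pair to pass a median-centered Levene
    test at ``gate``; a zero-variance group cannot be tested for normality
    and falls through to Mann-Whitney.  ``force_test`` ("t" or
    "mann_whitney") bypasses the gate, for deterministic fixtures.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise StudyError("each group needs >= 3 values")

    if force_test == "t":
        return "t", float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if force_test is None:
        use_t = True
        for g in (a, b):
            if np.ptp(g) == 0:
                use_t = False
                break
            if stats.shapiro(g).pvalue < gate:
                use_t = False
                break
        if use_t and stats.levene(a, b, center="median").pvalue < gate:
            use_t = False
        if use_t:
            return "t", float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    elif force_test != "mann_whitney":
        raise StudyError(f"unknown force_test {force_test!r}")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # all observations tied: zero rank variance, no evidence of difference
        return "mann_whitney", 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return "mann_whitney", float(res.pvalue)


def _walk(
    groups: dict[float, np.ndarray],
    order: list[float],
    alpha: float,
    force_test: str | None,
) -> list[Comparison]:
    """One pass of the ladder along ``order`` (reference starts at order[0])."""
    out = []
    ref = order[0]
    for nxt in order[1:]:
        test, p = compare_two_groups(groups[ref], groups[nxt], force_test=force_test)
        hi, lo = (ref, nxt) if ref > nxt else (nxt, ref)
        out.append(Comparison(hi, lo, test, p, _categorize(p, alpha)))
        if p <= alpha:
            ref = nxt
    return out


def run_ladder(
    table: ConcentrationTable,
    compound: str,
    matrix: str,
    design: StudyDesign,
    alpha: float = 0.05,
    force_test: str | None = None,
) -> LadderResult:
    """Run both ladder passes and merge their comparisons.

    The table must be ½-LOD-imputed (every record carries a value).  Pairs
    tested in both passes are deduplicated keeping the smaller p.
    """
    sub = table.subset(compound, matrix)
    groups: dict[float, np.ndarray] = {}
    for dose in design.dose_levels:
        vals = sub.loc[sub["dose"] == dose, "value"].to_numpy(dtype=float)
        if len(vals) == 0:
            raise StudyError(
                f"{compound}/{matrix}: no records for dose group {dose}"
            )
        if np.isnan(vals).any():
            raise StudyError(
                f"{compound}/{matrix}: non-imputed non-detects in group {dose}"
            )
        groups[dose] = vals

    top_down = _walk(groups, sorted(groups, reverse=True), alpha, force_test)
    down_top = _walk(groups, sorted(groups), alpha, force_test)

    merged: dict[tuple[float, float], Comparison] = {}
    for comp in top_down + down_top:
        key = (comp.dose_high, comp.dose_low)
        if key not in merged or comp.p < merged[key].p:
            merged[key] = comp
    ordered = sorted(merged.values(), key=lambda c: (-c.dose_high, -c.dose_low))
    return LadderResult(compound, matrix, alpha, ordered)
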