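"""Reverse Classification Analysis (RCA).

RCA asks: if we pick a handful of animals at random and rank them by their
measured concentration in one matrix, how often does that ranking reproduce
their true exposure ordering?  Formally, for a random subset of
``subset_size`` animals sorted ascending by concentration, the
classification is *correct* when the corresponding dose sequence is
non-decreasing — animals sharing a dose may appear in any relative order.
The percentage of correct classifications over many random subsets is the
RCA score; higher scores mean the matrix orders individuals by exposure
more reliably.

Two routes are provided: a Monte-Carlo estimate (:func:`rca_score`, the
production statistic, default 10,000 iterations) and an exact enumeration
over all subsets (:func:`rca_exact`) that serves as its oracle at small n.

Concentration ties (possible after ½-LOD imputation) are scored
*optimistically* by default: a subset counts as correct if some ordering of
each tied block is dose-non-decreasing, the natural analogue of the
dose-equality allowance.  ``tie_policy="pessimistic"`` requires every
ordering to work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .censoring import build_detection_matrix
from .study import ConcentrationTable, StudyDesign, StudyError

__all__ = ["RCAResult", "is_correct_classification", "rca_score", "rca_exact"]

MIN_LEVELS = 4       # dose groups with detection required to run RCA
EXACT_LIMIT = 10**6  # largest subset count rca_exact will enumerate


@dataclass(frozen=True)
class RCAResult:
    compound: str
    matrix: str
    status: str  # "ok" | "not_conducted"
    percent_correct: float | None = None  # in [0, 100]
    mc_se: float | None = None            # Monte-Carlo standard error, % points
    n_iterations: int = 0
    subset_size: int = 5
    seed: int | None = None


def is_correct_classification(dose_sequence: Sequence[float]) -> bool:
    """True iff doses ordered by ascending concentration are non-decreasing.

    Equal doses in adjacent positions are allowed: animals at the same
    exposure level cannot be mis-ordered relative to each other.
    """
    seq = np.asarray(dose_sequence, dtype=float)
    return bool(np.all(np.diff(seq) >= 0))


def _tie_sorted_doses(
    conc: np.ndarray, dose: np.ndarray, idx: np.ndarray, tie_policy: str
) -> np.ndarray:
    """Dose sequences for each row of subset indices ``idx`` after sorting by
    concentration, resolving concentration ties per ``tie_policy``.

    Optimistic: tied values are ordered dose-ascending (if any tied ordering
    is non-decreasing, this one is).  Pessimistic: dose-descending (if this
    ordering is non-decreasing, all are).
    """
    c = conc[idx]
    d = dose[idx]
    key = d if tie_policy == "optimistic" else -d
    # two stable argsorts: final order = by concentration, ties by key
    o1 = np.argsort(key, axis=-1, kind="stable")
    c1 = np.take_along_axis(c, o1, axis=-1)
    d1 = np.take_along_axis(d, o1, axis=-1)
    o2 = np.argsort(c1, axis=-1, kind="stable")
    return np.take_along_axis(d1, o2, axis=-1)


def _pooled_values(
    table: ConcentrationTable, compound: str, matrix: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = table.subset(compound, matrix)
    sub = sub[sub["value"].notna()]
    return sub["value"].to_numpy(dtype=float), sub["dose"].to_numpy(dtype=float)


def _eligible(
    table: ConcentrationTable, compound: str, matrix: str, design: StudyDesign
) -> bool:
    dm = build_detection_matrix(table, design)
    return dm.levels_detected(compound, matrix) >= MIN_LEVELS


def rca_score(
    table: ConcentrationTable,
    compound: str,
    matrix: str,
    design: StudyDesign,
    subset_size: int = 5,
    iterations: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    tie_policy: str = "optimistic",
    stratified: bool = False,
) -> RCAResult:
    """Monte-Carlo RCA score for one compound in one matrix.

    The table must be ½-LOD-imputed (animals lacking a value for the
    compound/matrix are excluded before sampling).  ``not_conducted`` is
    returned when the compound is detected in fewer than four dose groups.
    Sampling is uniform without replacement over all animals pooled across
    groups; ``stratified=True`` instead draws ``subset_size`` distinct dose
    groups and one animal from each.  Identical seeds reproduce results
    exactly.
    """
    if tie_policy not in ("optimistic", "pessimistic"):
        raise StudyError(f"unknown tie_policy {tie_policy!r}")
    if not _eligible(table, compound, matrix, design):
        return RCAResult(
            compound, matrix, "not_conducted",
            n_iterations=iterations, subset_size=subset_size,
            seed=seed if isinstance(seed, int) else None,
        )
    conc, dose = _pooled_values(table, compound, matrix)
    n = len(conc)
    if n < subset_size:
        raise StudyError(
            f"{compound}/{matrix}: {n} animals < subset size {subset_size}"
        )
    rng = np.random.default_rng(seed)
    if stratified:
        levels = np.unique(dose)
        if len(levels) < subset_size:
            raise StudyError("stratified sampling needs >= subset_size dose groups")
        idx = np.empty((iterations, subset_size), dtype=np.intp)
        by_level = [np.flatnonzero(dose == lv) for lv in levels]
        for it in range(iterations):
            chosen = rng.choice(len(levels), size=subset_size, replace=False)
            idx[it] = [by_level[g][rng.integers(len(by_level[g]))] for g in chosen]
    else:
        # vectorized sampling without replacement: first k of a random order
        keys = rng.random((iterations, n))
        idx = np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]
    doses_sorted = _tie_sorted_doses(conc, dose, idx, tie_policy)
    correct = np.all(np.diff(doses_sorted, axis=1) >= 0, axis=1)
    p = float(correct.mean())
    return RCAResult(
        compound,
        matrix,
        "ok",
        percent_correct=100.0 * p,
        mc_se=100.0 * math.sqrt(p * (1.0 - p) / iterations),
        n_iterations=iterations,
        subset_size=subset_size,
        seed=seed if isinstance(seed, int) else None,
    )


def rca_exact(
    table: ConcentrationTable,
    compound: str,
    matrix: str,
    design: StudyDesign,
    subset_size: int = 5,
    tie_policy: str = "optimistic",
) -> float:
    """Exact RCA probability by enumerating every animal subset.

    Oracle for :func:`rca_score`: same value selection, eligibility, and tie
    policy, but the probability is the exact fraction of all
    ``C(N, subset_size)`` subsets that classify correctly.  Refuses inputs
    with more than 10^6 subsets (use the Monte-Carlo estimate there).
    """
    if tie_policy not in ("optimistic", "pessimistic"):
        raise StudyError(f"unknown tie_policy {tie_policy!r}")
    if not _eligible(table, compound, matrix, design):
        raise StudyError(f"{compound}/{matrix}: detected in < {MIN_LEVELS} groups")
    conc, dose = _pooled_values(table, compound, matrix)
    n = len(conc)
    if n < subset_size:
        raise StudyError(f"{n} animals < subset size {subset_size}")
    n_subsets = math.comb(n, subset_size)
    if n_subsets > EXACT_LIMIT:
        raise StudyError(
            f"C({n},{subset_size}) = {n_subsets} subsets exceeds the "
            f"enumeration bound; use rca_score (Monte Carlo)"
        )
    idx = np.fromiter(
        (i for comb in combinations(range(n), subset_size) for i in comb),
        dtype=np.intp,
        count=n_subsets * subset_size,
    ).reshape(n_subsets, subset_size)
    doses_sorted = _tie_sorted_doses(conc, dose, idx, tie_policy)
    correct = np.all(np.diff(doses_sorted, axis=1) >= 0, axis=1)
    return float(correct.mean())
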