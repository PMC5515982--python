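"""Dose-response association: selection rules, slope, and correlations."""

import math

import numpy as np
import pytest

from biomatrix.association import (
    fit_slope,
    pearson,
    select_for_association,
    spearman,
    summarize_associations,
)
from biomatrix.simulate import SimulationConfig, generate_study
from biomatrix.study import CompoundSpec, SimParams, StudyDesign, StudyError
from conftest import make_table

# hand-computed on the 4-point fixture (T,c) = (0,1),(1,2),(2,2),(4,5):
# Sxy=8.5, Sxx=8.75, Syy=9 -> slope = 34/35, r = 8.5/sqrt(8.75*9)
FOUR_POINT_T = np.array([0.0, 1.0, 2.0, 4.0])
FOUR_POINT_C = np.array([1.0, 2.0, 2.0, 5.0])
FOUR_POINT_SLOPE = 34.0 / 35.0
FOUR_POINT_R = 8.5 / math.sqrt(8.75 * 9.0)


def midrank_oracle(values):
    """Midranks by direct enumeration: 1 + #smaller + (#equal - 1)/2."""
    return np.array(
        [
            1.0
            + sum(1 for u in values if u < x)
            + (sum(1 for u in values if u == x) - 1) / 2.0
            for x in values
        ]
    )


def pearson_oracle(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float(x @ y / math.sqrt((x @ x) * (y @ y)))


class TestSelection:
    def _table(self, detected_doses, registry):
        # 5-level design, 2 animals/group; 'cpd' detected only at given doses
        records = []
        for gi, dose in enumerate((0, 1, 2, 3, 4)):
            for ai in range(2):
                val = 1.0 + dose if dose in detected_doses else None
                records.append((f"g{gi}a{ai}", dose, "hair", "cpd", val))
        return make_table(records, registry)

    def test_three_levels_is_na(self, registry):
        t = self._table({2, 3, 4}, registry)
        _, status, levels = select_for_association(t, "cpd", "hair")
        assert status == "NA" and levels == 3

    def test_four_levels_is_ok(self, registry):
        t = self._table({1, 2, 3, 4}, registry)
        _, status, levels = select_for_association(t, "cpd", "hair")
        assert status == "ok" and levels == 4

    def test_never_detected_is_nd(self, registry):
        t = self._table(set(), registry)
        _, status, _ = select_for_association(t, "cpd", "hair")
        assert status == "ND"

    def test_nondetected_controls_excluded(self, registry):
        t = self._table({1, 2, 3, 4}, registry)
        subset, status, _ = select_for_association(t, "cpd", "hair")
        assert status == "ok"
        assert len(subset) == 8          # 4 levels x 2 animals
        assert 0.0 not in set(subset["dose"])

    def test_detected_controls_included(self, registry):
        t = self._table({0, 1, 2, 3, 4}, registry)
        subset, _, _ = select_for_association(t, "cpd", "hair")
        assert 0.0 in set(subset["dose"])
        assert len(subset) == 10


class TestFitSlope:
    def test_exact_line(self):
        t = np.array([0.0, 0.1, 0.2, 0.3])
        assert fit_slope(t, 100.0 * t) == pytest.approx(100.0)

    def test_flat_line_zero_slope(self):
        t = np.array([0.0, 1.0, 2.0, 4.0])
        assert fit_slope(t, np.full(4, 5.0)) == pytest.approx(0.0)

    def test_four_point_fixture(self):
        assert fit_slope(FOUR_POINT_T, FOUR_POINT_C) == pytest.approx(
            FOUR_POINT_SLOPE, abs=1e-12
        )

    def test_identical_exposures_rejected(self):
        with pytest.raises(StudyError):
            fit_slope(np.ones(4), np.arange(4.0))


class TestPearson:
    def test_exact_positive_and_negative_lines(self):
        t = np.array([0.0, 1.0, 2.0, 4.0])
        assert pearson(t, 3 + 2 * t)[0] == pytest.approx(1.0)
        assert pearson(t, 3 - 2 * t)[0] == pytest.approx(-1.0)

    def test_four_point_fixture_r_and_p(self):
        r, p = pearson(FOUR_POINT_T, FOUR_POINT_C)
        assert r == pytest.approx(FOUR_POINT_R, abs=1e-12)
        # p from t = r*sqrt((n-2)/(1-r^2)) with 2 df, two-sided
        from scipy import stats

        tstat = FOUR_POINT_R * math.sqrt(2 / (1 - FOUR_POINT_R**2))
        assert p == pytest.approx(2 * stats.t.sf(tstat, 2), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(StudyError):
            pearson(np.ones(4), np.arange(4.0))


class TestSpearman:
    def test_monotone_gives_one(self):
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        assert spearman(t, np.exp(t)) == pytest.approx(1.0)

    def test_tie_heavy_fixture_matches_midrank_formula(self):
        # two dose groups x 3 animals: dose midranks (2,2,2,5,5,5)
        doses = np.array([0.0, 0, 0, 1, 1, 1])
        conc = np.array([1.0, 2, 3, 4, 5, 6])
        expected = 0.8783100656536799  # pearson of midranks, hand enumeration
        assert spearman(doses, conc) == pytest.approx(expected, abs=1e-12)
        assert spearman(doses, conc) == pytest.approx(
            pearson_oracle(midrank_oracle(doses), midrank_oracle(conc))
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_rank_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        doses = rng.choice([0.0, 1.0, 2.0, 4.0], size=n)
        if len(set(doses)) < 2:
            doses[0], doses[1] = 0.0, 4.0
        conc = np.round(rng.lognormal(0, 1, size=n), 1)  # rounding makes ties
        expected = pearson_oracle(midrank_oracle(doses), midrank_oracle(conc))
        assert spearman(doses, conc) == pytest.approx(expected, abs=1e-12)

    def test_near_zero_for_independent_permutation(self, rng):
        t = np.repeat(np.arange(8.0), 25)
        conc = rng.permutation(200).astype(float)
        assert abs(spearman(t, conc)) < 0.15


class TestInvariances:
    def test_spearman_invariant_pearson_not_under_exp(self):
        t = np.array([0.0, 1, 2, 3, 4, 5, 6, 7])
        c = np.array([1.0, 1.5, 2.5, 2.0, 4.0, 3.5, 6.0, 8.0])
        assert spearman(t, c) == pytest.approx(spearman(t, np.exp(c)), abs=1e-12)
        assert pearson(t, c)[0] != pytest.approx(pearson(t, np.exp(c))[0], abs=1e-6)

    def test_both_invariant_under_dose_rescale(self):
        t = np.array([0.0, 4, 10, 20, 40, 100])
        c = np.array([1.0, 1.5, 2.5, 2.0, 4.0, 3.5])
        assert pearson(t, c)[0] == pytest.approx(pearson(1e-3 * t, c)[0])
        assert spearman(t, c) == pytest.approx(spearman(1e-3 * t, c))


class TestSummarize:
    def test_noiseless_study_perfect_correlations(self, design):
        spec = CompoundSpec(
            "x", lod={"hair": 1e-9}, sim={"hair": SimParams(a0=1.0, b=55.0, cv=0.0)}
        )
        cfg = SimulationConfig(design=design, compounds=(spec,), seed=0)
        table, _ = generate_study(cfg)
        res = summarize_associations(table, [spec], design)[0]
        assert res.status == "ok"
        assert res.slope == pytest.approx(55.0)
        assert res.r_pearson == pytest.approx(1.0)
        assert res.r_spearman == pytest.approx(1.0)

    def test_nd_and_range(self, registry, design):
        records = [("r1", 0, "hair", "cpd", None), ("r2", 4, "hair", "cpd", None)]
        t = make_table(records, registry)
        res = summarize_associations(t, registry[:1], design)[0]
        assert res.status == "ND" and res.slope is None

    def test_range_is_group_means(self, registry, design):
        records = [
            ("r1", 4, "hair", "cpd", 1.0),
            ("r2", 4, "hair", "cpd", 3.0),
            ("r3", 10, "hair", "cpd", 6.0),
            ("r4", 20, "hair", "cpd", 8.0),
            ("r5", 40, "hair", "cpd", 11.0),
        ]
        t = make_table(records, registry)
        res = summarize_associations(t, registry[:1], design)[0]
        assert res.concentration_range == pytest.approx((2.0, 11.0))
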