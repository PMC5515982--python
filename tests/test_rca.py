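"""Reverse classification analysis: scoring rule, Monte Carlo, exact oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from biomatrix.rca import is_correct_classification, rca_exact, rca_score
from biomatrix.study import ConcentrationTable, StudyDesign, StudyError
from conftest import monotone_table


def animals_table(doses, concs, compound="cpd", matrix="hair"):
    rows = [
        (f"r{i:02d}", d, matrix, compound, c, True)
        for i, (d, c) in enumerate(zip(doses, concs))
    ]
    return ConcentrationTable(
        pd.DataFrame(
            rows,
            columns=["animal_id", "dose", "matrix", "compound", "value", "detected"],
        )
    )


def exact_oracle(doses, concs, k):
    """Independent brute force: a subset is correct iff SOME permutation of it
    is simultaneously concentration-non-decreasing and dose-non-decreasing."""
    n = len(doses)
    n_correct = 0
    for subset in itertools.combinations(range(n), k):
        ok = False
        for perm in itertools.permutations(subset):
            cs = [concs[i] for i in perm]
            ds = [doses[i] for i in perm]
            if all(a <= b for a, b in zip(cs, cs[1:])) and all(
                a <= b for a, b in zip(ds, ds[1:])
            ):
                ok = True
                break
        n_correct += ok
    return n_correct / math.comb(n, k)


class TestIsCorrectClassification:
    def test_strictly_increasing(self):
        assert is_correct_classification([0, 4, 10, 20, 40])

    def test_equal_doses_allowed(self):
        assert is_correct_classification([0, 4, 4, 10, 20])

    def test_one_inversion(self):
        assert not is_correct_classification([4, 0, 10, 20, 40])


class TestRcaScore:
    def test_perfect_order_scores_100(self):
        design = StudyDesign(dose_levels=tuple(range(9))[0:8], animals_per_group=2)
        t = monotone_table(design)
        r = rca_score(t, "cpd", "hair", design, iterations=2000, seed=0)
        assert r.status == "ok"
        assert r.percent_correct == 100.0
        assert r.mc_se == 0.0

    def test_analytic_null_redrawn_concentrations(self):
        # concentrations iid, independent of dose: every ordering of a
        # 5-animal subset is equiprobable -> P(correct) = 1/5!.  Redrawing
        # the concentrations each iteration makes the draws i.i.d. with
        # exact binomial Monte-Carlo error.
        rng = np.random.default_rng(314)
        doses = np.array([0.0, 4, 10, 20, 40, 100, 200, 400])
        iters = 10_000
        hits = 0
        for _ in range(iters):
            concs = rng.random(8)
            pick = rng.choice(8, size=5, replace=False)
            order = pick[np.argsort(concs[pick])]
            hits += is_correct_classification(doses[order])
        p = hits / iters
        se = math.sqrt(p * (1 - p) / iters)
        assert abs(p - 1.0 / 120.0) <= 3 * se

    def test_invariant_under_monotone_transform(self):
        design = StudyDesign(dose_levels=(0, 1, 2, 3), animals_per_group=4)
        rng = np.random.default_rng(5)
        doses = np.repeat([0, 1, 2, 3], 4)
        concs = rng.lognormal(np.log1p(doses), 0.5)
        t1 = animals_table(doses, concs)
        t2 = animals_table(doses, np.exp(concs / concs.max() * 3))
        r1 = rca_score(t1, "cpd", "hair", design, iterations=3000, seed=7)
        r2 = rca_score(t2, "cpd", "hair", design, iterations=3000, seed=7)
        assert r1.percent_correct == r2.percent_correct

    def test_same_seed_reproduces_exactly(self):
        design = StudyDesign(dose_levels=(0, 1, 2, 3), animals_per_group=4)
        rng = np.random.default_rng(8)
        doses = np.repeat([0, 1, 2, 3], 4)
        concs = rng.lognormal(np.log1p(doses), 1.0)
        t = animals_table(doses, concs)
        r1 = rca_score(t, "cpd", "hair", design, iterations=5000, seed=42)
        r2 = rca_score(t, "cpd", "hair", design, iterations=5000, seed=42)
        assert r1.percent_correct == r2.percent_correct

    def test_not_conducted_below_four_detected_groups(self, registry):
        from conftest import make_table
        from biomatrix.censoring import impute_half_lod

        design = StudyDesign(dose_levels=(0, 1, 2, 3, 4), animals_per_group=2)
        records = []
        for gi, dose in enumerate(design.dose_levels):
            for ai in range(2):
                val = 1.0 + dose if dose >= 2 else None  # detected in 3 groups
                records.append((f"g{gi}a{ai}", dose, "hair", "cpd", val))
        t = impute_half_lod(make_table(records, registry), registry)
        r = rca_score(t, "cpd", "hair", design, iterations=100, seed=0)
        assert r.status == "not_conducted"
        assert r.percent_correct is None

    def test_too_few_animals_error(self):
        design = StudyDesign(dose_levels=(0, 1, 2, 3), animals_per_group=2)
        t = animals_table([0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(StudyError):
            rca_score(t, "cpd", "hair", design, subset_size=5, iterations=10, seed=0)

    def test_noise_monotonically_degrades_score(self):
        from biomatrix.simulate import SimulationConfig, generate_study
        from biomatrix.study import CompoundSpec, SimParams

        design = StudyDesign()
        means = []
        for cv in (0.0, 0.2, 0.5, 1.0):
            scores = []
            for seed in range(10):
                spec = CompoundSpec(
                    "x", lod={"hair": 1e-9},
                    sim={"hair": SimParams(a0=1.0, b=100.0, cv=cv)},
                )
                cfg = SimulationConfig(design=design, compounds=(spec,), seed=seed)
                table, _ = generate_study(cfg)
                r = rca_score(table, "x", "hair", design, iterations=2000, seed=seed)
                scores.append(r.percent_correct)
            means.append(np.mean(scores))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestRcaExact:
    def test_perfectly_monotone_is_one(self):
        design = StudyDesign(dose_levels=(0, 1, 2, 3), animals_per_group=3)
        t = monotone_table(design)
        assert rca_exact(t, "cpd", "hair", design) == 1.0

    def test_two_inverted_animals_counted_by_enumeration(self):
        # 10 animals at 5 doses; one adjacent-dose pair swapped
        design = StudyDesign(dose_levels=(0, 1, 2, 3, 4), animals_per_group=2)
        doses = np.repeat([0, 1, 2, 3, 4], 2)
        concs = np.array([1.0, 2, 3, 4, 5, 6, 8, 7.5, 9, 10])  # doses 2/3 inverted
        t = animals_table(doses, concs)
        got = rca_exact(t, "cpd", "hair", design)
        assert got == pytest.approx(exact_oracle(list(doses), list(concs), 5))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_permutation_oracle_with_ties(self, seed):
        # ties in concentration (half-LOD-like) and doses
        design = StudyDesign(dose_levels=(0, 1, 2, 3), animals_per_group=3)
        rng = np.random.default_rng(seed)
        doses = np.repeat([0, 1, 2, 3], 3)
        concs = rng.choice([0.5, 0.5, 1.0, 2.0, 3.0, 4.0], size=12, replace=True)
        t = animals_table(doses, concs)
        got = rca_exact(t, "cpd", "hair", design, subset_size=4)
        assert got == pytest.approx(exact_oracle(list(doses), list(concs), 4))

    def test_pessimistic_policy_scores_ties_against(self):
        design = StudyDesign(dose_levels=(0, 1, 2, 3, 4), animals_per_group=2)
        doses = [0, 1, 2, 3, 4]
        concs = [0.5, 0.5, 2.0, 3.0, 4.0]  # tie across different doses
        t = animals_table(doses, concs)
        opt = rca_exact(t, "cpd", "hair", design, tie_policy="optimistic")
        pes = rca_exact(t, "cpd", "hair", design, tie_policy="pessimistic")
        assert opt == 1.0 and pes == 0.0

    def test_monte_carlo_converges_to_exact(self):
        design = StudyDesign(dose_levels=(0, 1, 2, 3), animals_per_group=4)
        rng = np.random.default_rng(17)
        doses = np.repeat([0, 1, 2, 3], 4)
        concs = rng.lognormal(np.log1p(doses), 0.6)
        t = animals_table(doses, concs)
        exact = rca_exact(t, "cpd", "hair", design)
        r = rca_score(t, "cpd", "hair", design, iterations=10_000, seed=3)
        assert abs(r.percent_correct / 100 - exact) <= 3 * r.mc_se / 100

    def test_combinatorial_bound_enforced(self):
        design = StudyDesign(dose_levels=(0, 1, 2, 3), animals_per_group=20)
        doses = np.repeat([0, 1, 2, 3], 20)
        t = animals_table(doses, np.arange(80.0) + 1)
        with pytest.raises(StudyError, match="Monte Carlo"):
            rca_exact(t, "cpd", "hair", design, subset_size=20)
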