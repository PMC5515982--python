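"""Synthetic study generator.

Emulates the statistical structure of an 8-dose-group, 3-matrix,
multi-compound gavage study: per compound and matrix, the latent end-of-study
concentration of an animal at exposure rate ``T(dose)`` is

    c = (a0 + b * T(dose)) * exp(eps),      eps ~ Normal(0, sigma^2),

with ``sigma = sqrt(ln(1 + cv^2))`` so that ``cv`` is the coefficient of
variation of the multiplicative lognormal noise.  ``a0 > 0`` models the
background exposure that makes some compounds detectable in control animals.
Censoring is applied after noise, on the latent value: records below the
matrix LOD are emitted as non-detects (absent value, detected=False), the
way a real assay truncates.

Noise is independent across compounds and matrices; a shared per-animal
random effect is deliberately not modelled (a known simplification).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .study import (
    MATRICES,
    AnimalCovariates,
    CompoundSpec,
    ConcentrationTable,
    SimParams,
    StudyDesign,
    StudyError,
)

__all__ = [
    "CovariateParams",
    "SimulationConfig",
    "generate_study",
    "generate_pigmentation_pairs",
    "default_design",
    "default_registry",
    "default_config",
]


@dataclass(frozen=True)
class CovariateParams:
    """Distribution parameters for the per-animal urinary covariates.

    Defaults are typical of an adult laboratory rat: ~15 mL urine over 24 h
    and ~0.8 mg/mL urinary creatinine, with moderate lognormal variability.
    """

    urine_volume_mean: float = 15.0  # mL / 24 h
    urine_volume_cv: float = 0.30
    creatinine_mean: float = 0.8     # mg / mL
    creatinine_cv: float = 0.25

    def __post_init__(self) -> None:
        for v in (self.urine_volume_mean, self.creatinine_mean):
            if not v > 0:
                raise StudyError("covariate means must be > 0")
        for v in (self.urine_volume_cv, self.creatinine_cv):
            if v < 0:
                raise StudyError("covariate cv must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    design: StudyDesign
    compounds: tuple[CompoundSpec, ...]
    seed: int = 0
    covariates: CovariateParams = field(default_factory=CovariateParams)
    pigmentation_cv: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", tuple(self.compounds))
        if self.pigmentation_cv < 0:
            raise StudyError("pigmentation_cv must be >= 0")


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _animal_ids(design: StudyDesign) -> tuple[list[str], np.ndarray]:
    """Stable animal identifiers and their dose assignment, group by group."""
    ids, doses = [], []
    for gi, dose in enumerate(design.dose_levels):
        for ai in range(design.animals_per_group):
            ids.append(f"g{gi}a{ai + 1:02d}")
            doses.append(dose)
    return ids, np.asarray(doses, dtype=float)


def generate_study(
    config: SimulationConfig,
) -> tuple[ConcentrationTable, list[AnimalCovariates]]:
    """Draw one complete synthetic study.

    Returns the long-format concentration table (with non-detects censored
    at the matrix LOD) and the per-animal urinary covariates.  Fixing
    ``config.seed`` makes the output bit-reproducible; the concentration,
    covariate, and pigmentation streams are independent children of that
    seed.
    """
    conc_ss, cov_ss, _ = np.random.SeedSequence(config.seed).spawn(3)
    rng = np.random.default_rng(conc_ss)
    design = config.design
    ids, doses = _animal_ids(design)
    rate = np.asarray(design.exposure_rate(doses), dtype=float)
    n = len(ids)

    rows = []
    for spec, matrix in itertools.product(config.compounds, MATRICES):
        if matrix not in spec.lod:
            continue
        lod = spec.lod[matrix]
        params = spec.sim.get(matrix)
        if params is None:
            # analyte never present in this matrix: pure non-detects
            for aid, dose in zip(ids, doses):
                rows.append((aid, dose, matrix, spec.name, np.nan, False))
            continue
        sigma = _lognormal_sigma(params.cv)
        eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
        latent = (params.a0 + params.b * rate) * np.exp(eps)
        detected = latent >= lod
        for aid, dose, c, det in zip(ids, doses, latent, detected):
            rows.append((aid, dose, matrix, spec.name, c if det else np.nan, det))

    table = ConcentrationTable(
        pd.DataFrame(
            rows,
            columns=["animal_id", "dose", "matrix", "compound", "value", "detected"],
        )
    )

    cov_rng = np.random.default_rng(cov_ss)
    cp = config.covariates
    vol = _draw_lognormal(cov_rng, cp.urine_volume_mean, cp.urine_volume_cv, n)
    crea = _draw_lognormal(cov_rng, cp.creatinine_mean, cp.creatinine_cv, n)
    covariates = [
        AnimalCovariates(aid, float(v), float(c)) for aid, v, c in zip(ids, vol, crea)
    ]
    return table, covariates


def _draw_lognormal(
    rng: np.random.Generator, mean: float, cv: float, n: int
) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and cv."""
    if cv == 0:
        return np.full(n, mean)
    sigma = _lognormal_sigma(cv)
    mu = np.log(mean) - sigma * sigma / 2.0
    return rng.lognormal(mu, sigma, size=n)


def generate_pigmentation_pairs(
    config: SimulationConfig, ratio: float, cv: float | None = None
) -> pd.DataFrame:
    """Paired white/black hair concentrations per animal and compound.

    Black-hair values follow each compound's hair dose-response model;
    white values are ``ratio * black * exp(noise)`` where noise has
    coefficient of variation ``cv`` (defaults to ``config.pigmentation_cv``).
    A ratio of 1 means pigmentation does not influence incorporation.
    Columns: animal_id, compound, black_value, white_value.
    """
    if not ratio > 0:
        raise StudyError("pigmentation ratio must be > 0")
    if cv is None:
        cv = config.pigmentation_cv
    _, _, pig_ss = np.random.SeedSequence(config.seed).spawn(3)
    rng = np.random.default_rng(pig_ss)
    design = config.design
    ids, doses = _animal_ids(design)
    rate = np.asarray(design.exposure_rate(doses), dtype=float)
    n = len(ids)
    sigma_pair = _lognormal_sigma(cv)

    rows = []
    for spec in config.compounds:
        params = spec.sim.get("hair")
        if params is None:
            continue
        sigma = _lognormal_sigma(params.cv)
        eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
        black = (params.a0 + params.b * rate) * np.exp(eps)
        noise = (
            rng.normal(0.0, sigma_pair, size=n) if sigma_pair > 0 else np.zeros(n)
        )
        white = ratio * black * np.exp(noise)
        for aid, bl, wh in zip(ids, black, white):
            rows.append((aid, spec.name, bl, wh))
    return pd.DataFrame(
        rows, columns=["animal_id", "compound", "black_value", "white_value"]
    )


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_design() -> StudyDesign:
    """The study protocol: doses 0/4/10/20/40/100/200/400 µg/kg per gavage,
    8 animals per group, 3 gavages per week for 90 days."""
    return StudyDesign()


def _spec(name, cls, role, lod, sim):
    return CompoundSpec(
        name=name,
        chemical_class=cls,
        role=role,
        lod=lod,
        sim={m: SimParams(*p) for m, p in sim.items()},
    )


def default_registry() -> list[CompoundSpec]:
    """A 12-analyte registry emulating the detection patterns of a
    multi-class pesticide panel measured in hair (pg/mg), urine and plasma
    (ng/mL).

    Slopes span ~1 to ~600 concentration units per (mg/kg per day); LODs and
    intercepts are set so the panel reproduces the qualitative cases the
    analysis must handle: compounds detected everywhere including controls,
    compounds detected only at high doses (too few levels for association),
    compounds never detected in a matrix, and a metabolite present at every
    dose but unrelated to it.  All cv values default to 0.4.
    """
    R = [
        # name, class, role, lod{h,u,p}, sim{matrix:(a0, b, cv)}
        ("lindane", "organochlorine", "parent",
         {"hair": 0.18, "urine": 0.05, "plasma": 0.2},
         {"hair": (0.8, 120.0, 0.4), "urine": (0.15, 12.0, 0.6),
          "plasma": (0.9, 50.0, 0.4)}),
        ("beta_hch", "organochlorine", "parent",
         {"hair": 0.5, "urine": 0.1, "plasma": 0.3},
         {"hair": (3.0, 600.0, 0.4), "urine": (0.3, 15.0, 0.6),
          "plasma": (1.5, 200.0, 0.4)}),
        ("beta_endosulfan", "organochlorine", "parent",
         {"hair": 0.02, "urine": 0.05, "plasma": 0.0024},
         {"hair": (0.1, 2.7, 0.4), "plasma": (0.08, 1.5, 0.4)}),
        ("ppddt", "organochlorine", "parent",
         {"hair": 2.7, "urine": 0.4, "plasma": 0.679},
         {"hair": (0.4, 180.0, 0.4), "urine": (0.05, 0.5, 0.6),
          "plasma": (0.3, 175.0, 0.4)}),
        ("diazinon", "organophosphate", "parent",
         {"hair": 0.3, "urine": 0.2, "plasma": 0.05},
         {}),
        ("dep", "organophosphate", "metabolite",
         {"hair": 0.1, "urine": 2.0, "plasma": 0.5},
         {"hair": (0.3, 4.5, 0.4), "urine": (15.0, 4000.0, 0.6),
          "plasma": (3.0, 0.0, 0.4)}),
        ("tcpy", "organophosphate", "metabolite",
         {"hair": 0.5, "urine": 5.0, "plasma": 1.0},
         {"hair": (2.0, 85.0, 0.4), "urine": (25.0, 5000.0, 0.6),
          "plasma": (4.0, 110.0, 0.4)}),
        ("cypermethrin", "pyrethroid", "parent",
         {"hair": 0.9, "urine": 0.3, "plasma": 0.08},
         {"hair": (0.05, 9.0, 0.4), "plasma": (0.06, 10.0, 0.4)}),
        ("three_pba", "pyrethroid", "metabolite",
         {"hair": 0.1, "urine": 0.5, "plasma": 1.0},
         {"hair": (0.3, 7.0, 0.4), "urine": (1.5, 250.0, 0.6),
          "plasma": (3.0, 400.0, 0.4)}),
        ("trifluralin", "other", "parent",
         {"hair": 0.02, "urine": 0.0002, "plasma": 0.02},
         {"hair": (0.08, 1.1, 0.4), "urine": (0.0008, 0.02, 0.6),
          "plasma": (0.06, 1.6, 0.4)}),
        ("fipronil_sulfone", "other", "metabolite",
         {"hair": 0.4, "urine": 0.003, "plasma": 1.0},
         {"hair": (2.5, 770.0, 0.4), "urine": (0.005, 20.0, 0.6),
          "plasma": (4.0, 975.0, 0.4)}),
        ("propiconazole", "other", "parent",
         {"hair": 0.08, "urine": 0.1, "plasma": 0.1},
         {"hair": (0.2, 6.5, 0.4)}),
    ]
    return [_spec(*r) for r in R]


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        design=default_design(), compounds=tuple(default_registry()), seed=seed
    )
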