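"""Domain types and I/O for multi-matrix biomonitoring studies.

A study exposes groups of animals to graded doses of a pesticide mixture and
quantifies parent compounds and metabolites in three biological matrices
(hair, urine, plasma).  Everything downstream — censoring bookkeeping,
dose-response association, inter-group testing, reverse classification —
consumes the long-format :class:`ConcentrationTable` defined here, together
with a :class:`StudyDesign` and a registry of :class:`CompoundSpec`.

Concentrations are stored in matrix-native units: pg/mg for hair, ng/mL for
urine and plasma.  Administered doses are per-gavage µg/kg body weight; the
design's dose transform maps them to an exposure rate in mg/kg per day for
slope fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MATRICES = ("hair", "urine", "plasma")
MATRIX_UNITS = {"hair": "pg/mg", "urine": "ng/mL", "plasma": "ng/mL"}
CHEMICAL_CLASSES = (
    "organochlorine",
    "organophosphate",
    "pyrethroid",
    "carbamate",
    "other",
)

TABLE_COLUMNS = ["animal_id", "dose", "matrix", "compound", "value"]


class StudyError(ValueError):
    """Raised when a table, design, or registry violates its contract."""


# ---------------------------------------------------------------------------
# Dose transforms
# ---------------------------------------------------------------------------

def _weekly_average(dose_ug_kg: np.ndarray, gavages_per_week: int) -> np.ndarray:
    """Average daily exposure rate: spread the weekly intake over 7 days."""
    return np.asarray(dose_ug_kg, dtype=float) * gavages_per_week / 7.0 / 1000.0


def _per_gavage(dose_ug_kg: np.ndarray, gavages_per_week: int) -> np.ndarray:
    """Treat each gavage dose as the daily rate (unit change only)."""
    return np.asarray(dose_ug_kg, dtype=float) / 1000.0


def _identity(dose_ug_kg: np.ndarray, gavages_per_week: int) -> np.ndarray:
    return np.asarray(dose_ug_kg, dtype=float)


DOSE_TRANSFORMS: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "weekly_average": _weekly_average,
    "per_gavage": _per_gavage,
    "identity": _identity,
}


@dataclass(frozen=True)
class StudyDesign:
    """Exposure protocol: dose groups, group size, and dosing schedule.

    Parameters
    ----------
    dose_levels
        Administered doses in µg/kg body weight per gavage, strictly
        increasing, first entry 0 (controls).
    animals_per_group
        Number of animals per dose group.
    gavages_per_week, duration_days
        Dosing schedule.
    dose_transform
        Named rule mapping administered dose to an exposure rate in
        mg/kg per day, used for slope fitting.  ``"weekly_average"``
        (default) is dose × gavages_per_week / 7 / 1000.
    """

    dose_levels: tuple[float, ...] = (0.0, 4.0, 10.0, 20.0, 40.0, 100.0, 200.0, 400.0)
    animals_per_group: int = 8
    gavages_per_week: int = 3
    duration_days: int = 90
    dose_transform: str = "weekly_average"

    def __post_init__(self) -> None:
        levels = tuple(float(d) for d in self.dose_levels)
        object.__setattr__(self, "dose_levels", levels)
        if len(levels) < 2 or levels[0] != 0.0:
            raise StudyError("dose_levels must start at 0 (controls)")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise StudyError("dose_levels must be strictly increasing")
        if self.animals_per_group < 2:
            raise StudyError("animals_per_group must be >= 2")
        if not 1 <= self.gavages_per_week <= 7:
            raise StudyError("gavages_per_week must be in 1..7")
        if self.dose_transform not in DOSE_TRANSFORMS:
            raise StudyError(
                f"unknown dose_transform {self.dose_transform!r}; "
                f"choose from {sorted(DOSE_TRANSFORMS)}"
            )

    @property
    def n_animals(self) -> int:
        return len(self.dose_levels) * self.animals_per_group

    def exposure_rate(self, dose_ug_kg) -> np.ndarray | float:
        """Map administered dose(s) (µg/kg per gavage) to mg/kg per day."""
        fn = DOSE_TRANSFORMS[self.dose_transform]
        out = fn(np.asarray(dose_ug_kg, dtype=float), self.gavages_per_week)
        return float(out) if np.isscalar(dose_ug_kg) or out.ndim == 0 else out


@dataclass(frozen=True)
class SimParams:
    """Per-matrix dose-response parameters for the synthetic generator.

    Latent concentration is ``(a0 + b * rate) * exp(eps)`` with lognormal
    multiplicative noise of coefficient of variation ``cv``.
    """

    a0: float  # background concentration at dose 0, matrix units
    b: float   # concentration per (mg/kg per day), matrix units
    cv: float = 0.4

    def __post_init__(self) -> None:
        if self.a0 < 0:
            raise StudyError("sim intercept a0 must be >= 0")
        if self.cv < 0:
            raise StudyError("sim cv must be >= 0")


@dataclass(frozen=True)
class CompoundSpec:
    """A target analyte: identity, per-matrix LODs, simulation parameters.

    The LOD is the lowest concentration the assay reports; a measurement is
    *detected* iff its value is at or above the LOD of its matrix.  ``sim``
    may omit matrices where the analyte is never seen (the generator then
    emits pure non-detects there).
    """

    name: str
    chemical_class: str = "other"
    role: str = "parent"  # parent | metabolite
    lod: Mapping[str, float] = field(default_factory=dict)
    sim: Mapping[str, SimParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise StudyError(
                f"{self.name}: unknown chemical_class {self.chemical_class!r}"
            )
        if self.role not in ("parent", "metabolite"):
            raise StudyError(f"{self.name}: role must be parent or metabolite")
        for mat, val in self.lod.items():
            if mat not in MATRICES:
                raise StudyError(f"{self.name}: unknown matrix {mat!r} in lod")
            if not val > 0:
                raise StudyError(f"{self.name}: LOD for {mat} must be > 0")
        for mat in self.sim:
            if mat not in MATRICES:
                raise StudyError(f"{self.name}: unknown matrix {mat!r} in sim")


def registry_lookup(registry: Sequence[CompoundSpec], name: str) -> CompoundSpec:
    for spec in registry:
        if spec.name == name:
            return spec
    raise StudyError(f"compound {name!r} not in registry")


def registry_lod(registry: Sequence[CompoundSpec], compound: str, matrix: str) -> float:
    spec = registry_lookup(registry, compound)
    try:
        return spec.lod[matrix]
    except KeyError:
        raise StudyError(f"no LOD for compound {compound!r} in matrix {matrix!r}")


# ---------------------------------------------------------------------------
# Concentration table
# ---------------------------------------------------------------------------

class ConcentrationTable:
    """Long-format concentration measurements with detection flags.

    One record per animal × matrix × compound.  Non-detects carry an absent
    value (NaN) and ``detected=False``; ½-LOD imputation is an explicit
    pipeline stage (:func:`biomatrix.censoring.impute_half_lod`), never an
    I/O side effect, so a present value *below* the LOD (an imputed ½-LOD)
    is legal but always flagged ``detected=False``.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        df = data.copy()
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise StudyError(f"concentration table missing columns {missing}")
        if "detected" not in df.columns:
            raise StudyError("concentration table missing 'detected' flags")
        df = df[TABLE_COLUMNS + ["detected"]].reset_index(drop=True)
        df["animal_id"] = df["animal_id"].astype(str)
        df["dose"] = df["dose"].astype(float)
        df["matrix"] = df["matrix"].astype(str)
        df["compound"] = df["compound"].astype(str)
        df["value"] = df["value"].astype(float)
        df["detected"] = df["detected"].astype(bool)
        self._df = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self._df
        bad_matrix = set(df["matrix"]) - set(MATRICES)
        if bad_matrix:
            raise StudyError(f"unknown matrix labels {sorted(bad_matrix)}")
        present = df["value"].notna()
        if (df.loc[present, "value"] <= 0).any():
            bad = df.loc[present & (df["value"] <= 0)].iloc[0]
            raise StudyError(
                f"non-positive value for {bad['compound']}/{bad['matrix']}"
                f"/animal {bad['animal_id']}"
            )
        if (df["detected"] & ~present).any():
            raise StudyError("detected records must carry a value")
        dup = df.duplicated(subset=["animal_id", "matrix", "compound"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise StudyError(
                "duplicate record for "
                f"({bad['animal_id']}, {bad['matrix']}, {bad['compound']})"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """The underlying long-format DataFrame (copy-on-write semantics)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self._df["compound"]))

    @property
    def matrices(self) -> list[str]:
        return [m for m in MATRICES if m in set(self._df["matrix"])]

    def subset(self, compound: str, matrix: str) -> pd.DataFrame:
        df = self._df
        return df[(df["compound"] == compound) & (df["matrix"] == matrix)]

    def equals(self, other: "ConcentrationTable") -> bool:
        a = self._df.sort_values(["compound", "matrix", "animal_id"]).reset_index(drop=True)
        b = other._df.sort_values(["compound", "matrix", "animal_id"]).reset_index(drop=True)
        return a.equals(b)

    def with_detection(self, registry: Sequence[CompoundSpec]) -> "ConcentrationTable":
        """Recompute detection flags from registry LODs (value >= LOD)."""
        df = self._df.copy()
        lods = np.array(
            [
                registry_lod(registry, c, m)
                for c, m in zip(df["compound"], df["matrix"])
            ]
        )
        df["detected"] = df["value"].notna().to_numpy() & (
            df["value"].to_numpy() >= lods
        )
        return ConcentrationTable(df)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], registry: Sequence[CompoundSpec] | None = None
    ) -> "ConcentrationTable":
        """Build from (animal_id, dose, matrix, compound, value) tuples.

        ``value=None`` encodes a non-detect.  Detection flags are recomputed
        from the registry when given, else value-presence is used.
        """
        df = pd.DataFrame(list(records), columns=TABLE_COLUMNS)
        df["detected"] = df["value"].notna()
        table = cls(df, validate=registry is None)
        if registry is not None:
            table = table.with_detection(registry)
        return table


@dataclass(frozen=True)
class AnimalCovariates:
    """Per-animal urinary covariates used by the adjustment analyses."""

    animal_id: str
    urine_volume_24h: float  # mL collected over 24 h
    creatinine: float        # mg per mL urine

    def __post_init__(self) -> None:
        if not self.urine_volume_24h > 0:
            raise StudyError(f"{self.animal_id}: urine volume must be > 0")
        if not self.creatinine > 0:
            raise StudyError(f"{self.animal_id}: creatinine must be > 0")


def covariates_frame(covariates: Sequence[AnimalCovariates]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [c.animal_id for c in covariates],
            "urine_volume_24h_ml": [c.urine_volume_24h for c in covariates],
            "creatinine_mg_ml": [c.creatinine for c in covariates],
        }
    )


def covariates_from_frame(df: pd.DataFrame) -> list[AnimalCovariates]:
    return [
        AnimalCovariates(str(r.animal_id), float(r.urine_volume_24h_ml), float(r.creatinine_mg_ml))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_concentration_table(
    path: str | Path, registry: Sequence[CompoundSpec]
) -> ConcentrationTable:
    """Read a long-format concentration CSV and recompute detection flags.

    The file has columns ``animal_id,dose,matrix,compound,value``; an empty
    value cell encodes a non-detect.  Unknown compounds or matrices and
    negative values are rejected with the offending record named.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"animal_id": str, "matrix": str, "compound": str},
        float_precision="round_trip",
    )
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise StudyError(f"{path}: missing columns {missing}")
    known = {spec.name for spec in registry}
    for i, row in df.iterrows():
        if row["matrix"] not in MATRICES:
            raise StudyError(f"{path} row {i}: unknown matrix {row['matrix']!r}")
        if row["compound"] not in known:
            raise StudyError(f"{path} row {i}: unknown compound {row['compound']!r}")
        if pd.notna(row["value"]) and row["value"] <= 0:
            raise StudyError(
                f"{path} row {i}: non-positive value {row['value']} "
                f"for {row['compound']}/{row['matrix']}"
            )
    df["detected"] = False  # recomputed below
    return ConcentrationTable(df, validate=False).with_detection(registry)


def write_concentration_table(table: ConcentrationTable, path: str | Path) -> None:
    """Write the 5 public columns; non-detects become empty cells.

    Note an imputed table loses its ½-LOD fill on round trip: values below
    the LOD read back as present-but-undetected, exactly as written.
    """
    out = table.df[TABLE_COLUMNS].copy()
    out.loc[~table.df["detected"] & out["value"].isna(), "value"] = np.nan
    out.to_csv(path, index=False)


def read_covariates(path: str | Path) -> list[AnimalCovariates]:
    df = pd.read_csv(path, dtype={"animal_id": str})
    return covariates_from_frame(df)


def write_covariates(covariates: Sequence[AnimalCovariates], path: str | Path) -> None:
    covariates_frame(covariates).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Config (design + registry) serialization
# ---------------------------------------------------------------------------

def design_to_dict(design: StudyDesign) -> dict:
    return {
        "dose_levels": list(design.dose_levels),
        "animals_per_group": design.animals_per_group,
        "gavages_per_week": design.gavages_per_week,
        "duration_days": design.duration_days,
        "dose_transform": design.dose_transform,
    }


def registry_to_dict(registry: Sequence[CompoundSpec]) -> dict:
    out: dict = {}
    for spec in registry:
        entry: dict = {
            "class": spec.chemical_class,
            "role": spec.role,
            "lod": dict(spec.lod),
        }
        if spec.sim:
            entry["sim"] = {
                m: {"a0": p.a0, "b": p.b, "cv": p.cv} for m, p in spec.sim.items()
            }
        out[spec.name] = entry
    return out


def load_config(path: str | Path) -> tuple[StudyDesign, list[CompoundSpec]]:
    """Load a YAML config with ``design`` and ``compounds`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    design = StudyDesign(**raw.get("design", {}))
    registry = []
    for name, entry in raw.get("compounds", {}).items():
        sim = {
            m: SimParams(**params) for m, params in (entry.get("sim") or {}).items()
        }
        registry.append(
            CompoundSpec(
                name=name,
                chemical_class=entry.get("class", "other"),
                role=entry.get("role", "parent"),
                lod=entry.get("lod", {}),
                sim=sim,
            )
        )
    return design, registry


def dump_config(
    design: StudyDesign, registry: Sequence[CompoundSpec], path: str | Path
) -> None:
    payload = {"design": design_to_dict(design), "compounds": registry_to_dict(registry)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
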