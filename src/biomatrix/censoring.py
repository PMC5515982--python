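"""Detection bookkeeping and ½-LOD imputation for left-censored data.

Non-detects (values below the limit of detection) are left-censored
observations.  For inter-group difference testing and reverse
classification, every non-detect is assigned the value LOD/2 — the
conventional substitution — while its ``detected`` flag stays False so
downstream stages can always tell imputed from measured values.
Association statistics never see imputed values; they use detected
records only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .study import (
    CompoundSpec,
    ConcentrationTable,
    StudyDesign,
    StudyError,
    registry_lod,
)

__all__ = [
    "impute_half_lod",
    "DetectionMatrix",
    "build_detection_matrix",
    "count_detected_per_level",
]


def impute_half_lod(
    table: ConcentrationTable, registry: Sequence[CompoundSpec]
) -> ConcentrationTable:
    """Assign LOD/2 to every non-detect; detected records are untouched.

    Idempotent: re-imputing an imputed table changes nothing.  Raises when
    a non-detect's (compound, matrix) has no LOD in the registry.
    """
    df = table.df.copy()
    mask = ~df["detected"].to_numpy()
    if mask.any():
        lods = np.array(
            [
                registry_lod(registry, c, m)
                for c, m in zip(df.loc[mask, "compound"], df.loc[mask, "matrix"])
            ]
        )
        df.loc[mask, "value"] = lods / 2.0
    return ConcentrationTable(df)


@dataclass
class DetectionMatrix:
    """Group-level detection grid: (compound, matrix, dose) -> detected.

    A dose group counts as positive when at least one of its animals has a
    detected measurement.  ``levels_detected`` gives, per compound and
    matrix, the number of dose levels with a positive group.
    """

    entries: pd.DataFrame  # columns compound, matrix, dose, detected

    def levels_detected(self, compound: str, matrix: str) -> int:
        df = self.entries
        sel = (df["compound"] == compound) & (df["matrix"] == matrix)
        return int(df.loc[sel, "detected"].sum())

    def is_detected(self, compound: str, matrix: str, dose: float) -> bool:
        df = self.entries
        sel = (
            (df["compound"] == compound)
            & (df["matrix"] == matrix)
            & (df["dose"] == dose)
        )
        if not sel.any():
            raise StudyError(
                f"no entry for ({compound}, {matrix}, dose={dose})"
            )
        return bool(df.loc[sel, "detected"].iloc[0])

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def build_detection_matrix(
    table: ConcentrationTable, design: StudyDesign
) -> DetectionMatrix:
    """One entry per compound × matrix × dose level present in the table."""
    df = table.df
    rows = []
    for (compound, matrix), sub in df.groupby(["compound", "matrix"], sort=True):
        by_dose = sub.groupby("dose")["detected"].any()
        for dose in design.dose_levels:
            rows.append(
                (compound, matrix, dose, bool(by_dose.get(dose, False)))
            )
    return DetectionMatrix(
        pd.DataFrame(rows, columns=["compound", "matrix", "dose", "detected"])
    )


def count_detected_per_level(dm: DetectionMatrix) -> pd.DataFrame:
    """Number of compounds with a positive group, per matrix per dose level.

    Columns: matrix, dose, n_compounds.
    """
    counts = (
        dm.entries.groupby(["matrix", "dose"], sort=True)["detected"]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"detected": "n_compounds"})
    )
    return counts
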