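import numpy as np
import pandas as pd
import pytest

from biomatrix.study import (
    CompoundSpec,
    ConcentrationTable,
    SimParams,
    StudyDesign,
)


@pytest.fixture
def design():
    return StudyDesign()


@pytest.fixture
def small_design():
    return StudyDesign(dose_levels=(0, 1, 2, 3, 4), animals_per_group=2)


@pytest.fixture
def registry():
    return [
        CompoundSpec(
            "cpd",
            chemical_class="organochlorine",
            lod={"hair": 0.5, "urine": 0.1, "plasma": 0.2},
            sim={"hair": SimParams(a0=1.0, b=100.0, cv=0.4)},
        ),
        CompoundSpec(
            "met",
            chemical_class="other",
            role="metabolite",
            lod={"hair": 0.02, "urine": 0.05, "plasma": 0.01},
        ),
    ]


def make_table(records, registry=None):
    """records: (animal_id, dose, matrix, compound, value-or-None)."""
    return ConcentrationTable.from_records(records, registry=registry)


@pytest.fixture
def make_table_fn():
    return make_table


def monotone_table(design, compound="cpd", matrix="hair", per_value=1.0):
    """Noiseless strictly dose-monotone table: value = base + dose*per_value,
    one record per animal, all detected."""
    rows = []
    for gi, dose in enumerate(design.dose_levels):
        for ai in range(design.animals_per_group):
            value = 1.0 + dose * per_value + ai * 1e-6  # distinct within group
            rows.append((f"g{gi}a{ai}", dose, matrix, compound, value, True))
    return ConcentrationTable(
        pd.DataFrame(
            rows,
            columns=["animal_id", "dose", "matrix", "compound", "value", "detected"],
        )
    )


@pytest.fixture
def monotone_table_fn():
    return monotone_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
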