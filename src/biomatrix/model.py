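"""Model/Results interface over the whole analysis.

:class:`ExposureStudy` bundles a concentration table with its study design,
compound registry, and optional covariates; :meth:`ExposureStudy.fit` runs
every stage — ½-LOD imputation, dose-response association, the sequential
group-comparison ladder, reverse classification analysis, detection counts,
and the urinary/pigmentation adjustment analyses — and returns an
:class:`ExposureStudyResults` carrying the estimates as tidy DataFrames,
with ``summary()`` and ``save()`` for reporting.

Example
-------
>>> from biomatrix import ExposureStudy, simulate
>>> table, cov = simulate.generate_study(simulate.default_config(seed=7))
>>> study = ExposureStudy(table, simulate.default_design(),
...                       simulate.default_registry(), covariates=cov)
>>> res = study.fit(seed=7)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .adjustments import compare_adjustments, pigmentation_slope
from .association import associations_frame, summarize_associations
from .censoring import (
    build_detection_matrix,
    count_detected_per_level,
    impute_half_lod,
)
from .ladder import run_ladder
from .rca import rca_score
from .study import (
    AnimalCovariates,
    CompoundSpec,
    ConcentrationTable,
    StudyDesign,
    StudyError,
    load_config,
    read_concentration_table,
    read_covariates,
)

__all__ = ["ExposureStudy", "ExposureStudyResults"]


class ExposureStudy:
    """A multi-matrix biomonitoring study ready to be analysed.

    Parameters
    ----------
    table
        Long-format measurements (NOT ½-LOD-imputed; imputation is applied
        internally where a stage requires it).
    design, registry
        The exposure protocol and the analyte registry with per-matrix LODs.
    covariates
        Optional per-animal urinary covariates enabling the adjustment
        comparison.
    pigmentation_pairs
        Optional DataFrame (animal_id, compound, black_value, white_value)
        enabling the pigmentation slope analysis.
    """

    def __init__(
        self,
        table: ConcentrationTable,
        design: StudyDesign,
        registry: Sequence[CompoundSpec],
        covariates: Sequence[AnimalCovariates] | None = None,
        pigmentation_pairs: pd.DataFrame | None = None,
    ):
        self.table = table
        self.design = design
        self.registry = list(registry)
        self.covariates = list(covariates) if covariates is not None else None
        self.pigmentation_pairs = pigmentation_pairs

    @classmethod
    def from_csv(
        cls,
        table_path: str | Path,
        config_path: str | Path,
        covariates_path: str | Path | None = None,
        pigmentation_path: str | Path | None = None,
    ) -> "ExposureStudy":
        """Build a study from the on-disk CSV/YAML artifacts."""
        design, registry = load_config(config_path)
        table = read_concentration_table(table_path, registry)
        covariates = (
            read_covariates(covariates_path) if covariates_path else None
        )
        pigmentation = (
            pd.read_csv(pigmentation_path, dtype={"animal_id": str})
            if pigmentation_path
            else None
        )
        return cls(table, design, registry, covariates, pigmentation)

    def fit(
        self,
        alpha: float = 0.05,
        rca_iterations: int = 10_000,
        rca_subset_size: int = 5,
        seed: int = 0,
        rca_tie_policy: str = "optimistic",
        rca_stratified: bool = False,
        pigmentation_through_origin: bool = True,
        force_test: str | None = None,
    ) -> "ExposureStudyResults":
        """Run every analysis stage and collect the results.

        ``seed`` drives the RCA resampling only (the data are given); each
        compound × matrix gets an independent child stream, so changing
        ``rca_iterations`` never perturbs another cell.
        """
        imputed = impute_half_lod(self.table, self.registry)
        associations = associations_frame(
            summarize_associations(self.table, self.registry, self.design)
        )
        detection = build_detection_matrix(self.table, self.design)
        counts = count_detected_per_level(detection)

        cells = [
            (spec.name, matrix)
            for spec in self.registry
            for matrix in self.table.matrices
            if len(self.table.subset(spec.name, matrix)) > 0
        ]

        ladder_rows = []
        for compound, matrix in cells:
            res = run_ladder(
                imputed, compound, matrix, self.design, alpha, force_test
            )
            for c in res.comparisons:
                ladder_rows.append(
                    {
                        "compound": compound,
                        "matrix": matrix,
                        "dose_high": c.dose_high,
                        "dose_low": c.dose_low,
                        "test": c.test_used,
                        "p": c.p,
                        "category": c.category,
                        "stars": c.stars,
                    }
                )
        brackets = pd.DataFrame(
            ladder_rows,
            columns=[
                "compound", "matrix", "dose_high", "dose_low",
                "test", "p", "category", "stars",
            ],
        )

        rca_rows = []
        children = np.random.SeedSequence(seed).spawn(len(cells))
        for (compound, matrix), child in zip(cells, children):
            r = rca_score(
                imputed,
                compound,
                matrix,
                self.design,
                subset_size=rca_subset_size,
                iterations=rca_iterations,
                seed=child,
                tie_policy=rca_tie_policy,
                stratified=rca_stratified,
            )
            rca_rows.append(
                {
                    "compound": compound,
                    "matrix": matrix,
                    "status": r.status,
                    "percent_correct": (
                        r.percent_correct if r.percent_correct is not None else np.nan
                    ),
                    "mc_se": r.mc_se if r.mc_se is not None else np.nan,
                    "n_iterations": r.n_iterations,
                    "subset_size": r.subset_size,
                }
            )
        rca = pd.DataFrame(rca_rows)

        adjustments = None
        if self.covariates is not None and "urine" in self.table.matrices:
            adj_rows = []
            for spec in self.registry:
                if len(self.table.subset(spec.name, "urine")) == 0:
                    continue
                a = compare_adjustments(
                    self.table, self.covariates, spec.name, self.design
                )
                adj_rows.append(
                    {
                        "compound": a.compound,
                        "status": a.status,
                        "r2_unadjusted": _nan(a.r2_unadjusted),
                        "r2_volume_adjusted": _nan(a.r2_volume_adjusted),
                        "r2_creatinine_adjusted": _nan(a.r2_creatinine_adjusted),
                        "volume_direction": a.direction("volume") or "",
                        "creatinine_direction": a.direction("creatinine") or "",
                    }
                )
            adjustments = pd.DataFrame(adj_rows)

        pigmentation = None
        if self.pigmentation_pairs is not None and len(self.pigmentation_pairs):
            pig_rows = []
            for compound, sub in self.pigmentation_pairs.groupby("compound", sort=True):
                fit = pigmentation_slope(
                    sub["black_value"].to_numpy(),
                    sub["white_value"].to_numpy(),
                    compound=str(compound),
                    through_origin=pigmentation_through_origin,
                )
                pig_rows.append(
                    {
                        "compound": fit.compound,
                        "slope_white_vs_black": fit.slope_white_vs_black,
                        "n_pairs": fit.n_pairs,
                    }
                )
            pigmentation = pd.DataFrame(pig_rows)

        return ExposureStudyResults(
            model=self,
            associations=associations,
            detection=detection.entries,
            counts=counts,
            brackets=brackets,
            rca=rca,
            adjustments=adjustments,
            pigmentation=pigmentation,
            settings={
                "alpha": alpha,
                "rca_iterations": rca_iterations,
                "rca_subset_size": rca_subset_size,
                "seed": seed,
                "rca_tie_policy": rca_tie_policy,
                "rca_stratified": rca_stratified,
                "pigmentation_through_origin": pigmentation_through_origin,
                "force_test": force_test,
            },
        )


def _nan(x):
    return x if x is not None else np.nan


@dataclass
class ExposureStudyResults:
    """Fitted results: one tidy DataFrame per analysis stage."""

    model: ExposureStudy
    associations: pd.DataFrame
    detection: pd.DataFrame
    counts: pd.DataFrame
    brackets: pd.DataFrame
    rca: pd.DataFrame
    adjustments: pd.DataFrame | None = None
    pigmentation: pd.DataFrame | None = None
    settings: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable report of every stage, statsmodels-style."""
        lines = [
            "Exposure-matrix comparison results",
            "=" * 70,
            f"compounds: {len(self.model.registry)}   "
            f"matrices: {', '.join(self.model.table.matrices)}   "
            f"records: {len(self.model.table)}",
            "",
            "Dose-concentration association (detected values only)",
            "-" * 70,
            self.associations.round(4).to_string(index=False),
            "",
            "Reverse classification analysis "
            f"({self.settings.get('rca_iterations', '?')} iterations, "
            f"subsets of {self.settings.get('rca_subset_size', '?')})",
            "-" * 70,
            self.rca.round(3).to_string(index=False),
            "",
            "Significant inter-group brackets "
            f"(alpha={self.settings.get('alpha', 0.05)})",
            "-" * 70,
        ]
        sig = self.brackets[self.brackets["category"] == "significant"]
        lines.append(sig.round(5).to_string(index=False) if len(sig) else "(none)")
        if self.adjustments is not None and len(self.adjustments):
            lines += [
                "",
                "Urinary adjustment comparison (r² vs exposure rate)",
                "-" * 70,
                self.adjustments.round(4).to_string(index=False),
            ]
        if self.pigmentation is not None and len(self.pigmentation):
            lines += [
                "",
                "Pigmentation slopes (white vs black hair)",
                "-" * 70,
                self.pigmentation.round(4).to_string(index=False),
            ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write every stage to CSV under ``outdir`` plus a run log.

        Identical model + settings produce byte-identical numeric outputs.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        frames = {
            "associations": self.associations,
            "detection_matrix": self.detection,
            "counts_per_level": self.counts,
            "brackets": self.brackets,
            "rca": self.rca,
        }
        if self.adjustments is not None:
            frames["adjustments"] = self.adjustments
        if self.pigmentation is not None:
            frames["pigmentation"] = self.pigmentation
        for name, frame in frames.items():
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written[name] = path
        log = outdir / "run_log.txt"
        with open(log, "w") as fh:
            fh.write(f"biomatrix-rca {_version}\n")
            for key in sorted(self.settings):
                fh.write(f"{key} = {self.settings[key]}\n")
        written["run_log"] = log
        return written

    def plot_dose_response(self, compound: str, matrix: str, ax=None):
        """Scatter of detected concentrations vs exposure rate with the OLS
        line whose slope is reported in ``associations``."""
        import matplotlib.pyplot as plt

        sub = self.model.table.subset(compound, matrix)
        det = sub[sub["detected"]]
        if len(det) == 0:
            raise StudyError(f"{compound}/{matrix}: nothing detected to plot")
        rate = np.asarray(self.model.design.exposure_rate(det["dose"].to_numpy()))
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(rate, det["value"], s=18, alpha=0.7)
        row = self.associations[
            (self.associations["compound"] == compound)
            & (self.associations["matrix"] == matrix)
        ]
        if len(row) and row.iloc[0]["status"] == "ok":
            s = row.iloc[0]["slope"]
            x = np.linspace(0, rate.max(), 50)
            inter = det["value"].mean() - s * rate.mean()
            ax.plot(x, inter + s * x, color="crimson", lw=1.5)
        ax.set_xlabel("exposure rate (mg/kg per day)")
        ax.set_ylabel(f"{compound} in {matrix}")
        return ax
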