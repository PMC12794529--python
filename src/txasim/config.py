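"""Run configuration, validation and the end-to-end pipeline.

A run is described by a single YAML/JSON config: model-parameter overrides,
the two cohorts (adult reference and pediatric), the candidate regimens, the
sampling grid, the error mode and one root seed.  All randomness flows from
that seed through deterministic ``numpy.random.SeedSequence`` spawning, with
separate streams per stage (population vs residual error), so toggling the
error mode does not perturb the population draws.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .comparison import (ComparisonReport, build_report, render_report,
                         summaries_to_frame, summarize)
from .exposure import (DEFAULT_CAP_MG, DoseRegimen, SamplingGrid, default_grid,
                       profiles_to_frame, simulate_cohort)
from .model import PopPKParameters
from .nca import DEFAULT_THRESHOLD, metrics_to_frame, nca_batch
from .population import (ADULT_MEDIAN_COVARIATES, PEDIATRIC_RANGES,
                         CovariateRanges, PopulationSpec, generate_population,
                         subjects_to_frame)


class PopulationBlock(BaseModel):
    mode: Literal["adult", "pediatric"]
    n_subjects: int = Field(1000, ge=1)
    fixed_covariates: dict[str, float] = Field(
        default_factory=lambda: dict(ADULT_MEDIAN_COVARIATES))
    ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(PEDIATRIC_RANGES))

    @model_validator(mode="after")
    def _check(self) -> "PopulationBlock":
        if self.mode == "pediatric":
            for name, (lo, hi) in self.ranges.items():
                if not (0 < lo <= hi):
                    raise ValueError(
                        f"population.ranges.{name}: need 0 < lower <= upper, "
                        f"got ({lo}, {hi})")
        else:
            for name, v in self.fixed_covariates.items():
                if not v > 0:
                    raise ValueError(
                        f"population.fixed_covariates.{name} must be positive")
        return self

    def to_spec(self, seed: int = 0) -> PopulationSpec:
        return PopulationSpec(
            n_subjects=self.n_subjects, mode=self.mode,
            fixed_covariates=dict(self.fixed_covariates),
            ranges=CovariateRanges(**{k: tuple(v)
                                      for k, v in self.ranges.items()}),
            seed=seed)


class RegimenBlock(BaseModel):
    label: str
    dose_per_kg: float | None = Field(None, gt=0)
    dose_mg: float | None = Field(None, gt=0)
    cap_mg: float = Field(DEFAULT_CAP_MG, gt=0)
    infusion_duration: float = Field(1.0, gt=0)
    dose_times: list[float] = Field(default_factory=lambda: [0.0])

    @model_validator(mode="after")
    def _check(self) -> "RegimenBlock":
        if (self.dose_per_kg is None) == (self.dose_mg is None):
            raise ValueError(
                f"regimen {self.label!r}: set exactly one of dose_per_kg "
                f"and dose_mg")
        return self

    def to_regimen(self) -> DoseRegimen:
        return DoseRegimen(label=self.label, dose_per_kg=self.dose_per_kg,
                           dose_mg=self.dose_mg, cap_mg=self.cap_mg,
                           infusion_duration=self.infusion_duration,
                           dose_times=tuple(self.dose_times))


class GridBlock(BaseModel):
    times: list[float] | None = None
    horizon: float = Field(480.0, gt=0)

    def to_grid(self) -> SamplingGrid:
        if self.times is not None:
            return SamplingGrid(times=np.asarray(self.times, float))
        return SamplingGrid(times=default_grid(self.horizon))


class RunConfig(BaseModel):
    """Validated top-level configuration for one reproducible run."""

    model_parameters: dict[str, float] = Field(default_factory=dict)
    adult_population: PopulationBlock
    pediatric_population: PopulationBlock
    adult_regimen: RegimenBlock
    pediatric_regimens: list[RegimenBlock] = Field(min_length=1)
    grid: GridBlock = Field(default_factory=GridBlock)
    threshold: float = Field(DEFAULT_THRESHOLD, gt=0)
    auc_windows: tuple[float, float] = (240.0, 480.0)
    error_mode: bool = True
    seed: int = Field(...)

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        errors = []
        try:
            PopPKParameters.from_dict(self.model_parameters)
        except (ValueError, TypeError) as exc:
            errors.append(f"model_parameters: {exc}")
        grid = None
        try:
            grid = self.grid.to_grid()
        except ValueError as exc:
            errors.append(f"grid: {exc}")
        if grid is not None and grid.horizon < max(self.auc_windows):
            errors.append(
                f"grid horizon {grid.horizon:g} min does not cover the "
                f"requested AUC window {max(self.auc_windows):g} min")
        if self.adult_population.mode != "adult":
            errors.append("adult_population.mode must be 'adult'")
        if self.pediatric_population.mode != "pediatric":
            errors.append("pediatric_population.mode must be 'pediatric'")
        if errors:
            raise ValueError("; ".join(errors))
        return self

    def params(self) -> PopPKParameters:
        return PopPKParameters().with_overrides(**self.model_parameters)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML/JSON config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Validate a config file; returns (config, []) or (None, error list)."""
    try:
        return load_config(path), []
    except Exception as exc:  # pydantic aggregates field errors in str(exc)
        return None, [ln for ln in str(exc).splitlines() if ln.strip()]


def default_config() -> RunConfig:
    """The shipped default run: adult 2 g reference plus the 20/25/30/35
    mg/kg pediatric bolus sweep."""
    text = resources.files("txasim").joinpath("data/default_config.yaml") \
        .read_text()
    return RunConfig.model_validate(yaml.safe_load(text))


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(seed)
    adult_pop, ped_pop, adult_err, ped_err, sweep = root.spawn(5)
    return {"adult_pop": adult_pop, "ped_pop": ped_pop,
            "adult_err": adult_err, "ped_err": ped_err, "sweep": sweep}


def run_pipeline(config: RunConfig,
                 outdir: str | Path | None = None) -> ComparisonReport:
    """Population generation -> simulation -> NCA -> comparison.

    When ``outdir`` is given, writes the cohort tables, per-regimen profiles
    and metrics, the summary table, the comparison report and a run log
    (seed, config hash, package version).
    """
    params = config.params()
    seeds = _stage_seeds(config.seed)
    grid = config.grid.to_grid()

    adult_spec = config.adult_population.to_spec()
    ped_spec = config.pediatric_population.to_spec()
    adults = generate_population(
        adult_spec, params, np.random.default_rng(seeds["adult_pop"]))
    peds = generate_population(
        ped_spec, params, np.random.default_rng(seeds["ped_pop"]))

    adult_regimen = config.adult_regimen.to_regimen()
    adult_profiles = simulate_cohort(adults, params, adult_regimen, grid,
                                     config.error_mode, seeds["adult_err"])
    adult_metrics = nca_batch(adult_profiles, config.threshold,
                              config.auc_windows, config.error_mode)
    adult_summary = summarize(adult_metrics, adult_regimen.label)

    ped_summaries = []
    ped_outputs = []
    err_streams = seeds["ped_err"].spawn(len(config.pediatric_regimens))
    for block, ss in zip(config.pediatric_regimens, err_streams):
        regimen = block.to_regimen()
        profiles = simulate_cohort(peds, params, regimen, grid,
                                   config.error_mode, ss)
        metrics = nca_batch(profiles, config.threshold, config.auc_windows,
                            config.error_mode)
        ped_summaries.append(summarize(metrics, regimen.label))
        ped_outputs.append((regimen, profiles, metrics))

    report = build_report(adult_summary, ped_summaries)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        subjects_to_frame(adults).to_csv(outdir / "adult_population.csv",
                                         index=False)
        subjects_to_frame(peds).to_csv(outdir / "pediatric_population.csv",
                                       index=False)
        profiles_to_frame(adult_profiles).to_csv(
            outdir / "profiles_adult.csv", index=False)
        metrics_to_frame(adult_metrics).to_csv(
            outdir / "metrics_adult.csv", index=False)
        for regimen, profiles, metrics in ped_outputs:
            slug = regimen.label.replace(" ", "_").replace("/", "-")
            profiles_to_frame(profiles).to_csv(
                outdir / f"profiles_{slug}.csv", index=False)
            metrics_to_frame(metrics).to_csv(
                outdir / f"metrics_{slug}.csv", index=False)
        summaries_to_frame([adult_summary] + ped_summaries).to_csv(
            outdir / "summary.csv", index=False)
        (outdir / "report.txt").write_text(
            render_report(report, config.threshold) + "\n")
        cfg_json = json.dumps(config.model_dump(), sort_keys=True)
        log = {"seed": config.seed,
               "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
               "txasim_version": __version__,
               "numpy_version": np.__version__}
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
        (outdir / "config_used.json").write_text(cfg_json + "\n")
    return report
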