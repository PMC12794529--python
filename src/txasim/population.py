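"""Virtual cohorts for the dose-extrapolation simulations.

Two cohort types are used.  The adult reference cohort fixes every covariate
at the trial-median values and varies only the lognormal random effects.  The
virtual pediatric trauma cohort samples each covariate independently and
uniformly from literature-derived ranges (25th-75th percentile or mean +/- SD
summaries), again with independently sampled random effects.  Both are fully
seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PopPKParameters, Subject

#: Trial-median adult covariates at time 0.
ADULT_MEDIAN_COVARIATES: dict[str, float] = {
    "weight": 80.1,   # kg
    "plt": 197.0,     # K/uL
    "nirs": 88.0,     # %
    "il8": 20.3,      # pg/mL
}

#: Published pediatric-trauma covariate ranges (closed intervals).
PEDIATRIC_RANGES: dict[str, tuple[float, float]] = {
    "weight": (17.7, 58.2),
    "plt": (205.0, 433.0),
    "nirs": (51.0, 80.0),
    "il8": (6.6, 50.2),
    "age": (4.7, 15.4),
}

_ETA_FIELDS = ("eta_cl", "eta_v1", "eta_q", "eta_v2")
_SUBJECT_COLUMNS = ("id", "weight", "plt", "nirs", "il8", "age") + _ETA_FIELDS


@dataclass(frozen=True)
class CovariateRanges:
    """Closed sampling ranges for pediatric covariates (endpoints inclusive)."""

    weight: tuple[float, float] = PEDIATRIC_RANGES["weight"]
    plt: tuple[float, float] = PEDIATRIC_RANGES["plt"]
    nirs: tuple[float, float] = PEDIATRIC_RANGES["nirs"]
    il8: tuple[float, float] = PEDIATRIC_RANGES["il8"]
    age: tuple[float, float] = PEDIATRIC_RANGES["age"]

    def __post_init__(self) -> None:
        for name in ("weight", "plt", "nirs", "il8", "age"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(
                    f"invalid {name} range ({lo}, {hi}): need 0 < lower <= upper")


@dataclass(frozen=True)
class PopulationSpec:
    """What cohort to generate: size, mode and covariate source."""

    n_subjects: int = 1000
    mode: str = "pediatric"  # "adult" | "pediatric"
    fixed_covariates: dict[str, float] = field(
        default_factory=lambda: dict(ADULT_MEDIAN_COVARIATES))
    ranges: CovariateRanges = field(default_factory=CovariateRanges)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.mode not in ("adult", "pediatric"):
            raise ValueError(f"unknown population mode {self.mode!r}")


def sample_random_effects(params: PopPKParameters, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw (n, 4) independent etas ~ Normal(0, omega^2) for CL, V1, Q, V2.

    The omega matrix is diagonal: no random-effect covariances are modeled.
    """
    sds = np.sqrt([params.omega2_cl, params.omega2_v1,
                   params.omega2_q, params.omega2_v2])
    return rng.standard_normal((n, 4)) * sds


def _as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_adult_cohort(spec: PopulationSpec, params: PopPKParameters,
                          rng: np.random.Generator | None = None
                          ) -> list[Subject]:
    """Adult reference cohort: identical median covariates, sampled etas."""
    if spec.mode != "adult":
        raise ValueError("spec.mode must be 'adult'")
    missing = {"weight", "plt", "nirs", "il8"} - set(spec.fixed_covariates)
    if missing:
        raise ValueError(f"missing fixed covariates: {sorted(missing)}")
    rng = _as_rng(spec.seed) if rng is None else rng
    etas = sample_random_effects(params, spec.n_subjects, rng)
    cov = spec.fixed_covariates
    return [
        Subject(id=f"A{i + 1:04d}", weight=cov["weight"], plt=cov["plt"],
                nirs=cov["nirs"], il8=cov["il8"],
                age=cov.get("age", float("nan")),
                eta_cl=e[0], eta_v1=e[1], eta_q=e[2], eta_v2=e[3])
        for i, e in enumerate(etas)
    ]


def generate_pediatric_population(spec: PopulationSpec,
                                  params: PopPKParameters,
                                  rng: np.random.Generator | None = None
                                  ) -> list[Subject]:
    """Virtual pediatric cohort: covariates uniform on their closed ranges.

    Each covariate is drawn independently (no joint weight-age structure; the
    literature summaries provide none) together with per-subject etas.
    Deterministic given the spec seed.
    """
    if spec.mode != "pediatric":
        raise ValueError("spec.mode must be 'pediatric'")
    rng = _as_rng(spec.seed) if rng is None else rng
    r = spec.ranges
    n = spec.n_subjects
    draws = {
        name: rng.uniform(*getattr(r, name), size=n)
        for name in ("weight", "plt", "nirs", "il8", "age")
    }
    etas = sample_random_effects(params, n, rng)
    return [
        Subject(id=f"P{i + 1:04d}", weight=draws["weight"][i],
                plt=draws["plt"][i], nirs=draws["nirs"][i],
                il8=draws["il8"][i], age=draws["age"][i],
                eta_cl=etas[i, 0], eta_v1=etas[i, 1],
                eta_q=etas[i, 2], eta_v2=etas[i, 3])
        for i in range(n)
    ]


def generate_population(spec: PopulationSpec, params: PopPKParameters,
                        rng: np.random.Generator | None = None
                        ) -> list[Subject]:
    if spec.mode == "adult":
        return generate_adult_cohort(spec, params, rng)
    return generate_pediatric_population(spec, params, rng)


def subjects_to_frame(subjects: Sequence[Subject]) -> pd.DataFrame:
    """One row per subject: id, covariates, age, realized etas."""
    return pd.DataFrame(
        [{c: getattr(s, c) for c in _SUBJECT_COLUMNS} for s in subjects],
        columns=list(_SUBJECT_COLUMNS))


def frame_to_subjects(df: pd.DataFrame) -> list[Subject]:
    missing = set(_SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return [
        Subject(id=str(row.id), weight=float(row.weight), plt=float(row.plt),
                nirs=float(row.nirs), il8=float(row.il8), age=float(row.age),
                eta_cl=float(row.eta_cl), eta_v1=float(row.eta_v1),
                eta_q=float(row.eta_q), eta_v2=float(row.eta_v2))
        for row in df.itertuples(index=False)
    ]


def write_population(subjects: Sequence[Subject], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def read_population(path: str | Path) -> list[Subject]:
    return frame_to_subjects(pd.read_csv(path))
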