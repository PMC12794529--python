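"""Adult two-compartment population-PK model of IV tranexamic acid.

The model describes TXA disposition with a central compartment (volume V1,
elimination clearance CL), a peripheral compartment (volume V2) and an
intercompartmental clearance Q.  Typical values are scaled allometrically by
body weight (exponent 0.75 on the flows CL and Q, 1.0 on the volumes) relative
to a 70 kg reference adult, and clearance additionally carries power terms for
platelet count, skeletal-muscle oxygen saturation (NIRS) and interleukin-8.
Between-subject variability is lognormal: each individual parameter is the
typical value multiplied by exp(eta), eta ~ Normal(0, omega^2).

Internal units are fixed: amounts in mg, volumes in mL, times in minutes,
flows in mL/min.  Concentrations are reported in mg/L (mg/mL x 1000).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping


@dataclass(frozen=True)
class PopPKParameters:
    """Fixed and random-effect parameters of the adult TXA popPK model.

    Defaults are the published final-model values; the slightly different
    point estimates printed in the parameter-estimate table (cl_typ 192,
    exp_il8 -0.0887) can be set via :meth:`with_overrides`.
    """

    cl_typ: float = 190.0      # mL/min at reference covariates
    v1_typ: float = 17_300.0   # mL at 70 kg
    q_typ: float = 80.1        # mL/min at 70 kg
    v2_typ: float = 11_400.0   # mL at 70 kg

    exp_cl_wt: float = 0.75
    exp_q_wt: float = 0.75
    exp_v1_wt: float = 1.0
    exp_v2_wt: float = 1.0

    exp_plt: float = 0.468
    exp_nirs: float = -0.29
    exp_il8: float = -0.0873   # IL-8 enters unnormalized (no reference division)

    ref_wt: float = 70.0       # kg
    ref_plt: float = 196.0     # K/uL
    ref_nirs: float = 88.0     # %

    omega2_cl: float = 0.106
    omega2_v1: float = 0.0688
    omega2_q: float = 0.879
    omega2_v2: float = 0.0589

    sigma2_prop: float = 0.0238

    def __post_init__(self) -> None:
        for name in ("cl_typ", "v1_typ", "q_typ", "v2_typ",
                     "ref_wt", "ref_plt", "ref_nirs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("omega2_cl", "omega2_v1", "omega2_q", "omega2_v2",
                     "sigma2_prop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("exp_cl_wt", "exp_q_wt", "exp_v1_wt", "exp_v2_wt",
                     "exp_plt", "exp_nirs", "exp_il8"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "PopPKParameters":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(d))

    def with_overrides(self, **kwargs: float) -> "PopPKParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Subject:
    """One virtual patient: covariates plus realized random effects.

    Age is carried for reporting only; the model has no age term.
    Etas are on the log scale and multiply their parameter as exp(eta).
    """

    id: str
    weight: float   # kg
    plt: float      # K/uL
    nirs: float     # %
    il8: float      # pg/mL
    age: float = float("nan")  # years, reporting only
    eta_cl: float = 0.0
    eta_v1: float = 0.0
    eta_q: float = 0.0
    eta_v2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("weight", "plt", "nirs", "il8"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("eta_cl", "eta_v1", "eta_q", "eta_v2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class IndividualParameters:
    """Realized disposition parameters for one subject."""

    cl: float   # mL/min
    v1: float   # mL
    q: float    # mL/min
    v2: float   # mL

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class DispositionConstants:
    """Micro and hybrid (macro) rate constants of the two-compartment system.

    alpha and beta are the eigenvalue magnitudes of the disposition matrix
    (alpha > beta > 0); coef_a/coef_b are the central-compartment
    biexponential coefficients for a unit IV bolus, in 1/mL (multiply by the
    dose in mg for a concentration in mg/mL).  ``degenerate`` flags the
    measure-zero alpha == beta case, which is resolved by a relative
    eigenvalue-split floor of 1e-9 (see :func:`disposition_constants`).
    """

    alpha: float
    beta: float
    coef_a: float
    coef_b: float
    k10: float
    k12: float
    k21: float
    degenerate: bool = False


def typical_clearance(subject: Subject, params: PopPKParameters) -> float:
    """Typical-value clearance (mL/min) for a subject's covariates.

    Product of the reference clearance, the allometric weight factor and the
    three covariate power terms (platelets and NIRS normalized to their
    reference values; IL-8 unnormalized).
    """
    return (
        params.cl_typ
        * (subject.weight / params.ref_wt) ** params.exp_cl_wt
        * (subject.plt / params.ref_plt) ** params.exp_plt
        * (subject.nirs / params.ref_nirs) ** params.exp_nirs
        * subject.il8 ** params.exp_il8
    )


def individual_parameters(subject: Subject,
                          params: PopPKParameters) -> IndividualParameters:
    """Realize CL, V1, Q, V2 for a subject (typical value x exp(eta)).

    Covariates other than weight affect clearance only; CL and Q scale with
    (WT/70)^0.75, V1 and V2 with (WT/70)^1.
    """
    wt = subject.weight / params.ref_wt
    return IndividualParameters(
        cl=typical_clearance(subject, params) * math.exp(subject.eta_cl),
        v1=params.v1_typ * wt ** params.exp_v1_wt * math.exp(subject.eta_v1),
        q=params.q_typ * wt ** params.exp_q_wt * math.exp(subject.eta_q),
        v2=params.v2_typ * wt ** params.exp_v2_wt * math.exp(subject.eta_v2),
    )


#: Relative floor on the (alpha - beta) eigenvalue split.  At exactly
#: alpha == beta the biexponential form degenerates; the discriminant is
#: floored so downstream closed forms stay finite, and the result is flagged.
_DEGENERATE_REL_TOL = 1e-9


def disposition_constants(ind: IndividualParameters) -> DispositionConstants:
    """Micro constants and eigen-decomposition of the disposition system.

    k10 = CL/V1, k12 = Q/V1, k21 = Q/V2; alpha and beta are the roots of
    s^2 - (k10+k12+k21) s + k10*k21, so alpha*beta = k10*k21 and
    alpha+beta = k10+k12+k21 hold to machine precision.
    """
    k10 = ind.cl / ind.v1
    k12 = ind.q / ind.v1
    k21 = ind.q / ind.v2
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    floor = (s * _DEGENERATE_REL_TOL) ** 2
    degenerate = disc < floor
    root = math.sqrt(max(disc, floor))
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    # unit-bolus central concentration: (1/V1) [A e^-at + B e^-bt], A+B = 1/V1
    coef_a = (alpha - k21) / (alpha - beta) / ind.v1
    coef_b = (k21 - beta) / (alpha - beta) / ind.v1
    return DispositionConstants(alpha=alpha, beta=beta,
                                coef_a=coef_a, coef_b=coef_b,
                                k10=k10, k12=k12, k21=k21,
                                degenerate=degenerate)
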