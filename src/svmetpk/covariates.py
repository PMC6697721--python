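"""Covariate relationships and per-subject parameter realisation.

The final model carries two covariate effects:

* SLCO1B1 c.521T>C (rs4149056) enters the SVA sub-model additively per C
  allele through two latent parameters: the formation clearance CL_LA
  (coefficient ``theta562``) and the SVA volume V_SVA (``theta561``).  Because
  only the apparent ratios CL_LA/V_SVA and CL_SVAe/V_SVA are identifiable,
  the effect appears as

      CL_LA/V_SVA   -> ratio * (1 + rs56*theta562) / (1 + rs56*theta561)
      CL_SVAe/V_SVA -> ratio / (1 + rs56*theta561)

* Age reduces the apparent elimination ratios of HMSVA and DHSV following a
  sigmoid Imax function ``value * (1 - fra*age/(t50 + age))``; the published
  intercepts are therefore age-0 values.

Machinery for candidate relationships that were screened but rejected
(allometric body size, dominant/recessive genetic forms, other SNPs) is kept
for the covariate-search module; none of it is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np

from .params import BSV_PARAMS, ThetaSet, split_bioavailability

#: genotype columns of the dataset schema, in order
SNP_NAMES = ("rs4149056", "rs4149015", "rs2306283",
             "rs15524", "rs776746", "rs10264272")

GENETIC_MODELS = ("additive", "dominant", "recessive")


@dataclass
class CovariateVector:
    """Demographics and variant-allele counts for one subject."""

    age: float
    weight: float = float("nan")
    height: float = float("nan")
    lean_body_weight: float = float("nan")
    bmi: float = float("nan")
    sex: str = "F"
    rs4149056: int = 0
    rs4149015: int = 0
    rs2306283: int = 0
    rs15524: int = 0
    rs776746: int = 0
    rs10264272: int = 0

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        for name in SNP_NAMES:
            if getattr(self, name) not in (0, 1, 2):
                raise ValueError(f"{name} allele count must be 0, 1 or 2")


def genetic_multiplier(copies, frac, model: str = "additive"):
    """Fractional-change multiplier for a variant-allele count.

    additive: 1 + copies*frac; dominant: 1 + frac for any carrier;
    recessive: 1 + frac only for homozygous variant.
    """
    copies = np.asarray(copies)
    if not np.isin(copies, (0, 1, 2)).all():
        raise ValueError("allele count must be 0, 1 or 2")
    if model == "additive":
        mult = 1.0 + copies * frac
    elif model == "dominant":
        mult = np.where(copies >= 1, 1.0 + frac, 1.0)
    elif model == "recessive":
        mult = np.where(copies == 2, 1.0 + frac, 1.0)
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    if np.any(mult <= 0):
        raise ValueError("genetic multiplier must be positive")
    if np.isscalar(copies) or copies.ndim == 0:
        return float(mult)
    return mult


def age_imax(theta, fra, t50, age):
    """Sigmoid Imax age effect: theta * (1 - fra*age/(t50 + age)).

    Monotone non-increasing in age, bounded below by theta*(1-fra).
    """
    if not t50 > 0:
        raise ValueError("t50 must be positive")
    if not 0.0 <= fra <= 1.0:
        raise ValueError("fra must lie in [0, 1]")
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    out = theta * (1.0 - fra * age / (t50 + age))
    return float(out) if out.ndim == 0 else out


def allometric_scale(value, body_size, reference, exponent):
    """Power-law body-size scaling value*(size/reference)^exponent.

    Exponents 0.75 (clearances) and 1 (volumes) are conventional; body size
    was screened and rejected for this model, so this is selection machinery
    only.
    """
    body_size = np.asarray(body_size, dtype=float)
    if np.any(body_size <= 0) or not reference > 0:
        raise ValueError("body sizes must be positive")
    out = value * (body_size / reference) ** exponent
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# per-subject parameters
# ---------------------------------------------------------------------------

#: structural parameter names realised per subject (ThetaSet minus the
#: covariate coefficients), plus the dose-split fractions
STRUCTURAL_PARAMS = (
    "D1", "D2", "ka1", "ka2", "ALAG", "CL_SLe_F", "V_SL_F",
    "CLLA_VSVA", "CLSVAe_VSVA",
    "CLLH_VHSV", "CLEmax_VHSV", "CLEC50", "gamma",
    "CLAH_VHSVA", "CLHSVHSVA_VHSVA", "CLHSVAe_VHSVA",
    "CLLD_VDHSV", "CLDHSe_VDHSV",
)


@dataclass
class IndividualParams:
    """Realised structural parameters for one subject (after covariates and
    random effects), including the absorption dose fractions F1/F2."""

    D1: float
    D2: float
    ka1: float
    ka2: float
    ALAG: float
    CL_SLe_F: float
    V_SL_F: float
    CLLA_VSVA: float
    CLSVAe_VSVA: float
    CLLH_VHSV: float
    CLEmax_VHSV: float
    CLEC50: float
    gamma: float
    CLAH_VHSVA: float
    CLHSVHSVA_VHSVA: float
    CLHSVAe_VHSVA: float
    CLLD_VDHSV: float
    CLDHSe_VDHSV: float
    F1: float
    F2: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("F1", "F2"):
                if v < 0:
                    raise ValueError(f"{f.name} must be non-negative")
            elif not v > 0:
                raise ValueError(f"{f.name} must be positive")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def typical_params(theta: ThetaSet, age, rs56) -> dict[str, np.ndarray]:
    """Vectorised covariate application (eta = 0).

    ``age`` and ``rs56`` may be scalars or arrays; returns a dict of
    broadcast parameter arrays including F1/F2.
    """
    age = np.asarray(age, dtype=float)
    rs56 = np.asarray(rs56)
    mult_cl_la = genetic_multiplier(rs56, theta.theta562, "additive")
    mult_v_sva = genetic_multiplier(rs56, theta.theta561, "additive")
    f1, f2 = split_bioavailability(theta.BA)
    ones = np.ones(np.broadcast_shapes(age.shape, np.shape(rs56)))
    p = {name: getattr(theta, name) * ones for name in STRUCTURAL_PARAMS}
    p["CLLA_VSVA"] = theta.CLLA_VSVA * mult_cl_la / mult_v_sva * ones
    p["CLSVAe_VSVA"] = theta.CLSVAe_VSVA / mult_v_sva * ones
    p["CLHSVAe_VHSVA"] = age_imax(theta.CLHSVAe_VHSVA, theta.thetaAGE1,
                                  theta.thetaAGE2, age) * ones
    p["CLLD_VDHSV"] = theta.CLLD_VDHSV * ones
    p["CLDHSe_VDHSV"] = age_imax(theta.CLDHSe_VDHSV, theta.thetaAGE3,
                                 theta.thetaAGE4, age) * ones
    p["F1"] = f1 * ones
    p["F2"] = f2 * ones
    return p


def apply_covariates(theta: ThetaSet, cov: CovariateVector) -> IndividualParams:
    """Typical (eta = 0) individual parameters under the final covariate
    model."""
    p = typical_params(theta, cov.age, cov.rs4149056)
    return IndividualParams(**{k: float(np.asarray(v)) for k, v in p.items()})


def individual_params(theta: ThetaSet, cov: CovariateVector,
                      eta: Mapping[str, float]) -> IndividualParams:
    """Realise subject parameters: covariate-adjusted typical value times
    exp(eta) for each BSV-carrying parameter.

    ``eta`` must be indexed exactly over :data:`~svmetpk.params.BSV_PARAMS`.
    """
    if set(eta) != set(BSV_PARAMS):
        raise ValueError("eta must be indexed over the 14 BSV parameters")
    p = apply_covariates(theta, cov).as_dict()
    for name in BSV_PARAMS:
        p[name] = p[name] * float(np.exp(eta[name]))
    return IndividualParams(**p)
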