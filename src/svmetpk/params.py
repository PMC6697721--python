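"""Fixed effects, between-subject variability and residual-error specifications.

The joint model describes simvastatin lactone (SV) and four metabolites --
simvastatin acid (SVA), 6-hydroxymethyl simvastatin (HMSV), 6-hydroxymethyl
simvastatin acid (HMSVA) and 3,5-dihydrodiol simvastatin (DHSV) -- after a
single oral dose.  Metabolite volumes of distribution are not structurally
identifiable from plasma data, so every metabolite parameter is an *apparent*
ratio (formation or elimination clearance divided by the metabolite volume,
units 1/h, except the saturable HMSV elimination capacity which is nM/h).

All quantities are exchanged in hours, litres, nmol, nM and years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np

#: Molar mass of simvastatin (g/mol), used to convert mg doses to nmol so that
#: amount / V is on the nM scale of the bioanalytical data.
SV_MOLAR_MASS = 418.57

#: Analyte labels in canonical order.
ANALYTES = ("SV", "SVA", "HMSV", "HMSVA", "DHSV")


def mg_to_nmol(dose_mg: float) -> float:
    """Convert a simvastatin dose in mg to nmol."""
    return float(dose_mg) * 1e6 / SV_MOLAR_MASS


# ---------------------------------------------------------------------------
# fixed effects
# ---------------------------------------------------------------------------

@dataclass
class ThetaSet:
    """Structural fixed effects and covariate coefficients of the final model.

    Defaults are the published typical values.  ``theta561``/``theta562`` are
    the additive fractional changes per SLCO1B1 c.521C allele on the latent
    V_SVA and CL_LA parameters; ``thetaAGE1..4`` parameterize the sigmoid
    Imax age effect on the HMSVA and DHSV elimination ratios.
    """

    # absorption: two parallel pathways, each sequential zero-order (duration
    # D, h) into a depot followed by first-order (ka, 1/h) transfer
    D1: float = 0.069
    D2: float = 0.39
    ka1: float = 0.030
    ka2: float = 0.41
    BA: float = 0.78           # dose-split parameter: F1=1/(1+BA), F2=BA/(1+BA)
    ALAG: float = 0.18         # lag of the second pathway (h)
    # SV disposition (apparent, /F)
    CL_SLe_F: float = 1300.0   # L/h
    V_SL_F: float = 110.0      # L
    # SVA (apparent ratios, 1/h)
    CLLA_VSVA: float = 0.043
    CLSVAe_VSVA: float = 0.13
    # HMSV: first-order formation, saturable (Hill) elimination
    CLLH_VHSV: float = 16.1
    CLEmax_VHSV: float = 660.0  # nM/h
    CLEC50: float = 20.0        # nM
    gamma: float = 0.86
    # HMSVA: formed from both SVA and HMSV
    CLAH_VHSVA: float = 0.48
    CLHSVHSVA_VHSVA: float = 0.55
    CLHSVAe_VHSVA: float = 4.91
    # DHSV
    CLLD_VDHSV: float = 4.11
    CLDHSe_VDHSV: float = 12.9
    # covariate coefficients
    theta561: float = -0.37    # c.521T>C on V_SVA (fraction per C allele)
    theta562: float = 0.93     # c.521T>C on CL_LA (fraction per C allele)
    thetaAGE1: float = 1.0     # max fractional reduction, CL_HSVAe (fixed)
    thetaAGE2: float = 5.34    # age of 50% reduction, CL_HSVAe (y)
    thetaAGE3: float = 0.90    # max fractional reduction, CL_DHSe
    thetaAGE4: float = 6.3     # age of 50% reduction, CL_DHSe (y)

    _POSITIVE = (
        "D1", "D2", "ka1", "ka2", "ALAG", "CL_SLe_F", "V_SL_F",
        "CLLA_VSVA", "CLSVAe_VSVA", "CLLH_VHSV", "CLEmax_VHSV", "CLEC50",
        "gamma", "CLAH_VHSVA", "CLHSVHSVA_VHSVA", "CLHSVAe_VHSVA",
        "CLLD_VDHSV", "CLDHSe_VDHSV", "thetaAGE2", "thetaAGE4",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._POSITIVE:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.BA < 0:
            raise ValueError("BA must be non-negative")
        for name in ("thetaAGE1", "thetaAGE3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        # denominator of the genotype equations must stay positive for CC
        if not 1.0 + 2.0 * self.theta561 > 0:
            raise ValueError("1 + 2*theta561 must be positive")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kwargs) -> "ThetaSet":
        return replace(self, **kwargs)

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


def split_bioavailability(ba: float):
    """Split the dose between the two absorption pathways.

    F1 = 1/(1+BA) goes through the fast-onset first pathway, F2 = BA/(1+BA)
    through the lagged second pathway; F1 + F2 = 1 by construction.
    """
    if ba < 0:
        raise ValueError("BA must be non-negative")
    f1 = 1.0 / (1.0 + ba)
    return f1, 1.0 - f1


# ---------------------------------------------------------------------------
# between-subject variability
# ---------------------------------------------------------------------------

#: Parameters that carry between-subject variability (exponential model),
#: in canonical order.  All other parameters are purely typical values.
BSV_PARAMS = (
    "D2", "ka2", "ALAG", "CL_SLe_F", "V_SL_F",
    "CLLA_VSVA", "CLSVAe_VSVA",
    "CLLH_VHSV", "CLEC50",
    "CLAH_VHSVA", "CLHSVAe_VHSVA", "CLHSVHSVA_VHSVA",
    "CLLD_VDHSV", "CLDHSe_VDHSV",
)

#: Published BSV magnitudes, reported as CV = sqrt(exp(omega^2) - 1).
TABLE_BSV_CV = {
    "D2": 2.07,
    "ka2": 0.41,
    "ALAG": 1.70,
    "CL_SLe_F": 0.63,
    "V_SL_F": 2.17,
    "CLLA_VSVA": 0.96,
    "CLSVAe_VSVA": 0.79,
    "CLLH_VHSV": 0.26,
    "CLEC50": 0.67,
    "CLAH_VHSVA": 0.33,
    "CLHSVAe_VHSVA": 0.18,
    "CLHSVHSVA_VHSVA": 0.51,
    "CLLD_VDHSV": 0.29,
    "CLDHSe_VDHSV": 0.28,
}


def cv_to_omega2(cv: float) -> float:
    """Variance of a log-normal random effect from its reported CV.

    The CV convention is sqrt(exp(omega^2) - 1), hence omega^2 = ln(1 + cv^2).
    """
    if cv < 0:
        raise ValueError("CV must be non-negative")
    return math.log1p(cv * cv)


def omega2_to_cv(omega2: float) -> float:
    """Inverse of :func:`cv_to_omega2`."""
    if omega2 < 0:
        raise ValueError("omega^2 must be non-negative")
    return math.sqrt(math.expm1(omega2))


@dataclass
class OmegaSpec:
    """Diagonal between-subject variance matrix.

    Off-diagonal correlations are deliberately not supported: they destabilise
    estimation on this design, so only variances are modelled.
    """

    omega2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.omega2.items():
            if name not in BSV_PARAMS:
                raise ValueError(f"unknown BSV parameter {name!r}")
            if v < 0:
                raise ValueError(f"omega^2 for {name} must be non-negative")

    @classmethod
    def from_cv(cls, cv: Mapping[str, float]) -> "OmegaSpec":
        return cls({k: cv_to_omega2(v) for k, v in cv.items()})

    @property
    def names(self) -> tuple[str, ...]:
        """BSV parameters with non-zero variance, in canonical order."""
        return tuple(n for n in BSV_PARAMS if self.omega2.get(n, 0.0) > 0)

    def variances(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = self.names if names is None else tuple(names)
        return np.array([self.omega2.get(n, 0.0) for n in names])

    def cv(self, name: str) -> float:
        return omega2_to_cv(self.omega2.get(name, 0.0))

    def replace(self, **kwargs) -> "OmegaSpec":
        new = dict(self.omega2)
        new.update(kwargs)
        return OmegaSpec(new)


def table_omega() -> OmegaSpec:
    """Published BSV variances of the final model."""
    return OmegaSpec.from_cv(TABLE_BSV_CV)


# ---------------------------------------------------------------------------
# residual error
# ---------------------------------------------------------------------------

@dataclass
class ResidualSpec:
    """Double-exponential residual error model for one analyte.

    On the log scale the observation is

        ln y = ln(f + m) + (f/(f+m)) * eps1 + (m/(f+m)) * eps2

    which behaves proportionally where the prediction f dominates and
    additively (scale m) near and below the quantification limit.  For SV,
    HMSV and DHSV the eps1 variance is phase dependent: ``var1_abs`` applies
    to the absorption phase [0, 2) h and ``var1_elim`` to [2, 8] h.
    """

    analyte: str
    var1_abs: float
    var1_elim: float
    var2: float
    m: float
    fixed_m: bool = False

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        for name in ("var1_abs", "var1_elim", "var2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.m < 0:
            raise ValueError("m must be non-negative")

    def var1(self, time):
        """eps1 variance at observation time(s); boundary 2 h belongs to the
        elimination phase."""
        return np.where(np.asarray(time, dtype=float) < 2.0,
                        self.var1_abs, self.var1_elim)

    def replace(self, **kwargs) -> "ResidualSpec":
        return replace(self, **kwargs)


def table_residuals() -> dict[str, ResidualSpec]:
    """Published residual-error specifications, keyed by analyte."""
    return {
        "SV": ResidualSpec("SV", var1_abs=0.38, var1_elim=0.32, var2=0.30,
                           m=0.012),
        "SVA": ResidualSpec("SVA", var1_abs=0.26, var1_elim=0.26, var2=0.16,
                            m=0.22),
        "HMSV": ResidualSpec("HMSV", var1_abs=0.29, var1_elim=0.24, var2=0.12,
                             m=1e-4, fixed_m=True),
        "HMSVA": ResidualSpec("HMSVA", var1_abs=0.18, var1_elim=0.18,
                              var2=0.10, m=1e-4, fixed_m=True),
        "DHSV": ResidualSpec("DHSV", var1_abs=0.24, var1_elim=0.21,
                             var2=0.086, m=1e-4, fixed_m=True),
    }
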