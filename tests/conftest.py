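import numpy as np
import pytest

from svmetpk.estimate import ModelSpec
from svmetpk.params import OmegaSpec, ResidualSpec, ThetaSet
from svmetpk.simulate import TrialDesign, simulate_trial

np.seterr(all="ignore")


@pytest.fixture(scope="session")
def default_trial():
    """One default-design virtual trial (32 subjects, published model)."""
    return simulate_trial(seed=20240)


@pytest.fixture(scope="session")
def sv_sva_spec():
    """SV-SVA sub-model specification at the published values."""
    return ModelSpec(analytes=("SV", "SVA"))


@pytest.fixture()
def small_design():
    return TrialDesign(n_subjects=8,
                       genotype_counts={"TT": 4, "TC": 3, "CC": 1})


def quiet_residuals(scale: float = 1e-4) -> dict:
    """Residual specs with near-zero noise and no additive offset."""
    return {a: ResidualSpec(a, var1_abs=scale, var1_elim=scale, var2=scale,
                            m=1e-8)
            for a in ("SV", "SVA", "HMSV", "HMSVA", "DHSV")}


def zero_omega() -> OmegaSpec:
    return OmegaSpec({})
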