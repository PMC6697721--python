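"""YAML configuration: model parameters, variability, residual error and
trial design, defaulting to the published final model and study design.

Every value is overridable; unknown keys are rejected so typos never pass
silently.  BSV may be given either as variances (``omega2``) or as CVs
(``bsv_cv``), the latter converted via omega^2 = ln(1 + cv^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .estimate import ModelSpec
from .params import (BSV_PARAMS, OmegaSpec, ResidualSpec, ThetaSet,
                     cv_to_omega2, table_omega, table_residuals)
from .simulate import TrialDesign


class ConfigError(ValueError):
    pass


_DESIGN_KEYS = {"n_subjects", "genotype_counts", "age_range", "lloq",
                "sampling_times", "include_predose"}
_RESID_KEYS = {"var1_abs", "var1_elim", "var2", "m", "fixed_m"}
_TOP_KEYS = {"theta", "omega2", "bsv_cv", "residuals", "design", "seed",
             "dt", "analytes"}


@dataclass
class RunConfig:
    spec: ModelSpec
    design: TrialDesign
    seed: int = 0


def _check_keys(given, allowed, where: str) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: "
                          f"{', '.join(sorted(map(str, unknown)))}")


def load_config(path=None, text: str | None = None) -> RunConfig:
    """Read a config file (or literal text); absent sections fall back to
    the published final model and the study design."""
    if text is None:
        text = "" if path is None else open(path, "r", encoding="utf-8").read()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    theta_over = raw.get("theta", {})
    _check_keys(theta_over, ThetaSet.names(), "theta")
    try:
        theta = ThetaSet(**{k: float(v) for k, v in theta_over.items()})
    except ValueError as err:
        raise ConfigError(f"invalid theta: {err}") from err

    omega = table_omega()
    if "bsv_cv" in raw:
        _check_keys(raw["bsv_cv"], BSV_PARAMS, "bsv_cv")
        omega = omega.replace(**{k: cv_to_omega2(float(v))
                                 for k, v in raw["bsv_cv"].items()})
    if "omega2" in raw:
        _check_keys(raw["omega2"], BSV_PARAMS, "omega2")
        try:
            omega = omega.replace(**{k: float(v)
                                     for k, v in raw["omega2"].items()})
        except ValueError as err:
            raise ConfigError(f"invalid omega2: {err}") from err

    residuals = table_residuals()
    for analyte, over in raw.get("residuals", {}).items():
        if analyte not in residuals:
            raise ConfigError(f"unknown analyte {analyte!r} in residuals")
        _check_keys(over, _RESID_KEYS, f"residuals.{analyte}")
        try:
            residuals[analyte] = residuals[analyte].replace(
                **{k: (bool(v) if k == "fixed_m" else float(v))
                   for k, v in over.items()})
        except ValueError as err:
            raise ConfigError(f"invalid residual spec for {analyte}: {err}") \
                from err

    dkw = dict(raw.get("design", {}))
    _check_keys(dkw, _DESIGN_KEYS, "design")
    if "age_range" in dkw:
        dkw["age_range"] = tuple(float(v) for v in dkw["age_range"])
    if "sampling_times" in dkw:
        dkw["sampling_times"] = tuple(float(v)
                                      for v in dkw["sampling_times"])
    try:
        design = TrialDesign(**dkw)
    except ValueError as err:
        raise ConfigError(f"invalid design: {err}") from err

    kw = {}
    if "analytes" in raw:
        kw["analytes"] = tuple(raw["analytes"])
    if "dt" in raw:
        kw["dt"] = float(raw["dt"])
    spec = ModelSpec(theta=theta, omega=omega, residuals=residuals, **kw)
    return RunConfig(spec=spec, design=design, seed=int(raw.get("seed", 0)))


#: conventional alias
read_config = load_config
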