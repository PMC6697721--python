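"""Stepwise covariate model building.

Stage 1 screens covariates against the empirical Bayes estimates of the
base model: simple linear regression for continuous covariates, one-way
ANOVA across groups for categorical ones (allele counts, sex).  Parameters
whose eta shrinkage exceeds 40% give unreliable EBEs, so their candidate
relationships are flagged for direct testing in the model irrespective of
the screening p-value.

Stage 2 is a greedy likelihood-ratio search: forward inclusion requires the
OFV drop to exceed the chi-squared 0.05 quantile for the candidate's degrees
of freedom (3.84 for 1 df), backward elimination retains a covariate only if
its removal raises the OFV by more than the 0.005 quantile (7.88 for 1 df).
Ties are broken by candidate-list order; the search is deterministic given
the dataset and the candidate ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import (CovariateEffect, FitError, LaplaceEstimator, ModelSpec)

#: covariates treated as categorical in screening
CATEGORICAL = ("SEX", "RS4149056", "RS4149015", "RS2306283",
               "RS15524", "RS776746", "RS10264272")

SHRINKAGE_DIRECT_THRESHOLD = 40.0  # percent


@dataclass
class CovariateCandidate:
    """A screened (parameter, covariate) pair proposed for model testing."""

    param: str
    covariate: str
    relationship: str = "additive"   # effect kind for model testing
    p_value: float = float("nan")
    direct_test: bool = False        # high shrinkage: bypass the screen

    def effect(self, reference: float = 0.0) -> CovariateEffect:
        return CovariateEffect(self.param, self.covariate,
                               kind=self.relationship, reference=reference)


def screen_covariates(ebes: pd.DataFrame, covariates: pd.DataFrame,
                      shrinkage: pd.DataFrame | None = None,
                      alpha: float = 0.05,
                      relationships: dict[str, str] | None = None
                      ) -> list[CovariateCandidate]:
    """Rank (eta, covariate) associations for candidacy.

    ``ebes``: per-subject EBEs (ID + one column per BSV parameter).
    ``covariates``: per-subject covariate table (ID + columns).
    ``shrinkage``: optional output of :func:`svmetpk.estimate.shrinkage`;
    candidates on parameters above the 40% threshold carry ``direct_test``.
    Returns candidates with p-value below ``alpha`` (or flagged direct),
    sorted by p-value.
    """
    merged = ebes.merge(covariates, on="ID")
    high = set()
    if shrinkage is not None:
        high = set(shrinkage.loc[shrinkage["high"], "param"])
    out: list[CovariateCandidate] = []
    params = [c for c in ebes.columns if c != "ID"]
    for cov in covariates.columns:
        if cov == "ID":
            continue
        x = merged[cov]
        if x.nunique() <= 1:
            warnings.warn(f"covariate {cov} is constant; excluded from "
                          "screening")
            continue
        for par in params:
            y = merged[par].to_numpy(dtype=float)
            if cov in CATEGORICAL:
                groups = [y[(x == lv).to_numpy()] for lv in sorted(x.unique())]
                with np.errstate(invalid="ignore"):
                    _, p = stats.f_oneway(*groups)
                rel = "additive" if cov.startswith("RS") else "loglinear"
            else:
                res = stats.linregress(x.to_numpy(dtype=float), y)
                p = res.pvalue
                rel = "loglinear"
            if relationships and (par, cov) in relationships:
                rel = relationships[(par, cov)]
            direct = par in high
            if direct or (np.isfinite(p) and p < alpha):
                out.append(CovariateCandidate(par, cov, rel,
                                              float(p), direct))
    out.sort(key=lambda c: (not c.direct_test, c.p_value))
    return out


@dataclass
class SelectionStep:
    """One row of the forward/backward trace."""

    stage: str              # 'forward' or 'backward'
    candidate: str
    df: int
    ofv: float
    delta_ofv: float
    threshold: float
    decision: str           # 'added', 'rejected', 'kept', 'removed'


@dataclass
class SelectionResult:
    final_spec: ModelSpec
    selected: list[CovariateEffect]
    trace: pd.DataFrame
    base_ofv: float
    final_ofv: float


def _effect_free_names(effects: Sequence[CovariateEffect]) -> list[str]:
    names: list[str] = []
    for eff in effects:
        names.extend(eff.coef_names)
    return names


def _fit_with_effects(dataset, spec: ModelSpec, free_base: Sequence[str],
                      effects: Sequence[CovariateEffect],
                      method: str, maxiter: int):
    trial = spec.copy()
    trial.effects = tuple(effects)
    for eff in effects:
        for name, v in eff.init_values().items():
            trial.betas.setdefault(name, v)
    est = LaplaceEstimator(dataset, trial)
    free = list(free_base) + _effect_free_names(effects)
    if not free:
        return est.ofv(), trial
    fit = est.fit(free, method=method, maxiter=maxiter)
    return fit.ofv, fit.spec


def forward_backward_select(dataset, candidates: Sequence[CovariateCandidate],
                            base_spec: ModelSpec,
                            free_base: Sequence[str] = (),
                            forward_alpha: float = 0.05,
                            backward_alpha: float = 0.005,
                            method: str = "lbfgsb",
                            maxiter: int = 100) -> SelectionResult:
    """Greedy forward inclusion / backward elimination on the OFV.

    ``free_base`` lists additional parameters re-estimated in every step
    (the base model's free set); candidate coefficients are added on top.
    Thresholds are chi-squared quantiles at the candidate's degrees of
    freedom; a failed refit rejects the candidate with a warning rather
    than aborting the search.
    """
    base_ofv, base_spec_fit = _fit_with_effects(
        dataset, base_spec, free_base, base_spec.effects, method, maxiter)
    steps: list[SelectionStep] = []
    selected: list[CovariateEffect] = list(base_spec.effects)
    current_ofv = base_ofv
    current_spec = base_spec_fit
    remaining = [c.effect() for c in candidates]

    # forward inclusion: best candidate per sweep while any passes
    while remaining:
        best = None
        for eff in remaining:
            thr = stats.chi2.ppf(1.0 - forward_alpha, eff.df)
            try:
                ofv, spec_fit = _fit_with_effects(
                    dataset, current_spec, free_base, selected + [eff],
                    method, maxiter)
            except FitError as err:
                warnings.warn(f"forward step for {eff.param}~{eff.covariate} "
                              f"failed: {err}")
                steps.append(SelectionStep("forward",
                                           f"{eff.param}~{eff.covariate}",
                                           eff.df, float("nan"), float("nan"),
                                           thr, "failed"))
                continue
            delta = current_ofv - ofv
            decision = "candidate" if delta > thr else "rejected"
            steps.append(SelectionStep("forward",
                                       f"{eff.param}~{eff.covariate}",
                                       eff.df, ofv, delta, thr, decision))
            if delta > thr and (best is None or delta > best[0]):
                best = (delta, eff, ofv, spec_fit)
        if best is None:
            break
        _, eff, ofv, spec_fit = best
        selected.append(eff)
        remaining = [e for e in remaining if e is not eff]
        current_ofv = ofv
        current_spec = spec_fit
        steps.append(SelectionStep("forward", f"{eff.param}~{eff.covariate}",
                                   eff.df, ofv, base_ofv - ofv,
                                   stats.chi2.ppf(1 - forward_alpha, eff.df),
                                   "added"))

    # backward elimination: drop any effect whose removal costs too little
    changed = True
    while changed:
        changed = False
        for eff in [e for e in selected if e not in base_spec.effects]:
            thr = stats.chi2.ppf(1.0 - backward_alpha, eff.df)
            reduced = [e for e in selected if e is not eff]
            try:
                ofv, spec_fit = _fit_with_effects(
                    dataset, current_spec, free_base, reduced, method,
                    maxiter)
            except FitError as err:
                warnings.warn(f"backward step for {eff.param}~"
                              f"{eff.covariate} failed: {err}")
                continue
            delta = ofv - current_ofv
            if delta > thr:
                steps.append(SelectionStep(
                    "backward", f"{eff.param}~{eff.covariate}", eff.df,
                    ofv, delta, thr, "kept"))
            else:
                steps.append(SelectionStep(
                    "backward", f"{eff.param}~{eff.covariate}", eff.df,
                    ofv, delta, thr, "removed"))
                selected = reduced
                current_ofv = ofv
                current_spec = spec_fit
                changed = True
                break

    trace = pd.DataFrame([s.__dict__ for s in steps])
    return SelectionResult(current_spec, list(selected), trace,
                           base_ofv, current_ofv)
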