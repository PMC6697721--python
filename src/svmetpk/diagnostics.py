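"""Model evaluation: visual predictive checks, nonparametric bootstrap,
conditional weighted residuals and BLQ summaries.

The VPC simulates a large number of virtual individuals per dose group,
resampling whole covariate vectors from the analysed dataset (with
replacement, preserving the covariate covariance structure), and overlays
observed data on the simulated 5th/50th/95th percentile bands.  A companion
panel tracks the fraction of samples below the quantification limit, with a
90% prediction band obtained by splitting the simulated individuals into
replicate trials of the observed size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariates import typical_params
from .dataio import ANALYTE_CODES, CODE_ANALYTES
from .estimate import FitError, LaplaceEstimator, ModelSpec
from .params import ANALYTES
from .simulate import apply_residual_error, censor_blq
from .structural import predict_profiles


@dataclass
class VpcResult:
    """Percentile and BLQ-fraction bands per analyte/dose plus observed
    points, all as tidy DataFrames (tests and plots read the numbers, never
    images)."""

    bands: pd.DataFrame        # dose, analyte, time, p5, p50, p95
    blq_bands: pd.DataFrame    # dose, analyte, time, lo90, median, hi90, observed
    observed: pd.DataFrame     # dose, analyte, time, dv, blq
    n_sim: int


def _simulate_individuals(spec: ModelSpec, cov: pd.DataFrame, dose_nmol,
                          times, lloq: Mapping[str, float], rng,
                          analytes: Sequence[str]):
    """Simulate analyte observations for one batch of virtual individuals
    whose covariates are the rows of ``cov``."""
    n = len(cov)
    age = cov["AGE"].to_numpy(dtype=float)
    rs56 = cov["RS4149056"].to_numpy(dtype=int)
    p = typical_params(spec.theta, age, rs56)
    names = [nm for nm in spec.omega.names]
    sd = np.sqrt(spec.omega.variances(names))
    eta = rng.normal(0.0, 1.0, size=(n, len(names))) * sd
    for k, nm in enumerate(names):
        p[nm] = p[nm] * np.exp(eta[:, k])
    prof = predict_profiles(times, dose_nmol, p, analytes=analytes,
                            dt=spec.dt)
    out = {}
    for a in analytes:
        rs = spec.residuals[a]
        y = apply_residual_error(prof[a], rs, times, rng)
        out[a] = y
    return out


def vpc(spec: ModelSpec, dataset, n_sim: int = 1000, seed: int = 0,
        analytes: Sequence[str] = ANALYTES,
        stratify_genotype: bool = False) -> VpcResult:
    """Visual predictive check of ``spec`` against ``dataset``.

    Simulates ``n_sim`` individuals per dose group (covariate vectors
    resampled with replacement from the dataset) at the nominal sampling
    times and summarises 5th/50th/95th percentiles and BLQ fractions.
    With ``stratify_genotype`` the bands are computed per c.521T>C group
    (dose strata merged).
    """
    df = dataset.df if hasattr(dataset, "df") else dataset
    obs = df[df["EVID"] == 0].copy()
    obs = obs[obs["TIME"] > 0]
    doses = df[df["EVID"] == 1][["ID", "AMT"]].rename(columns={"AMT": "DOSE"})
    obs = obs.merge(doses, on="ID")
    cov_tab = df[df["EVID"] == 1].drop_duplicates("ID")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    times = np.unique(obs["TIME"].to_numpy())
    lloq = {a: float(obs.loc[obs["CMT"] == ANALYTE_CODES[a], "LLOQ"].iloc[0])
            if (obs["CMT"] == ANALYTE_CODES[a]).any() else 0.5
            for a in analytes}

    strata = ("RS4149056",) if stratify_genotype else ("DOSE",)
    if stratify_genotype:
        cov_tab = cov_tab.assign(DOSE=cov_tab["AMT"])
        groups = cov_tab.groupby("RS4149056")
    else:
        cov_tab = cov_tab.assign(DOSE=cov_tab["AMT"])
        groups = cov_tab.groupby("DOSE")

    bands_rows, blq_rows, obs_rows = [], [], []
    for gval, g in groups:
        n_obs_subj = len(g)
        if n_obs_subj == 0:
            warnings.warn(f"empty stratum {gval}")
            continue
        take = rng.integers(0, n_obs_subj, size=n_sim)
        cov = g.iloc[take].reset_index(drop=True)
        dose_nmol = cov["AMT"].to_numpy(dtype=float)
        sims = _simulate_individuals(spec, cov, dose_nmol, times, lloq, rng,
                                     analytes)
        n_rep = max(n_sim // n_obs_subj, 1)
        for a in analytes:
            y = sims[a]
            q5, q50, q95 = np.percentile(y, [5, 50, 95], axis=0)
            for j, t in enumerate(times):
                bands_rows.append({"stratum": gval, "analyte": a,
                                   "time": t, "p5": q5[j], "p50": q50[j],
                                   "p95": q95[j]})
            blq = y < lloq[a]
            # replicate trials of the observed size for the 90% band
            rep = blq[:n_rep * n_obs_subj].reshape(n_rep, n_obs_subj, -1)
            frac = rep.mean(axis=1)
            lo, med, hi = np.percentile(frac, [5, 50, 95], axis=0)
            sel = obs["CMT"] == ANALYTE_CODES[a]
            if stratify_genotype:
                sel &= obs["RS4149056"] == gval
            else:
                sel &= obs["DOSE"] == gval
            for j, t in enumerate(times):
                o = obs[sel & (obs["TIME"] == t)]
                blq_rows.append({"stratum": gval, "analyte": a, "time": t,
                                 "lo90": lo[j], "median": med[j],
                                 "hi90": hi[j],
                                 "observed": o["BLQ"].mean()
                                 if len(o) else np.nan})
        sel = obs["RS4149056"] == gval if stratify_genotype \
            else obs["DOSE"] == gval
        for _, r in obs[sel].iterrows():
            obs_rows.append({"stratum": gval,
                             "analyte": CODE_ANALYTES[r["CMT"]],
                             "time": r["TIME"], "dv": r["DV"],
                             "blq": int(r["BLQ"])})
    return VpcResult(pd.DataFrame(bands_rows), pd.DataFrame(blq_rows),
                     pd.DataFrame(obs_rows), n_sim)


def bootstrap(dataset, spec: ModelSpec, free: Sequence[str],
              n_boot: int = 500, seed: int = 0, method: str = "lbfgsb",
              maxiter: int = 100, inner_tol: float = 1e-4,
              identity_resample: bool = False) -> pd.DataFrame:
    """Nonparametric bootstrap: resample subjects with replacement, refit,
    report percentile confidence intervals.

    Refits start from the point estimate in ``spec`` (standard practice,
    speeds convergence) and run the inner mode search at a looser
    tolerance than point estimation -- percentile intervals are far wider
    than the resulting parameter noise.  Returns a DataFrame indexed by
    parameter with estimate, ci2.5, ci97.5, boot_median; a failure
    fraction above 20% raises a hard warning.
    """
    df = dataset.df if hasattr(dataset, "df") else dataset
    if df[df["EVID"] == 1]["ID"].nunique() < 2:
        raise FitError("bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    point = {n: spec.get(n) for n in free}
    est = LaplaceEstimator(dataset, spec, inner_tol=inner_tol, refine=False)
    n = est.n_subjects
    rows = []
    n_failed = 0
    for b in range(n_boot):
        # resampling subjects with replacement is exactly a frequency
        # reweighting of the independent per-subject marginal likelihoods
        if identity_resample:
            counts = np.ones(n)
        else:
            counts = np.bincount(rng.integers(0, n, size=n), minlength=n)
        est.subject_weights = counts.astype(float)
        try:
            fit = est.fit(free, init=dict(point), method=method,
                          maxiter=maxiter, compute_ebes=False)
            rows.append(fit.estimates)
        except (FitError, ValueError) as err:
            n_failed += 1
            warnings.warn(f"bootstrap replicate {b} failed: {err}")
    est.subject_weights = np.ones(n)
    if n_boot and n_failed / n_boot > 0.2:
        warnings.warn(f"bootstrap: {n_failed}/{n_boot} refits failed -- "
                      "confidence intervals are unreliable", stacklevel=2)
    est = pd.DataFrame(rows)
    out = pd.DataFrame({
        "estimate": [point[n] for n in free],
        "ci2.5": [np.percentile(est[n], 2.5) if len(est) else np.nan
                  for n in free],
        "ci97.5": [np.percentile(est[n], 97.5) if len(est) else np.nan
                   for n in free],
        "boot_median": [est[n].median() if len(est) else np.nan
                        for n in free],
    }, index=free)
    out.attrs["n_failed"] = n_failed
    out.attrs["n_boot"] = n_boot
    return out


def cwres(dataset, spec: ModelSpec) -> pd.DataFrame:
    """Conditional weighted residuals (FOCE-style linearisation at the
    EBEs) for the non-censored observations.

    Censored rows are excluded and flagged.  Returns a tidy frame with
    ID, time, analyte, dv, pred (population prediction, eta = 0) and cwres.
    """
    est = LaplaceEstimator(dataset, spec)
    eta, mu, w2, G, ok = est.linearized()
    omega2 = est.spec.omega.variances(est.bsv_names)
    # population prediction on the log scale (eta = 0)
    pop_mu, _ = est._moments(est._pop_params(), est._residual_rows(),
                             np.zeros_like(eta))
    rows = []
    for i in range(est.n_subjects):
        sel = ok[i]
        if not sel.any():
            continue
        Gi = G[i][sel]
        cov = Gi @ (omega2[:, None] * Gi.T) + np.diag(w2[i][sel])
        # FOCE residual: observed minus linearised population mean
        resid = (est.logdv[i][sel] - (mu[i][sel] - Gi @ eta[i]))
        w, v = np.linalg.eigh(cov)
        if np.any(w <= 1e-12):
            warnings.warn(f"singular linearised covariance for subject "
                          f"{est.subject_ids[i]}; eigenvalues clipped "
                          "(pseudo-inverse square root)")
            w = np.maximum(w, 1e-12)
        half_inv = v @ np.diag(1.0 / np.sqrt(w)) @ v.T
        cw = half_inv @ resid
        times = est.time[i][sel]
        codes = est.code[i][sel]
        for j in range(sel.sum()):
            rows.append({"ID": est.subject_ids[i], "time": times[j],
                         "analyte": CODE_ANALYTES[int(codes[j])],
                         "logdv": est.logdv[i][sel][j],
                         "pred": pop_mu[i][sel][j], "cwres": cw[j]})
    return pd.DataFrame(rows)


def blq_summary(dataset) -> pd.DataFrame:
    """Observation counts and censored fractions per analyte (post-dose
    rows)."""
    df = dataset.df if hasattr(dataset, "df") else dataset
    obs = df[(df["EVID"] == 0) & (df["TIME"] > 0)]
    if len(obs) == 0:
        raise ValueError("dataset has no post-dose observations")
    rows = []
    for a in ANALYTES:
        g = obs[obs["CMT"] == ANALYTE_CODES[a]]
        if len(g) == 0:
            continue
        n_cens = int((g["BLQ"] == 1).sum())
        rows.append({"analyte": a, "n": len(g), "n_blq": n_cens,
                     "fraction_blq": n_cens / len(g)})
    return pd.DataFrame(rows)
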