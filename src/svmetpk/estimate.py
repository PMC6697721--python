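"""Marginal-likelihood estimation by the Laplace approximation.

The subject-level marginal likelihood integrates the conditional likelihood
(censored double-exponential observation model, see :mod:`svmetpk.likelihood`)
over the subject's random effects eta ~ N(0, Omega) with diagonal Omega and
an exponential parameter model (parameter = typical * exp(eta)).  The
integral is approximated by expanding the joint log-density around its mode:

    -2 ln L_i  ~=  2 * negjoint_i(eta_hat) + ln det(Omega) + ln det(H_i)

where negjoint is the negative joint log-density (without the per-observation
2*pi constants, NONMEM convention) and H_i its Hessian in eta at the mode.
The population objective OFV is the sum over subjects; differences are
comparable to chi-squared quantiles in likelihood-ratio tests.

The inner mode search runs batched over all subjects (damped Newton with a
finite-difference Hessian that is frozen between refreshes), warm-started
from the previous outer iteration; the outer optimisation works on
log/logit-transformed parameters.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .covariates import (age_imax, allometric_scale, genetic_multiplier,
                         typical_params)
from .dataio import CODE_ANALYTES
from .likelihood import censored_curvature, row_nll_moments
from .params import (ANALYTES, BSV_PARAMS, OmegaSpec, ResidualSpec, ThetaSet)
from .structural import predict_profiles

#: BSV-carrying parameters needed to predict each analyte (with upstream
#: dependencies included)
_SV_SET = ("D2", "ka2", "ALAG", "CL_SLe_F", "V_SL_F")
ANALYTE_BSV = {
    "SV": _SV_SET,
    "SVA": _SV_SET + ("CLLA_VSVA", "CLSVAe_VSVA"),
    "DHSV": _SV_SET + ("CLLD_VDHSV", "CLDHSe_VDHSV"),
    "HMSV": _SV_SET + ("CLLH_VHSV", "CLEC50"),
    "HMSVA": _SV_SET + ("CLLA_VSVA", "CLSVAe_VSVA", "CLLH_VHSV", "CLEC50",
                        "CLAH_VHSVA", "CLHSVAe_VHSVA", "CLHSVHSVA_VHSVA"),
}


class FitError(RuntimeError):
    """Estimation failure (non-convergence, non-finite objective)."""


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

class Transform:
    """Bijection between a natural parameter and the unconstrained scale."""

    def to_internal(self, x: float) -> float:
        raise NotImplementedError

    def to_natural(self, z: float) -> float:
        raise NotImplementedError


class LogTransform(Transform):
    def to_internal(self, x):
        if x <= 0:
            raise ValueError("log-transformed parameter must be positive")
        return math.log(x)

    def to_natural(self, z):
        return math.exp(min(max(z, -700.0), 700.0))


class LogitTransform(Transform):
    def __init__(self, lo: float, hi: float):
        self.lo, self.hi = lo, hi

    def to_internal(self, x):
        if not self.lo < x < self.hi:
            raise ValueError(f"parameter must lie in ({self.lo}, {self.hi})")
        u = (x - self.lo) / (self.hi - self.lo)
        return math.log(u / (1.0 - u))

    def to_natural(self, z):
        z = min(max(z, -700.0), 700.0)
        if z >= 0:
            u = 1.0 / (1.0 + math.exp(-z))
        else:
            e = math.exp(z)
            u = e / (1.0 + e)
        return self.lo + (self.hi - self.lo) * u


class IdentityTransform(Transform):
    def to_internal(self, x):
        return x

    def to_natural(self, z):
        return z


def default_transform(name: str) -> Transform:
    """Transform used for a free parameter: log for positives, bounded
    logits for the fractional-change coefficients."""
    if name in ("theta561", "theta562") or name.startswith("beta_gen_"):
        return LogitTransform(-0.5, 5.0)
    if name == "thetaAGE3" or name.startswith("beta_fra_"):
        return LogitTransform(0.0, 1.0)
    if name.startswith("beta_lin_") or name.startswith("beta_exp_"):
        return IdentityTransform()
    return LogTransform()


# ---------------------------------------------------------------------------
# covariate-effect machinery (candidate relationships for the search)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative covariate relationship on one structural parameter.

    ``kind``: 'additive' | 'dominant' | 'recessive' (genetic fractional
    change), 'allometric' (fixed exponent, no free coefficient), 'loglinear'
    (exp(beta*(x - ref)) for continuous covariates) or 'imax' (sigmoid age
    effect with free fraction and t50).
    """

    param: str
    covariate: str          # dataset column, e.g. "RS15524" or "AGE"
    kind: str = "additive"
    reference: float = 0.0  # centring value (loglinear) or size (allometric)
    exponent: float = 0.75  # allometric only

    @property
    def coef_names(self) -> tuple[str, ...]:
        tag = f"{self.param}_{self.covariate}"
        if self.kind in ("additive", "dominant", "recessive"):
            return (f"beta_gen_{tag}",)
        if self.kind == "loglinear":
            return (f"beta_exp_{tag}",)
        if self.kind == "imax":
            return (f"beta_fra_{tag}", f"beta_t50_{tag}")
        if self.kind == "allometric":
            return ()
        raise ValueError(f"unknown effect kind {self.kind!r}")

    @property
    def df(self) -> int:
        return len(self.coef_names)

    def init_values(self) -> dict[str, float]:
        if self.kind in ("additive", "dominant", "recessive"):
            return {self.coef_names[0]: 0.05}
        if self.kind == "loglinear":
            return {self.coef_names[0]: 0.0}
        if self.kind == "imax":
            return {self.coef_names[0]: 0.5, self.coef_names[1]: 5.0}
        return {}

    def multiplier(self, betas: Mapping[str, float], x: np.ndarray):
        if self.kind in ("additive", "dominant", "recessive"):
            return genetic_multiplier(x.astype(int),
                                      betas[self.coef_names[0]], self.kind)
        if self.kind == "loglinear":
            return np.exp(betas[self.coef_names[0]] * (x - self.reference))
        if self.kind == "imax":
            fra = betas[self.coef_names[0]]
            t50 = betas[self.coef_names[1]]
            return 1.0 - fra * x / (t50 + x)
        if self.kind == "allometric":
            return allometric_scale(1.0, x, self.reference, self.exponent)
        raise ValueError(self.kind)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Everything needed to evaluate the population likelihood."""

    theta: ThetaSet = field(default_factory=ThetaSet)
    omega: OmegaSpec = None
    residuals: dict[str, ResidualSpec] = None
    analytes: tuple[str, ...] = ANALYTES
    effects: tuple[CovariateEffect, ...] = ()
    betas: dict[str, float] = field(default_factory=dict)
    dt: float = 0.005

    def __post_init__(self) -> None:
        from .params import table_omega, table_residuals
        if self.omega is None:
            self.omega = table_omega()
        if self.residuals is None:
            self.residuals = table_residuals()
        for eff in self.effects:
            for name, v in eff.init_values().items():
                self.betas.setdefault(name, v)

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)

    def add_effects(self, *effects: "CovariateEffect") -> None:
        """Attach covariate effects, seeding their coefficients at the
        standard starting values."""
        self.effects = tuple(self.effects) + tuple(effects)
        for eff in effects:
            for name, v in eff.init_values().items():
                self.betas.setdefault(name, v)

    # -- generic named-parameter access ------------------------------------
    def get(self, name: str) -> float:
        if name in ThetaSet.names():
            return getattr(self.theta, name)
        if name.startswith("omega2_"):
            return self.omega.omega2.get(name[len("omega2_"):], 0.0)
        if name.startswith("beta_"):
            return self.betas[name]
        analyte, _, what = name.partition("_")
        if analyte in ANALYTES and what:
            return getattr(self.residuals[analyte], what)
        raise KeyError(f"unknown parameter {name!r}")

    def set(self, name: str, value: float) -> None:
        if name in ThetaSet.names():
            self.theta = self.theta.replace(**{name: value})
        elif name.startswith("omega2_"):
            self.omega = self.omega.replace(**{name[len("omega2_"):]: value})
        elif name.startswith("beta_"):
            self.betas[name] = value
        else:
            analyte, _, what = name.partition("_")
            if analyte in ANALYTES and what:
                self.residuals = dict(self.residuals)
                self.residuals[analyte] = \
                    self.residuals[analyte].replace(**{what: value})
            else:
                raise KeyError(f"unknown parameter {name!r}")


@dataclass
class FitResult:
    """Converged population fit."""

    spec: ModelSpec
    estimates: dict[str, float]
    ofv: float
    converged: bool
    n_ofv_evals: int
    ebes: pd.DataFrame            # subject ID + eta_hat per BSV parameter
    shrinkage: dict[str, float]   # percent, NaN where omega^2 = 0
    se: dict[str, float] | None = None
    message: str = ""


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class LaplaceEstimator:
    """Population Laplace estimator bound to one dataset and model spec."""

    def __init__(self, dataset, spec: ModelSpec,
                 inner_tol: float = 1e-5, inner_maxit: int = 60,
                 fd_grad: float = 1e-4, fd_hess: float = 5e-3,
                 hessian: str = "gn", refine: bool = True):
        if hessian not in ("gn", "exact"):
            raise ValueError("hessian must be 'gn' or 'exact'")
        self.hessian = hessian
        #: exact-Newton refinement of straggler modes; switching it off
        #: trades ~1e-2 OFV accuracy for a several-fold speed-up (used for
        #: bootstrap replicates, never for point estimation)
        self.refine = refine
        self.spec = spec.copy()
        self.inner_tol = inner_tol
        self.inner_maxit = inner_maxit
        self.fd_grad = fd_grad
        self.fd_hess = fd_hess
        self._prepare(dataset)
        self.bsv_names = tuple(
            n for n in self.spec.omega.names
            if any(n in ANALYTE_BSV[a] for a in self.spec.analytes))
        self._eta_cache = np.zeros((self.n_subjects, len(self.bsv_names)))
        # frequency weights per subject: a with-replacement resample of
        # subjects is exactly a reweighted sum of the independent
        # per-subject marginal contributions
        self.subject_weights = np.ones(self.n_subjects)
        self.n_ofv_evals = 0

    # -- data preparation ---------------------------------------------------
    def _prepare(self, dataset) -> None:
        df = dataset.df if hasattr(dataset, "df") else dataset
        obs = df[(df["EVID"] == 0) & ~((df["BLQ"] == 1) & (df["TIME"] == 0.0))]
        doses = df[df["EVID"] == 1]
        codes = [c for c, a in CODE_ANALYTES.items()
                 if a in self.spec.analytes]
        obs = obs[obs["CMT"].isin(codes)]
        ids = sorted(doses["ID"].unique())
        if len(ids) == 0:
            raise FitError("dataset has no dose rows")
        self.subject_ids = np.asarray(ids)
        self.n_subjects = len(ids)
        groups = {sid: g for sid, g in obs.groupby("ID")}
        rmax = max((len(g) for g in groups.values()), default=0)
        if rmax == 0:
            raise FitError("dataset has no usable observations")
        n = self.n_subjects

        def alloc(fill=0.0):
            return np.full((n, rmax), fill)

        self.time = alloc()
        self.code = np.zeros((n, rmax), dtype=int)
        self.logdv = alloc(np.nan)
        self.blq = np.zeros((n, rmax), dtype=bool)
        self.loglloq = alloc()
        self.mask = np.zeros((n, rmax), dtype=bool)
        self.dose = np.zeros(n)
        cov_rows = []
        for i, sid in enumerate(ids):
            g = groups.get(sid)
            drow = doses[doses["ID"] == sid].iloc[0]
            self.dose[i] = drow["AMT"]
            cov_rows.append(drow)
            if g is None:
                continue
            r = len(g)
            self.time[i, :r] = g["TIME"].to_numpy()
            self.code[i, :r] = g["CMT"].to_numpy()
            self.blq[i, :r] = g["BLQ"].to_numpy() == 1
            with np.errstate(invalid="ignore"):
                self.logdv[i, :r] = np.log(g["DV"].to_numpy())
            self.loglloq[i, :r] = np.log(g["LLOQ"].to_numpy())
            self.mask[i, :r] = True
        cov = pd.DataFrame(cov_rows).reset_index(drop=True)
        self.age = cov["AGE"].to_numpy(dtype=float)
        self.rs56 = cov["RS4149056"].to_numpy(dtype=int)
        self.cov_columns = {
            c: cov[c].to_numpy() for c in cov.columns
            if c not in ("ID", "TIME", "AMT", "EVID", "CMT", "DV", "MDV",
                         "BLQ", "LLOQ")}
        # per-row analyte index for residual-spec gathering
        self._arow = {a: self.code == c for c, a in CODE_ANALYTES.items()
                      if a in self.spec.analytes}

    # -- residual arrays under the current spec -----------------------------
    def _residual_rows(self):
        shape = self.time.shape
        var1 = np.zeros(shape)
        var2 = np.zeros(shape)
        m = np.zeros(shape)
        for a, sel in self._arow.items():
            spec = self.spec.residuals[a]
            var1 = np.where(sel, spec.var1(self.time), var1)
            var2 = np.where(sel, spec.var2, var2)
            m = np.where(sel, spec.m, m)
        return var1, var2, m + ~self.mask  # pad rows get m=1 to avoid log(0)

    # -- population (eta = 0) parameters under the current spec -------------
    def _pop_params(self) -> dict[str, np.ndarray]:
        p = typical_params(self.spec.theta, self.age, self.rs56)
        for eff in self.spec.effects:
            x = np.asarray(self.cov_columns[eff.covariate], dtype=float)
            mult = eff.multiplier(self.spec.betas, x)
            if np.any(mult <= 0):
                raise FitError(f"covariate effect on {eff.param} produced a "
                               "non-positive multiplier")
            p[eff.param] = p[eff.param] * mult
        return p

    # -- joint negative log-density -----------------------------------------
    def _moments(self, pop_p, resid, eta: np.ndarray, idx=None):
        """Log-scale observation moments (mu, w2) at the given random
        effects, optionally restricted to a subject subset."""
        sub = (lambda a: a) if idx is None else (lambda a: a[idx])
        p = {k: sub(v) for k, v in pop_p.items()}
        for k, name in enumerate(self.bsv_names):
            p[name] = p[name] * np.exp(np.clip(eta[:, k], -35.0, 35.0))
        time = sub(self.time)
        prof = predict_profiles(time, sub(self.dose), p,
                                analytes=self.spec.analytes, dt=self.spec.dt)
        f = np.zeros_like(time)
        for a, sel in self._arow.items():
            f = np.where(sub(sel), prof[a], f)
        var1, var2, m = (sub(r) for r in resid)
        fm = f + m
        w1 = f / fm
        wm = m / fm
        return np.log(fm), w1 * w1 * var1 + wm * wm * var2

    def _nll_rows(self, mu, w2, idx=None) -> np.ndarray:
        """Per-subject summed observation negative log-likelihood."""
        sub = (lambda a: a) if idx is None else (lambda a: a[idx])
        nll = row_nll_moments(sub(self.logdv), sub(self.blq),
                              sub(self.loglloq), mu, w2)
        return np.where(sub(self.mask), nll, 0.0).sum(axis=1)

    def _neg_joint(self, pop_p, resid, omega2, eta: np.ndarray,
                   idx=None) -> np.ndarray:
        mu, w2 = self._moments(pop_p, resid, eta, idx=idx)
        out = self._nll_rows(mu, w2, idx=idx)
        if omega2.size:
            out = out + 0.5 * (eta * eta / omega2).sum(axis=1)
        return out

    def _gn_pack(self, pop_p, resid, omega2, eta: np.ndarray, idx=None):
        """One sweep of central-difference evaluations delivering the joint
        negative log-density, its gradient in eta, and the Gauss-Newton
        Hessian surrogate (curvature of the observation terms through the
        prediction sensitivities, plus the exact prior curvature)."""
        sub = (lambda a: a) if idx is None else (lambda a: a[idx])
        n, d = eta.shape
        mu0, w20 = self._moments(pop_p, resid, eta, idx=idx)
        nll0 = self._nll_rows(mu0, w20, idx=idx)
        nj0 = nll0 + 0.5 * (eta * eta / omega2).sum(axis=1)
        h = self.fd_grad
        J = np.empty(mu0.shape + (d,))
        g = np.empty((n, d))
        for k in range(d):
            ep = eta.copy()
            ep[:, k] += h
            mup, w2p = self._moments(pop_p, resid, ep, idx=idx)
            em = eta.copy()
            em[:, k] -= h
            mum, w2m = self._moments(pop_p, resid, em, idx=idx)
            J[..., k] = (mup - mum) / (2.0 * h)
            g[:, k] = (self._nll_rows(mup, w2p, idx=idx)
                       - self._nll_rows(mum, w2m, idx=idx)) / (2.0 * h)
        g = g + eta / omega2
        c = np.where(sub(self.blq),
                     censored_curvature(sub(self.loglloq), mu0, w20),
                     1.0 / np.maximum(w20, 1e-300))
        c = np.where(sub(self.mask), c, 0.0)
        H = np.einsum("nr,nri,nrj->nij", c, J, J)
        H[:, np.arange(d), np.arange(d)] += 1.0 / omega2
        return nj0, g, H

    # -- batched finite differences ------------------------------------------
    def _grad(self, nj_fun, eta):
        d = eta.shape[1]
        g = np.empty_like(eta)
        h = self.fd_grad
        for k in range(d):
            ep = eta.copy()
            ep[:, k] += h
            em = eta.copy()
            em[:, k] -= h
            g[:, k] = (nj_fun(ep) - nj_fun(em)) / (2.0 * h)
        return g

    def _hess(self, nj_fun, eta, f0=None):
        n, d = eta.shape
        h = self.fd_hess
        if f0 is None:
            f0 = nj_fun(eta)
        fi = np.empty((d, n))
        for k in range(d):
            ep = eta.copy()
            ep[:, k] += h
            fi[k] = nj_fun(ep)
        H = np.empty((n, d, d))
        for i in range(d):
            for j in range(i, d):
                ep = eta.copy()
                ep[:, i] += h
                ep[:, j] += h
                fij = nj_fun(ep)
                H[:, i, j] = H[:, j, i] = (fij - fi[i] - fi[j] + f0) / (h * h)
        return H

    @staticmethod
    def _spd(H):
        """Positive-definite surrogate of each subject Hessian (modified
        Newton: absolute eigenvalues with a relative floor), so the inner
        step is well defined away from the mode and at saddles."""
        w, v = np.linalg.eigh(H)
        floor = 1e-6 * np.maximum(np.abs(w).max(axis=1, keepdims=True), 1.0)
        w = np.maximum(np.abs(w), floor)
        return np.einsum("nij,nj,nkj->nik", v, w, v), \
            np.log(w).sum(axis=1)

    # -- inner problem: posterior modes --------------------------------------
    def _polish(self, pop_p, resid, omega2, eta, nj, g, gidx=None):
        """Per-subject quasi-Newton rescue for subjects whose batched mode
        search stalled (strongly non-quadratic joints).  Returns the max
        displacement applied.  ``gidx`` maps rows of ``eta`` to global
        subject indices."""
        moved = 0.0
        gmax = np.abs(g).max(axis=1)
        # gradients within ~10x of the target are at the finite-difference
        # noise floor; their residual mode error is negligible for the OFV
        tol_i = 10.0 * self.inner_tol * np.maximum(1.0, np.abs(nj))
        for i in np.where(gmax > tol_i)[0]:
            sel = np.array([i if gidx is None else gidx[i]])

            def fi(ev, sel=sel):
                return float(self._neg_joint(pop_p, resid, omega2,
                                             ev[None, :], idx=sel)[0])

            r = optimize.minimize(fi, eta[i], method="BFGS",
                                  options={"gtol": 0.1 * tol_i[i],
                                           "maxiter": 40})
            if r.fun < nj[i] - 1e-12:
                moved = max(moved, float(np.abs(r.x - eta[i]).max()))
                eta[i] = r.x
                nj[i] = r.fun
        return moved

    def _inner(self, pop_p, resid, omega2, eta0):
        if self.hessian == "gn":
            return self._inner_gn(pop_p, resid, omega2, eta0)
        return self._inner_exact(pop_p, resid, omega2, eta0)

    def _inner_gn(self, pop_p, resid, omega2, eta0):
        """Batched mode search using the Gauss-Newton curvature surrogate;
        gradient and curvature come from one central-difference sweep."""
        nj_fun = lambda e: self._neg_joint(pop_p, resid, omega2, e)
        eta = eta0.copy()
        nj, g, H = self._gn_pack(pop_p, resid, omega2, eta)
        if not np.all(np.isfinite(nj)):
            eta = np.where(np.isfinite(nj)[:, None], eta, 0.0)
            nj, g, H = self._gn_pack(pop_p, resid, omega2, eta)
            if not np.all(np.isfinite(nj)):
                raise FitError("non-finite joint density at eta = 0")
        n, d = eta.shape
        lam = np.full(n, 1e-2)   # Levenberg-Marquardt damping per subject
        rng_d = np.arange(d)
        last_total = np.inf
        stall = 0
        # without refinement (bootstrap fast mode) a short sweep suffices;
        # point estimation lets Gauss-Newton run until it stops helping
        maxit = min(self.inner_maxit, 8) if not self.refine \
            else self.inner_maxit
        for it in range(maxit):
            # work to within 10x of the refinement target: below that the
            # residual mode error is invisible in the OFV
            tol_i = 10.0 * self.inner_tol * np.maximum(1.0, np.abs(nj))
            bad = np.abs(g).max(axis=1) >= tol_i
            if not bad.any():
                break
            if bad.sum() <= max(2, len(eta) // 50):
                break  # hand the stragglers to the exact refinement
            total = nj.sum()
            stall = stall + 1 if last_total - total < 1e-7 * n else 0
            if stall >= 3:
                break  # no joint progress; refine what remains
            last_total = total
            Hd = H.copy()
            Hd[:, rng_d, rng_d] *= (1.0 + lam)[:, None]
            Hd[:, rng_d, rng_d] += 1e-10
            step = np.linalg.solve(Hd, g[..., None])[..., 0]
            # trust region: shrink the whole vector (direction-preserving)
            norm = np.abs(step).max(axis=1, keepdims=True)
            step = step * np.minimum(1.0, 2.0 / np.maximum(norm, 1e-300))
            alpha = np.ones(len(eta))
            ftol = 1e-10 * np.maximum(1.0, np.abs(nj))
            for _ in range(12):
                cand = eta - alpha[:, None] * step
                njc = nj_fun(cand)
                worse = ~(njc <= nj + ftol)
                if not worse.any():
                    break
                alpha = np.where(worse, alpha * 0.5, alpha)
            accept = njc <= nj + ftol
            eta = eta - np.where(accept[:, None], alpha[:, None] * step, 0.0)
            lam = np.clip(np.where(accept, lam / 3.0, lam * 10.0),
                          1e-4, 1e8)
            nj, g, H = self._gn_pack(pop_p, resid, omega2, eta)
        # refine seriously unconverged subjects with exact-Hessian Newton:
        # quadratically convergent where the Gauss-Newton surrogate stalls.
        # Gradients within 10x of the target have negligible OFV impact.
        tol_i = 10.0 * self.inner_tol * np.maximum(1.0, np.abs(nj))
        bad = np.where(np.abs(g).max(axis=1) >= tol_i)[0]
        if bad.size and self.refine:
            fsub = lambda e: self._neg_joint(pop_p, resid, omega2, e,
                                             idx=bad)
            esub, njs, gs = self._refine_exact(fsub, eta[bad], nj[bad])
            self._polish(pop_p, resid, omega2, esub, njs, gs, gidx=bad)
            eta[bad] = esub
            njb, gb, Hb = self._gn_pack(pop_p, resid, omega2, esub, idx=bad)
            nj[bad] = njb
            H[bad] = Hb
        Hspd, logdet = self._spd(H)
        return eta, nj, logdet

    def _refine_exact(self, nj_fun, eta, nj, maxit=12):
        """Damped Newton with a fresh exact finite-difference Hessian each
        iteration, on a (small) batch.

        Stops on the gradient criterion or on value stagnation: the
        zero-order absorption windows make some subjects' joint density
        non-smooth exactly at the mode (an observation time crossing an
        infusion boundary), where the gradient cannot vanish although the
        joint value -- all the marginal likelihood needs -- is converged.
        """
        eta = eta.copy()
        nj = nj.copy()
        g = None
        for _ in range(maxit):
            g = self._grad(nj_fun, eta)
            if np.all(np.abs(g).max(axis=1)
                      < self.inner_tol * np.maximum(1.0, np.abs(nj))):
                break
            H, _ = self._spd(self._hess(nj_fun, eta, f0=nj))
            step = np.linalg.solve(H, g[..., None])[..., 0]
            norm = np.abs(step).max(axis=1, keepdims=True)
            step = step * np.minimum(1.0, 2.0 / np.maximum(norm, 1e-300))
            alpha = np.ones(len(eta))
            ftol = 1e-11 * np.maximum(1.0, np.abs(nj))
            for _ in range(15):
                cand = eta - alpha[:, None] * step
                njc = nj_fun(cand)
                worse = ~(njc <= nj + ftol)
                if not worse.any():
                    break
                alpha = np.where(worse, alpha * 0.5, alpha)
            accept = njc <= nj + ftol
            improvement = np.where(accept, nj - njc, 0.0)
            eta = eta - np.where(accept[:, None], alpha[:, None] * step, 0.0)
            nj = np.where(accept, njc, nj)
            if improvement.max(initial=0.0) < 1e-9 * max(1.0,
                                                         np.abs(nj).max()):
                break  # value-converged (possibly at a kink)
        return eta, nj, g

    def _inner_exact(self, pop_p, resid, omega2, eta0):
        """Batched mode search with exact finite-difference Hessians
        (frozen between refreshes); slower but free of the Gauss-Newton
        curvature approximation."""
        nj_fun = lambda e: self._neg_joint(pop_p, resid, omega2, e)
        eta = eta0.copy()
        nj = nj_fun(eta)
        if not np.all(np.isfinite(nj)):
            eta = np.where(np.isfinite(nj)[:, None], eta, 0.0)
            nj = nj_fun(eta)
            if not np.all(np.isfinite(nj)):
                raise FitError("non-finite joint density at eta = 0")
        H, _ = self._spd(self._hess(nj_fun, eta, f0=nj))
        moved = 0.0
        stalled = 0
        g = None
        for it in range(self.inner_maxit):
            g = self._grad(nj_fun, eta)
            tol_i = self.inner_tol * np.maximum(1.0, np.abs(nj))
            bad = np.abs(g).max(axis=1) >= tol_i
            if not bad.any():
                break
            if bad.sum() <= max(2, len(eta) // 50):
                break  # hand the stragglers to the per-subject polish
            step = np.linalg.solve(H, g[..., None])[..., 0]
            norm = np.abs(step).max(axis=1, keepdims=True)
            step = step * np.minimum(1.0, 2.0 / np.maximum(norm, 1e-300))
            alpha = np.ones(len(eta))
            ftol = 1e-10 * np.maximum(1.0, np.abs(nj))
            for _ in range(20):
                cand = eta - alpha[:, None] * step
                njc = nj_fun(cand)
                worse = ~(njc <= nj + ftol)
                if not worse.any():
                    break
                alpha = np.where(worse, alpha * 0.5, alpha)
            accept = njc <= nj + ftol
            delta = np.where(accept[:, None], alpha[:, None] * step, 0.0)
            progress = np.abs(delta).max(initial=0.0)
            moved = max(moved, progress)
            eta = eta - delta
            nj = np.where(accept, njc, nj)
            stalled = stalled + 1 if progress < 1e-8 else 0
            if stalled >= 1 or (it + 1) % 6 == 0:
                # frozen curvature is no longer trustworthy: refresh
                H, _ = self._spd(self._hess(nj_fun, eta, f0=nj))
                stalled = 0
        if g is not None:
            moved = max(moved,
                        self._polish(pop_p, resid, omega2, eta, nj, g))
        if moved > 1e-6:
            H = self._hess(nj_fun, eta, f0=nj)
        Hspd, logdet = self._spd(H)
        return eta, nj, logdet

    # -- objective ------------------------------------------------------------
    def ofv(self) -> float:
        """Objective function value (-2 log marginal likelihood, NONMEM
        constant convention) at the estimator's current spec."""
        self.n_ofv_evals += 1
        pop_p = self._pop_params()
        resid = self._residual_rows()
        omega2 = self.spec.omega.variances(self.bsv_names)
        if np.any(omega2 < 0):
            raise FitError("negative omega^2")
        if omega2.size == 0:
            nj = self._neg_joint(pop_p, resid, omega2,
                                 np.zeros((self.n_subjects, 0)))
            return float(2.0 * (self.subject_weights * nj).sum())
        eta, nj, logdet = self._inner(pop_p, resid, omega2, self._eta_cache)
        self._eta_cache = eta
        val = 2.0 * nj + np.log(omega2).sum() + logdet
        return float((self.subject_weights * val).sum())

    def subject_ofv(self) -> np.ndarray:
        """Per-subject -2 log marginal likelihood at the current spec."""
        pop_p = self._pop_params()
        resid = self._residual_rows()
        omega2 = self.spec.omega.variances(self.bsv_names)
        if omega2.size == 0:
            nj = self._neg_joint(pop_p, resid, omega2,
                                 np.zeros((self.n_subjects, 0)))
            return 2.0 * nj
        eta, nj, logdet = self._inner(pop_p, resid, omega2, self._eta_cache)
        self._eta_cache = eta
        return 2.0 * nj + np.log(omega2).sum() + logdet

    # -- empirical Bayes -------------------------------------------------------
    def empirical_bayes(self) -> pd.DataFrame:
        """Posterior modes of eta at the current spec (one column per BSV
        parameter carried by the fitted analytes)."""
        pop_p = self._pop_params()
        resid = self._residual_rows()
        omega2 = self.spec.omega.variances(self.bsv_names)
        if omega2.size:
            eta, _, _ = self._inner(pop_p, resid, omega2, self._eta_cache)
            self._eta_cache = eta
        else:
            eta = np.zeros((self.n_subjects, 0))
        out = pd.DataFrame(eta, columns=list(self.bsv_names))
        out.insert(0, "ID", self.subject_ids)
        return out

    def linearized(self):
        """FOCE-style linearisation at the EBEs, for residual diagnostics.

        Returns (eta_hat, mu, w2, G, mask) where mu/w2 are the log-scale
        observation moments at eta_hat and G = d mu / d eta (N, R, d).
        """
        pop_p = self._pop_params()
        resid = self._residual_rows()
        omega2 = self.spec.omega.variances(self.bsv_names)
        if omega2.size:
            eta, _, _ = self._inner(pop_p, resid, omega2, self._eta_cache)
            self._eta_cache = eta
        else:
            eta = np.zeros((self.n_subjects, 0))
        var1, var2, m = resid

        def moments(e):
            p = dict(pop_p)
            for k, name in enumerate(self.bsv_names):
                p[name] = pop_p[name] * np.exp(e[:, k])
            prof = predict_profiles(self.time, self.dose, p,
                                    analytes=self.spec.analytes,
                                    dt=self.spec.dt)
            f = np.zeros_like(self.time)
            for a, sel in self._arow.items():
                f = np.where(sel, prof[a], f)
            fm = f + m
            w1 = f / fm
            wm = m / fm
            return np.log(fm), w1 * w1 * var1 + wm * wm * var2

        mu, w2 = moments(eta)
        d = len(self.bsv_names)
        G = np.empty(self.time.shape + (d,))
        h = self.fd_grad
        for k in range(d):
            ep = eta.copy()
            ep[:, k] += h
            em = eta.copy()
            em[:, k] -= h
            G[..., k] = (moments(ep)[0] - moments(em)[0]) / (2.0 * h)
        return eta, mu, w2, G, self.mask & ~self.blq

    def shrinkage(self) -> dict[str, float]:
        """Eta shrinkage, 100*(1 - SD(eta_hat)/omega), per BSV parameter."""
        ebes = self.empirical_bayes()
        out = {}
        for name in self.bsv_names:
            w2 = self.spec.omega.omega2.get(name, 0.0)
            if w2 <= 0 or self.n_subjects < 2:
                out[name] = float("nan")
            else:
                out[name] = 100.0 * (1.0 - ebes[name].std(ddof=1)
                                     / math.sqrt(w2))
        return out

    # -- outer optimisation ----------------------------------------------------
    def fit(self, free: Sequence[str], init: Mapping[str, float] | None = None,
            method: str = "lbfgsb", maxiter: int = 200,
            compute_se: bool = False, outer_tol: float = 1e-4,
            compute_ebes: bool = True) -> FitResult:
        """Maximise the marginal likelihood over the named free parameters.

        ``free`` entries are ThetaSet fields, ``omega2_<param>``,
        ``<analyte>_<var1_abs|var1_elim|var2|m>`` or effect coefficients
        (``beta_*``).  ``init`` overrides starting values by name.
        """
        free = list(free)
        if init:
            for k, v in init.items():
                self.spec.set(k, v)
        transforms = [default_transform(n) for n in free]
        x0 = np.array([tr.to_internal(self.spec.get(n))
                       for n, tr in zip(free, transforms)])
        self.n_ofv_evals = 0

        def objective(x):
            for n, tr, z in zip(free, transforms, x):
                self.spec.set(n, tr.to_natural(z))
            try:
                v = self.ofv()
            except (FitError, ValueError, OverflowError,
                    np.linalg.LinAlgError):
                return 1e12
            return v if np.isfinite(v) else 1e12

        f0 = objective(x0)
        if not np.isfinite(f0) or f0 >= 1e12:
            raise FitError("objective not finite at the initial values")

        if method == "lbfgsb":
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-4,
                         "eps": 1e-3})
        elif method == "nm-bfgs":
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"maxiter": maxiter * 10, "xatol": 1e-4,
                         "fatol": outer_tol})
            res = optimize.minimize(
                objective, res.x, method="BFGS",
                options={"maxiter": maxiter, "gtol": 1e-5, "eps": 1e-4})
        else:
            raise ValueError(f"unknown method {method!r}")

        # leave the spec at the optimum
        final = objective(res.x)
        estimates = {n: self.spec.get(n) for n in free}
        se = None
        if compute_se:
            se = self._standard_errors(free, transforms, res.x, objective)
        if compute_ebes and self.bsv_names:
            ebes = self.empirical_bayes()
            shr = self.shrinkage()
        else:
            ebes = pd.DataFrame({"ID": self.subject_ids})
            shr = {}
        return FitResult(
            spec=self.spec.copy(), estimates=estimates, ofv=float(final),
            converged=bool(res.success) or abs(final - res.fun) < 1e-6,
            n_ofv_evals=self.n_ofv_evals, ebes=ebes, shrinkage=shr, se=se,
            message=str(res.message))

    def _standard_errors(self, free, transforms, xopt, objective):
        """Delta-method SEs from a central finite-difference Hessian of the
        OFV on the internal scale (covariance = 2 * H^-1)."""
        d = len(xopt)
        h = 1e-3
        H = np.zeros((d, d))
        f0 = objective(xopt)
        fp = np.zeros(d)
        fm = np.zeros(d)
        for i in range(d):
            xp = xopt.copy()
            xp[i] += h
            fp[i] = objective(xp)
            xm = xopt.copy()
            xm[i] -= h
            fm[i] = objective(xm)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / (h * h)
        for i in range(d):
            for j in range(i + 1, d):
                xp = xopt.copy()
                xp[i] += h
                xp[j] += h
                fpp = objective(xp)
                H[i, j] = H[j, i] = \
                    (fpp - fp[i] - fp[j] + f0) / (h * h)
        objective(xopt)  # restore spec
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn("OFV Hessian singular; no standard errors")
            return None
        se = {}
        for i, (n, tr) in enumerate(zip(free, transforms)):
            var = cov[i, i]
            if var <= 0:
                se[n] = float("nan")
                continue
            # derivative of natural wrt internal at the optimum
            eps = 1e-6
            dnat = (tr.to_natural(xopt[i] + eps)
                    - tr.to_natural(xopt[i] - eps)) / (2 * eps)
            se[n] = math.sqrt(var) * abs(dnat)
        return se


# ---------------------------------------------------------------------------
# module-level convenience operations
# ---------------------------------------------------------------------------

def fit_population(dataset, spec: ModelSpec, free: Sequence[str],
                   init: Mapping[str, float] | None = None,
                   method: str = "lbfgsb", maxiter: int = 200,
                   compute_se: bool = False) -> FitResult:
    """Fit the population model; see :meth:`LaplaceEstimator.fit`."""
    if (dataset.df if hasattr(dataset, "df") else dataset)["ID"].nunique() < 2:
        raise FitError("population fit requires at least 2 subjects")
    est = LaplaceEstimator(dataset, spec)
    return est.fit(free, init=init, method=method, maxiter=maxiter,
                   compute_se=compute_se)


def population_ofv(dataset, spec: ModelSpec) -> float:
    """OFV of a dataset under a fixed model spec (no estimation)."""
    return LaplaceEstimator(dataset, spec).ofv()


def subject_marginal_loglik(dataset, spec: ModelSpec, subject_id=None):
    """Laplace marginal log-likelihood per subject (NONMEM constant
    convention, i.e. -OFV_i / 2).

    Returns a float for a single ``subject_id``, else a Series over IDs.
    """
    est = LaplaceEstimator(dataset, spec)
    vals = -0.5 * est.subject_ofv()
    s = pd.Series(vals, index=est.subject_ids)
    if subject_id is not None:
        return float(s.loc[subject_id])
    return s


def empirical_bayes(dataset, spec: ModelSpec) -> pd.DataFrame:
    """EBEs (posterior modes of eta) at a fixed population spec."""
    return LaplaceEstimator(dataset, spec).empirical_bayes()


def shrinkage(ebes: pd.DataFrame, omega: OmegaSpec,
              threshold: float = 40.0) -> pd.DataFrame:
    """Eta shrinkage 100*(1 - SD(eta_hat)/omega) with the high-shrinkage
    flag (> threshold %) used to route covariates to direct testing."""
    rows = []
    for name in ebes.columns:
        if name == "ID" or name not in BSV_PARAMS:
            continue
        w2 = omega.omega2.get(name, 0.0)
        if w2 <= 0 or len(ebes) < 2:
            rows.append({"param": name, "shrinkage_pct": float("nan"),
                         "high": False})
            continue
        val = 100.0 * (1.0 - ebes[name].std(ddof=1) / math.sqrt(w2))
        rows.append({"param": name, "shrinkage_pct": val,
                     "high": bool(val > threshold)})
    return pd.DataFrame(rows)
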