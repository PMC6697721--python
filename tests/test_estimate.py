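import math

import numpy as np
import pandas as pd
import pytest

from svmetpk.estimate import (FitError, LaplaceEstimator, ModelSpec,
                              fit_population, population_ofv, shrinkage,
                              subject_marginal_loglik)
from svmetpk.likelihood import row_nll
from svmetpk.params import OmegaSpec, ResidualSpec, ThetaSet
from svmetpk.simulate import TrialDataset, TrialDesign, simulate_trial

from .conftest import quiet_residuals, zero_omega


# ---------------------------------------------------------------------------
# conjugate log-linear toy: ln y = ln theta + eta + eps, one observation per
# subject.  The marginal is Normal(ln theta, omega^2 + sigma^2) in closed
# form, so the Laplace machinery can be checked exactly.
# ---------------------------------------------------------------------------

def toy_dataset(y):
    rows = []
    base = dict(AGE=10.0, WT=40.0, HT=140.0, SEX="F", RS4149056=0,
                RS4149015=0, RS2306283=0, RS15524=0, RS776746=0,
                RS10264272=0)
    for i, yi in enumerate(np.atleast_1d(y)):
        rows.append(dict(ID=i + 1, TIME=0.0, AMT=1000.0, EVID=1, CMT=1,
                         DV=np.nan, MDV=1, BLQ=0, LLOQ=np.nan, **base))
        rows.append(dict(ID=i + 1, TIME=4.0, AMT=np.nan, EVID=0, CMT=3,
                         DV=float(yi), MDV=0, BLQ=0, LLOQ=1e-9, **base))
    return TrialDataset(pd.DataFrame(rows))


class LogLinearToy(LaplaceEstimator):
    """Laplace machinery bound to the analytically tractable model."""

    def _moments(self, pop_p, resid, eta, idx=None):
        sub = (lambda a: a) if idx is None else (lambda a: a[idx])
        base = np.log(sub(pop_p["CLLA_VSVA"]))[:, None]
        mu = base + (eta[:, :1] if eta.shape[1] else 0.0)
        var1 = sub(resid[0])
        return mu + 0.0 * var1, np.broadcast_to(var1, mu.shape).copy()


def toy_spec(theta_val=2.0, om2=0.5, sigma2=0.3):
    spec = ModelSpec(
        theta=ThetaSet(CLLA_VSVA=theta_val),
        omega=OmegaSpec({"CLLA_VSVA": om2}),
        residuals={"SVA": ResidualSpec("SVA", sigma2, sigma2, 0.0, m=0.0)},
        analytes=("SVA",))
    return spec


def closed_form_ofv(y, theta_val, om2, sigma2):
    z = np.log(y) - math.log(theta_val)
    v = om2 + sigma2
    return float(np.sum(z * z / v + math.log(v)))


class TestLaplaceOracle:
    @pytest.mark.parametrize("hessian", ["gn", "exact"])
    def test_matches_conjugate_closed_form(self, hessian):
        rng = np.random.default_rng(42)
        om2, s2, th = 0.5, 0.3, 2.0
        y = th * np.exp(rng.normal(0, math.sqrt(om2 + s2), 25))
        est = LogLinearToy(toy_dataset(y), toy_spec(th, om2, s2),
                           hessian=hessian)
        assert est.ofv() == pytest.approx(closed_form_ofv(y, th, om2, s2),
                                          abs=1e-6)

    def test_fitted_theta_equals_closed_form_mle(self):
        rng = np.random.default_rng(7)
        y = 2.0 * np.exp(rng.normal(0, 0.8, 40))
        est = LogLinearToy(toy_dataset(y), toy_spec())
        fit = est.fit(["CLLA_VSVA"])
        # with fixed variances the MLE is the geometric mean
        assert fit.estimates["CLLA_VSVA"] == \
            pytest.approx(float(np.exp(np.log(y).mean())), rel=1e-3)

    def test_marginal_bounded_by_joint_maximum(self):
        # -2 ln L_marg >= 2 * negjoint(eta_hat) + ln det Omega (the Laplace
        # correction ln det H is positive here since curvature > 1)
        rng = np.random.default_rng(3)
        y = 2.0 * np.exp(rng.normal(0, 0.8, 10))
        om2, s2 = 0.5, 0.3
        est = LogLinearToy(toy_dataset(y), toy_spec(2.0, om2, s2))
        ofv = est.ofv()
        pop = est._pop_params()
        resid = est._residual_rows()
        om = est.spec.omega.variances(est.bsv_names)
        nj = est._neg_joint(pop, resid, om, est._eta_cache)
        assert ofv >= 2 * nj.sum() + len(y) * math.log(om2) - 1e-9


class TestDegenerateCases:
    def test_zero_bsv_marginal_equals_conditional(self):
        ds = simulate_trial(TrialDesign(n_subjects=4,
                                        genotype_counts={"TT": 2, "TC": 1,
                                                         "CC": 1}),
                            omega=zero_omega(), seed=5,
                            analytes=("SV", "SVA"))
        spec = ModelSpec(omega=zero_omega(), analytes=("SV", "SVA"))
        est = LaplaceEstimator(ds, spec)
        assert est.bsv_names == ()
        # direct conditional computation at eta = 0
        pop = est._pop_params()
        resid = est._residual_rows()
        nj = est._neg_joint(pop, resid, np.zeros(0),
                            np.zeros((est.n_subjects, 0)))
        assert est.ofv() == pytest.approx(2 * nj.sum(), abs=1e-10)

    def test_subject_reordering_invariance(self, sv_sva_spec):
        ds = simulate_trial(TrialDesign(n_subjects=6,
                                        genotype_counts={"TT": 3, "TC": 2,
                                                         "CC": 1}),
                            seed=2, analytes=("SV", "SVA"))
        v1 = population_ofv(ds, sv_sva_spec)
        shuffled = TrialDataset(
            ds.df.sort_values(["ID"], ascending=False,
                              kind="stable").reset_index(drop=True))
        v2 = population_ofv(shuffled, sv_sva_spec)
        assert v1 == pytest.approx(v2, abs=1e-6)

    def test_m3_limit_reduces_to_dropping_censored_rows(self):
        # censoring at lloq: as lloq -> 0 the M3 OFV of the censored
        # dataset converges to the OFV of the same data with the censored
        # rows dropped entirely
        rng = np.random.default_rng(11)
        y = np.concatenate([2.0 * np.exp(rng.normal(0, 0.8, 20)),
                            [0.3, 0.05, 0.008]])
        ds = toy_dataset(y)
        diffs = []
        for lloq in (0.5, 0.1, 0.02, 1e-4):
            df = ds.df.copy()
            obs = df["EVID"] == 0
            sel = obs & (df["DV"] < lloq)
            df.loc[obs, "LLOQ"] = lloq
            df.loc[sel, "BLQ"] = 1
            df.loc[sel, "MDV"] = 1
            df.loc[sel, "DV"] = np.nan
            # drop the would-be censored subjects' rows for the reference
            keep_ids = df.loc[obs & ~sel.reindex(df.index, fill_value=False),
                              "ID"]
            kept = TrialDataset(
                df[df["ID"].isin(keep_ids) & ~sel].reset_index(drop=True))
            est = LogLinearToy(TrialDataset(df), toy_spec())
            est_kept = LogLinearToy(kept, toy_spec())
            diffs.append(abs(est.ofv() - est_kept.ofv()))
        assert diffs[-1] < 1e-6
        assert diffs[0] > diffs[-1]


class TestFitPopulation:
    def test_noise_free_recovery_within_one_percent(self):
        design = TrialDesign(n_subjects=12,
                             genotype_counts={"TT": 6, "TC": 4, "CC": 2},
                             lloq=1e-6)
        ds = simulate_trial(design, omega=zero_omega(),
                            residuals=quiet_residuals(1e-4), seed=8,
                            analytes=("SV", "SVA"))
        spec = ModelSpec(omega=zero_omega(),
                         residuals=quiet_residuals(1e-4),
                         analytes=("SV", "SVA"))
        fit = fit_population(ds, spec, ["CLLA_VSVA", "CLSVAe_VSVA"],
                             init={"CLLA_VSVA": 0.06, "CLSVAe_VSVA": 0.09})
        assert fit.estimates["CLLA_VSVA"] == pytest.approx(0.043, rel=0.01)
        assert fit.estimates["CLSVAe_VSVA"] == pytest.approx(0.13, rel=0.01)

    def test_ofv_at_truth_beats_perturbed_clearance(self):
        design = TrialDesign(n_subjects=64,
                             genotype_counts={"TT": 30, "TC": 30, "CC": 4})
        ds = simulate_trial(design, seed=21, analytes=("SV", "SVA"))
        spec = ModelSpec(analytes=("SV", "SVA"))
        v_truth = population_ofv(ds, spec)
        bad = spec.copy()
        bad.theta = bad.theta.replace(CLSVAe_VSVA=0.26)  # 2x the truth
        v_bad = population_ofv(ds, bad)
        assert v_truth < v_bad

    def test_single_subject_rejected(self):
        ds = simulate_trial(TrialDesign(n_subjects=1,
                                        genotype_counts={"TT": 1, "TC": 0,
                                                         "CC": 0}),
                            seed=0, analytes=("SV",))
        with pytest.raises(FitError):
            fit_population(ds, ModelSpec(analytes=("SV",)), ["CL_SLe_F"])

    def test_nonfinite_initials_reported(self):
        rng = np.random.default_rng(0)
        y = 2.0 * np.exp(rng.normal(0, 0.5, 5))
        est = LogLinearToy(toy_dataset(y), toy_spec())
        with pytest.raises(ValueError):
            est.fit(["CLLA_VSVA"], init={"CLLA_VSVA": -1.0})


class TestEmpiricalBayesAndShrinkage:
    def test_uninformative_subject_shrinks_to_prior(self):
        # all observations censored far below the limit: the prior
        # dominates and eta_hat ~ 0
        y = np.full(6, 1e-6)
        ds = toy_dataset(y)
        df = ds.df.copy()
        sel = df["EVID"] == 0
        df.loc[sel, ["BLQ", "MDV"]] = 1
        df.loc[sel, "DV"] = np.nan
        df.loc[sel, "LLOQ"] = 0.5
        est = LogLinearToy(TrialDataset(df), toy_spec(theta_val=1e-4))
        ebes = est.empirical_bayes()
        assert np.abs(ebes["CLLA_VSVA"]).max() < 0.05

    def test_ebe_determinism(self, sv_sva_spec):
        ds = simulate_trial(TrialDesign(n_subjects=5,
                                        genotype_counts={"TT": 3, "TC": 1,
                                                         "CC": 1}),
                            seed=13, analytes=("SV", "SVA"))
        a = LaplaceEstimator(ds, sv_sva_spec).empirical_bayes()
        b = LaplaceEstimator(ds, sv_sva_spec).empirical_bayes()
        pd.testing.assert_frame_equal(a, b)

    def test_rich_data_ebe_approaches_subject_mle(self):
        # with a huge prior variance the posterior mode is the per-subject
        # MLE; in the toy model that is ln y - ln theta
        y = np.array([1.0, 2.0, 4.0])
        est = LogLinearToy(toy_dataset(y), toy_spec(2.0, om2=50.0,
                                                    sigma2=0.1))
        ebes = est.empirical_bayes()
        np.testing.assert_allclose(ebes["CLLA_VSVA"],
                                   np.log(y / 2.0), atol=0.02)

    def test_shrinkage_extremes(self):
        om = OmegaSpec({"CLLA_VSVA": 0.25})
        all_zero = pd.DataFrame({"ID": [1, 2, 3],
                                 "CLLA_VSVA": [0.0, 0.0, 0.0]})
        tab = shrinkage(all_zero, om)
        assert tab.loc[0, "shrinkage_pct"] == pytest.approx(100.0)
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 0.5, 4000)
        draws = (draws - draws.mean()) / draws.std(ddof=1) * 0.5
        spread = pd.DataFrame({"ID": np.arange(len(draws)),
                               "CLLA_VSVA": draws})
        tab = shrinkage(spread, om)
        assert tab.loc[0, "shrinkage_pct"] == pytest.approx(0.0, abs=1e-6)
        assert not tab.loc[0, "high"]

    def test_shrinkage_flag_threshold(self):
        om = OmegaSpec({"CLLA_VSVA": 1.0})
        ebes = pd.DataFrame({"ID": range(10),
                             "CLLA_VSVA": np.linspace(-0.5, 0.5, 10)})
        tab = shrinkage(ebes, om)
        assert bool(tab.loc[0, "high"]) == \
            (tab.loc[0, "shrinkage_pct"] > 40.0)

    def test_zero_omega_reported_not_applicable(self):
        om = OmegaSpec({"CLLA_VSVA": 0.0})
        ebes = pd.DataFrame({"ID": [1, 2], "CLLA_VSVA": [0.1, -0.1]})
        tab = shrinkage(ebes, om)
        assert math.isnan(tab.loc[0, "shrinkage_pct"])


def test_subject_marginal_loglik_zero_bsv_case():
    rng = np.random.default_rng(1)
    y = 2.0 * np.exp(rng.normal(0, 0.5, 4))
    # om2 = 0: marginal = conditional at eta = 0 exactly (toy closed form)
    est = LogLinearToy(toy_dataset(y), toy_spec(om2=0.0))
    ll = -0.5 * est.subject_ofv()
    z = np.log(y) - math.log(2.0)
    expect = -0.5 * (z * z / 0.3 + math.log(0.3))
    np.testing.assert_allclose(ll, expect, atol=1e-10)
    # public API on the structural model: one finite value per subject
    ds = simulate_trial(TrialDesign(n_subjects=3,
                                    genotype_counts={"TT": 2, "TC": 1,
                                                     "CC": 0}),
                        seed=6, analytes=("SV", "SVA"))
    series = subject_marginal_loglik(ds, ModelSpec(analytes=("SV", "SVA")))
    assert list(series.index) == [1, 2, 3]
    assert np.isfinite(series.to_numpy()).all()
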