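import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svmetpk import dataio
from svmetpk.params import (OmegaSpec, ResidualSpec, cv_to_omega2,
                            table_residuals)
from svmetpk.simulate import (TrialDesign, apply_residual_error, censor_blq,
                              generate_population, sample_random_effects,
                              simulate_trial)

from .conftest import quiet_residuals, zero_omega


class TestDesign:
    def test_default_matches_study(self):
        d = TrialDesign()
        assert d.n_subjects == 32
        assert d.genotype_counts == {"TT": 15, "TC": 15, "CC": 2}
        assert d.sampling_times == (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0,
                                    6.0, 8.0)
        assert d.lloq_map()["SVA"] == 0.5

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            TrialDesign(n_subjects=10,
                        genotype_counts={"TT": 5, "TC": 4, "CC": 2})


class TestPopulation:
    def test_counts_doses_and_ages(self):
        subs = generate_population(TrialDesign(), seed=1)
        assert len(subs) == 32
        rs = [s.covariates.rs4149056 for s in subs]
        assert rs.count(0) == 15 and rs.count(1) == 15 and rs.count(2) == 2
        for s in subs:
            assert 8.0 <= s.covariates.age <= 20.0
            expect = 10.0 if s.covariates.age < 18 else 20.0
            assert s.dose_mg == expect

    def test_deterministic_per_seed(self):
        a = generate_population(TrialDesign(), seed=7)
        b = generate_population(TrialDesign(), seed=7)
        assert all(x.covariates == y.covariates for x, y in zip(a, b))
        c = generate_population(TrialDesign(), seed=8)
        assert any(x.covariates != y.covariates for x, y in zip(a, c))

    def test_adding_subjects_preserves_earlier_streams(self):
        small = generate_population(TrialDesign(), seed=3)
        big_design = TrialDesign(n_subjects=40,
                                 genotype_counts={"TT": 23, "TC": 15,
                                                  "CC": 2})
        big = generate_population(big_design, seed=3)
        for i in range(15):  # same genotype label block
            assert small[i].covariates == big[i].covariates


class TestRandomEffects:
    def test_zero_variance_gives_zero(self):
        eta = sample_random_effects(OmegaSpec({"ka2": 0.0}), 5, seed=0)
        assert eta.shape == (5, 0)

    def test_sample_variance_matches_cv(self):
        om = OmegaSpec({"CL_SLe_F": cv_to_omega2(0.63)})
        eta = sample_random_effects(om, 20_000, seed=1)
        assert eta.std() ** 2 == pytest.approx(0.3289, rel=0.03)

    def test_seeds_give_same_distribution(self):
        om = OmegaSpec({"ka2": 0.15})
        a = sample_random_effects(om, 2000, seed=1)[:, 0]
        b = sample_random_effects(om, 2000, seed=2)[:, 0]
        assert not np.allclose(a, b)
        assert stats.ks_2samp(a, b).pvalue > 0.001


class TestResidualError:
    def test_m_zero_limit_is_lognormal(self):
        spec = ResidualSpec("SVA", 0.09, 0.09, 0.5, m=0.0)
        rng = np.random.default_rng(0)
        f = np.full(50_000, 2.0)
        y = apply_residual_error(f, spec, 4.0, rng)
        # var2 must not contribute when m = 0
        assert np.log(y).var() == pytest.approx(0.09, rel=0.03)
        assert np.median(y) == pytest.approx(2.0, rel=0.02)

    def test_log_variance_composition(self):
        spec = table_residuals()["SVA"]  # var1 0.26, var2 0.16, m 0.22
        f = 0.8
        w1 = f / (f + spec.m)
        w2 = spec.m / (f + spec.m)
        expect = w1 ** 2 * 0.26 + w2 ** 2 * 0.16
        rng = np.random.default_rng(3)
        y = apply_residual_error(np.full(100_000, f), spec, 4.0, rng)
        assert np.log(y).var() == pytest.approx(expect, rel=0.02)

    def test_phase_dependent_variance_for_parent(self):
        spec = table_residuals()["SV"]
        rng = np.random.default_rng(1)
        f = np.full(60_000, 5.0)
        early = np.log(apply_residual_error(f, spec, 1.0, rng)).var()
        late = np.log(apply_residual_error(f, spec, 3.0, rng)).var()
        w1 = (5.0 / 5.012) ** 2
        w2 = (0.012 / 5.012) ** 2
        assert early == pytest.approx(w1 * 0.38 + w2 * 0.30, rel=0.03)
        assert late == pytest.approx(w1 * 0.32 + w2 * 0.30, rel=0.03)

    def test_noise_free_limit(self):
        spec = ResidualSpec("SV", 0.0, 0.0, 0.0, m=0.012)
        y = apply_residual_error(np.array([1.5]), spec, 1.0,
                                 np.random.default_rng(0))
        assert y[0] == pytest.approx(1.512)


class TestCensoring:
    def test_below_limit_flagged(self):
        dv, blq = censor_blq(0.4, 0.5)
        assert blq and np.isnan(dv)

    def test_exactly_at_limit_reported(self):
        dv, blq = censor_blq(0.5, 0.5)
        assert not blq and dv == 0.5

    def test_tiny_limit_censors_nothing(self):
        y = np.array([0.01, 0.2, 5.0])
        dv, blq = censor_blq(y, 1e-12)
        assert not blq.any()

    def test_invalid_limit(self):
        with pytest.raises(ValueError):
            censor_blq(1.0, 0.0)


class TestSimulateTrial:
    def test_row_counts_default_design(self, default_trial):
        obs = default_trial.observations()
        assert len(obs) == 32 * 8 * 5 == 1280
        assert len(default_trial.doses()) == 32

    def test_deterministic_byte_identical(self):
        a, b = (simulate_trial(seed=99) for _ in range(2))
        for ds in (a, b):
            pass
        buf_a, buf_b = io.StringIO(), io.StringIO()
        dataio.write_dataset(a, buf_a)
        dataio.write_dataset(b, buf_b)
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_noise_free_limit_reproduces_typical_plus_offset(self):
        res = quiet_residuals(0.0)
        ds = simulate_trial(omega=zero_omega(), residuals=res, seed=0,
                            analytes=("SV", "SVA"))
        obs = ds.observations()
        sv = obs[obs["CMT"] == dataio.ANALYTE_CODES["SV"]]
        # quantified rows equal the typical prediction plus the tiny offset
        from svmetpk.covariates import typical_params
        from svmetpk.params import ThetaSet
        from svmetpk.structural import predict_profiles
        doses = ds.doses().set_index("ID")["AMT"]
        for sid in list(sv["ID"].unique())[:4]:
            rows = sv[(sv["ID"] == sid) & (sv["BLQ"] == 0)]
            p = typical_params(ThetaSet(),
                               rows["AGE"].iloc[0], 0)
            pred = predict_profiles(rows["TIME"].to_numpy(), doses[sid],
                                    p, analytes=("SV",))["SV"][0]
            np.testing.assert_allclose(rows["DV"].to_numpy(), pred + 1e-8,
                                       rtol=1e-6)

    def test_blq_fraction_monotone_in_dose(self):
        # doubling every dose cannot increase the BLQ fraction of the
        # linear analytes
        lo = simulate_trial(TrialDesign(dose_rule=lambda age: 10.0), seed=4,
                            analytes=("SV", "SVA", "DHSV"))
        hi = simulate_trial(TrialDesign(dose_rule=lambda age: 40.0), seed=4,
                            analytes=("SV", "SVA", "DHSV"))
        for code in (2, 3, 6):
            f_lo = lo.observations().query("CMT == @code")["BLQ"].mean()
            f_hi = hi.observations().query("CMT == @code")["BLQ"].mean()
            assert f_hi <= f_lo + 1e-12

    def test_genotype_monotone_sva_exposure(self):
        # typical SVA concentrations are non-decreasing in the variant
        # allele count at every post-dose time
        from svmetpk.covariates import typical_params
        from svmetpk.params import ThetaSet, mg_to_nmol
        from svmetpk.structural import predict_profiles
        times = np.array([0.5, 1, 2, 4, 6, 8.0])
        prev = None
        for rs in (0, 1, 2):
            p = typical_params(ThetaSet(), 12.0, rs)
            c = predict_profiles(times, mg_to_nmol(10.0), p,
                                 analytes=("SVA",))["SVA"][0]
            if prev is not None:
                assert np.all(c >= prev - 1e-12)
            prev = c
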