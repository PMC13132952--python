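"""FIML engine: moments, likelihood, optimisation, SEs, indices, LRT."""

import math

import numpy as np
import pytest
from scipy import stats

import twinsem as ts
from twinsem.cholesky import CholeskyParams
from twinsem.fiml import (
    LN_2PI, SourceLoadingModel, delta_method, expected_moments,
    fiml_neg2loglik, fiml_neg2loglik_rowwise, fit_independence, fit_indices,
    fit_saturated, fit_source_model, fix_params, likelihood_ratio_test,
    pattern_statistics, standard_errors,
)
from twinsem.simulate import SimulationScenario


def _identity_ae_theta(model):
    """AE Cholesky with a = e = I and zero means."""
    theta = np.zeros(model.n_params)
    for n in ("a11", "a22", "a33", "e11", "e22", "e33"):
        theta[model.index(n)] = 1.0
    return theta


class TestExpectedMoments:
    def test_identity_paths_blocks(self):
        model = ts.build_cholesky_model("AE")
        theta = _identity_ae_theta(model)
        _, mz = expected_moments(model, theta, "MZ")
        _, dz = expected_moments(model, theta, "DZ")
        assert np.allclose(mz[:3, :3], 2 * np.eye(3))
        assert np.allclose(mz[:3, 3:], np.eye(3))
        assert np.allclose(dz[:3, 3:], 0.5 * np.eye(3))
        assert np.allclose(dz[:3, :3], 2 * np.eye(3))

    def test_e_only_has_zero_cross_twin_blocks(self):
        model = ts.build_cholesky_model("ACE")
        theta = np.zeros(model.n_params)
        for n in ("e11", "e21", "e32", "e33"):
            theta[model.index(n)] = 0.7
        theta[model.index("e22")] = 1.2
        for g in ("MZ", "DZ"):
            _, Sig = expected_moments(model, theta, g)
            assert np.allclose(Sig[:3, 3:], 0.0)

    def test_mz_equals_dz_when_a_zero(self):
        model = ts.build_cholesky_model("ACE")
        rng = np.random.default_rng(0)
        theta = np.zeros(model.n_params)
        for i, n in enumerate(model.param_names):
            if n[0] in "ce":
                theta[i] = rng.uniform(0.2, 1.0)
        mu1, s1 = expected_moments(model, theta, "MZ")
        mu2, s2 = expected_moments(model, theta, "DZ")
        assert np.allclose(s1, s2)
        assert np.allclose(mu1, mu2)

    @pytest.mark.parametrize("seed", range(5))
    def test_implied_covariance_psd_for_random_params(self, seed):
        model = ts.build_cholesky_model("ACE")
        rng = np.random.default_rng(seed)
        lo = np.array([0.0 if b == (0.0, None) else -2.0 for b in model.bounds])
        theta = rng.uniform(lo, 2.0)
        for g in ("MZ", "DZ"):
            _, Sig = expected_moments(model, theta, g)
            assert np.min(np.linalg.eigvalsh(Sig)) >= -1e-10

    def test_matches_large_simulation(self):
        """Implied covariance agrees with the empirical covariance of many
        simulated pairs within Monte-Carlo error."""
        sc = ts.study_scenario("cholesky", n_mz=100000, n_dz=100000, seed=3)
        ds = ts.simulate_pairs(sc)
        data = ds.pair_matrix(sc.observed_layout())
        model = sc.model()
        theta = sc.params.to_theta()
        for g in ("MZ", "DZ"):
            _, Sig = expected_moments(model, theta, g)
            emp = np.cov(data[g], rowvar=False)
            n = data[g].shape[0]
            mc_se = np.sqrt((np.outer(np.diag(Sig), np.diag(Sig)) + Sig**2) / n)
            assert np.all(np.abs(emp - Sig) < 4 * mc_se)


class TestLikelihood:
    def test_standard_normal_single_observation(self):
        """One observed value 0 under N(0,1): -2lnL = ln(2*pi)."""
        model = SourceLoadingModel(
            "unit", ["mu"], [(None, None)], 1,
            loadings=lambda th, g: np.array([[1.0]]),
            means=lambda th, g: np.array([th[0]]),
            start=lambda d: np.zeros(1))
        val = fiml_neg2loglik(model, np.zeros(1), {"MZ": np.array([[0.0]])})
        assert val == pytest.approx(LN_2PI, abs=1e-12)

    def test_complete_data_matches_closed_form(self):
        sc = ts.study_scenario("cholesky", n_mz=200, n_dz=300, seed=8)
        ds = ts.simulate_pairs(sc)
        data = ds.pair_matrix(sc.observed_layout())
        model = sc.model()
        theta = sc.params.to_theta()
        got = fiml_neg2loglik(model, theta, data)
        # oracle: -2lnL = sum_g n_g [k ln 2pi + ln|Sigma| + tr(Sigma^-1 S) + d'Sigma^-1 d]
        expect = 0.0
        for g, Y in data.items():
            mu, Sig = expected_moments(model, theta, g)
            n, k = Y.shape
            xbar = Y.mean(axis=0)
            S = np.cov(Y, rowvar=False, bias=True)
            d = xbar - mu
            Si = np.linalg.inv(Sig)
            expect += n * (k * LN_2PI + np.linalg.slogdet(Sig)[1]
                           + np.trace(Si @ S) + d @ Si @ d)
        assert got == pytest.approx(expect, rel=1e-10)

    def test_row_duplication_doubles_value(self):
        sc = ts.study_scenario("cholesky", n_mz=50, n_dz=50, seed=2)
        ds = ts.simulate_pairs(sc)
        data = ds.pair_matrix(sc.observed_layout())
        model = sc.model()
        theta = sc.params.to_theta()
        v1 = fiml_neg2loglik(model, theta, data)
        doubled = {g: np.vstack([Y, Y]) for g, Y in data.items()}
        assert fiml_neg2loglik(model, theta, doubled) == pytest.approx(2 * v1, rel=1e-12)

    def test_pattern_grouping_equals_rowwise_with_missingness(self):
        sc = ts.study_scenario("riclpm", n_mz=150, n_dz=150, realism=True, seed=4)
        ds = ts.simulate_pairs(sc)
        data = ds.pair_matrix(sc.observed_layout())
        model = sc.model()
        theta = sc.params.to_theta()
        grouped = fiml_neg2loglik(model, theta, data)
        rowwise = fiml_neg2loglik_rowwise(model, theta, data)
        assert grouped == pytest.approx(rowwise, abs=1e-8 * abs(rowwise))

    def test_all_missing_rows_dropped(self):
        model = ts.build_cholesky_model("AE")
        theta = _identity_ae_theta(model)
        Y = np.array([[0.1, 0.2, 0.3, 0.0, 0.1, -0.2]])
        with_blank = np.vstack([Y, np.full((3, 6), np.nan)])
        assert fiml_neg2loglik(model, theta, {"MZ": with_blank}) == pytest.approx(
            fiml_neg2loglik(model, theta, {"MZ": Y}), rel=1e-12)


class TestFitting:
    def test_saturated_equals_sample_moments_closed_form(self):
        sc = ts.study_scenario("cholesky", n_mz=100, n_dz=120, seed=6)
        ds = ts.simulate_pairs(sc)
        data = ds.pair_matrix(sc.observed_layout())
        sat = fit_saturated(data)
        expect = 0.0
        for g, Y in data.items():
            n, k = Y.shape
            S = np.cov(Y, rowvar=False, bias=True)
            expect += n * (k * LN_2PI + np.linalg.slogdet(S)[1] + k)
        assert sat.minus2ll == pytest.approx(expect, rel=1e-10)
        assert sat.n_free == 2 * (6 + 21)

    def test_saturated_fiml_with_missingness_close_to_complete_case(self):
        """Optimised FIML saturated fit reproduces the closed form when the
        missing-data path is forced on a complete dataset."""
        sc = ts.study_scenario("cholesky", n_mz=80, n_dz=80, seed=13)
        ds = ts.simulate_pairs(sc)
        data = ds.pair_matrix(sc.observed_layout())
        complete = fit_saturated(data)
        poked = {g: Y.copy() for g, Y in data.items()}
        poked["MZ"][0, 0] = np.nan   # one missing cell switches to optimisation
        approx = fit_saturated(poked)
        assert approx.minus2ll == pytest.approx(complete.minus2ll, abs=25.0)

    def test_independence_never_beats_saturated(self):
        sc = ts.study_scenario("cholesky", n_mz=60, n_dz=60, seed=7)
        data = ts.simulate_pairs(sc).pair_matrix(sc.observed_layout())
        assert fit_independence(data).minus2ll >= fit_saturated(data).minus2ll

    def test_one_variable_saturated_equals_independence(self):
        rng = np.random.default_rng(1)
        data = {"MZ": rng.normal(size=(200, 1))}
        assert fit_saturated(data).minus2ll == pytest.approx(
            fit_independence(data).minus2ll, rel=1e-10)

    def test_refit_from_optimum_is_fixed_point(self, cholesky_study_fit):
        ds, res = cholesky_study_fit
        model = res.model.slm
        refit = fit_source_model(model, res.model.data, n_starts=1,
                                 start=res.fitresult.params)
        assert refit.minus2ll == pytest.approx(res.minus2ll, abs=1e-6)
        assert np.allclose(refit.params, res.fitresult.params, atol=1e-3)

    def test_mean_se_closed_form(self):
        """Mean of N(mu, 1) with sigma known: SE(mu-hat) = 1/sqrt(n)."""
        rng = np.random.default_rng(5)
        n = 400
        data = {"MZ": rng.normal(size=(n, 1))}
        model = SourceLoadingModel(
            "unit", ["mu"], [(None, None)], 1,
            loadings=lambda th, g: np.array([[1.0]]),
            means=lambda th, g: np.array([th[0]]),
            start=lambda d: np.zeros(1))
        res = fit_source_model(model, data, n_starts=1)
        se, ok = standard_errors(model, res, data)
        assert ok
        assert se[0] == pytest.approx(1 / math.sqrt(n), rel=1e-3)

    def test_se_invariant_to_row_order(self, cholesky_study_fit):
        ds, res = cholesky_study_fit
        data = res.model.data
        rng = np.random.default_rng(0)
        shuffled = {g: Y[rng.permutation(len(Y))] for g, Y in data.items()}
        se1, _ = standard_errors(res.model.slm, res.fitresult, data)
        se2, _ = standard_errors(res.model.slm, res.fitresult, shuffled)
        assert np.allclose(se1, se2, atol=1e-4)

    def test_profile_ci_agrees_with_wald(self):
        """Profile-likelihood half-width within 20% of 1.96*SE at n=2000."""
        sc = ts.study_scenario("cholesky", n_mz=1000, n_dz=1000, seed=4)
        ds = ts.simulate_pairs(sc)
        res = ts.CholeskyACE(ds).fit(n_starts=1, compute_se=True)
        i = res.model.slm.index("a21")
        se = res.fitresult.bse[i]
        lo, hi = res.profile_ci("a21")
        half = (hi - lo) / 2
        assert half == pytest.approx(1.96 * se, rel=0.20)


class TestFitIndicesAndLrt:
    def _fr(self, m2ll, q, name="m"):
        from twinsem.fiml import FitResult
        return FitResult(name, [], np.array([]), m2ll, q, True, 0.0, {"MZ": 100})

    def test_target_equals_saturated_is_perfect_fit(self):
        sat = self._fr(1000.0, 54)
        ind = self._fr(1400.0, 24)
        fi = fit_indices(self._fr(1000.0, 15), sat, ind, n_total=200)
        assert fi.chisq == 0.0
        assert fi.cfi == 1.0
        assert fi.rmsea == 0.0

    def test_aic_formula(self):
        assert self._fr(100.0, 10).aic == 120.0

    def test_df_zero_reported_undefined(self):
        sat = self._fr(1000.0, 15)
        ind = self._fr(1200.0, 6)
        fi = fit_indices(self._fr(1000.0, 15), sat, ind, n_total=200)
        assert fi.df == 0 and math.isnan(fi.rmsea) and math.isnan(fi.tli)

    def test_correctly_specified_model_fits_well(self, riclpm_study_fit):
        ds, res = riclpm_study_fit
        fi = res.fit_statistics()
        assert fi.cfi > 0.95
        assert fi.tli > 0.95
        assert fi.rmsea < 0.06

    def test_identical_fits_give_p_one(self):
        lrt = likelihood_ratio_test(self._fr(500.0, 10), self._fr(500.0, 8))
        assert lrt.delta_chisq == 0.0 and lrt.p == 1.0

    def test_chi2_critical_value(self):
        lrt = likelihood_ratio_test(self._fr(500.0, 10), self._fr(503.84, 9))
        assert lrt.p == pytest.approx(0.0500, abs=5e-4)

    def test_nested_better_warns(self):
        with pytest.warns(UserWarning, match="optimizer failure"):
            likelihood_ratio_test(self._fr(505.0, 10), self._fr(500.0, 9))

    def test_lrt_type_i_error_calibrated(self):
        """Constraint true in the generating model: rejection rate at
        alpha=0.05 stays inside the binomial 95% band over 200 replicates."""
        E = np.array([[1.0, 0.0], [0.0, 0.9]])
        params = CholeskyParams(a=None, c=None, e=E, mu=np.zeros(2), components="E")
        model = ts.build_cholesky_model("E", 2)
        rejections = 0
        n_reps = 200
        for r in range(n_reps):
            scn = SimulationScenario("cholesky", params, n_mz=100, n_dz=100,
                                     seed=1000 + r)
            data = ts.simulate_pairs(scn).pair_matrix([("wb", 1), ("wb", 2)])
            full = fit_source_model(model, data, n_starts=1)
            nested = fit_source_model(fix_params(model, {"e21": 0.0}), data,
                                      n_starts=1)
            rejections += likelihood_ratio_test(full, nested).p < 0.05
        rate = rejections / n_reps
        band = 1.96 * math.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) <= band

    def test_aic_unchanged_by_fully_missing_rows(self):
        sc = ts.study_scenario("cholesky", n_mz=80, n_dz=80, seed=9)
        ds = ts.simulate_pairs(sc)
        data = ds.pair_matrix(sc.observed_layout())
        model = sc.model()
        res1 = fit_source_model(model, data, n_starts=1)
        padded = {g: np.vstack([Y, np.full((5, 6), np.nan)]) for g, Y in data.items()}
        res2 = fit_source_model(model, padded, n_starts=1)
        assert res2.aic == pytest.approx(res1.aic, abs=1e-4)


class TestDeltaMethod:
    def test_linear_map_exact(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        A = np.array([[1.0, -1.0]])
        vals, ses = delta_method(lambda t: A @ t, np.array([1.0, 2.0]), cov)
        assert vals[0] == pytest.approx(-1.0)
        assert ses[0] == pytest.approx(math.sqrt(0.04 + 0.09 - 2 * 0.01), rel=1e-6)
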