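"""Lag datasets, the mixture likelihood, ML fitting, and AIC machinery."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import dlspop as d
from dlspop.likelihood_fit import PlotTimeSeries, aic
from dlspop.popmodels import ModelSpec

DLS_SPEC = ModelSpec(order=1, linear=True, variance="dls", mixture=True)
CONST_SPEC = ModelSpec(order=1, linear=True, variance="constant")


def make_plot(years, counts, n_max=100, plot_id="p1"):
    return PlotTimeSeries(plot_id=plot_id, years=np.asarray(years),
                          counts=np.asarray(counts), n_max=n_max)


def oracle_row_count(available_years, max_lag):
    """Enumeration oracle: count target years whose full lag window exists."""
    have = set(available_years)
    return sum(1 for y in have if all(y - l in have for l in range(1, max_lag + 1)))


class TestBuildLagDataset:
    def test_consecutive_years_pair_count(self, rng):
        years = np.arange(1993, 2011)
        plot = make_plot(years, rng.integers(0, 101, size=len(years)))
        assert d.build_lag_dataset([plot], max_lag=1).n_rows == 17
        assert d.build_lag_dataset([plot], max_lag=4).n_rows == 14

    @pytest.mark.parametrize("missing_idx", [1, 5, 16])
    def test_gap_breaks_transition_chain(self, rng, missing_idx):
        years = np.arange(1993, 2011)
        keep = np.ones(18, dtype=bool)
        keep[missing_idx] = False
        plot = make_plot(years[keep], rng.integers(0, 101, size=17))
        ds = d.build_lag_dataset([plot], max_lag=1)
        assert ds.n_rows == oracle_row_count(years[keep], 1)
        assert ds.n_rows == 15

    def test_empty_result_errors(self):
        plot = make_plot([2000, 2002], [5, 10])
        with pytest.raises(ValueError, match="transition"):
            d.build_lag_dataset([plot], max_lag=1)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            make_plot([2000, 2000], [1, 2])
        with pytest.raises(ValueError, match="n_max"):
            make_plot([2000, 2001], [5, 101])
        with pytest.raises(ValueError, match="gap"):
            make_plot([2000, 2004], [5, 10])


class TestNegativeLogLikelihood:
    def _dataset(self, rng, n_rows=20):
        years = np.arange(2000, 2000 + n_rows + 1)
        counts = rng.integers(5, 480, size=n_rows + 1)
        plot = make_plot(years, counts, n_max=484)
        return d.build_lag_dataset([plot], max_lag=1)

    def test_matches_brute_force_mixture(self, rng, dls_preset):
        """Row-by-row oracle built on an independent beta-binomial pmf."""
        _, spec, params = dls_preset
        ds = self._dataset(rng)
        full = spec.full_params(params)
        expected = 0.0
        for i in range(ds.n_rows):
            p1 = ds.lags[i, 0]
            mu = full["I"] * (1 - p1) + p1 * np.exp(full["r"] + full["alpha1"] * p1)
            phi_u = 1.0 / np.exp(full["x"] + full["y"] * p1 ** full["z"]) - 1.0
            phi_d = 1.0 / full["sigma2_d"] - 1.0
            psi = expit(full["j"] + full["k"] * p1)
            lik = ((1 - psi) * stats.betabinom.pmf(ds.counts[i], 484,
                                                   mu * phi_u, (1 - mu) * phi_u)
                   + psi * stats.betabinom.pmf(ds.counts[i], 484,
                                               full["mu_d"] * phi_d,
                                               (1 - full["mu_d"]) * phi_d))
            expected -= np.log(lik)
        got = d.negative_log_likelihood(ds, spec, params)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_single_row_equals_log_mixture_pmf(self, dls_preset):
        _, spec, params = dls_preset
        plot = make_plot([2000, 2001], [40, 70], n_max=100)
        ds = d.build_lag_dataset([plot], max_lag=1)
        td = d.transition_distribution([0.4], spec, params, 100)
        assert d.negative_log_likelihood(ds, spec, params) == pytest.approx(
            -np.log(td.pmf(70)), abs=1e-10)

    def test_mixture_off_equals_plain_betabinom(self, rng, constant_preset):
        _, spec, params = constant_preset
        ds = self._dataset(rng)
        full = spec.full_params(params)
        phi = 1.0 / full["sigma2"] - 1.0
        expected = 0.0
        for i in range(ds.n_rows):
            p1 = ds.lags[i, 0]
            mu = full["I"] * (1 - p1) + p1 * np.exp(full["r"] + full["alpha1"] * p1)
            expected -= stats.betabinom.logpmf(ds.counts[i], 484,
                                               mu * phi, (1 - mu) * phi)
        assert d.negative_log_likelihood(ds, spec, params) == pytest.approx(
            expected, abs=1e-8)

    def test_invariant_to_row_and_plot_order(self, rng, dls_preset):
        _, spec, params = dls_preset
        years = np.arange(2000, 2010)
        p1 = make_plot(years, rng.integers(0, 101, 10), plot_id="a")
        p2 = make_plot(years, rng.integers(0, 485, 10), n_max=484, plot_id="b")
        ds_ab = d.build_lag_dataset([p1, p2], max_lag=1)
        ds_ba = d.build_lag_dataset([p2, p1], max_lag=1)
        assert ds_ab.fingerprint() == ds_ba.fingerprint()
        assert d.negative_log_likelihood(ds_ab, spec, params) == pytest.approx(
            d.negative_log_likelihood(ds_ba, spec, params), abs=1e-10)


class TestAic:
    def test_zero_case(self):
        assert aic(0.0, 0) == 0.0

    def test_formula(self):
        assert aic(100.0, 3) == pytest.approx(206.0)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            aic(1.0, -1)


class TestCompareModels:
    def _fit(self, spec, aic_val, fp="ds1"):
        neg_ll = (aic_val - 2 * spec.k_free) / 2.0
        return d.FitResult(spec=spec, params={}, neg_ll=neg_ll, k=spec.k_free,
                           aic=aic_val, dataset_fingerprint=fp, n_rows=100)

    def test_equal_aics_give_equal_weights(self):
        specs = [CONST_SPEC, DLS_SPEC, ModelSpec(order=1, linear=False)]
        fits = [self._fit(s, 1000.0) for s in specs]
        table = d.compare_models(fits)
        assert np.allclose(table.weights, 1.0 / 3.0, atol=1e-12)
        assert table.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_weights_and_er(self):
        fits = [self._fit(ModelSpec(order=o + 1, linear=True), a)
                for o, a in enumerate([100.0, 102.0, 110.0])]
        table = d.compare_models(fits)
        raw = np.exp([-0.0, -1.0, -5.0])
        assert np.allclose(table.weights, raw / raw.sum(), atol=1e-12)
        assert table.evidence_ratios[1] == pytest.approx(np.e, rel=1e-12)
        assert table.evidence_ratios[table.best_index] == 1.0

    def test_mismatched_datasets_rejected(self):
        fits = [self._fit(CONST_SPEC, 100.0, fp="ds1"),
                self._fit(DLS_SPEC, 101.0, fp="ds2")]
        with pytest.raises(ValueError, match="different datasets"):
            d.compare_models(fits)

    def test_support_rule_with_nested_veto(self):
        lin = self._fit(CONST_SPEC, 100.0)
        nonlin = self._fit(ModelSpec(order=1, linear=False), 101.5)
        far = self._fit(DLS_SPEC, 110.0)
        table = d.compare_models([lin, nonlin, far])
        assert table.supported[0]          # best model
        assert not table.supported[1]      # dAIC < 6 but simpler nested wins
        assert not table.supported[2]      # dAIC >= 6

    def test_min_aic_tie_breaks_toward_smaller_k(self):
        small = self._fit(CONST_SPEC, 100.0)
        big = self._fit(DLS_SPEC, 100.0)
        table = d.compare_models([big, small])
        assert table.specs[table.best_index] == CONST_SPEC


class TestModelAverage:
    def _fit(self, params, spec=CONST_SPEC):
        return d.FitResult(spec=spec, params=params, neg_ll=0.0, k=spec.k_free,
                           aic=0.0, dataset_fingerprint="ds", n_rows=10)

    def test_single_model_unchanged(self):
        p = {"I": 0.1, "r": 0.3, "alpha1": -0.2, "sigma2": 0.05}
        avg = d.model_average([self._fit(p)])
        for k, v in p.items():
            assert avg[k] == pytest.approx(v)

    def test_equal_weights_give_mean(self):
        f1 = self._fit({"I": 0.1, "r": 0.2, "alpha1": -0.2, "sigma2": 0.04})
        f2 = self._fit({"I": 0.3, "r": 0.4, "alpha1": -0.4, "sigma2": 0.06})
        avg = d.model_average([f1, f2], weights=[0.5, 0.5])
        assert avg["I"] == pytest.approx(0.2)
        assert avg["sigma2"] == pytest.approx(0.05)

    def test_hand_computed_three_model_average(self):
        fits = [self._fit({"I": i, "r": r, "alpha1": a, "sigma2": s})
                for i, r, a, s in [(0.1, 0.1, -0.1, 0.03),
                                   (0.2, 0.3, -0.2, 0.04),
                                   (0.4, 0.5, -0.6, 0.05)]]
        avg = d.model_average(fits, weights=[0.5, 0.3, 0.2])
        assert avg["I"] == pytest.approx(0.5 * 0.1 + 0.3 * 0.2 + 0.2 * 0.4)
        assert avg["alpha1"] == pytest.approx(-(0.5 * 0.1 + 0.3 * 0.2 + 0.2 * 0.6))

    def test_fixed_values_contribute(self):
        nonlin = ModelSpec(order=1, linear=False)
        f1 = self._fit({"I": 0.1, "r": 0.2, "alpha1": -0.2, "sigma2": 0.04})
        f2 = self._fit({"I": 0.3, "r": 0.4, "alpha1": -0.4, "beta1": 0.02,
                        "c1": 10.0, "sigma2": 0.06}, spec=nonlin)
        avg = d.model_average([f1, f2], weights=[0.5, 0.5])
        assert avg["beta1"] == pytest.approx(0.5 * 0.0 + 0.5 * 0.02)
        assert avg["c1"] == pytest.approx(0.5 * 1.0 + 0.5 * 10.0)


class TestFitMl:
    def test_refit_from_optimum_is_idempotent(self, small_study, dls_preset):
        _, spec_c, _ = d.preset("constant_table1")
        ds = d.build_lag_dataset(small_study, max_lag=1)
        fit1 = d.fit_ml(ds, spec_c, n_starts=2, seed=0)
        fit2 = d.fit_ml(ds, spec_c, n_starts=1, seed=0, start=fit1.params)
        assert fit2.neg_ll <= fit1.neg_ll + 1e-6

    def test_seed_determinism(self, small_study):
        _, spec_c, _ = d.preset("constant_table1")
        ds = d.build_lag_dataset(small_study, max_lag=1)
        fit1 = d.fit_ml(ds, spec_c, n_starts=3, seed=7)
        fit2 = d.fit_ml(ds, spec_c, n_starts=3, seed=7)
        assert fit1.neg_ll == fit2.neg_ll
        assert fit1.params == fit2.params

    def test_nesting_monotonicity(self, small_study):
        """The non-linear variant can never fit worse than its nested linear
        special case (up to optimizer tolerance)."""
        ds = d.build_lag_dataset(small_study, max_lag=1)
        lin_spec = ModelSpec(order=1, linear=True, variance="constant")
        nonlin_spec = ModelSpec(order=1, linear=False, variance="constant")
        lin = d.fit_ml(ds, lin_spec, n_starts=3, seed=0)
        start = dict(lin.params, beta1=0.0, c1=5.0)
        nonlin = d.fit_ml(ds, nonlin_spec, n_starts=3, seed=0, start=start)
        assert nonlin.neg_ll <= lin.neg_ll + 1e-4

    def test_aic_consistency_and_fingerprint(self, small_study):
        _, spec_c, _ = d.preset("constant_table1")
        ds = d.build_lag_dataset(small_study, max_lag=1)
        fit = d.fit_ml(ds, spec_c, n_starts=2, seed=0)
        assert fit.aic == pytest.approx(2 * fit.k + 2 * fit.neg_ll)
        assert fit.dataset_fingerprint == ds.fingerprint()
        assert fit.k == 4

    def test_underidentified_data_warns(self, rng):
        plot = make_plot(np.arange(2000, 2006), rng.integers(10, 90, 6))
        ds = d.build_lag_dataset([plot], max_lag=1)
        with pytest.warns(UserWarning, match="rows"):
            d.fit_ml(ds, DLS_SPEC, n_starts=1, seed=0, maxiter=20)

    def test_constant_model_parameter_recovery(self, constant_preset):
        """Median estimates across replicated synthetic studies recover the
        generating immigration, density-dependence and variance parameters."""
        design, spec, truth = constant_preset
        est = []
        for rep in range(50):
            plots = d.generate_study(design, spec, truth, seed=3_000 + rep)
            ds = d.build_lag_dataset(plots, max_lag=1)
            fit = d.fit_ml(ds, spec, n_starts=3, seed=rep)
            est.append([fit.params[k] for k in ("I", "alpha1", "sigma2")])
        med = np.median(est, axis=0)
        assert abs(med[0] - truth["I"]) / truth["I"] < 0.15
        assert abs(med[1] - truth["alpha1"]) / abs(truth["alpha1"]) < 0.15
        assert abs(med[2] - truth["sigma2"]) / truth["sigma2"] < 0.20
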