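"""NSUR estimation: start values, weighting, FGLS behaviour."""

import numpy as np
import pytest
from scipy import optimize

from allocarbon.allometry import AdditiveParams, predict_components
from allocarbon.data import biomass_matrix
from allocarbon.nsur import (
    KOREAN_PINE_VARIANCE_EXPONENTS,
    CompatibleSystemModel,
    FitError,
    WeightSpec,
    estimate_weight_exponents,
    fit_nsur,
    start_values,
)
from allocarbon.simulate import DEFAULT_BIOMASS_PARAMS, SimulationConfig, simulate_dataset

TRUTH = DEFAULT_BIOMASS_PARAMS


class TestStartValues:
    def test_exact_on_common_power_law(self):
        """Four identical power-law components linearise exactly in log–log."""
        x = np.linspace(5, 40, 30)
        y = 0.1 * x ** 2.4
        Y = np.column_stack([y, y, y, y])
        sv = start_values(x, Y)
        assert sv.a == pytest.approx(0.4, rel=1e-10)
        assert sv.b == pytest.approx(2.4, rel=1e-10)
        np.testing.assert_allclose([sv.r1, sv.r2, sv.r3], 1.0, rtol=1e-10)
        np.testing.assert_allclose([sv.k1, sv.k2, sv.k3], 0.0, atol=1e-10)

    def test_close_to_truth_on_noisy_data(self):
        df = simulate_dataset(SimulationConfig(n_trees=400, seed=42))
        sv = start_values(df["D_cm"].to_numpy(), biomass_matrix(df))
        rel = np.abs(sv.as_array() - TRUTH.as_array()) / np.abs(TRUTH.as_array())
        assert np.all(rel < 0.25)

    def test_nonpositive_responses_excluded(self, caplog):
        x = np.linspace(5, 40, 30)
        Y = np.column_stack([0.1 * x ** 2.4] * 4)
        Y[0, 1] = 0.0
        with caplog.at_level("WARNING"):
            sv = start_values(x, Y)
        assert "non-positive" in caplog.text
        assert np.isfinite(sv.as_array()).all()

    def test_all_excluded_is_an_error(self):
        x = np.linspace(5, 40, 30)
        Y = np.column_stack([0.1 * x ** 2.4] * 4)
        Y[:, 2] = 0.0
        with pytest.raises(FitError):
            start_values(x, Y)


class TestWeightExponents:
    def test_recovers_known_variance_power(self, rng):
        """Variance ∝ D^2.33 is read back off simulated residuals."""
        x = rng.lognormal(np.log(16.5), 0.28, 20_000)
        resid = rng.normal(size=(x.size, 4)) * 0.3 * x[:, None] ** (2.33 / 2)
        w = estimate_weight_exponents(x, resid)
        np.testing.assert_allclose(w.as_array(), 2.33, atol=0.2)

    def test_homoscedastic_residuals_give_near_zero(self, rng):
        x = rng.lognormal(np.log(16.5), 0.28, 20_000)
        w = estimate_weight_exponents(x, rng.normal(size=(x.size, 4)))
        assert np.all(np.abs(w.as_array()) < 0.15)

    def test_zero_residuals_give_zero_exponent(self):
        x = np.linspace(5, 40, 30)
        w = estimate_weight_exponents(x, np.zeros((30, 4)))
        assert np.all(w.as_array() == 0)

    def test_published_exponents_available_as_fixed_weighting(self, default_dataset):
        fixed = KOREAN_PINE_VARIANCE_EXPONENTS["BM1"]
        np.testing.assert_allclose(fixed.as_array(), [2.33, 2.01, 1.67, 2.19])
        res = CompatibleSystemModel(default_dataset, "BM1", weights="fixed").fit()
        assert res.weight_spec == fixed

    def test_sd_weights_halve_the_variance_exponent(self):
        w = WeightSpec(2.0, 2.0, 2.0, 2.0)
        np.testing.assert_allclose(w.sd_weights(np.array([4.0]))[0], 4.0)


def _noise_free_system(n=40):
    x = np.linspace(6, 35, n)
    Y = predict_components(TRUTH, x)
    return x, Y


class TestFitNsur:
    def test_recovers_exactly_from_noise_free_data(self):
        x, Y = _noise_free_system()
        start = AdditiveParams(a=0.05, b=2.2, r1=0.002, r2=0.04, r3=0.12,
                               k1=1.5, k2=0.4, k3=0.6)
        raw = fit_nsur(x, Y, WeightSpec.unit(), start)
        np.testing.assert_allclose(raw["params"].as_array(), TRUTH.as_array(), rtol=1e-6)
        assert raw["converged"]

    def test_matches_stacked_nls_under_identity_sigma(self):
        """With Σ fixed at the identity and unit weights, the FGLS step is
        plain stacked nonlinear least squares; an independent Nelder-Mead
        minimiser of the stacked objective finds the same optimum."""
        df = simulate_dataset(SimulationConfig(n_trees=60, seed=9))
        x, Y = df["D_cm"].to_numpy(), biomass_matrix(df)
        start = start_values(x, Y)
        raw = fit_nsur(x, Y, WeightSpec.unit(), start, max_iter=1, sigma0=np.eye(4))

        def sse(phi):
            p = AdditiveParams(np.exp(phi[0]), phi[1], np.exp(phi[2]), np.exp(phi[3]),
                               np.exp(phi[4]), phi[5], phi[6], phi[7])
            return float(((Y - predict_components(p, x)) ** 2).sum())

        t = start.as_array()
        phi0 = np.array([np.log(t[0]), t[1], np.log(t[2]), np.log(t[3]), np.log(t[4]),
                         t[5], t[6], t[7]])
        oracle = optimize.minimize(sse, phi0, method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        theta_oracle = np.array([np.exp(oracle.x[0]), oracle.x[1], np.exp(oracle.x[2]),
                                 np.exp(oracle.x[3]), np.exp(oracle.x[4]),
                                 oracle.x[5], oracle.x[6], oracle.x[7]])
        np.testing.assert_allclose(raw["params"].as_array(), theta_oracle, rtol=2e-3)
        assert sse(np.array([np.log(raw["params"].a), raw["params"].b,
                             np.log(raw["params"].r1), np.log(raw["params"].r2),
                             np.log(raw["params"].r3), raw["params"].k1,
                             raw["params"].k2, raw["params"].k3])) <= oracle.fun * (1 + 1e-8)

    def test_gls_invariant_to_sigma_scale(self, default_dataset):
        x = default_dataset["D_cm"].to_numpy()
        Y = biomass_matrix(default_dataset)
        start = start_values(x, Y)
        w = KOREAN_PINE_VARIANCE_EXPONENTS["BM1"]
        a = fit_nsur(x, Y, w, start, max_iter=1, sigma0=np.eye(4))
        b = fit_nsur(x, Y, w, start, max_iter=1, sigma0=7.3 * np.eye(4))
        np.testing.assert_allclose(a["params"].as_array(), b["params"].as_array(), rtol=1e-7)

    def test_fgls_fixed_point(self, default_dataset):
        """Restarting a converged fit from its own solution moves nothing."""
        model = CompatibleSystemModel(default_dataset, "BM1")
        res = model.fit(tol=1e-8)
        assert res.converged
        res2 = model.fit(start=res.params, sigma0=res.sigma, tol=1e-8)
        np.testing.assert_allclose(res2.params_array, res.params_array, rtol=1e-6)

    def test_sigma_symmetric_positive_semidefinite(self, default_dataset):
        res = CompatibleSystemModel(default_dataset, "BM1").fit()
        np.testing.assert_allclose(res.sigma, res.sigma.T)
        assert np.linalg.eigvalsh(res.sigma).min() >= -1e-12

    def test_too_few_trees_is_explicit_failure(self):
        x, Y = _noise_free_system(2)
        with pytest.raises(FitError, match="at least 3"):
            fit_nsur(x, Y, WeightSpec.unit(), TRUTH)

    def test_estimated_weights_mode_runs(self, default_dataset):
        res = CompatibleSystemModel(default_dataset, "BM1", weights="estimate").fit()
        assert res.converged
        # variance clearly grows with D: every exponent positive
        assert np.all(res.weight_spec.as_array() > 0)

    def test_two_step_close_to_iterated(self, default_dataset):
        model = CompatibleSystemModel(default_dataset, "BM1")
        full = model.fit()
        two = model.fit(two_step=True)
        rel = np.abs(two.params_array - full.params_array) / np.abs(full.params_array)
        assert np.all(rel < 0.05)

    def test_summary_mentions_convergence_and_weights(self, default_dataset):
        res = CompatibleSystemModel(default_dataset, "BM1").fit()
        text = res.summary()
        assert "converged" in text and "2.33" in text and "BM1" in text
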