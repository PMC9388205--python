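"""Likelihood, transfer-model estimation, and residual diagnostics."""

from datetime import date

import numpy as np
import pytest

from edseries import (
    ModelParams,
    NoiseSpec,
    SeriesPair,
    TransferModelSpec,
    WeeklySeries,
    acf_pacf,
    fit_transfer_model,
    gen_pair,
    identify_noise,
    ljung_box,
    model_loglik,
    simulate_subset_ar,
)
from conftest import spec_for

ANCHOR = date(2018, 1, 5)


def make_pair(y, x):
    y = np.asarray(np.rint(y), dtype=int)
    x = np.asarray(np.rint(x), dtype=int)
    return SeriesPair(
        dependent=WeeklySeries(ANCHOR, tuple(y), "dep"),
        control=WeeklySeries(ANCHOR, tuple(x), "ctl"),
    )


def ols_closed_form(y, exog):
    """Gaussian-ML closed form for iid-error regression: coefficients,
    sigma2 = RSS/T, standard errors, log-likelihood."""
    beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid = y - exog @ beta
    t = len(y)
    sigma2 = resid @ resid / t
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(exog.T @ exog)))
    loglik = -0.5 * t * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
    return beta, sigma2, se, loglik


@pytest.fixture
def noisy_pair():
    rng = np.random.default_rng(123)
    x = rng.normal(571, 91, 80)
    y = 20 + 0.9 * x + rng.normal(0, 50, 80)
    return make_pair(np.maximum(y, 0), np.maximum(x, 0))


WHITE_SPEC = TransferModelSpec(noise=NoiseSpec((), (), 0), intervention=None, burn_in_weeks=0)


class TestModelLoglik:
    def test_zero_residuals_unit_variance_closed_form(self):
        x = np.arange(100, 180)
        pair = make_pair(2 * x, x)
        params = ModelParams(alpha=0.0, beta_control=2.0, sigma2=1.0)
        value = model_loglik(params, pair, WHITE_SPEC)
        assert value == pytest.approx(-(len(pair) / 2) * np.log(2 * np.pi))

    def test_matches_ols_closed_form(self, noisy_pair):
        y = noisy_pair.dependent.values
        exog = np.column_stack([np.ones(len(noisy_pair)), noisy_pair.control.values])
        beta, sigma2, _, loglik = ols_closed_form(y, exog)
        params = ModelParams(alpha=beta[0], beta_control=beta[1], sigma2=sigma2)
        assert model_loglik(params, noisy_pair, WHITE_SPEC) == pytest.approx(loglik)

    def test_nonpositive_sigma2_rejected(self, noisy_pair):
        with pytest.raises(ValueError, match="sigma2"):
            model_loglik(ModelParams(sigma2=0.0, beta_control=1.0), noisy_pair, WHITE_SPEC)

    def test_nonfinite_params_rejected(self, noisy_pair):
        with pytest.raises(ValueError, match="finite"):
            model_loglik(
                ModelParams(alpha=np.nan, beta_control=1.0), noisy_pair, WHITE_SPEC
            )

    def test_lags_outside_spec_rejected(self, noisy_pair):
        with pytest.raises(ValueError, match="outside the noise spec"):
            model_loglik(
                ModelParams(beta_control=1.0, phi={3: 0.2}), noisy_pair, WHITE_SPEC
            )

    def test_perturbation_lowers_loglik_at_optimum(self, noisy_pair):
        fit = fit_transfer_model(noisy_pair, WHITE_SPEC)
        at_opt = fit.loglik
        for da, db in ((0.5, 0.0), (0.0, 0.01), (-0.5, 0.01)):
            params = ModelParams(
                alpha=fit.params["const"] + da,
                beta_control=fit.params["control"] + db,
                sigma2=fit.sigma2,
            )
            assert model_loglik(params, noisy_pair, WHITE_SPEC) < at_opt


class TestFitTransferModel:
    def test_ols_reduction_coefficients_and_ses(self, noisy_pair):
        fit = fit_transfer_model(noisy_pair, WHITE_SPEC)
        y = noisy_pair.dependent.values
        exog = np.column_stack([np.ones(len(noisy_pair)), noisy_pair.control.values])
        beta, sigma2, se, loglik = ols_closed_form(y, exog)
        assert fit.params["const"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.params["control"] == pytest.approx(beta[1], abs=1e-6)
        assert fit.se["const"] == pytest.approx(se[0], abs=1e-6)
        assert fit.se["control"] == pytest.approx(se[1], abs=1e-6)
        assert fit.loglik == pytest.approx(loglik, abs=1e-6)

    def test_ci_brackets_estimate_symmetrically(self, noisy_pair):
        fit = fit_transfer_model(noisy_pair, WHITE_SPEC)
        for name in fit.param_names:
            lo, hi = fit.ci95[name]
            assert lo <= fit.params[name] <= hi
            assert (hi - fit.params[name]) == pytest.approx(fit.params[name] - lo)

    def test_residual_count_drops_burn_in(self, short_config):
        pair, truth = gen_pair(short_config, seed=5)
        fit = fit_transfer_model(pair, spec_for(truth))
        assert len(fit.residuals) == len(pair) - 6
        assert len(fit.residuals_full) == len(pair)
        # residual mean is centred relative to its own spread
        sd = fit.residuals.std(ddof=1)
        assert abs(fit.residuals.mean()) < 3 * sd / np.sqrt(len(fit.residuals))

    def test_recovers_generator_truth_within_ci(self, default_config):
        pair, truth = gen_pair(default_config, seed=3)
        fit = fit_transfer_model(pair, spec_for(truth))
        checks = {
            "control": truth.beta_control,
            "intervention": truth.omega,
            "ar.L1": truth.phi[1],
            "ar.L5": truth.phi[5],
        }
        for name, true_value in checks.items():
            lo, hi = fit.ci95[name]
            assert lo <= true_value <= hi, f"{name}: {true_value} outside ({lo}, {hi})"

    def test_loglik_at_estimate_beats_truth(self, default_config):
        pair, truth = gen_pair(default_config, seed=9)
        spec = spec_for(truth)
        fit = fit_transfer_model(pair, spec)
        at_truth = model_loglik(
            ModelParams(
                alpha=truth.alpha,
                beta_control=truth.beta_control,
                omega=truth.omega,
                phi=truth.phi,
                sigma2=truth.noise_sd**2,
            ),
            pair,
            spec,
        )
        assert fit.loglik >= at_truth

    def test_series_too_short_rejected(self):
        pair = make_pair(np.arange(10) + 50, np.arange(10) + 40)
        spec = TransferModelSpec(noise=NoiseSpec((1, 5)), intervention=None)
        with pytest.raises(ValueError, match="too short"):
            fit_transfer_model(pair, spec)


class TestAcfPacf:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        report = acf_pacf(rng.normal(size=500), 10)
        assert report.acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(report.acf) <= 1 + 1e-12)

    def test_iid_noise_has_negligible_lag_one_acf(self):
        rng = np.random.default_rng(1)
        report = acf_pacf(rng.normal(size=10_000), 5)
        assert abs(report.acf[1]) < 0.05

    def test_ar1_theoretical_acf(self):
        rng = np.random.default_rng(2)
        x = simulate_subset_ar({1: 0.5}, 1.0, 10_000, rng)
        report = acf_pacf(x, 5)
        assert report.acf[1] == pytest.approx(0.5, abs=0.03)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            acf_pacf(np.ones(100), 5)


class TestLjungBox:
    def test_null_rarely_rejects(self):
        rng = np.random.default_rng(3)
        pvals = [ljung_box(rng.normal(size=5000), 12, 0)[1] for _ in range(50)]
        assert np.mean(np.asarray(pvals) > 0.01) >= 0.98

    def test_strong_ar1_rejected(self):
        rng = np.random.default_rng(4)
        x = simulate_subset_ar({1: 0.8}, 1.0, 500, rng)
        _, p = ljung_box(x, 12, 0)
        assert p < 0.001

    def test_invalid_dof_rejected(self):
        with pytest.raises(ValueError, match="must exceed"):
            ljung_box(np.random.default_rng(5).normal(size=100), 5, 5)

    def test_degenerate_residuals_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ljung_box(np.zeros(100), 12, 0)


class TestIdentifyNoise:
    def test_flags_lags_one_and_five_most_often(self):
        # noise calibrated to the initial-model AR estimates
        from collections import Counter

        counts = Counter()
        for seed in range(150):
            rng = np.random.default_rng(seed)
            x = simulate_subset_ar({1: 0.28, 5: 0.19}, 1.0, 142, rng)
            counts.update(identify_noise(x, 10).ar_lags)
        top_two = {lag for lag, _ in counts.most_common(2)}
        assert top_two == {1, 5}

    def test_white_noise_family_false_flag_rate(self):
        # with a per-lag 1.96 band over 10 lags the no-flag probability
        # is about 0.95**10 ~ 0.60; check the empirical rate sits there
        empty = 0
        n = 150
        for seed in range(n):
            rng = np.random.default_rng(1000 + seed)
            empty += len(identify_noise(rng.normal(size=142), 10).ar_lags) == 0
        assert 0.45 <= empty / n <= 0.80

    def test_constant_residuals_error_propagates(self):
        with pytest.raises(ValueError, match="constant"):
            identify_noise(np.full(100, 3.0))


class TestNoiseSpec:
    def test_subset_order_frees_only_configured_lags(self):
        spec = NoiseSpec((1, 5))
        assert spec.sarimax_order() == ([1, 0, 0, 0, 1], 0, 0)

    def test_invalid_lags_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec((0, 2))
        with pytest.raises(ValueError):
            NoiseSpec((1,), d=2)
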