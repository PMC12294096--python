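"""Attenuation coefficient estimation and the alpha-vs-contact-pressure line."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaugebp.attenuation import (
    AlphaObservation,
    AttenuationRegression,
    estimate_alpha,
    fit_alpha_vs_pressure,
    predict_alpha,
    summarize_alpha,
)
from gaugebp.simulate import apply_attenuation, generate_pulse

# group means observed in static characterization: contact pressure -> alpha
STATIC_ALPHA_MEANS = {20.0: 5.0, 30.0: 4.8, 40.0: 4.5, 50.0: 4.2, 60.0: 3.9}


class TestEstimateAlpha:
    def test_equal_amplitudes_give_zero(self):
        assert estimate_alpha(10.0, 10.0) == 0.0

    def test_exact_inverse_of_exponential_decay(self):
        assert estimate_alpha(10.0 * math.exp(-4.5), 10.0) == pytest.approx(4.5, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 3.9, 4.5, 5.0])
    def test_roundtrip_against_simulator(self, alpha, two_harmonic_pulse):
        series = generate_pulse(two_harmonic_pulse, 5.0, 250.0)
        attenuated = apply_attenuation(series, alpha)
        est = estimate_alpha(float(np.ptp(attenuated)), float(np.ptp(series)))
        assert est == pytest.approx(alpha, abs=1e-6)

    def test_amplified_signal_rejected(self):
        with pytest.raises(ValueError, match="out of model"):
            estimate_alpha(11.0, 10.0)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            estimate_alpha(0.0, 10.0)


class TestSummarizeAlpha:
    def test_identical_observations_have_zero_sd(self):
        obs = [AlphaObservation(40.0, 4.5) for _ in range(3)]
        table = summarize_alpha(obs)
        assert table.loc[40.0, "mean_alpha"] == 4.5
        assert table.loc[40.0, "sd_alpha"] == 0.0
        assert table.loc[40.0, "n"] == 3

    def test_two_point_sample_statistics(self):
        obs = [AlphaObservation(20.0, 5.1), AlphaObservation(20.0, 4.9)]
        table = summarize_alpha(obs)
        assert table.loc[20.0, "mean_alpha"] == pytest.approx(5.0)
        assert table.loc[20.0, "sd_alpha"] == pytest.approx(0.1414, abs=5e-4)

    def test_group_means_track_truth_within_three_standard_errors(self):
        rng = np.random.default_rng(7)
        sd, n = 0.15, 30
        obs = [
            AlphaObservation(pc, rng.normal(mu, sd))
            for pc, mu in STATIC_ALPHA_MEANS.items()
            for _ in range(n)
        ]
        table = summarize_alpha(obs)
        for pc, mu in STATIC_ALPHA_MEANS.items():
            se = sd / math.sqrt(n)
            assert abs(table.loc[pc, "mean_alpha"] - mu) < 3 * se

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            table = summarize_alpha([])
        assert table.empty


class TestAlphaPressureFit:
    def test_static_group_means_give_published_slope(self):
        fit = fit_alpha_vs_pressure(
            contact_pressures=list(STATIC_ALPHA_MEANS),
            alphas=list(STATIC_ALPHA_MEANS.values()),
        )
        assert fit.slope_ == pytest.approx(-0.028, abs=5e-4)
        # closed-form OLS intercept for these five means is 5.60
        assert fit.intercept_ == pytest.approx(5.60, abs=5e-3)

    def test_exact_line_recovered_with_zero_residual(self):
        pc = np.array([15.0, 25.0, 45.0, 65.0])
        alpha = -0.03 * pc + 5.5
        fit = AttenuationRegression().fit(pc, alpha)
        assert fit.slope_ == pytest.approx(-0.03, rel=1e-12)
        assert fit.intercept_ == pytest.approx(5.5, rel=1e-12)
        assert fit.residual_sd_ == pytest.approx(0.0, abs=1e-12)

    def test_accepts_mean_table_and_observation_list(self):
        obs = [
            AlphaObservation(pc, a, subject_id="s1")
            for pc, a in STATIC_ALPHA_MEANS.items()
        ]
        via_obs = fit_alpha_vs_pressure(obs)
        via_table = fit_alpha_vs_pressure(summarize_alpha(obs))
        assert via_obs.slope_ == pytest.approx(via_table.slope_)

    @given(delta=st.floats(-2.0, 2.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_shift_equivariance(self, delta):
        pc = np.array(list(STATIC_ALPHA_MEANS))
        alpha = np.array(list(STATIC_ALPHA_MEANS.values()))
        base = AttenuationRegression().fit(pc, alpha)
        shifted = AttenuationRegression().fit(pc, alpha + delta)
        assert shifted.slope_ == pytest.approx(base.slope_, abs=1e-10)
        assert shifted.intercept_ == pytest.approx(base.intercept_ + delta, abs=1e-10)

    def test_negative_slope_fit_is_monotonically_decreasing_over_range(self):
        fit = fit_alpha_vs_pressure(
            contact_pressures=list(STATIC_ALPHA_MEANS),
            alphas=list(STATIC_ALPHA_MEANS.values()),
        )
        grid = np.linspace(15.0, 70.0, 12)
        preds = fit.predict(grid)
        assert np.all(np.diff(preds) < 0)

    def test_single_pressure_level_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            AttenuationRegression().fit([40.0, 40.0, 40.0], [4.5, 4.4, 4.6])

    def test_trial_level_noisy_slope_within_three_standard_errors(self):
        truth_m, truth_b, sd, n_per = -0.028, 5.56, 0.15, 3
        misses = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pc, alpha = [], []
            for level in STATIC_ALPHA_MEANS:
                for _ in range(n_per):
                    pc.append(level)
                    alpha.append(truth_m * level + truth_b + rng.normal(0.0, sd))
            fit = AttenuationRegression().fit(pc, alpha)
            if abs(fit.slope_ - truth_m) > 3.0 * fit.slope_se_:
                misses += 1
        assert misses <= 4


class TestPredictAlpha:
    def _fit(self, m, b):
        pc = np.array([20.0, 60.0])
        return AttenuationRegression().fit(pc, m * pc + b)

    def test_published_model_at_dynamic_contact_pressure(self):
        fit = self._fit(-0.028, 5.56)
        assert predict_alpha(fit, 40.0) == pytest.approx(4.44, abs=1e-9)

    def test_constant_model(self):
        fit = self._fit(0.0, 5.0)
        assert predict_alpha(fit, 33.0) == pytest.approx(5.0)

    def test_guard_band_rejects_extrapolation(self):
        fit = self._fit(-0.028, 5.56)
        with pytest.raises(ValueError, match="guard band"):
            predict_alpha(fit, 5.0)
        with pytest.raises(ValueError, match="guard band"):
            predict_alpha(fit, 90.0)

    def test_nonpositive_prediction_rejected(self):
        fit = self._fit(-0.028, 1.0)  # crosses zero around 36 mmHg
        with pytest.raises(ValueError, match="nonpositive"):
            predict_alpha(fit, 60.0)
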