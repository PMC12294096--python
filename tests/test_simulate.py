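"""Simulator unit and property tests: pulse synthesis, attenuation physics,
dual-channel composition, ADC quantization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaugebp.simulate import (
    AdcModel,
    ContactPressureProfile,
    Harmonic,
    PulseWaveModel,
    TissueModel,
    apply_attenuation,
    generate_pulse,
    mechanical_impedance,
    pulse_extrema,
    synthesize_recording,
)


class TestGeneratePulse:
    def test_constant_model_yields_mean_pressure(self):
        series = generate_pulse(PulseWaveModel(mean_pressure=93.0), 1.0, 100.0)
        assert len(series) == 100
        assert np.all(series == 93.0)

    def test_single_harmonic_quarter_period_value(self):
        model = PulseWaveModel(mean_pressure=0.0, harmonics=(Harmonic(1.0, 1.0, 0.0),))
        series = generate_pulse(model, 1.0, 100.0)
        assert series[25] == pytest.approx(1.0, abs=1e-12)  # sin(pi/2)

    def test_mean_over_integer_cycles(self, two_harmonic_pulse):
        # closed form: each sinusoid sums to zero over whole periods
        series = generate_pulse(two_harmonic_pulse, 10.0, 250.0)
        assert len(series) == 2500
        assert np.mean(series) == pytest.approx(100.0, abs=1e-9)

    def test_sub_nyquist_sampling_rejected(self, two_harmonic_pulse):
        with pytest.raises(ValueError, match="[Aa]lias"):
            generate_pulse(two_harmonic_pulse, 10.0, 4.0)

    def test_invalid_harmonic_ordering_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PulseWaveModel(100.0, (Harmonic(5.0, 2.0), Harmonic(3.0, 1.0)))

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            Harmonic(-1.0, 1.0)


class TestApplyAttenuation:
    def test_zero_alpha_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(apply_attenuation(x, 0.0), x)

    def test_ln2_halves_a_constant(self):
        out = apply_attenuation(np.full(10, 100.0), math.log(2.0))
        np.testing.assert_allclose(out, 50.0, rtol=1e-12)

    def test_amplitude_scaling_matches_closed_form(self, two_harmonic_pulse):
        series = generate_pulse(two_harmonic_pulse, 5.0, 100.0)
        out = apply_attenuation(series, TissueModel(alpha=4.5))
        expected = np.ptp(series) * math.exp(-4.5)
        assert np.ptp(out) == pytest.approx(expected, rel=1e-12)
        # reference arithmetic: a 40 mmHg swing shrinks to ~0.444 mmHg
        assert 40.0 * math.exp(-4.5) == pytest.approx(0.4444, abs=5e-4)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            apply_attenuation(np.ones(3), -0.1)

    @given(
        a1=st.floats(0.0, 3.0),
        a2=st.floats(0.0, 3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_attenuation_composes_additively(self, a1, a2):
        x = np.linspace(-5.0, 5.0, 11)
        once = apply_attenuation(apply_attenuation(x, a1), a2)
        np.testing.assert_allclose(once, apply_attenuation(x, a1 + a2), rtol=1e-12)


class TestMechanicalImpedance:
    def test_unit_product(self):
        t = TissueModel(0.0, 1.0, 1.0, 1.0, 1.0)
        assert mechanical_impedance(t) == 1.0

    def test_linear_in_elastic_modulus(self):
        base = TissueModel(0.0, 1e5, 1050.0, 1540.0, 0.003)
        doubled = TissueModel(0.0, 2e5, 1050.0, 1540.0, 0.003)
        assert mechanical_impedance(doubled) == pytest.approx(
            2.0 * mechanical_impedance(base)
        )

    def test_soft_tissue_product(self):
        # direct arithmetic oracle: 1e5 * 1050 * 1540 * 0.003
        t = TissueModel(0.0, 1e5, 1050.0, 1540.0, 0.003)
        assert mechanical_impedance(t) == pytest.approx(4.851e8, rel=1e-12)

    def test_missing_field_rejected(self):
        with pytest.raises(ValueError, match="effective_depth"):
            mechanical_impedance(TissueModel(0.0, 1e5, 1050.0, 1540.0, None))


class TestSynthesizeRecording:
    def test_identical_seeds_identical_recordings(
        self, two_harmonic_pulse, wrist_tissue, adc
    ):
        contact = ContactPressureProfile(baseline=40.0, noise_sd=0.5)
        a = synthesize_recording(
            two_harmonic_pulse, wrist_tissue, contact, adc, 10.0, 100.0, seed=7
        )
        b = synthesize_recording(
            two_harmonic_pulse, wrist_tissue, contact, adc, 10.0, 100.0, seed=7
        )
        np.testing.assert_array_equal(a.primary, b.primary)
        np.testing.assert_array_equal(a.reference, b.reference)

    def test_channel_subtraction_inverts_construction(
        self, two_harmonic_pulse, quiet_contact
    ):
        rec = synthesize_recording(
            two_harmonic_pulse, TissueModel(alpha=0.0), quiet_contact, None,
            10.0, 100.0, seed=0, quantize=False,
        )
        pulse = generate_pulse(two_harmonic_pulse, 10.0, 100.0)
        np.testing.assert_allclose(rec.primary - rec.reference, pulse, atol=1e-10)

    def test_attenuated_reconstruction_within_quantization(
        self, two_harmonic_pulse, wrist_tissue, quiet_contact, adc
    ):
        rec = synthesize_recording(
            two_harmonic_pulse, wrist_tissue, quiet_contact, adc, 10.0, 100.0, seed=0
        )
        pulse = generate_pulse(two_harmonic_pulse, 10.0, 100.0)
        recon = (rec.primary - rec.reference) * math.exp(wrist_tissue.alpha)
        tol = (1.0 + math.exp(wrist_tissue.alpha)) * adc.step
        assert np.max(np.abs(recon - pulse)) <= tol

    def test_channel_noise_matches_stated_model(self, two_harmonic_pulse, wrist_tissue):
        contact = ContactPressureProfile(baseline=40.0, noise_sd=0.5)
        rec = synthesize_recording(
            two_harmonic_pulse, wrist_tissue, contact, None, 60.0, 100.0,
            seed=42, quantize=False,
        )
        residual_sd = np.std(rec.reference - 40.0)
        assert residual_sd == pytest.approx(0.5, rel=0.10)

    def test_shared_drift_and_motion_cancel_in_difference(self, two_harmonic_pulse):
        contact = ContactPressureProfile(
            baseline=40.0,
            drift=lambda t: 0.1 * t,
            noise_sd=0.0,
            motion_events=((2.0, 1.0, 5.0),),
        )
        rec = synthesize_recording(
            two_harmonic_pulse, TissueModel(alpha=0.0), contact, None,
            10.0, 100.0, seed=0, quantize=False,
        )
        pulse = generate_pulse(two_harmonic_pulse, 10.0, 100.0)
        np.testing.assert_allclose(rec.primary - rec.reference, pulse, atol=1e-10)

    def test_nonpositive_duration_rejected(
        self, two_harmonic_pulse, wrist_tissue, quiet_contact
    ):
        with pytest.raises(ValueError):
            synthesize_recording(
                two_harmonic_pulse, wrist_tissue, quiet_contact, None, 0.0, 100.0, 0
            )


class TestSpectralFidelity:
    def test_fft_recovers_harmonic_amplitudes_and_frequencies(self, two_harmonic_pulse):
        fs, duration = 100.0, 10.0  # 12 whole fundamental cycles
        series = generate_pulse(two_harmonic_pulse, duration, fs)
        n = len(series)
        spectrum = np.fft.rfft(series - np.mean(series)) / n * 2.0
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        for h in two_harmonic_pulse.harmonics:
            k = np.argmin(np.abs(freqs - h.frequency))
            assert freqs[k] == pytest.approx(h.frequency, abs=freqs[1] / 2)
            assert np.abs(spectrum[k]) == pytest.approx(h.amplitude, rel=0.02)


class TestQuantization:
    def test_quantization_moves_no_sample_more_than_one_step(self, rng):
        adc = AdcModel(bits=12, full_scale_min=0.0, full_scale_max=240.0)
        x = rng.uniform(0.0, 240.0, 1000)
        q = adc.quantize(x)
        assert np.max(np.abs(q - x)) <= adc.step
        assert adc.step == pytest.approx(240.0 / 2**12)

    def test_out_of_range_bits_rejected(self):
        with pytest.raises(ValueError):
            AdcModel(bits=4)


class TestPulseExtrema:
    def test_constant_model(self):
        assert pulse_extrema(PulseWaveModel(90.0)) == (90.0, 90.0)

    def test_single_harmonic_closed_form(self):
        model = PulseWaveModel(100.0, (Harmonic(20.0, 1.0),))
        sbp, dbp = pulse_extrema(model)
        assert sbp == pytest.approx(120.0, abs=1e-6)
        assert dbp == pytest.approx(80.0, abs=1e-6)
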