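"""Run configuration: pydantic models that round-trip losslessly through JSON.

A scenario config fully determines a synthetic recording (pulse harmonics,
tissue, contact profile, ADC, duration, sample rate, seed); a processing
config fully determines a pipeline run.  Every stochastic run carries an
explicit seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import simulate


class HarmonicConfig(BaseModel):
    amplitude_mmHg: float = Field(ge=0)
    frequency_hz: float = Field(gt=0)
    phase_rad: float = 0.0


class PulseConfig(BaseModel):
    mean_pressure_mmHg: float
    harmonics: list[HarmonicConfig] = []

    def build(self) -> simulate.PulseWaveModel:
        return simulate.PulseWaveModel(
            mean_pressure=self.mean_pressure_mmHg,
            harmonics=tuple(
                simulate.Harmonic(h.amplitude_mmHg, h.frequency_hz, h.phase_rad)
                for h in self.harmonics
            ),
        )


class TissueConfig(BaseModel):
    alpha: float = Field(ge=0)

    def build(self) -> simulate.TissueModel:
        return simulate.TissueModel(alpha=self.alpha)


class MotionEventConfig(BaseModel):
    onset_s: float
    duration_s: float = Field(gt=0)
    amplitude_mmHg: float


class ContactConfig(BaseModel):
    """Parametric contact profile: baseline + linear drift + sinusoidal drift."""

    baseline_mmHg: float = Field(ge=0)
    noise_sd_mmHg: float = Field(default=0.0, ge=0)
    drift_slope_mmHg_per_s: float = 0.0
    drift_sine_amplitude_mmHg: float = 0.0
    drift_sine_period_s: float = Field(default=30.0, gt=0)
    motion_events: list[MotionEventConfig] = []

    def build(self) -> simulate.ContactPressureProfile:
        slope = self.drift_slope_mmHg_per_s
        amp = self.drift_sine_amplitude_mmHg
        period = self.drift_sine_period_s
        drift: Callable[[np.ndarray], np.ndarray] | None = None
        if slope != 0.0 or amp != 0.0:
            def drift(t, _s=slope, _a=amp, _p=period):
                return _s * t + _a * np.sin(2.0 * np.pi * t / _p)
        return simulate.ContactPressureProfile(
            baseline=self.baseline_mmHg,
            drift=drift,
            noise_sd=self.noise_sd_mmHg,
            motion_events=tuple(
                (m.onset_s, m.duration_s, m.amplitude_mmHg) for m in self.motion_events
            ),
        )


class AdcConfig(BaseModel):
    bits: int = Field(default=24, ge=8, le=32)
    full_scale_min_mmHg: float = 0.0
    full_scale_max_mmHg: float = 240.0
    enabled: bool = True

    def build(self) -> simulate.AdcModel:
        return simulate.AdcModel(self.bits, self.full_scale_min_mmHg, self.full_scale_max_mmHg)


class ScenarioConfig(BaseModel):
    """Everything needed to synthesize one recording deterministically."""

    pulse: PulseConfig
    tissue: TissueConfig
    contact: ContactConfig
    adc: AdcConfig = AdcConfig()
    duration_s: float = Field(default=60.0, gt=0)
    sample_rate_hz: float = Field(default=100.0, gt=0)
    seed: int

    def synthesize(self) -> simulate.DualChannelRecording:
        return simulate.synthesize_recording(
            self.pulse.build(),
            self.tissue.build(),
            self.contact.build(),
            self.adc.build() if self.adc.enabled else None,
            self.duration_s,
            self.sample_rate_hz,
            self.seed,
            quantize=self.adc.enabled,
        )


class ProcessConfig(BaseModel):
    """Pipeline run parameters (paths resolved by the CLI)."""

    alpha: float | None = None
    attenuation_fit_path: str | None = None
    lowpass_cutoff_hz: float = 10.0
    filter_order: int = 4
    reference_smoothing_window_s: float = 1.0
    detection_cutoff_hz: float = 5.0
    refine: str = "template"
    beat_average: int = 5
    calibration_duration_s: float = 30.0
    max_pair_gap_s: float = 1.0


def default_static_scenario(seed: int = 0) -> ScenarioConfig:
    """Static 40 mmHg contact scenario with the canonical two-harmonic pulse."""
    return ScenarioConfig(
        pulse=PulseConfig(
            mean_pressure_mmHg=100.0,
            harmonics=[
                HarmonicConfig(amplitude_mmHg=20.0, frequency_hz=1.2),
                HarmonicConfig(amplitude_mmHg=8.0, frequency_hz=2.4),
            ],
        ),
        tissue=TissueConfig(alpha=4.5),
        contact=ContactConfig(baseline_mmHg=40.0, noise_sd_mmHg=0.0),
        seed=seed,
    )


def load_config(path: str | Path, model: type[BaseModel]):
    """Read and validate a JSON config file against a pydantic model."""
    text = Path(path).read_text(encoding="utf-8")
    return model.model_validate_json(text)


def dump_config(cfg: BaseModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(cfg.model_dump(), indent=2) + "\n", encoding="utf-8"
    )
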