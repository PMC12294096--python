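"""Physics simulator for a dual-transducer strain-gauge wrist sensor.

The wearable carries two pressure transducers on one strap: the *primary*
transducer sits over the radial artery and records the arterial pulse wave,
exponentially attenuated by the overlying tissue, riding on the strap's
contact pressure; the *reference* transducer sits off the artery and records
contact pressure alone.  The model implemented here is

    primary(t)   = P_a(t) * exp(-alpha) + P_contact(t) + noise_1(t)
    reference(t) =                        P_contact(t) + noise_2(t)

with the arterial wave P_a(t) a mean pressure plus a finite sum of cardiac
harmonics, alpha a lumped dimensionless tissue attenuation coefficient, and
P_contact a baseline plus slow drift plus optional motion bumps shared by
both channels (they ride the same strap).  Channel noise is additive
Gaussian, drawn independently per channel.  Samples can be quantized to a
24-bit ADC grid spanning 0-240 mmHg.

Everything is seeded; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Harmonic",
    "PulseWaveModel",
    "TissueModel",
    "ContactPressureProfile",
    "AdcModel",
    "DualChannelRecording",
    "generate_pulse",
    "apply_attenuation",
    "synthesize_recording",
    "mechanical_impedance",
    "pulse_extrema",
    "pulse_peak_phase",
]


@dataclass(frozen=True)
class Harmonic:
    """One cardiac harmonic: amplitude (mmHg), frequency (Hz), phase (rad)."""

    amplitude: float
    frequency: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"harmonic amplitude must be >= 0, got {self.amplitude}")
        if self.frequency <= 0:
            raise ValueError(f"harmonic frequency must be > 0, got {self.frequency}")


@dataclass(frozen=True)
class PulseWaveModel:
    """Arterial pressure as mean pressure plus a sum of sinusoidal harmonics.

    ``P_a(t) = mean_pressure + sum_n A_n sin(2 pi f_n t + phi_n)``
    """

    mean_pressure: float
    harmonics: tuple[Harmonic, ...] = ()

    def __post_init__(self) -> None:
        harmonics = tuple(
            h if isinstance(h, Harmonic) else Harmonic(*h) for h in self.harmonics
        )
        object.__setattr__(self, "harmonics", harmonics)
        freqs = [h.frequency for h in harmonics]
        if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
            raise ValueError("harmonic frequencies must be strictly increasing")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    @property
    def max_frequency(self) -> float:
        return self.harmonics[-1].frequency if self.harmonics else 0.0


@dataclass(frozen=True)
class TissueModel:
    """Tissue between artery and transducer.

    ``alpha`` is the lumped dimensionless attenuation exponent: the measured
    wave is the arterial wave times exp(-alpha).  Arterial depth, stiffness
    and density effects are all folded into alpha; the mechanical fields
    (elastic modulus E [Pa], density rho [kg/m^3], sound speed c [m/s],
    effective depth d [m]) are optional and feed only the qualitative
    impedance product, never the estimation path.
    """

    alpha: float
    elastic_modulus: float | None = None
    density: float | None = None
    sound_speed: float | None = None
    effective_depth: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")
        for name in ("elastic_modulus", "density", "sound_speed", "effective_depth"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


# drift signature: time array [s] -> mmHg offset array
DriftFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ContactPressureProfile:
    """Contact pressure from the strap: baseline + drift + noise + motion.

    ``motion_events`` are (onset_s, duration_s, amplitude_mmHg) raised-cosine
    bumps, shared by both channels.  ``drift`` is an arbitrary function of
    time (seconds -> mmHg), also shared; channel noise is independent.
    """

    baseline: float
    drift: DriftFn | None = None
    noise_sd: float = 0.0
    motion_events: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError(f"baseline contact pressure must be >= 0, got {self.baseline}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        object.__setattr__(self, "motion_events", tuple(tuple(e) for e in self.motion_events))

    def deterministic_series(self, time: np.ndarray) -> np.ndarray:
        """Baseline + drift + motion bumps on the given time grid (no noise)."""
        out = np.full_like(time, float(self.baseline))
        if self.drift is not None:
            out = out + np.asarray(self.drift(time), dtype=float)
        for onset, duration, amplitude in self.motion_events:
            if duration <= 0:
                raise ValueError("motion event duration must be > 0")
            u = (time - onset) / duration
            mask = (u >= 0) & (u <= 1)
            out[mask] += 0.5 * amplitude * (1.0 - np.cos(2.0 * np.pi * u[mask]))
        return out


@dataclass(frozen=True)
class AdcModel:
    """Uniform quantizer emulating the acquisition ADC at the pressure level."""

    bits: int = 24
    full_scale_min: float = 0.0
    full_scale_max: float = 240.0

    def __post_init__(self) -> None:
        if not 8 <= self.bits <= 32:
            raise ValueError(f"bits must be in [8, 32], got {self.bits}")
        if self.full_scale_max <= self.full_scale_min:
            raise ValueError("full_scale_max must exceed full_scale_min")

    @property
    def step(self) -> float:
        """Quantization step in mmHg: full-scale range over 2**bits levels."""
        return (self.full_scale_max - self.full_scale_min) / 2**self.bits

    def quantize(self, series: np.ndarray) -> np.ndarray:
        x = np.clip(series, self.full_scale_min, self.full_scale_max)
        k = np.round((x - self.full_scale_min) / self.step)
        return self.full_scale_min + k * self.step


@dataclass(frozen=True)
class DualChannelRecording:
    """Synchronized primary (over-artery) and reference (off-artery) series."""

    time: np.ndarray
    primary: np.ndarray
    reference: np.ndarray
    sample_rate: float
    units: str = "mmHg"

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        primary = np.asarray(self.primary, dtype=float)
        reference = np.asarray(self.reference, dtype=float)
        if not (len(time) == len(primary) == len(reference)):
            raise ValueError("time, primary and reference must have equal length")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if np.isnan(primary).any() or np.isnan(reference).any():
            raise ValueError("recording contains missing samples")
        for name, arr in (("time", time), ("primary", primary), ("reference", reference)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate


def generate_pulse(
    model: PulseWaveModel, duration: float, sample_rate: float
) -> np.ndarray:
    """Sample the harmonic arterial pressure wave on a uniform grid.

    Raises if ``sample_rate`` does not strictly exceed twice the highest
    harmonic frequency (aliasing).
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if sample_rate <= 0:
        raise ValueError(f"sample_rate must be > 0, got {sample_rate}")
    if model.harmonics and sample_rate <= 2.0 * model.max_frequency:
        raise ValueError(
            f"sample_rate {sample_rate} Hz is at or below the Nyquist rate of the "
            f"highest harmonic ({model.max_frequency} Hz): aliasing"
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    return evaluate_pulse(model, t)


def evaluate_pulse(model: PulseWaveModel, t: np.ndarray) -> np.ndarray:
    """Evaluate the harmonic pulse model at arbitrary times (seconds)."""
    out = np.full_like(np.asarray(t, dtype=float), model.mean_pressure)
    for h in model.harmonics:
        out = out + h.amplitude * np.sin(2.0 * np.pi * h.frequency * t + h.phase)
    return out


def apply_attenuation(series: np.ndarray, tissue: TissueModel | float) -> np.ndarray:
    """Attenuate a pressure series through tissue: pointwise `* exp(-alpha)`.

    DC and AC components are scaled identically (the lumped model treats the
    whole transmitted wave as attenuated).  Negative alpha (amplification) is
    outside the model and rejected.
    """
    alpha = tissue.alpha if isinstance(tissue, TissueModel) else float(tissue)
    if not math.isfinite(alpha) or alpha < 0:
        raise ValueError(f"alpha must be finite and >= 0, got {alpha}")
    return np.asarray(series, dtype=float) * math.exp(-alpha)


def mechanical_impedance(tissue: TissueModel) -> float:
    """Qualitative tissue impedance product Z = E * rho * c * d.

    Exposed for exploration only; the estimation path never uses it.  The
    product is dimensionally nonstandard for a mechanical impedance and is
    computed literally.
    """
    fields = {
        "elastic_modulus": tissue.elastic_modulus,
        "density": tissue.density,
        "sound_speed": tissue.sound_speed,
        "effective_depth": tissue.effective_depth,
    }
    missing = [k for k, v in fields.items() if v is None]
    if missing:
        raise ValueError(f"mechanical_impedance requires {', '.join(missing)}")
    return (
        tissue.elastic_modulus * tissue.density * tissue.sound_speed * tissue.effective_depth
    )


def synthesize_recording(
    pulse: PulseWaveModel,
    tissue: TissueModel,
    contact: ContactPressureProfile,
    adc: AdcModel | None,
    duration: float,
    sample_rate: float,
    seed: int,
    quantize: bool = True,
) -> DualChannelRecording:
    """Compose a synthetic dual-channel recording.

    primary = attenuated pulse + contact (baseline/drift/motion) + noise_1;
    reference = contact + noise_2.  Drift and motion are shared across
    channels, noise draws are independent.  With ``adc`` given and
    ``quantize`` true, both channels are snapped to the ADC grid.
    Identical seeds give identical output.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be strictly positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    arterial = evaluate_pulse(pulse, t)
    contact_det = contact.deterministic_series(t)
    primary = apply_attenuation(arterial, tissue) + contact_det
    reference = contact_det.copy()
    if contact.noise_sd > 0:
        primary = primary + rng.normal(0.0, contact.noise_sd, n)
        reference = reference + rng.normal(0.0, contact.noise_sd, n)
    if adc is not None and quantize:
        primary = adc.quantize(primary)
        reference = adc.quantize(reference)
    return DualChannelRecording(t, primary, reference, sample_rate)


def pulse_extrema(model: PulseWaveModel, oversample: int = 4096) -> tuple[float, float]:
    """(systolic, diastolic) = (max, min) of the continuous pulse over one period.

    Evaluated on a dense grid over one fundamental period with parabolic
    refinement of the extremum; for a constant model returns the mean twice.
    """
    if not model.harmonics:
        return model.mean_pressure, model.mean_pressure
    period = 1.0 / model.harmonics[0].frequency
    t = np.linspace(0.0, period, oversample, endpoint=False)
    p = evaluate_pulse(model, t)

    def _refine(idx: int, sign: float) -> float:
        y0, y1, y2 = p[idx - 1], p[idx], p[(idx + 1) % len(p)]
        denom = y0 - 2 * y1 + y2
        if denom == 0:
            return y1
        return y1 - 0.125 * (y0 - y2) ** 2 / denom

    return _refine(int(np.argmax(p)), +1.0), _refine(int(np.argmin(p)), -1.0)


def pulse_peak_phase(model: PulseWaveModel, oversample: int = 4096) -> float:
    """Time (s) of the systolic peak within the first fundamental period."""
    if not model.harmonics:
        return 0.0
    period = 1.0 / model.harmonics[0].frequency
    t = np.linspace(0.0, period, oversample, endpoint=False)
    return float(t[np.argmax(evaluate_pulse(model, t))])


def sample_subject(
    rng: np.random.Generator,
    n_harmonics: int = 3,
) -> PulseWaveModel:
    """Draw a plausible resting-adult arterial pulse model.

    Mean arterial pressure U(85, 110) mmHg, pulse fundamental from heart
    rates U(55, 90) bpm, and harmonic amplitudes decaying roughly like a
    radial pulse (second and third harmonics at ~40% and ~15% of the first),
    jittered per subject.  Phases are drawn uniformly for the upper
    harmonics; the fundamental phase is zero so beats start near the foot.
    """
    mean = rng.uniform(85.0, 110.0)
    f0 = rng.uniform(55.0, 90.0) / 60.0
    a1 = rng.uniform(16.0, 24.0)
    ratios = [1.0, 0.4 * rng.uniform(0.8, 1.2), 0.15 * rng.uniform(0.8, 1.2)]
    harmonics = []
    for k in range(n_harmonics):
        phase = 0.0 if k == 0 else rng.uniform(-np.pi / 3, np.pi / 3)
        harmonics.append(Harmonic(a1 * ratios[k], (k + 1) * f0, phase))
    return PulseWaveModel(mean_pressure=mean, harmonics=tuple(harmonics))
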