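"""Simulation-study harness: cohorts of synthetic subjects end to end.

One "subject" is a drawn arterial pulse model worn at a given contact
pressure; the study synthesizes the dual-channel recording, calibrates the
monitor against ground-truth beat references over an opening baseline
segment, estimates beat-to-beat BP over the whole recording, and scores the
errors against the generator's truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import CuffLessBloodPressureMonitor
from .simulate import (
    AdcModel,
    ContactPressureProfile,
    DualChannelRecording,
    PulseWaveModel,
    TissueModel,
    pulse_extrema,
    pulse_peak_phase,
    sample_subject,
    synthesize_recording,
)

__all__ = ["SubjectResult", "run_subject", "cohort_errors", "default_drift"]


def default_drift(t: np.ndarray) -> np.ndarray:
    """Slow contact-pressure drift: 1 mmHg/min linear + 2 mmHg, 30 s sway."""
    return t / 60.0 + 2.0 * np.sin(2.0 * np.pi * t / 30.0)


@dataclass(frozen=True)
class SubjectResult:
    pulse: PulseWaveModel
    true_sbp: float
    true_dbp: float
    sbp_errors: np.ndarray
    dbp_errors: np.ndarray

    @property
    def sbp_mae(self) -> float:
        return float(np.mean(np.abs(self.sbp_errors)))

    @property
    def dbp_mae(self) -> float:
        return float(np.mean(np.abs(self.dbp_errors)))


def run_subject(
    seed: int,
    noise_sd: float = 0.5,
    drift: bool = True,
    alpha: float = 4.44,
    contact_baseline: float = 40.0,
    duration: float = 60.0,
    sample_rate: float = 100.0,
    calibration_duration: float = 30.0,
    monitor: CuffLessBloodPressureMonitor | None = None,
    quantize: bool = True,
) -> SubjectResult:
    """Simulate one subject and score the monitor against generator truth.

    The reference beat series handed to calibration is the generator's own
    per-beat truth (standing in for a beat-to-beat reference monitor).
    """
    rng = np.random.default_rng(seed)
    pulse = sample_subject(rng)
    contact = ContactPressureProfile(
        baseline=contact_baseline,
        drift=default_drift if drift else None,
        noise_sd=noise_sd,
    )
    rec = synthesize_recording(
        pulse, TissueModel(alpha=alpha), contact, AdcModel(),
        duration, sample_rate, seed, quantize=quantize,
    )
    true_sbp, true_dbp = pulse_extrema(pulse)
    period = 1.0 / pulse.harmonics[0].frequency
    beat_times = np.arange(pulse_peak_phase(pulse), duration, period)
    reference = pd.DataFrame(
        {"time_s": beat_times, "sbp_mmHg": true_sbp, "dbp_mmHg": true_dbp}
    )
    if monitor is None:
        monitor = CuffLessBloodPressureMonitor(alpha=alpha)
    n_cal = int(calibration_duration * sample_rate)
    cal_rec = DualChannelRecording(
        rec.time[:n_cal], rec.primary[:n_cal], rec.reference[:n_cal], sample_rate
    )
    monitor.fit(cal_rec, reference[reference["time_s"] <= calibration_duration])
    out = monitor.predict(rec)
    return SubjectResult(
        pulse=pulse,
        true_sbp=true_sbp,
        true_dbp=true_dbp,
        sbp_errors=out["sbp_mmHg"].to_numpy() - true_sbp,
        dbp_errors=out["dbp_mmHg"].to_numpy() - true_dbp,
    )


def cohort_errors(
    n_subjects: int = 10, seed: int = 0, **subject_kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-beat (SBP, DBP) errors across a seeded subject cohort."""
    base = np.random.default_rng(seed).integers(0, 2**31 - 1)
    sbp, dbp = [], []
    for k in range(n_subjects):
        res = run_subject(seed=int((base + k) % 2**31), **subject_kwargs)
        sbp.append(res.sbp_errors)
        dbp.append(res.dbp_errors)
    return np.concatenate(sbp), np.concatenate(dbp)
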