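"""Beat-to-beat blood pressure from a dual-channel recording.

Processing chain (both channels in mmHg):

1. zero-phase Butterworth low-pass on both channels (default 10 Hz, order 4);
2. centered moving-average smoothing of the reference channel (default 1 s)
   so it tracks contact-pressure drift but not sample noise;
3. arterial isolation: (primary - smoothed reference) * exp(alpha), which
   removes the common contact pressure and undoes tissue attenuation;
4. beat detection: prominence-based peak picking with a refractory interval
   on a more heavily smoothed copy, feet as the pre-peak minima;
5. per-beat peak/foot refinement by an affine (scale + offset) fit of each
   beat against the recording's ensemble mean-beat template, followed by a
   short centered moving average across beats.  Un-attenuation multiplies
   sensor noise by exp(alpha) (~90 at typical wrist coupling), so a peak
   read from a single sample is hopeless at realistic noise; the template
   fit spends every sample of the beat on two parameters and is exact in
   the noiseless limit, so clean signals pass through untouched;
6. affine calibration maps peak -> SBP and foot -> DBP, fitted against a
   reference monitor over a calibration segment.

``CuffLessBloodPressureMonitor`` wraps the chain as a sklearn-style
estimator: fit() learns the BP calibration maps against a reference
beat series, predict() emits the per-beat SBP/DBP table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .attenuation import AttenuationRegression
from .simulate import DualChannelRecording

__all__ = [
    "FilterSpec",
    "BeatSeries",
    "AffineMap",
    "BpCalibrationMap",
    "BpEstimate",
    "lowpass_filter",
    "smooth_reference",
    "isolate_arterial",
    "detect_beats",
    "refine_beats_template",
    "fit_bp_calibration",
    "estimate_bp",
    "cross_correlation_lag",
    "pair_nearest",
    "CuffLessBloodPressureMonitor",
]

# physiological plausibility bounds; estimates outside are flagged, not dropped
SBP_BOUNDS = (60.0, 260.0)
DBP_BOUNDS = (30.0, 150.0)

# assumed heart-rate band, 40-180 bpm
MIN_BEAT_INTERVAL_S = 60.0 / 180.0


@dataclass(frozen=True)
class FilterSpec:
    """Front-end filtering parameters.

    lowpass_cutoff: Hz, applied zero-phase to both channels (default 10 Hz,
    preserving pulse morphology while removing motion noise);
    filter_order: Butterworth order (effective order doubles under
    forward-backward application);
    reference_smoothing_window: seconds of centered moving average on the
    reference channel (default 1 s: longer than a beat, so pulse leakage and
    sample noise are suppressed while drift is tracked).
    """

    lowpass_cutoff: float = 10.0
    filter_order: int = 4
    reference_smoothing_window: float = 1.0

    def __post_init__(self) -> None:
        if self.lowpass_cutoff <= 0:
            raise ValueError("lowpass_cutoff must be > 0")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.reference_smoothing_window <= 0:
            raise ValueError("reference_smoothing_window must be > 0")


@dataclass(frozen=True)
class BeatSeries:
    """Per-beat landmarks: systolic peak time/value and diastolic foot value."""

    beat_times: np.ndarray
    peak_values: np.ndarray
    foot_values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.beat_times, dtype=float)
        peaks = np.asarray(self.peak_values, dtype=float)
        feet = np.asarray(self.foot_values, dtype=float)
        if not (len(times) == len(peaks) == len(feet)):
            raise ValueError("beat arrays must have equal length")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(peaks <= feet):
            raise ValueError("each beat's peak must exceed its foot")
        for name, arr in (
            ("beat_times", times),
            ("peak_values", peaks),
            ("foot_values", feet),
        ):
            object.__setattr__(self, name, arr)

    @property
    def ac_amplitudes(self) -> np.ndarray:
        """Peak minus foot, exactly."""
        return self.peak_values - self.foot_values

    def __len__(self) -> int:
        return len(self.beat_times)


def _empty_beats() -> BeatSeries:
    z = np.array([])
    return BeatSeries(z, z, z)


def lowpass_filter(series: np.ndarray, sample_rate: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth low-pass (filtfilt); unity DC gain, same length."""
    x = np.asarray(series, dtype=float)
    nyquist = sample_rate / 2.0
    if spec.lowpass_cutoff >= nyquist:
        raise ValueError(
            f"cutoff {spec.lowpass_cutoff} Hz is at or above Nyquist ({nyquist} Hz)"
        )
    sos = signal.butter(spec.filter_order, spec.lowpass_cutoff, fs=sample_rate, output="sos")
    padlen = 3 * (2 * spec.filter_order + 1)
    if len(x) <= padlen:
        raise ValueError(
            f"series of length {len(x)} too short for order-{spec.filter_order} "
            "zero-phase filtering"
        )
    return signal.sosfiltfilt(sos, x)


def smooth_reference(series: np.ndarray, sample_rate: float, window_s: float) -> np.ndarray:
    """Centered moving average; edges use a shrinking window, length preserved.

    The window is forced to an odd sample count so the average is symmetric
    (an even window would shift a ramp by half a sample).  Constants pass
    through exactly, which is what makes the pipeline's common-mode
    rejection exact for shared offsets.
    """
    x = np.asarray(series, dtype=float)
    w = int(round(window_s * sample_rate))
    if w < 2:
        raise ValueError("smoothing window must span at least 2 samples")
    if w % 2 == 0:
        w += 1
    if w > len(x):
        raise ValueError(f"window of {w} samples exceeds series length {len(x)}")
    return pd.Series(x).rolling(w, center=True, min_periods=1).mean().to_numpy()


def isolate_arterial(
    primary: np.ndarray, smoothed_reference: np.ndarray, alpha: float
) -> np.ndarray:
    """Arterial wave: (primary - smoothed reference) * exp(alpha), elementwise."""
    p = np.asarray(primary, dtype=float)
    r = np.asarray(smoothed_reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"length mismatch: primary {p.shape} vs reference {r.shape}")
    if not math.isfinite(alpha) or alpha < 0:
        raise ValueError(f"alpha must be finite and >= 0, got {alpha}")
    return (p - r) * math.exp(alpha)


def estimate_fundamental(
    series: np.ndarray, sample_rate: float, band: tuple[float, float] = (40 / 60, 180 / 60)
) -> float | None:
    """Heart-rate fundamental (Hz) as the strongest Welch peak in 40-180 bpm.

    Returns None when the series carries no measurable power in the band.
    """
    x = np.asarray(series, dtype=float)
    nperseg = min(len(x), int(20 * sample_rate))
    freqs, psd = signal.welch(x - x.mean(), fs=sample_rate, nperseg=nperseg)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any() or not np.any(psd[keep] > 0):
        return None
    return float(freqs[keep][np.argmax(psd[keep])])


def detect_beats(
    arterial: np.ndarray,
    sample_rate: float,
    detection_cutoff: float = 5.0,
    prominence_fraction: float = 0.3,
) -> BeatSeries:
    """Locate one systolic peak and diastolic foot per cardiac cycle.

    Timing comes from a narrowband copy of the signal: the heart-rate
    fundamental is estimated from the Welch spectrum (40-180 bpm band) and
    peaks are picked on a zero-phase band-pass around it (0.6-1.6 f0), with
    a refractory interval and a prominence floor at ``prominence_fraction``
    of the narrowband robust amplitude.  Narrowband timing is what keeps
    beat placement stable when un-attenuation has amplified sensor noise;
    harmonics and noise outside the fundamental's neighbourhood cannot
    displace a peak by a large fraction of a cycle.  Peak/foot *values* are
    then read from the unsmoothed input (peak = local max near the detected
    peak, foot = minimum over the preceding inter-peak interval).  A series
    with no oscillation yields an empty BeatSeries with a warning, not an
    error.  ``detection_cutoff`` caps the upper band edge.
    """
    x = np.asarray(arterial, dtype=float)
    min_len = int(MIN_BEAT_INTERVAL_S * sample_rate) + 2
    if len(x) < min_len:
        raise ValueError("series shorter than one expected beat")
    lp_spec = FilterSpec(
        lowpass_cutoff=min(detection_cutoff, 0.45 * sample_rate), filter_order=2
    )
    smoothed = lowpass_filter(x, sample_rate, lp_spec)
    robust_amp = float(np.percentile(smoothed, 95) - np.percentile(smoothed, 5))
    if robust_amp <= 0:
        warnings.warn("no oscillation above prominence floor; empty beat series")
        return _empty_beats()
    f0 = estimate_fundamental(smoothed, sample_rate)
    if f0 is None:
        warnings.warn("no cardiac fundamental in 40-180 bpm band; empty beat series")
        return _empty_beats()
    lo = 0.6 * f0
    hi = min(1.6 * f0, detection_cutoff, 0.45 * sample_rate)
    if hi <= lo:
        det = smoothed
    else:
        sos = signal.butter(2, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
        det = signal.sosfiltfilt(sos, x)
    det_amp = float(np.percentile(det, 95) - np.percentile(det, 5))
    distance = max(int(max(MIN_BEAT_INTERVAL_S, 0.6 / f0) * sample_rate), 1)
    peaks, _ = signal.find_peaks(
        det, distance=distance, prominence=prominence_fraction * det_amp
    )
    if len(peaks) == 0:
        warnings.warn("no peaks found above prominence floor; empty beat series")
        return _empty_beats()
    if len(peaks) >= 2:
        # an opening peak without a full preceding cycle has no readable foot
        interval = float(np.median(np.diff(peaks)))
        if peaks[0] < 0.75 * interval:
            peaks = peaks[1:]

    # read values off the unsmoothed series: peak = local max near the detected
    # location (the narrowband peak sits at a fixed phase offset from the true
    # systolic peak), foot = min over the preceding inter-peak interval
    half = max(int(min(0.25 / f0, 0.3) * sample_rate), 1)
    times, peak_vals, foot_vals = [], [], []
    for j, p in enumerate(peaks):
        lo = max(p - half, 0)
        hi = min(p + half + 1, len(x))
        k = lo + int(np.argmax(x[lo:hi]))
        # search window for the foot: previous detected peak, or up to 1.5 s back
        prev = int(peaks[j - 1]) if j > 0 else max(p - int(sample_rate * 1.5), 0)
        foot = float(np.min(x[prev:k])) if k > prev else float(x[k])
        if x[k] <= foot:
            continue  # degenerate cycle, skip
        times.append(k / sample_rate)
        peak_vals.append(float(x[k]))
        foot_vals.append(foot)
    if not times:
        warnings.warn("no valid peak/foot pairs; empty beat series")
        return _empty_beats()
    return BeatSeries(np.array(times), np.array(peak_vals), np.array(foot_vals))


def _parabolic_extreme(vec: np.ndarray, idx: int) -> float:
    if idx == 0 or idx == len(vec) - 1:
        return float(vec[idx])
    y0, y1, y2 = vec[idx - 1], vec[idx], vec[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(y1)
    return float(y1 - 0.125 * (y0 - y2) ** 2 / denom)


@dataclass(frozen=True)
class BeatTemplate:
    """Frozen ensemble mean beat: shape on a phase grid one period wide.

    Freezing the template at calibration time and reusing it for later
    estimation keeps the morphology reference consistent, so template noise
    cancels against the fitted BP offsets instead of re-entering as bias.
    """

    shape: np.ndarray
    period: float
    phase_grid: np.ndarray


def _smooth_beat_times(times: np.ndarray, window: int = 9) -> np.ndarray:
    """Suppress white detection jitter with a local linear fit of time vs index.

    Cardiac beats are quasi-periodic: over a handful of beats the peak times
    are well modelled as linear in beat number, so a centered first-order
    Savitzky-Golay fit removes most single-beat timing noise while tracking
    slow heart-rate changes exactly (it reproduces any locally linear grid).
    Falls back to the raw times if smoothing breaks monotonicity.
    """
    n = len(times)
    if n < 3 or window <= 1:
        return times
    w = min(window, n if n % 2 == 1 else n - 1)
    if w % 2 == 0:
        w -= 1
    if w < 3:
        return times
    smoothed = signal.savgol_filter(times, w, polyorder=1, mode="interp")
    if np.any(np.diff(smoothed) <= 0):
        return times
    return smoothed


def refine_beats_template(
    arterial: np.ndarray,
    sample_rate: float,
    beats: BeatSeries,
    phase_points: int = 128,
    time_smoothing_beats: int = 9,
    template: "BeatTemplate | None" = None,
) -> BeatSeries:
    refined, _ = refine_beats_template_with_template(
        arterial, sample_rate, beats, phase_points, time_smoothing_beats, template
    )
    return refined


def refine_beats_template_with_template(
    arterial: np.ndarray,
    sample_rate: float,
    beats: BeatSeries,
    phase_points: int = 128,
    time_smoothing_beats: int = 9,
    template: "BeatTemplate | None" = None,
) -> tuple[BeatSeries, "BeatTemplate | None"]:
    """Re-estimate per-beat peak/foot via an affine fit to the mean beat.

    Detected beat times are first regularized with a local linear fit
    (quasi-periodicity prior; see :func:`_smooth_beat_times`).  Each beat is
    then resampled onto a common phase grid (one median beat period wide,
    centered on its regularized peak time); the ensemble mean over beats is
    the template, and each beat is regressed as ``c_k + a_k * template``;
    the refined peak/foot are ``c_k + a_k * max/min(template)`` with
    parabolic refinement of the template extremes.  For identical noiseless
    beats the residual is zero and the refinement is exact; under noise the
    two-parameter fit averages the whole beat instead of trusting single
    samples.  Beats whose window partially leaves the recording are fitted
    over the covered part.
    """
    x = np.asarray(arterial, dtype=float)
    if len(beats) < 3:
        return beats, template
    aligned_times = _smooth_beat_times(beats.beat_times, time_smoothing_beats)
    if template is not None:
        period = template.period
        u = template.phase_grid
    else:
        period = float(np.median(np.diff(aligned_times)))
        u = (np.arange(phase_points) / phase_points - 0.5) * period
    t_axis = np.arange(len(x)) / sample_rate
    t_max = t_axis[-1]

    def _row(tb: float) -> tuple[np.ndarray, np.ndarray]:
        tt = tb + u
        mask = (tt >= 0.0) & (tt <= t_max)
        return np.interp(tt[mask], t_axis, x), mask

    if template is None:
        full = [
            _row(tb)[0]
            for tb in aligned_times
            if tb + u[0] >= 0.0 and tb + u[-1] <= t_max
        ]
        if len(full) < 3:
            return beats, None
        template = BeatTemplate(
            shape=np.mean(np.stack(full), axis=0), period=period, phase_grid=u
        )
    s = template.shape - template.shape.mean()
    s_max = _parabolic_extreme(s, int(np.argmax(s)))
    s_min = _parabolic_extreme(s, int(np.argmin(s)))

    peak_vals = beats.peak_values.copy()
    foot_vals = beats.foot_values.copy()
    for i, tb in enumerate(aligned_times):
        row, mask = _row(tb)
        if mask.sum() < phase_points // 2:
            continue
        sm = s[mask]
        sm_c = sm - sm.mean()
        ss = float(np.dot(sm_c, sm_c))
        if ss <= 0:
            continue
        a = float(np.dot(row - row.mean(), sm_c) / ss)
        c = float(row.mean() - a * sm.mean())
        pk, ft = c + a * s_max, c + a * s_min
        if pk > ft:
            peak_vals[i], foot_vals[i] = pk, ft
    return BeatSeries(beats.beat_times, peak_vals, foot_vals), template


def _centered_mean(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(values) == 0:
        return values
    if window % 2 == 0:
        window += 1
    return pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()


@dataclass(frozen=True)
class AffineMap:
    gain: float
    offset: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.gain * np.asarray(x, dtype=float) + self.offset


@dataclass(frozen=True)
class BpCalibrationMap:
    """Affine maps from waveform landmarks to BP: peak -> SBP, foot -> DBP."""

    systolic: AffineMap
    diastolic: AffineMap
    source: str = ""

    def __post_init__(self) -> None:
        for m in (self.systolic, self.diastolic):
            if not (math.isfinite(m.gain) and math.isfinite(m.offset)):
                raise ValueError("calibration map coefficients must be finite")


def fit_bp_calibration(
    beats: BeatSeries,
    reference_sbp,
    reference_dbp,
    source: str = "",
    min_spread: float = 1e-9,
) -> BpCalibrationMap:
    """Least-squares affine maps peak->SBP and foot->DBP over a calibration segment.

    ``reference_sbp``/``reference_dbp`` must already be time-matched to the
    beats (same count).  With fewer than two distinct landmark values the
    affine fit is rank-deficient and an offset-only map (unit gain) is used.
    """
    sbp = np.asarray(reference_sbp, dtype=float).reshape(-1)
    dbp = np.asarray(reference_dbp, dtype=float).reshape(-1)
    if len(beats) == 0 or len(sbp) == 0:
        raise ValueError("empty overlap between beats and reference values")
    if not (len(beats) == len(sbp) == len(dbp)):
        raise ValueError(
            f"beats ({len(beats)}) and reference values ({len(sbp)}, {len(dbp)}) "
            "must be time-matched to the same count"
        )

    def _fit(x: np.ndarray, y: np.ndarray) -> AffineMap:
        if len(x) < 2 or float(np.ptp(x)) <= min_spread or float(np.ptp(y)) <= min_spread:
            return AffineMap(gain=1.0, offset=float(np.mean(y - x)))
        gain, offset = np.polyfit(x, y, 1)
        return AffineMap(gain=float(gain), offset=float(offset))

    return BpCalibrationMap(
        systolic=_fit(beats.peak_values, sbp),
        diastolic=_fit(beats.foot_values, dbp),
        source=source,
    )


@dataclass(frozen=True)
class BpEstimate:
    """Per-beat SBP/DBP with plausibility flags ('ok' or a named violation)."""

    beat_times: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    flags: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("beat_times", "sbp", "dbp"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def __len__(self) -> int:
        return len(self.beat_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_time_s": self.beat_times,
                "sbp_mmHg": self.sbp,
                "dbp_mmHg": self.dbp,
                "flag": list(self.flags),
            }
        )


def estimate_bp(
    recording: DualChannelRecording,
    spec: FilterSpec,
    alpha: float,
    cal_map: BpCalibrationMap,
    detection_cutoff: float = 5.0,
    refine: str = "template",
    beat_average: int = 5,
    template: BeatTemplate | None = None,
) -> BpEstimate:
    """Full chain: lowpass -> smooth -> isolate -> detect -> refine -> map.

    ``beat_average`` is a centered moving average (in beats) applied to the
    landmark series before mapping; 5 beats (~4 s) suppresses amplified
    sensor noise while tracking physiological BP trends.  Estimates with
    SBP <= DBP or outside the 60-260 / 30-150 mmHg plausibility bounds are
    flagged, never silently dropped.
    """
    beats, _ = _landmarks(
        recording, spec, alpha, detection_cutoff, refine, beat_average, template
    )
    if len(beats) == 0:
        return BpEstimate(np.array([]), np.array([]), np.array([]), ())
    sbp = cal_map.systolic(beats.peak_values)
    dbp = cal_map.diastolic(beats.foot_values)
    flags = []
    for s, d in zip(sbp, dbp):
        if s <= d:
            flags.append("sbp_not_above_dbp")
        elif not (SBP_BOUNDS[0] <= s <= SBP_BOUNDS[1]) or not (
            DBP_BOUNDS[0] <= d <= DBP_BOUNDS[1]
        ):
            flags.append("out_of_physiological_range")
        else:
            flags.append("ok")
    return BpEstimate(beats.beat_times, sbp, dbp, tuple(flags))


def _landmarks(
    recording: DualChannelRecording,
    spec: FilterSpec,
    alpha: float,
    detection_cutoff: float,
    refine: str,
    beat_average: int,
    template: BeatTemplate | None = None,
) -> tuple[BeatSeries, BeatTemplate | None]:
    """Shared front half of the chain: filtered, isolated, detected, refined."""
    fs = recording.sample_rate
    primary = lowpass_filter(recording.primary, fs, spec)
    reference = lowpass_filter(recording.reference, fs, spec)
    smoothed = smooth_reference(reference, fs, spec.reference_smoothing_window)
    arterial = isolate_arterial(primary, smoothed, alpha)
    beats = detect_beats(arterial, fs, detection_cutoff=detection_cutoff)
    if len(beats) == 0:
        return beats, template
    if refine == "template":
        beats, template = refine_beats_template_with_template(
            arterial, fs, beats, template=template
        )
    elif refine != "none":
        raise ValueError(f"unknown refine mode {refine!r}")
    if beat_average > 1 and len(beats) > 1:
        beats = BeatSeries(
            beats.beat_times,
            _centered_mean(beats.peak_values, beat_average),
            _centered_mean(beats.foot_values, beat_average),
        )
    return beats, template


def cross_correlation_lag(
    device: np.ndarray, reference: np.ndarray, sample_rate: float, max_lag_s: float = 5.0
) -> float:
    """Lag (s) by which ``device`` trails ``reference``, via cross-correlation.

    Models the protocol's synchronization tap; positive lag means the device
    series must be shifted earlier to align.  A manual override is simply
    passing your own lag downstream instead of calling this.
    """
    a = np.asarray(device, dtype=float)
    b = np.asarray(reference, dtype=float)
    n = min(len(a), len(b))
    a, b = a[:n] - a[:n].mean(), b[:n] - b[:n].mean()
    max_lag = int(max_lag_s * sample_rate)
    corr = signal.correlate(a, b, mode="full")
    lags = signal.correlation_lags(n, n, mode="full")
    keep = np.abs(lags) <= max_lag
    return float(lags[keep][np.argmax(corr[keep])] / sample_rate)


def pair_nearest(
    beat_times: np.ndarray,
    ref_times: np.ndarray,
    max_gap_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour pairing of device beats to reference beats.

    Returns (device_idx, ref_idx) for pairs within ``max_gap_s``.  Each
    device beat takes its nearest reference beat; unmatched beats drop out.
    """
    bt = np.asarray(beat_times, dtype=float)
    rt = np.asarray(ref_times, dtype=float)
    if len(bt) == 0 or len(rt) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    pos = np.searchsorted(rt, bt)
    dev_idx, ref_idx = [], []
    for i, (t, p) in enumerate(zip(bt, pos)):
        candidates = [c for c in (p - 1, p) if 0 <= c < len(rt)]
        if not candidates:
            continue
        best = min(candidates, key=lambda c: abs(rt[c] - t))
        if abs(rt[best] - t) <= max_gap_s:
            dev_idx.append(i)
            ref_idx.append(best)
    return np.array(dev_idx, dtype=int), np.array(ref_idx, dtype=int)


class CuffLessBloodPressureMonitor(BaseEstimator):
    """Sklearn-style estimator wrapping the full dual-channel BP pipeline.

    Parameters mirror :class:`FilterSpec` plus the attenuation source:
    either a fixed ``alpha`` or an ``attenuation_model``
    (:class:`~gaugebp.attenuation.AttenuationRegression`), in which case
    alpha is predicted at the recording's measured contact pressure (mean of
    the smoothed reference channel).

    fit(recording, reference) learns the peak->SBP / foot->DBP calibration
    maps from a reference beat table (DataFrame with columns ``time_s``,
    ``sbp_mmHg``, ``dbp_mmHg``), pairing beats to reference rows by nearest
    time.  predict(recording) returns the per-beat estimate DataFrame.
    """

    def __init__(
        self,
        lowpass_cutoff: float = 10.0,
        filter_order: int = 4,
        reference_smoothing_window: float = 1.0,
        detection_cutoff: float = 5.0,
        refine: str = "template",
        beat_average: int = 5,
        alpha: float | None = None,
        attenuation_model: AttenuationRegression | None = None,
        max_pair_gap_s: float = 1.0,
    ) -> None:
        self.lowpass_cutoff = lowpass_cutoff
        self.filter_order = filter_order
        self.reference_smoothing_window = reference_smoothing_window
        self.detection_cutoff = detection_cutoff
        self.refine = refine
        self.beat_average = beat_average
        self.alpha = alpha
        self.attenuation_model = attenuation_model
        self.max_pair_gap_s = max_pair_gap_s

    def _spec(self) -> FilterSpec:
        return FilterSpec(
            lowpass_cutoff=self.lowpass_cutoff,
            filter_order=self.filter_order,
            reference_smoothing_window=self.reference_smoothing_window,
        )

    def _resolve_alpha(self, recording: DualChannelRecording) -> float:
        if self.alpha is not None:
            return float(self.alpha)
        if self.attenuation_model is None:
            raise ValueError("provide either alpha or a fitted attenuation_model")
        contact = float(np.mean(recording.reference))
        return self.attenuation_model.predict_one(contact)

    def fit(self, recording: DualChannelRecording, reference: pd.DataFrame):
        for col in ("time_s", "sbp_mmHg", "dbp_mmHg"):
            if col not in reference.columns:
                raise ValueError(f"reference table missing column {col!r}")
        alpha = self._resolve_alpha(recording)
        beats, template = _landmarks(
            recording, self._spec(), alpha, self.detection_cutoff, self.refine,
            self.beat_average,
        )
        dev_idx, ref_idx = pair_nearest(
            beats.beat_times, reference["time_s"].to_numpy(), self.max_pair_gap_s
        )
        if len(dev_idx) == 0:
            raise ValueError("no beats could be paired with the reference series")
        matched = BeatSeries(
            beats.beat_times[dev_idx],
            beats.peak_values[dev_idx],
            beats.foot_values[dev_idx],
        )
        self.calibration_map_ = fit_bp_calibration(
            matched,
            reference["sbp_mmHg"].to_numpy()[ref_idx],
            reference["dbp_mmHg"].to_numpy()[ref_idx],
            source="reference monitor (nearest-beat pairing)",
        )
        self.alpha_ = alpha
        self.n_calibration_beats_ = int(len(dev_idx))
        self.template_ = template
        return self

    def predict(self, recording: DualChannelRecording) -> pd.DataFrame:
        check_is_fitted(self, "calibration_map_")
        est = estimate_bp(
            recording,
            self._spec(),
            self._resolve_alpha(recording),
            self.calibration_map_,
            detection_cutoff=self.detection_cutoff,
            refine=self.refine,
            beat_average=self.beat_average,
            template=self.template_,
        )
        return est.to_frame()
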