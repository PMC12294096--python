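"""Weight-based transducer calibration.

Known masses placed on the transducer's elliptical contact face exert a
pressure P = m g / (pi (a/2)(b/2)) / 133.3 mmHg (mass in grams, axes in mm;
unit conversions internal; 133.3 Pa per mmHg, as printed on the device's
datasheet arithmetic).  An ordinary least-squares line then maps raw ADC
counts to mmHg.  ``AdcCalibration`` is the sklearn-style estimator that owns
that fit; ``daily_check`` compares a fitted calibration against fresh check
weights to flag drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .simulate import AdcModel

PA_PER_MMHG = 133.3  # conversion constant used throughout the calibration chain
STANDARD_GRAVITY = 9.81  # m/s^2

__all__ = [
    "EllipseGeometry",
    "CalibrationWeightSet",
    "AdcCalibration",
    "DailyCheckReport",
    "weight_to_pressure",
    "fit_adc_calibration",
    "theoretical_resolution",
    "daily_check",
]


@dataclass(frozen=True)
class EllipseGeometry:
    """Elliptical transducer contact face; axes are full lengths in mm.

    ``contact_area_mm2`` overrides the computed area when a directly measured
    value is available (the device's measured face is 62.53 mm^2, which
    differs in the last digit from pi*(11.89/2)*(6.7/2) = 62.57 mm^2).
    """

    major_axis_mm: float = 11.89
    minor_axis_mm: float = 6.7
    contact_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.minor_axis_mm <= 0 or self.major_axis_mm < self.minor_axis_mm:
            raise ValueError(
                "require major_axis_mm >= minor_axis_mm > 0, got "
                f"({self.major_axis_mm}, {self.minor_axis_mm})"
            )
        if self.contact_area_mm2 is not None and self.contact_area_mm2 <= 0:
            raise ValueError("contact_area_mm2 must be > 0")

    @property
    def area_mm2(self) -> float:
        if self.contact_area_mm2 is not None:
            return self.contact_area_mm2
        return math.pi * (self.major_axis_mm / 2.0) * (self.minor_axis_mm / 2.0)


@dataclass(frozen=True)
class CalibrationWeightSet:
    """(mass g, ADC counts) pairs from one stacking session."""

    entries: tuple[tuple[float, float], ...]
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        entries = tuple((float(m), float(c)) for m, c in self.entries)
        object.__setattr__(self, "entries", entries)
        masses = [m for m, _ in entries]
        if any(m <= 0 for m in masses):
            raise ValueError("calibration masses must be strictly positive")
        if len(set(masses)) != len(masses):
            raise ValueError("calibration masses must be unique")
        if self.gravity <= 0:
            raise ValueError("gravity must be > 0")

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.entries])

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.entries])


def weight_to_pressure(
    mass_g: float,
    geometry: EllipseGeometry = EllipseGeometry(),
    gravity: float = STANDARD_GRAVITY,
) -> float:
    """Pressure (mmHg) exerted by ``mass_g`` grams on the elliptical face.

    Linear and homogeneous in mass: P = m[kg] * g / area[m^2] / 133.3.
    """
    if mass_g < 0:
        raise ValueError(f"mass must be >= 0, got {mass_g}")
    area_m2 = geometry.area_mm2 * 1e-6
    return (mass_g * 1e-3) * gravity / area_m2 / PA_PER_MMHG


def theoretical_resolution(adc: AdcModel) -> float:
    """Smallest representable pressure change: full-scale range / 2**bits."""
    return adc.step


class AdcCalibration(BaseEstimator, RegressorMixin):
    """OLS line mapping raw ADC counts to mmHg via weight-derived pressures.

    fit(X=counts, y=masses_g) converts each mass to its theoretical pressure
    over the elliptical face and regresses pressure on counts.

    Attributes (after fit): ``slope_`` (mmHg/count), ``intercept_`` (mmHg),
    ``residual_rms_`` (mmHg), ``slope_se_``, ``n_points_``, ``fitted_at_``.
    """

    def __init__(
        self,
        geometry: EllipseGeometry = EllipseGeometry(),
        gravity: float = STANDARD_GRAVITY,
    ) -> None:
        self.geometry = geometry
        self.gravity = gravity

    def fit(self, X, y) -> "AdcCalibration":
        counts = np.asarray(X, dtype=float).reshape(-1)
        masses = np.asarray(y, dtype=float).reshape(-1)
        if counts.shape != masses.shape:
            raise ValueError("counts and masses must have equal length")
        if len(counts) < 2:
            raise ValueError("at least two calibration weights are required")
        if np.ptp(counts) == 0:
            raise ValueError("all ADC readings identical: rank-deficient calibration fit")
        pressures = np.array(
            [weight_to_pressure(m, self.geometry, self.gravity) for m in masses]
        )
        res = stats.linregress(counts, pressures)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.slope_se_ = float(res.stderr)
        predicted = self.slope_ * counts + self.intercept_
        self.residual_rms_ = float(np.sqrt(np.mean((pressures - predicted) ** 2)))
        self.n_points_ = len(counts)
        self.fitted_at_ = datetime.now(timezone.utc).isoformat()
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        counts = np.asarray(X, dtype=float)
        return self.slope_ * counts + self.intercept_

    def to_dict(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "slope_mmHg_per_count": self.slope_,
            "intercept_mmHg": self.intercept_,
            "residual_rms_mmHg": self.residual_rms_,
            "n_points": self.n_points_,
            "geometry": {
                "major_axis_mm": self.geometry.major_axis_mm,
                "minor_axis_mm": self.geometry.minor_axis_mm,
                "contact_area_mm2": self.geometry.contact_area_mm2,
            },
            "gravity_m_s2": self.gravity,
            "fitted_at": self.fitted_at_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdcCalibration":
        g = d.get("geometry", {})
        est = cls(
            geometry=EllipseGeometry(
                g.get("major_axis_mm", 11.89),
                g.get("minor_axis_mm", 6.7),
                g.get("contact_area_mm2"),
            ),
            gravity=d.get("gravity_m_s2", STANDARD_GRAVITY),
        )
        est.slope_ = d["slope_mmHg_per_count"]
        est.intercept_ = d["intercept_mmHg"]
        est.residual_rms_ = d.get("residual_rms_mmHg", 0.0)
        est.n_points_ = d.get("n_points", 0)
        est.fitted_at_ = d.get("fitted_at", "")
        return est


def fit_adc_calibration(
    weights: CalibrationWeightSet,
    geometry: EllipseGeometry = EllipseGeometry(),
) -> AdcCalibration:
    """Fit the counts -> mmHg line from one weight-stacking session."""
    return AdcCalibration(geometry=geometry, gravity=weights.gravity).fit(
        weights.counts, weights.masses
    )


@dataclass(frozen=True)
class DailyCheckReport:
    """Per-weight deviation between calibrated and theoretical pressure."""

    masses_g: tuple[float, ...]
    predicted_mmHg: tuple[float, ...]
    theoretical_mmHg: tuple[float, ...]
    deviations_mmHg: tuple[float, ...]
    tolerance_mmHg: float
    passed: bool

    @property
    def max_abs_deviation(self) -> float:
        return max(abs(d) for d in self.deviations_mmHg)


def daily_check(
    calibration: AdcCalibration,
    check_weights: CalibrationWeightSet,
    tolerance_mmHg: float = 0.5,
) -> DailyCheckReport:
    """Re-apply check weights and flag drift beyond ``tolerance_mmHg``.

    The default tolerance (0.5 mmHg) sits an order of magnitude below
    clinically relevant BP error.
    """
    check_is_fitted(calibration, "slope_")
    if len(check_weights.entries) == 0:
        raise ValueError("check weight set is empty")
    predicted = calibration.predict(check_weights.counts)
    theoretical = np.array(
        [
            weight_to_pressure(m, calibration.geometry, check_weights.gravity)
            for m in check_weights.masses
        ]
    )
    deviations = predicted - theoretical
    return DailyCheckReport(
        masses_g=tuple(check_weights.masses),
        predicted_mmHg=tuple(predicted),
        theoretical_mmHg=tuple(theoretical),
        deviations_mmHg=tuple(deviations),
        tolerance_mmHg=tolerance_mmHg,
        passed=bool(np.all(np.abs(deviations) <= tolerance_mmHg)),
    )
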