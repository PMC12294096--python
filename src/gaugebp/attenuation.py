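"""Tissue attenuation coefficient: per-trial estimation and the linear
attenuation-vs-contact-pressure model.

The lumped attenuation exponent for one trial is estimated from systolic
AC amplitudes, alpha = -ln(measured / arterial), the exact inverse of the
simulator's exp(-alpha) attenuation.  Across trials at several static
contact pressures, alpha falls approximately linearly with contact pressure
(better tissue coupling, shallower effective arterial depth), so a simple
OLS line alpha = m * P_c + b is fitted and used to predict alpha at the
contact pressure of a later dynamic recording.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AlphaObservation",
    "AttenuationRegression",
    "estimate_alpha",
    "summarize_alpha",
    "fit_alpha_vs_pressure",
    "predict_alpha",
]

# contact pressures outside this band are refused for prediction: the linear
# model is only trusted near the statically characterized range
GUARD_BAND_MMHG = (10.0, 80.0)


@dataclass(frozen=True)
class AlphaObservation:
    """One trial's attenuation estimate at a known static contact pressure."""

    contact_pressure: float
    alpha: float
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.contact_pressure <= 0:
            raise ValueError(f"contact_pressure must be > 0, got {self.contact_pressure}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


def estimate_alpha(measured_amplitude: float, arterial_amplitude: float) -> float:
    """alpha = -ln(measured / arterial) from systolic AC amplitudes.

    Requires 0 < measured <= arterial (a measured wave larger than the
    arterial wave would imply amplification, outside the model).
    """
    if measured_amplitude <= 0 or arterial_amplitude <= 0:
        raise ValueError("amplitudes must be strictly positive")
    if measured_amplitude > arterial_amplitude:
        raise ValueError(
            f"measured amplitude {measured_amplitude} exceeds arterial "
            f"{arterial_amplitude}: negative alpha is out of model"
        )
    return -math.log(measured_amplitude / arterial_amplitude)


def summarize_alpha(observations: list[AlphaObservation]) -> pd.DataFrame:
    """Group observations by contact pressure: sample mean and SD (ddof=1).

    Returns a DataFrame indexed by contact pressure with columns
    ``mean_alpha``, ``sd_alpha`` (NaN for singleton groups), ``n``.
    """
    if not observations:
        warnings.warn("no alpha observations supplied; empty summary")
        return pd.DataFrame(columns=["mean_alpha", "sd_alpha", "n"])
    df = pd.DataFrame(
        {
            "contact_pressure": [o.contact_pressure for o in observations],
            "alpha": [o.alpha for o in observations],
        }
    )
    grouped = df.groupby("contact_pressure")["alpha"]
    out = pd.DataFrame(
        {
            "mean_alpha": grouped.mean(),
            "sd_alpha": grouped.std(ddof=1),
            "n": grouped.size(),
        }
    )
    out.index.name = "contact_pressure_mmHg"
    return out


class AttenuationRegression(BaseEstimator, RegressorMixin):
    """OLS line alpha = m * P_c + b over static-trial observations.

    fit(X=contact_pressures, y=alphas).  Attributes after fit: ``slope_``
    (per mmHg), ``intercept_``, ``slope_se_``, ``residual_sd_`` (ddof=2),
    ``n_points_``, ``pressure_range_``.

    predict refuses contact pressures outside the [10, 80] mmHg guard band
    (extrapolating the linear trend toward arterial occlusion is not
    meaningful) and refuses nonpositive predicted alpha.
    """

    def fit(self, X, y) -> "AttenuationRegression":
        pc = np.asarray(X, dtype=float).reshape(-1)
        alpha = np.asarray(y, dtype=float).reshape(-1)
        if pc.shape != alpha.shape:
            raise ValueError("contact pressures and alphas must have equal length")
        if len(np.unique(pc)) < 2:
            raise ValueError("at least two distinct contact pressures are required")
        res = stats.linregress(pc, alpha)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.slope_se_ = float(res.stderr)
        resid = alpha - (self.slope_ * pc + self.intercept_)
        dof = max(len(pc) - 2, 1)
        self.residual_sd_ = float(np.sqrt(np.sum(resid**2) / dof))
        self.n_points_ = len(pc)
        self.pressure_range_ = (float(pc.min()), float(pc.max()))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        pc = np.atleast_1d(np.asarray(X, dtype=float))
        lo, hi = GUARD_BAND_MMHG
        if np.any(pc < lo) or np.any(pc > hi):
            raise ValueError(
                f"contact pressure outside the [{lo}, {hi}] mmHg guard band: "
                "refusing to extrapolate the linear attenuation model"
            )
        alpha = self.slope_ * pc + self.intercept_
        if np.any(alpha <= 0):
            raise ValueError(
                "linear model predicts nonpositive alpha at the requested pressure"
            )
        return alpha

    def predict_one(self, contact_pressure: float) -> float:
        return float(self.predict([contact_pressure])[0])

    def to_dict(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "slope_per_mmHg": self.slope_,
            "intercept": self.intercept_,
            "residual_sd": self.residual_sd_,
            "n_points": self.n_points_,
            "pressure_range_mmHg": list(self.pressure_range_),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttenuationRegression":
        est = cls()
        est.slope_ = d["slope_per_mmHg"]
        est.intercept_ = d["intercept"]
        est.residual_sd_ = d.get("residual_sd", 0.0)
        est.n_points_ = d.get("n_points", 2)
        est.pressure_range_ = tuple(d.get("pressure_range_mmHg", GUARD_BAND_MMHG))
        est.slope_se_ = d.get("slope_se", float("nan"))
        return est


def fit_alpha_vs_pressure(
    observations: list[AlphaObservation] | pd.DataFrame | None = None,
    *,
    contact_pressures=None,
    alphas=None,
) -> AttenuationRegression:
    """Fit the alpha-vs-contact-pressure line.

    Accepts trial-level ``AlphaObservation`` lists, a per-pressure mean table
    (as returned by :func:`summarize_alpha`), or explicit arrays.  Trial-level
    data is preferred when available; the mean-table path exists because
    published summaries often provide only group means.
    """
    if observations is not None:
        if isinstance(observations, pd.DataFrame):
            contact_pressures = observations.index.to_numpy(dtype=float)
            alphas = observations["mean_alpha"].to_numpy(dtype=float)
        else:
            contact_pressures = [o.contact_pressure for o in observations]
            alphas = [o.alpha for o in observations]
    if contact_pressures is None or alphas is None:
        raise ValueError("provide observations or contact_pressures and alphas")
    return AttenuationRegression().fit(contact_pressures, alphas)


def predict_alpha(fit: AttenuationRegression, contact_pressure: float) -> float:
    """alpha = m * P_c + b at one contact pressure (guard-banded)."""
    return fit.predict_one(contact_pressure)
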