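"""Device-vs-reference agreement statistics.

Mean absolute error with its SD, Pearson correlation, Bland-Altman bias and
95% limits of agreement (bias +- 1.96 x SD of the paired differences), plus
the British Hypertension Society (BHS) cumulative-error grade and the AAMI
mean-error/SD criterion.  Sample SDs use the n-1 denominator throughout;
"MAE +- SD" means the SD of the absolute differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedBpSeries",
    "AgreementStats",
    "BhsGrade",
    "AamiResult",
    "agreement",
    "bhs_grade",
    "aami_check",
    "bland_altman_table",
]

LOA_MULTIPLIER = 1.96

# BHS cumulative percentage thresholds: |error| within 5 / 10 / 15 mmHg
BHS_TIERS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


@dataclass(frozen=True)
class PairedBpSeries:
    """Matched device and reference BP values for one label (SBP or DBP)."""

    device: np.ndarray
    reference: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        device = np.asarray(self.device, dtype=float)
        reference = np.asarray(self.reference, dtype=float)
        if len(device) != len(reference):
            raise ValueError("device and reference must have equal length")
        if len(device) < 2:
            raise ValueError("at least two paired values are required")
        if np.isnan(device).any() or np.isnan(reference).any():
            raise ValueError("paired series contain missing values")
        object.__setattr__(self, "device", device)
        object.__setattr__(self, "reference", reference)

    @property
    def differences(self) -> np.ndarray:
        return self.device - self.reference


@dataclass(frozen=True)
class AgreementStats:
    mae: float
    mae_sd: float
    pearson_r: float  # NaN when either series has zero variance
    bias: float
    diff_sd: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mae_mmHg": self.mae,
            "mae_sd_mmHg": self.mae_sd,
            "pearson_r": None if math.isnan(self.pearson_r) else self.pearson_r,
            "bias_mmHg": self.bias,
            "diff_sd_mmHg": self.diff_sd,
            "loa_low_mmHg": self.loa_low,
            "loa_high_mmHg": self.loa_high,
            "n": self.n,
        }


def agreement(paired: PairedBpSeries) -> AgreementStats:
    """Full agreement panel for one paired series.

    Pearson r is undefined (NaN, with a warning) when either series is
    constant; every other statistic is still reported.
    """
    d = paired.differences
    n = len(d)
    mae = float(np.mean(np.abs(d)))
    mae_sd = float(np.std(np.abs(d), ddof=1))
    bias = float(np.mean(d))
    diff_sd = float(np.std(d, ddof=1))
    if np.ptp(paired.device) == 0 or np.ptp(paired.reference) == 0:
        warnings.warn("zero variance in a paired series; Pearson r undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(paired.device, paired.reference).statistic)
    return AgreementStats(
        mae=mae,
        mae_sd=mae_sd,
        pearson_r=r,
        bias=bias,
        diff_sd=diff_sd,
        loa_low=bias - LOA_MULTIPLIER * diff_sd,
        loa_high=bias + LOA_MULTIPLIER * diff_sd,
        n=n,
    )


@dataclass(frozen=True)
class BhsGrade:
    grade: str
    pct_within_5: float
    pct_within_10: float
    pct_within_15: float


def bhs_grade(differences) -> BhsGrade:
    """BHS grade from cumulative |error| percentages at 5/10/15 mmHg.

    A requires >= 60/85/95, B >= 50/75/90, C >= 40/65/85; otherwise D.
    """
    d = np.abs(np.asarray(differences, dtype=float))
    if len(d) == 0:
        raise ValueError("at least one difference is required")
    pcts = tuple(100.0 * float(np.mean(d <= thr)) for thr in (5.0, 10.0, 15.0))
    grade = "D"
    for g, thresholds in BHS_TIERS.items():
        if all(p >= t for p, t in zip(pcts, thresholds)):
            grade = g
            break
    return BhsGrade(grade, *pcts)


@dataclass(frozen=True)
class AamiResult:
    passed: bool
    mean_error: float
    sd_error: float


def aami_check(differences) -> AamiResult:
    """AAMI criterion: |mean error| <= 5 mmHg and SD of errors <= 8 mmHg."""
    d = np.asarray(differences, dtype=float)
    if len(d) < 2:
        raise ValueError("at least two differences are required")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AamiResult(passed=(abs(mean) <= 5.0 and sd <= 8.0), mean_error=mean, sd_error=sd)


def bland_altman_table(paired: PairedBpSeries) -> pd.DataFrame:
    """Per-beat (mean, difference) pairs for a Bland-Altman plot."""
    return pd.DataFrame(
        {
            "mean_mmHg": (paired.device + paired.reference) / 2.0,
            "difference_mmHg": paired.differences,
        }
    )
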