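"""Inverse-variance combination of replicate radiocarbon determinations.

Replicate uncalibrated 14C measurements x_i +/- sigma_i of the same event are
combined as the inverse-variance weighted mean,

    mean  = sum(x_i / sigma_i^2) / sum(1 / sigma_i^2)
    sigma = (sum 1 / sigma_i^2)^(-1/2)

with the chi-square consistency test chi2 = sum((x_i - mean)/sigma_i)^2 on
n - 1 degrees of freedom (the check OxCal's R_Combine reports).  A low
upper-tail p flags statistically inconsistent replicates.  No internal
rounding is done; calibration against a curve is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ParameterError


@dataclass(frozen=True)
class C14Date:
    """One uncalibrated radiocarbon determination (14C years BP, 1-sigma)."""

    mean: float
    sigma: float
    lab_code: str = ""

    def __post_init__(self):
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ParameterError(f"sigma must be > 0 (got {self.sigma})")
        if not np.isfinite(self.mean) or self.mean <= 0:
            raise ParameterError(f"mean must be > 0 (got {self.mean})")


@dataclass(frozen=True)
class C14Combination:
    mean: float
    sigma: float
    chi2: float
    df: int
    p: float

    @property
    def consistent_at_05(self) -> bool:
        return self.p >= 0.05

    def rounded(self) -> tuple[int, int]:
        """(mean, sigma) rounded to the nearest integer year for display."""
        return int(round(self.mean)), int(round(self.sigma))


def combine_dates(dates: Sequence[C14Date]) -> C14Combination:
    """Inverse-variance weighted mean of >= 2 dates with chi2 consistency."""
    if len(dates) < 2:
        raise InsufficientDataError("need at least two dates to combine")
    x = np.array([d.mean for d in dates], dtype=float)
    s = np.array([d.sigma for d in dates], dtype=float)
    w = 1.0 / s**2
    mean = float(np.sum(w * x) / np.sum(w))
    sigma = float(np.sum(w) ** -0.5)
    chi2 = float(np.sum(((x - mean) / s) ** 2))
    df = len(dates) - 1
    p = float(stats.chi2.sf(chi2, df))
    return C14Combination(mean, sigma, chi2, df, p)
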