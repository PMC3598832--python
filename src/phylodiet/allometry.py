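"""Reduced major axis (RMA) regression and allometric scaling tests.

The RMA slope is sign(r) * sd_y / sd_x, appropriate when both variables are
measured with error (as with morphological and dietary estimates).  The
confidence interval uses the standard RMA formula slope * (sqrt(B+1) +/-
sqrt(B)) with B = t^2 (1 - r^2)/(n - 2); significance comes from the
correlation t-test.  ``allometry_test`` applies the fit to log10 length data
and flags departures from isometry (slope 1.0 outside the 95% CI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RmaFit", "rma_fit", "allometry_test"]


@dataclass
class RmaFit:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    slope_ci_low: float
    slope_ci_high: float
    n: int


def rma_fit(x, y, alpha: float = 0.05) -> RmaFit:
    """Reduced major axis fit of y on x with a (1-alpha) CI on the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3 or n != len(y):
        raise ValueError("need at least 3 paired points")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("constant variable; RMA undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = np.sign(r) if r != 0 else 1.0
    slope = float(sign * sy / sx)
    intercept = float(np.mean(y) - slope * np.mean(x))
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
        ci_low = ci_high = slope
    else:
        t = r * np.sqrt(df) / np.sqrt(1 - r * r)
        p = float(2 * stats.t.sf(abs(t), df))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        B = tcrit**2 * (1 - r * r) / df
        lo = slope * (np.sqrt(B + 1) - np.sqrt(B))
        hi = slope * (np.sqrt(B + 1) + np.sqrt(B))
        ci_low, ci_high = (min(lo, hi), max(lo, hi))
    return RmaFit(
        slope=slope, intercept=intercept, r=r, r_squared=r * r,
        p_value=p, slope_ci_low=float(ci_low), slope_ci_high=float(ci_high), n=n,
    )


def allometry_test(sl_obs, il_obs, alpha: float = 0.05) -> tuple[RmaFit, bool]:
    """RMA of log10 intestinal length on log10 standard length.

    Returns the fit and a flag that is True when the scaling departs
    significantly from isometry (slope 1.0 outside the CI).
    """
    sl = np.asarray(sl_obs, float)
    il = np.asarray(il_obs, float)
    if np.any(sl <= 0) or np.any(il <= 0):
        raise ValueError("lengths must be positive")
    fit = rma_fit(np.log10(sl), np.log10(il), alpha=alpha)
    significant = not (fit.slope_ci_low <= 1.0 <= fit.slope_ci_high)
    return fit, significant
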