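"""Expansion dating: convert a growth-onset time into a substitution rate.

Because all inference runs in mutation-scaled units, the posterior of the
transition time t_trans (expected substitutions per site before present)
can be converted into a substitution-rate estimate once the onset of
population growth is equated with a dated environmental event:

    mu = t_trans / c        [substitutions / site / year]

for a calibration age c in years.  Rates are reported in percent per
site per million years (x 1e8: x 1e6 for years -> MY, x 100 for percent).
For a calibration window [c_low, c_high] (default 13 000 - 18 000 years,
post-glacial sea-level rise to surface-water warming), the combined
interval is the envelope [HPD lower at c_high, HPD upper at c_low].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import hpd

__all__ = ["RateEstimate", "calibrate_rate", "rate_window"]

PCT_PER_MY = 1e8  # (subs/site/year) * 1e6 years/MY * 100 percent


@dataclass
class RateEstimate:
    """Substitution-rate estimate in % per site per MY for one calibration age."""

    calibration_years: float
    mean: float
    hpd_lower: float
    hpd_upper: float

    def __post_init__(self) -> None:
        if self.calibration_years <= 0:
            raise ValueError("calibration age must be positive")
        if not (self.hpd_lower <= self.mean <= self.hpd_upper):
            raise ValueError("mean outside its HPD interval")


def calibrate_rate(t_samples, c_years: float) -> RateEstimate:
    """Rate estimate mu = t/c from posterior draws (or a point value) of t_trans."""
    if c_years <= 0:
        raise ValueError("calibration age must be positive")
    t = np.atleast_1d(np.asarray(t_samples, dtype=float))
    if np.any(t < 0):
        raise ValueError("non-positive transition-time draws present")
    rates = t / c_years * PCT_PER_MY
    if rates.size >= 20:
        lo, hi = hpd(rates, 0.95)
    elif rates.size == 1:
        lo = hi = float(rates[0])
    else:
        raise ValueError("need >= 20 posterior draws (or a single point value)")
    return RateEstimate(
        calibration_years=c_years, mean=float(rates.mean()), hpd_lower=lo, hpd_upper=hi
    )


def rate_window(
    t_samples, c_low: float = 13_000.0, c_high: float = 18_000.0
) -> tuple[RateEstimate, RateEstimate, tuple[float, float]]:
    """Rate estimates at both calibration endpoints plus the envelope interval.

    Returns (estimate at c_high = slow end, estimate at c_low = fast end,
    combined interval).  The older calibration gives the lower rates, so
    the envelope is [lower HPD bound at c_high, upper HPD bound at c_low].
    """
    if not (0 < c_low < c_high):
        raise ValueError("need 0 < c_low < c_high")
    at_high = calibrate_rate(t_samples, c_high)
    at_low = calibrate_rate(t_samples, c_low)
    return at_high, at_low, (at_high.hpd_lower, at_low.hpd_upper)
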