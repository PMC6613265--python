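"""First-order enzyme-stability kinetics.

Purified luciferase used as a calibration standard slowly loses activity in
storage.  Treating the loss as first-order, activity follows
``A(t) = A0 * exp(-k t)`` and the canonical estimator is ordinary least
squares of ``ln A`` on time: the slope is ``-k`` and the half-life is
``ln 2 / k``.  A nonlinear exponential fit is provided for comparison but
the log-linear fit is the default.  Rates measured at one storage
temperature can be transferred to the assay temperature with the Q10 rule,
and signals read against an aged calibrator can be decay-corrected.

All rates are per hour and all times are hours; day conversions belong to
the presentation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DecaySeries",
    "DecayFit",
    "TemperatureScaling",
    "fit_first_order_decay",
    "fit_first_order_decay_nls",
    "half_life_from_rate",
    "fraction_remaining",
    "q10_scale_rate",
    "decay_correct",
]


@dataclass(frozen=True)
class DecaySeries:
    """An activity-vs-time course (times in hours, strictly increasing)."""

    times_h: np.ndarray
    activity: np.ndarray
    temperature_C: float = 4.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times_h and activity must be 1-D arrays of equal length")
        if np.any(t < 0):
            raise ValueError("times_h must be non-negative")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times_h must be strictly increasing")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "activity", a)

    def __len__(self) -> int:
        return self.times_h.size


@dataclass(frozen=True)
class DecayFit:
    """Result of a first-order decay fit.

    ``rate_per_h`` is the decay constant (h^-1), ``half_life_h`` is
    ``ln 2 / rate`` (``inf`` with ``no_decay`` set when the fitted rate is
    not positive), ``log_intercept`` is the intercept of the ln-activity
    regression, and ``rate_std_err`` the standard error of the slope.
    """

    rate_per_h: float
    half_life_h: float
    log_intercept: float
    r_squared: float
    rate_std_err: float
    no_decay: bool = False

    @property
    def half_life_days(self) -> float:
        return self.half_life_h / 24.0


@dataclass(frozen=True)
class TemperatureScaling:
    """Q10 transfer of a rate from ``temp_from_C`` to ``temp_to_C``."""

    q10: float = 2.5
    temp_from_C: float = 4.0
    temp_to_C: float = 21.0

    def __post_init__(self) -> None:
        if self.q10 <= 0:
            raise ValueError("q10 must be > 0")


def fit_first_order_decay(series: DecaySeries) -> DecayFit:
    """Log-linear OLS estimate of the first-order decay rate.

    Regresses ``ln(activity)`` on time; the decay rate is the negated slope.
    Raises ``ValueError`` on non-positive activities (log undefined) or
    fewer than two points.  A fitted rate <= 0 is reported as an infinite
    half-life with the ``no_decay`` flag rather than an error.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 points to fit a decay rate")
    if np.any(series.activity <= 0):
        raise ValueError("all activities must be > 0 for the log-linear fit")
    res = stats.linregress(series.times_h, np.log(series.activity))
    rate = -res.slope
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    if rate <= 0:
        return DecayFit(
            rate_per_h=float(rate),
            half_life_h=math.inf,
            log_intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            rate_std_err=stderr,
            no_decay=True,
        )
    return DecayFit(
        rate_per_h=float(rate),
        half_life_h=math.log(2) / rate,
        log_intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        rate_std_err=stderr,
    )


def fit_first_order_decay_nls(series: DecaySeries) -> DecayFit:
    """Nonlinear least-squares variant of the exponential fit.

    Fits ``A0 * exp(-k t)`` directly on the linear scale; seeded from the
    log-linear fit.  Provided for comparison; the log-linear fit remains the
    canonical estimator.
    """
    seed = fit_first_order_decay(series)
    k0 = max(seed.rate_per_h, 0.0)
    popt, pcov = optimize.curve_fit(
        lambda t, lnA0, k: np.exp(lnA0 - k * t),
        series.times_h,
        series.activity,
        p0=[seed.log_intercept, k0],
        maxfev=10000,
    )
    lnA0, rate = float(popt[0]), float(popt[1])
    resid = series.activity - np.exp(lnA0 - rate * series.times_h)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((series.activity - series.activity.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    stderr = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else math.nan
    if rate <= 0:
        return DecayFit(rate, math.inf, lnA0, r2, stderr, no_decay=True)
    return DecayFit(rate, math.log(2) / rate, lnA0, r2, stderr)


def half_life_from_rate(rate_per_h: float) -> float:
    """Half-life in hours, ``ln 2 / rate``; requires a positive rate."""
    if rate_per_h <= 0:
        raise ValueError("rate must be > 0 for a finite half-life")
    return math.log(2) / rate_per_h


def fraction_remaining(rate_per_h: float, elapsed_h: float) -> float:
    """Fraction of activity left after ``elapsed_h`` hours: exp(-k t)."""
    if rate_per_h < 0:
        raise ValueError("rate must be >= 0")
    if elapsed_h < 0:
        raise ValueError("elapsed time must be >= 0")
    return math.exp(-rate_per_h * elapsed_h)


def q10_scale_rate(rate_per_h: float, scaling: TemperatureScaling) -> float:
    """Transfer a rate between temperatures: rate * q10^(dT / 10)."""
    if rate_per_h < 0:
        raise ValueError("rate must be >= 0")
    d_t = scaling.temp_to_C - scaling.temp_from_C
    return rate_per_h * scaling.q10 ** (d_t / 10.0)


def decay_correct(measured_signal: float, calibrator_age_h: float, rate_per_h: float) -> float:
    """Rescale a signal read from an aged enzyme to its fresh-equivalent value.

    Divides by the fraction of activity remaining at the calibrator's age,
    so ``decay_correct(fraction_remaining(k, t) * x, t, k) == x`` exactly
    and age 0 is the identity.
    """
    if measured_signal < 0:
        raise ValueError("signal must be >= 0")
    return measured_signal / fraction_remaining(rate_per_h, calibrator_age_h)
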