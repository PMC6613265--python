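"""Period, phase and amplitude estimation for luminescence traces.

A single-component analogue of the FFT-NLLS family of circadian period
estimators: the trace is linearly detrended, the dominant period inside
user-supplied bounds is read off a zero-padded discrete Fourier spectrum,
and that seed initialises a nonlinear least-squares fit of

    signal(t) = mean + trend * t + amplitude * cos(2*pi*t/period + phase)

The single cosine is sufficient for traces with one dominant circadian
component over a few cycles; exponential damping and multi-component fits
are deliberately excluded.  Phase is reported at t = 0 on the cosine
convention, wrapped to (-pi, pi]; relative amplitude is amplitude divided
by the fitted mid-trace level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RhythmFit",
    "detrend",
    "estimate_rhythm",
    "relative_amplitude",
    "phase_difference",
]

#: Default period search window in hours (circadian band).
DEFAULT_PERIOD_BOUNDS = (15.0, 35.0)


@dataclass(frozen=True)
class RhythmFit:
    """Fitted rhythm parameters for one trace.

    ``mean_level`` is the fitted baseline evaluated at the trace midpoint
    (so the linear trend does not bias it); ``relative_amplitude`` is
    amplitude / mean_level, NaN when the mean is not positive.
    """

    period_h: float
    phase_rad: float
    amplitude: float
    mean_level: float
    linear_trend: float
    relative_amplitude: float
    rss: float
    converged: bool
    message: str = ""


def _wrap_phase(phi: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    out = math.fmod(phi, 2.0 * math.pi)
    if out <= -math.pi:
        out += 2.0 * math.pi
    elif out > math.pi:
        out -= 2.0 * math.pi
    return out


def detrend(times_h: np.ndarray, signal: np.ndarray, mode: str = "linear") -> np.ndarray:
    """Remove a least-squares line (or nothing) from a trace."""
    t = np.asarray(times_h, dtype=float)
    s = np.asarray(signal, dtype=float)
    if mode == "none":
        return s.copy()
    if mode != "linear":
        raise ValueError(f"unknown detrend mode {mode!r}")
    if t.size < 3:
        raise ValueError("linear detrend needs at least 3 points")
    coef = np.polynomial.polynomial.polyfit(t, s, 1)
    return s - (coef[0] + coef[1] * t)


def _fft_seed(
    t: np.ndarray,
    resid: np.ndarray,
    bounds: tuple[float, float],
    scale: float,
) -> tuple[float, float, float] | None:
    """Dominant (period, amplitude, phase) from a zero-padded spectrum, or None.

    Peaks below 1e-9 of the signal scale are numerical noise on an
    effectively flat trace and are treated as "no peak".
    """
    n = t.size
    dt = t[1] - t[0]
    n_pad = 8 * n
    spec = np.fft.rfft(resid, n=n_pad)
    freq = np.fft.rfftfreq(n_pad, d=dt)
    with np.errstate(divide="ignore"):
        period = np.where(freq > 0, 1.0 / freq, np.inf)
    in_band = (period >= bounds[0]) & (period <= bounds[1])
    if not np.any(in_band):
        return None
    mag = np.abs(spec)
    k = np.flatnonzero(in_band)[np.argmax(mag[in_band])]
    amp = 2.0 * mag[k] / n
    if amp <= 1e-9 * max(scale, 1e-300):
        return None
    # A cos(w t + phi) gives X[k] ~ (n/2) exp(i (phi + w t0))
    phi = math.atan2(spec.imag[k], spec.real[k]) - 2.0 * math.pi * freq[k] * t[0]
    return float(period[k]), float(amp), _wrap_phase(phi)


def estimate_rhythm(
    times_h: np.ndarray,
    signal: np.ndarray,
    period_bounds_h: tuple[float, float] = DEFAULT_PERIOD_BOUNDS,
) -> RhythmFit:
    """Fit mean + trend + single cosine, seeded from the Fourier spectrum.

    Requires uniform sampling and a duration of at least twice the lower
    period bound.  If no spectral peak lies within the bounds the result
    carries ``converged=False`` with the fitted line only; it is not an
    exception, so batch analyses of arrhythmic wells keep running.
    """
    t = np.asarray(times_h, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.ndim != 1 or s.shape != t.shape or t.size < 4:
        raise ValueError("need matching 1-D arrays with at least 4 points")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("uniform sampling required; resample irregular traces upstream")
    lo, hi = period_bounds_h
    if not 0 < lo < hi:
        raise ValueError("period bounds must satisfy 0 < lower < upper")
    if t[-1] - t[0] < 2 * lo:
        raise ValueError("trace must span at least two periods at the lower bound")

    coef = np.polynomial.polynomial.polyfit(t, s, 1)
    resid = s - (coef[0] + coef[1] * t)
    t_mid = 0.5 * (t[0] + t[-1])
    base_mean = float(coef[0] + coef[1] * t_mid)

    seed = _fft_seed(t, resid, (lo, hi), float(np.max(np.abs(s))))
    if seed is None:
        rss = float(np.sum(resid**2))
        return RhythmFit(
            period_h=math.nan,
            phase_rad=math.nan,
            amplitude=0.0,
            mean_level=base_mean,
            linear_trend=float(coef[1]),
            relative_amplitude=0.0 if base_mean > 0 else math.nan,
            rss=rss,
            converged=False,
            message="no spectral peak within the period bounds",
        )
    period0, amp0, phase0 = seed

    def model(x: np.ndarray) -> np.ndarray:
        m, b, amp, per, phi = x
        return m + b * (t - t_mid) + amp * np.cos(2.0 * np.pi * t / per + phi)

    x0 = np.array([base_mean, coef[1], amp0, period0, phase0])
    lower = [-np.inf, -np.inf, 0.0, lo, -2.0 * np.pi]
    upper = [np.inf, np.inf, np.inf, hi, 2.0 * np.pi]
    res = least_squares(
        lambda x: model(x) - s, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    m, b, amp, per, phi = res.x
    phi = _wrap_phase(float(phi))
    rss = float(np.sum(res.fun**2))
    mean_level = float(m)
    return RhythmFit(
        period_h=float(per),
        phase_rad=phi,
        amplitude=float(amp),
        mean_level=mean_level,
        linear_trend=float(b),
        relative_amplitude=float(amp / mean_level) if mean_level > 0 else math.nan,
        rss=rss,
        converged=bool(res.success),
        message=str(res.message),
    )


def relative_amplitude(fit: RhythmFit) -> float:
    """Amplitude over mean level; errors on a non-positive mean."""
    if not fit.mean_level > 0:
        raise ValueError("relative amplitude undefined for non-positive mean level")
    return fit.amplitude / fit.mean_level


def phase_difference(phase_a_rad: float, phase_b_rad: float) -> float:
    """Circular phase difference a - b, wrapped to (-pi, pi]."""
    return _wrap_phase(phase_a_rad - phase_b_rad)
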