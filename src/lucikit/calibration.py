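"""Calibration curves from serial dilutions.

A dilution ladder of purified enzyme measured in the assay matrix gives a
log-log calibration line: log10(signal) = slope * log10(concentration) +
intercept, with slope 1 for a perfectly proportional assay.  The module
fits that line (excluding saturated and zero readings), reports per-step
linearity diagnostics, quantifies matrix inhibition against a buffer
reference, and inverts the curve to infer enzyme amounts in extracts —
optionally compensating for a calibrator that has aged in storage.

Concentrations are relative (dilution-factor scale); converting to molar
amounts requires an external protein quantification and is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decay import fraction_remaining

__all__ = [
    "DilutionSeries",
    "CalibrationCurve",
    "InferredAmount",
    "fit_calibration",
    "linearity_report",
    "matrix_inhibition",
    "infer_amount",
]


@dataclass(frozen=True)
class DilutionSeries:
    """Dilution-ladder measurements in one matrix.

    ``dilution_factors`` are cumulative relative concentrations (e.g.
    1e-1 ... 1e-6), strictly decreasing and at most 1; ``signal`` in cps.
    ``saturation_ceiling`` marks the detector limit, if known.
    """

    dilution_factors: np.ndarray
    signal: np.ndarray
    matrix_label: str = "buffer"
    saturation_ceiling: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.dilution_factors, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if f.ndim != 1 or s.shape != f.shape:
            raise ValueError("dilution_factors and signal must be 1-D arrays of equal length")
        if np.any(f <= 0) or np.any(f > 1):
            raise ValueError("dilution factors must lie in (0, 1]")
        if f.size >= 2 and not np.all(np.diff(f) < 0):
            raise ValueError("dilution factors must be strictly decreasing")
        if np.any(s < 0):
            raise ValueError("signals must be >= 0")
        object.__setattr__(self, "dilution_factors", f)
        object.__setattr__(self, "signal", s)

    def __len__(self) -> int:
        return self.dilution_factors.size


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted log-log response line and the range it covers."""

    log10_slope: float
    log10_intercept: float
    r_squared: float
    linear_range: tuple[float, float]
    n_points_used: int
    signal_range: tuple[float, float]
    low_n: bool = False


@dataclass(frozen=True)
class InferredAmount:
    """Relative concentration inferred from a signal, with an extrapolation flag."""

    concentration: float
    extrapolated: bool = False


def fit_calibration(
    series: DilutionSeries, saturation_ceiling: float | None = None
) -> CalibrationCurve:
    """OLS of log10(signal) on log10(relative concentration).

    Points with zero signal, or at/above the saturation ceiling (argument
    overrides the series' own ceiling), are excluded before fitting; at
    least two usable points must remain.  A slope of 1 indicates ideal
    proportionality.  Exactly two points fit a line exactly (r^2 = 1 by
    construction) and are flagged ``low_n``.
    """
    ceiling = saturation_ceiling if saturation_ceiling is not None else series.saturation_ceiling
    mask = series.signal > 0
    if ceiling is not None:
        mask &= series.signal < ceiling
    n = int(mask.sum())
    if n < 2:
        causes = []
        if ceiling is not None and np.any(series.signal >= ceiling):
            causes.append("saturated")
        if np.any(series.signal <= 0):
            causes.append("zero-signal")
        detail = " and ".join(causes) if causes else "too few"
        raise ValueError(f"fewer than 2 usable points after excluding {detail} readings")
    x = np.log10(series.dilution_factors[mask])
    y = np.log10(series.signal[mask])
    res = stats.linregress(x, y)
    factors = series.dilution_factors[mask]
    signals = series.signal[mask]
    return CalibrationCurve(
        log10_slope=float(res.slope),
        log10_intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        linear_range=(float(factors.min()), float(factors.max())),
        n_points_used=n,
        signal_range=(float(signals.min()), float(signals.max())),
        low_n=n == 2,
    )


def linearity_report(series: DilutionSeries) -> pd.DataFrame:
    """Per-step signal ratios against the nominal dilution fold.

    For each adjacent pair, reports the measured ratio
    ``signal_i / signal_{i+1}``, the nominal fold from the dilution
    factors, and the relative deviation ``|ratio - fold| / fold``.  Steps
    with a zero denominator are marked undefined (NaN) rather than fatal.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 points for a linearity report")
    s = series.signal
    f = series.dilution_factors
    fold = f[:-1] / f[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s[1:] > 0, s[:-1] / s[1:], np.nan)
    deviation = np.abs(ratio - fold) / fold
    return pd.DataFrame(
        {
            "step": np.arange(1, len(series)),
            "factor_high": f[:-1],
            "factor_low": f[1:],
            "nominal_fold": fold,
            "signal_ratio": ratio,
            "deviation": deviation,
            "undefined": ~np.isfinite(ratio),
        }
    )


def matrix_inhibition(
    extract_series: DilutionSeries,
    buffer_series: DilutionSeries,
    dilution_factor: float | None = None,
) -> float:
    """Extract/buffer signal ratio at a matched dilution.

    A ratio <= 1 indicates inhibition by the extract matrix.  With
    ``dilution_factor=None`` the largest dilution factor present in both
    series is used; a missing match raises.
    """
    if dilution_factor is None:
        common = [
            f for f in extract_series.dilution_factors
            if np.any(np.isclose(buffer_series.dilution_factors, f, rtol=1e-9))
        ]
        if not common:
            raise ValueError("no matched dilution factor between extract and buffer series")
        dilution_factor = float(max(common))
    i = np.flatnonzero(np.isclose(extract_series.dilution_factors, dilution_factor, rtol=1e-9))
    j = np.flatnonzero(np.isclose(buffer_series.dilution_factors, dilution_factor, rtol=1e-9))
    if i.size == 0 or j.size == 0:
        raise ValueError(f"dilution factor {dilution_factor} not present in both series")
    buffer_signal = buffer_series.signal[j[0]]
    if buffer_signal <= 0:
        raise ValueError("buffer signal at the matched dilution is zero")
    return float(extract_series.signal[i[0]] / buffer_signal)


def infer_amount(
    signal: float,
    curve: CalibrationCurve,
    calibrator_age_h: float = 0.0,
    calibrator_decay_rate: float = 0.0,
) -> InferredAmount:
    """Invert the calibration curve to a relative concentration.

    The raw inversion is 10**((log10(signal) - intercept) / slope).  If the
    calibrator had aged ``calibrator_age_h`` hours when the curve was
    measured, its active-enzyme content was only ``fraction_remaining``
    of nominal, so the curve over-reads fresh unknowns; the inverted value
    is multiplied by that fraction to compensate.  (The direction was fixed
    by an end-to-end simulation of an aged-calibrator experiment; see the
    test suite.)  Signals outside the fitted signal range are flagged as
    extrapolation, not rejected.
    """
    if signal <= 0:
        raise ValueError("signal must be > 0")
    log10_c = (math.log10(signal) - curve.log10_intercept) / curve.log10_slope
    conc = 10.0**log10_c
    conc *= fraction_remaining(calibrator_decay_rate, calibrator_age_h)
    lo, hi = curve.signal_range
    extrapolated = not (lo <= signal <= hi)
    return InferredAmount(concentration=float(conc), extrapolated=extrapolated)
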