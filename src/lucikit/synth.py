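"""Synthetic plate-reader data generation.

Every input the analysis consumes can be generated here with controlled
noise and explicit seeds: exponential enzyme-stability time courses,
serial-dilution ladders, and multi-well rhythmic luminescence experiments
driven by the reporter ODE model.  Defaults emulate the laboratory setup
the package targets: 30-minute sampling with 1.5 s counting integration on
a 96-well luminometer, signals in counts per second.

One :class:`numpy.random.Generator` stream is created per generated object
from the caller's seed; no global RNG state is touched, so identical
arguments and seed reproduce identical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import DilutionSeries
from .decay import DecaySeries
from .noise import NoiseModel
from .plates import LuminescenceTrace, PlateExperiment, REPORTERS
from .reporter import ReporterParams, simulate

__all__ = ["WellDesign", "generate_decay_series", "generate_dilution_series", "generate_plate_experiment"]


@dataclass(frozen=True)
class WellDesign:
    """Label set for one well: reporter, genotype tag, replicate index."""

    reporter: str
    genotype: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.reporter not in REPORTERS:
            raise ValueError(f"unknown reporter label {self.reporter!r}; expected one of {REPORTERS}")


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_decay_series(
    rate_per_h: float,
    times_h: np.ndarray,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    initial_activity: float = 1e6,
    temperature_C: float = 4.0,
) -> DecaySeries:
    """First-order stability series: activity(t) = A0 * exp(-rate * t).

    ``noise=None`` yields the exact noiseless mean.  Negative rates and
    empty or non-increasing time grids are rejected.
    """
    if rate_per_h < 0:
        raise ValueError("rate_per_h must be >= 0")
    t = np.asarray(times_h, dtype=float)
    if t.size == 0:
        raise ValueError("times_h must not be empty")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("times_h must be strictly increasing")
    if initial_activity <= 0:
        raise ValueError("initial_activity must be > 0")
    activity = initial_activity * np.exp(-rate_per_h * t)
    if noise is not None:
        activity = noise.apply(activity, _rng(seed))
    return DecaySeries(times_h=t, activity=activity, temperature_C=temperature_C)


def generate_dilution_series(
    top_concentration: float,
    fold: float,
    n_steps: int,
    response_slope: float = 1.0,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    gain_cps: float = 1e8,
    matrix_label: str = "buffer",
    inhibition: float = 1.0,
    saturation_ceiling: float | None = None,
) -> DilutionSeries:
    """Geometric dilution ladder with a power-law assay response.

    Relative concentrations are ``top_concentration / fold**i`` for
    i = 0 .. n_steps-1; the ideal signal is
    ``gain_cps * inhibition * concentration**response_slope``, so
    ``response_slope = 1`` is a perfectly proportional assay and the
    per-step signal ratio is ``fold**response_slope``.  ``inhibition`` < 1
    models uniform matrix suppression (e.g. a crude plant extract).
    Signals at or above ``saturation_ceiling`` are clipped to it, mimicking
    detector saturation.
    """
    if top_concentration <= 0:
        raise ValueError("top_concentration must be > 0")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if not 0 < inhibition <= 1:
        raise ValueError("inhibition must be in (0, 1]")
    conc = top_concentration / fold ** np.arange(n_steps, dtype=float)
    signal = gain_cps * inhibition * conc**response_slope
    if noise is not None:
        signal = noise.apply(signal, _rng(seed))
    if saturation_ceiling is not None:
        signal = np.minimum(signal, saturation_ceiling)
    return DilutionSeries(
        dilution_factors=conc,
        signal=signal,
        matrix_label=matrix_label,
        saturation_ceiling=saturation_ceiling,
    )


def generate_plate_experiment(
    params: ReporterParams,
    design: Sequence[WellDesign | tuple],
    duration_h: float = 72.0,
    sampling_interval_h: float = 0.5,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    zero_start: bool = False,
) -> PlateExperiment:
    """Simulated multi-well rhythmic luminescence experiment.

    Each well's noiseless mean is the model-predicted observed signal for
    its reporter channel; replicate wells differ only by noise, drawn from
    one shared RNG stream so the whole plate is reproducible from a single
    seed.  Wells are named W01, W02, ... in design order.
    """
    if duration_h < 2 * params.period_h:
        raise ValueError("duration_h must cover at least two forcing periods")
    if sampling_interval_h <= 0:
        raise ValueError("sampling_interval_h must be > 0")
    wells: list[WellDesign] = [w if isinstance(w, WellDesign) else WellDesign(*w) for w in design]
    if not wells:
        raise ValueError("design must contain at least one well")

    n_points = int(round(duration_h / sampling_interval_h)) + 1
    times = np.arange(n_points) * sampling_interval_h
    init = {"initial_cBNL": 0.0, "initial_cBFLUC": 0.0} if zero_start else {}
    traces = simulate(params, times, **init)

    rng = _rng(seed)
    out: list[LuminescenceTrace] = []
    for i, w in enumerate(wells):
        ideal = traces.observed(w.reporter)
        signal = noise.apply(ideal, rng) if noise is not None else ideal.copy()
        out.append(
            LuminescenceTrace(
                well=f"W{i + 1:02d}",
                times_h=times,
                signal_cps=signal,
                reporter=w.reporter,
                genotype=w.genotype,
                replicate=w.replicate,
            )
        )
    return PlateExperiment(wells=out, sampling_interval_h=sampling_interval_h)
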