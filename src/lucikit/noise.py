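"""Plate-reader noise model for synthetic luminescence data.

Luminometers count photons over a short integration window (1.5 s per well
in the emulated setup), so the dominant instrument noise is Poisson counting
noise on the accumulated counts.  On top of that, pipetting and well-position
effects introduce a multiplicative, roughly log-normal spread, and the reader
has a small additive dark/background rate.  The model applies the three
components in that order:

1. counts ~ Poisson(signal_cps * integration_s), reported back as cps;
2. multiply by a log-normal factor with unit mean and the stated CV;
3. add a constant background in cps.

A ``NoiseModel`` instance only describes the noise; randomness always comes
from a caller-supplied :class:`numpy.random.Generator`, so generators that
share a model remain independently seedable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseModel", "NOISELESS"]


@dataclass(frozen=True)
class NoiseModel:
    """Counting + multiplicative + additive noise for cps signals.

    Parameters
    ----------
    multiplicative_cv:
        Coefficient of variation of the log-normal multiplicative component
        (dimensionless fraction, >= 0).  0 disables it.
    counting_integration_s:
        Photon-counting integration window in seconds (> 0).  Counting
        variance on the cps scale is ``signal / integration``, so halving
        the window doubles the counting variance contribution.
    baseline_cps:
        Additive background, counts per second (>= 0).
    counting:
        If False, the Poisson stage is skipped (useful for purely
        multiplicative noise studies).
    """

    multiplicative_cv: float = 0.0
    counting_integration_s: float = 1.5
    baseline_cps: float = 0.0
    counting: bool = True

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0:
            raise ValueError("multiplicative_cv must be >= 0")
        if self.counting_integration_s <= 0:
            raise ValueError("counting_integration_s must be > 0")
        if self.baseline_cps < 0:
            raise ValueError("baseline_cps must be >= 0")

    def apply(self, ideal_cps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Perturb an array of ideal cps values; returns a new array."""
        ideal_cps = np.asarray(ideal_cps, dtype=float)
        if np.any(ideal_cps < 0):
            raise ValueError("ideal signal must be non-negative")
        out = ideal_cps.copy()
        if self.counting:
            t = self.counting_integration_s
            out = rng.poisson(out * t).astype(float) / t
        if self.multiplicative_cv > 0:
            sigma2 = np.log1p(self.multiplicative_cv**2)
            sigma = np.sqrt(sigma2)
            # mean-1 log-normal: exp(N(-sigma^2/2, sigma^2))
            out = out * rng.lognormal(-sigma2 / 2.0, sigma, size=out.shape)
        return out + self.baseline_cps


#: A noiseless sentinel: generators accept ``noise=None`` as well.
NOISELESS: NoiseModel | None = None
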