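"""In-memory containers for plate-reader luminescence time courses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LuminescenceTrace", "PlateExperiment", "REPORTERS"]

#: Recognised reporter labels: NanoLUC and firefly luciferase.
REPORTERS = ("NL", "FLUC")


@dataclass(frozen=True)
class LuminescenceTrace:
    """One well's luminescence time course.

    ``times_h`` are hours since transfer to constant light; ``signal_cps``
    are plate-reader counts per second.  ``reporter`` is ``"NL"`` or
    ``"FLUC"``; ``genotype`` is a free-text line label; ``replicate`` is the
    1-based replicate index within (reporter, genotype).
    """

    well: str
    times_h: np.ndarray
    signal_cps: np.ndarray
    reporter: str
    genotype: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        s = np.asarray(self.signal_cps, dtype=float)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("times_h and signal_cps must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times_h must be strictly increasing")
        if self.reporter not in REPORTERS:
            raise ValueError(f"unknown reporter label {self.reporter!r}; expected one of {REPORTERS}")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "signal_cps", s)

    def __len__(self) -> int:
        return self.times_h.size


@dataclass
class PlateExperiment:
    """A labelled collection of wells sharing one sampling grid."""

    wells: list[LuminescenceTrace]
    sampling_interval_h: float = field(default=0.5)

    def __post_init__(self) -> None:
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be > 0")
        if self.wells:
            grid = self.wells[0].times_h
            for w in self.wells[1:]:
                if w.times_h.shape != grid.shape or not np.allclose(w.times_h, grid):
                    raise ValueError(f"well {w.well!r} is not on the shared time grid")

    @property
    def times_h(self) -> np.ndarray:
        if not self.wells:
            raise ValueError("experiment has no wells")
        return self.wells[0].times_h

    def __len__(self) -> int:
        return len(self.wells)

    def by_reporter(self, reporter: str) -> list[LuminescenceTrace]:
        return [w for w in self.wells if w.reporter == reporter]
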