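"""Tidy-CSV input/output for plate experiments.

Schema: one row per (well, timepoint) with columns
``well, time_h, signal_cps, reporter, genotype, replicate`` — one header
row, UTF-8, '.' decimal.  Floats are written with ``repr`` precision (17
significant digits) so a write/read round trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .plates import LuminescenceTrace, PlateExperiment

__all__ = ["read_traces", "write_traces", "TRACE_COLUMNS"]

TRACE_COLUMNS = ("well", "time_h", "signal_cps", "reporter", "genotype", "replicate")


def write_traces(experiment: PlateExperiment, path: str | Path) -> Path:
    """Write a plate experiment to tidy CSV; returns the path."""
    path = Path(path)
    rows = []
    for w in experiment.wells:
        rows.append(
            pd.DataFrame(
                {
                    "well": w.well,
                    "time_h": w.times_h,
                    "signal_cps": w.signal_cps,
                    "reporter": w.reporter,
                    "genotype": w.genotype,
                    "replicate": w.replicate,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    return path


def read_traces(path: str | Path) -> PlateExperiment:
    """Read a tidy-CSV plate experiment; rows are canonicalised by (well, time).

    Missing columns and non-numeric time/signal entries raise a
    ``ValueError`` naming the offending column and data row number
    (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"well": str, "reporter": str, "genotype": str}, float_precision="round_trip"
    )
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in ("time_h", "signal_cps"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: non-numeric {col} at data row {row}")
        df[col] = vals
    df["genotype"] = df["genotype"].fillna("")
    df = df.sort_values(["well", "time_h"], kind="mergesort").reset_index(drop=True)

    wells: list[LuminescenceTrace] = []
    for well, grp in df.groupby("well", sort=True):
        wells.append(
            LuminescenceTrace(
                well=str(well),
                times_h=grp["time_h"].to_numpy(),
                signal_cps=grp["signal_cps"].to_numpy(),
                reporter=str(grp["reporter"].iloc[0]),
                genotype=str(grp["genotype"].iloc[0]),
                replicate=int(grp["replicate"].iloc[0]),
            )
        )
    times = wells[0].times_h
    interval = float(times[1] - times[0]) if times.size >= 2 else 0.5
    return PlateExperiment(wells=wells, sampling_interval_h=interval)
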