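#!/usr/bin/env python
"""Simulate the two fusion-reporter channels and derive the half-lives.

Integrates the forced linear ODE model with the reference parameters
(k1 = 50 cps/h, k2 = 0.08 1/h, k3 = 0.0121 1/h, k4 = 0.15 1/h,
a = 0.004 1/h, 25 h forcing) over 6 days at 30-min sampling, writes the
noiseless observed NL and FLUC traces to a tidy CSV, and reports the
half-lives implied by the decay constants.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from lucikit import (
    LuminescenceTrace,
    PlateExperiment,
    ReporterParams,
    derived_half_lives,
    simulate,
    write_traces,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--duration", type=float, default=144.0, help="hours")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    params = ReporterParams()
    times = np.arange(int(round(args.duration / 0.5)) + 1) * 0.5
    tr = simulate(params, times)

    exp = PlateExperiment(
        wells=[
            LuminescenceTrace("W01", times, tr.observed_NL, "NL", "model", 1),
            LuminescenceTrace("W02", times, tr.observed_FLUC, "FLUC", "model", 1),
        ]
    )
    out_csv = write_traces(exp, args.outdir / "model_traces.csv")

    hl = derived_half_lives(params)
    (args.outdir / "derived_half_lives.json").write_text(
        json.dumps(hl, indent=2, sort_keys=True) + "\n"
    )

    print(f"wrote {out_csv} ({len(times)} timepoints per channel)")
    print("half-lives implied by the decay constants (hours):")
    print(f"  fusion partner (BOA, ln2/k2): {hl['BOA']:.2f}")
    print(f"  NanoLUC activity (ln2/k3):    {hl['NL_activity']:.1f}")
    print(f"  FLUC activity (ln2/k4):       {hl['FLUC_activity']:.2f}")
    print(
        "the stable NanoLUC fusion is dominated by partner degradation "
        "(k2 >> k3); the FLUC channel is dominated by reporter decay (k4 > k2)"
    )


if __name__ == "__main__":
    main()
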