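#!/usr/bin/env python
"""Rhythm analysis of a simulated plate experiment, and model refitting.

Generates a noisy 96-hour plate experiment (four NL and four FLUC wells,
5% multiplicative noise plus photon counting over 1.5 s), estimates period,
phase and relative amplitude per well with the FFT-seeded cosine fit, and
refits the ODE model's free parameters (k1, k2, k4) to the replicate-mean
traces with k3 fixed to its independently measured value.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lucikit import (
    NoiseModel,
    ReporterParams,
    WellDesign,
    estimate_rhythm,
    fit_model,
    generate_plate_experiment,
    write_traces,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    params = ReporterParams()
    design = [WellDesign("NL", "BOA-NL", r) for r in range(1, 5)] + [
        WellDesign("FLUC", "BOA-FLUC", r) for r in range(1, 5)
    ]
    noise = NoiseModel(multiplicative_cv=0.05, counting_integration_s=1.5)
    exp = generate_plate_experiment(params, design, 96.0, 0.5, noise=noise, seed=args.seed)
    write_traces(exp, args.outdir / "plate_experiment.csv")

    rows = []
    for w in exp.wells:
        fit = estimate_rhythm(w.times_h, w.signal_cps)
        rows.append({"well": w.well, "reporter": w.reporter, **dataclasses.asdict(fit)})
    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "rhythm_fits.csv", index=False)

    summary = table.groupby("reporter")[["period_h", "relative_amplitude"]].mean()
    print("per-reporter means over 4 replicate wells:")
    for rep, row in summary.iterrows():
        print(f"  {rep:5s} period {row['period_h']:6.2f} h, "
              f"relative amplitude {row['relative_amplitude']:.3f}")
    print("both reporters oscillate at the 25 h forcing period; the unstable FLUC "
          "fusion shows the higher relative amplitude")

    mean_nl = np.mean([w.signal_cps for w in exp.by_reporter("NL")], axis=0)
    mean_fluc = np.mean([w.signal_cps for w in exp.by_reporter("FLUC")], axis=0)
    start = dataclasses.replace(params, k1=80.0, k2=0.12, k4=0.25)
    refit = fit_model(exp.times_h, mean_nl, mean_fluc, start)
    rec = {
        "converged": refit.converged,
        "params": dataclasses.asdict(refit.params),
        "stderr": refit.stderr,
        "residual_norm": refit.residual_norm,
    }
    (args.outdir / "model_refit.json").write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
    print(f"model refit (k3 fixed at {params.k3}): k1 = {refit.params.k1:.2f}, "
          f"k2 = {refit.params.k2:.4f}, k4 = {refit.params.k4:.4f} "
          f"(true 50, 0.08, 0.15; converged = {refit.converged})")


if __name__ == "__main__":
    main()
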