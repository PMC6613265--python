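#!/usr/bin/env python
"""Calibration-curve analysis: linearity, matrix inhibition, aged calibrator.

Generates 10-fold dilution ladders of a purified calibrator in clean buffer
and in a mildly inhibitory plant-extract matrix (2% measurement CV), fits
log-log calibration curves, quantifies the extract/buffer inhibition ratio,
and demonstrates decay correction when the calibrator ladder was measured a
week after purification.
"""

import argparse
import dataclasses
import json
import math
from pathlib import Path

from lucikit import (
    NoiseModel,
    fit_calibration,
    fraction_remaining,
    generate_dilution_series,
    infer_amount,
    linearity_report,
    matrix_inhibition,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    noise = NoiseModel(multiplicative_cv=0.02, counting=False)
    gain = 1e8
    buffer = generate_dilution_series(0.1, 10, 6, noise=noise, seed=args.seed, gain_cps=gain)
    extract = generate_dilution_series(
        0.1, 10, 6, noise=noise, seed=args.seed + 1, gain_cps=gain,
        matrix_label="plant_extract", inhibition=0.9,
    )

    curves = {label: fit_calibration(s) for label, s in (("buffer", buffer), ("extract", extract))}
    report = linearity_report(extract)
    report.to_csv(args.outdir / "linearity_report.csv", index=False)
    inhibition = matrix_inhibition(extract, buffer)

    # aged-calibrator demonstration: ladder measured 168 h after purification
    rate = math.log(2) / (37.2 * 24.0)
    age = 168.0
    aged = generate_dilution_series(
        0.1, 10, 6, noise=noise, seed=args.seed + 2,
        gain_cps=gain * fraction_remaining(rate, age),
    )
    aged_curve = fit_calibration(aged)
    true_conc = 0.004
    unknown_signal = gain * true_conc
    naive = infer_amount(unknown_signal, aged_curve).concentration
    corrected = infer_amount(unknown_signal, aged_curve, age, rate).concentration

    rec = {
        "curves": {k: dataclasses.asdict(v) for k, v in curves.items()},
        "matrix_inhibition_ratio": inhibition,
        "max_step_deviation": float(report["deviation"].max()),
        "aged_calibrator": {
            "age_h": age,
            "true_concentration": true_conc,
            "inferred_uncorrected": naive,
            "inferred_corrected": corrected,
        },
    }
    out = args.outdir / "calibration_analysis.json"
    out.write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")

    print(f"buffer curve:  slope {curves['buffer'].log10_slope:.3f}, r^2 {curves['buffer'].r_squared:.4f}")
    print(f"extract curve: slope {curves['extract'].log10_slope:.3f}, r^2 {curves['extract'].r_squared:.4f}")
    print(f"signal drops ~10x per dilution step (max step deviation {rec['max_step_deviation']:.1%})")
    print(f"extract/buffer ratio at matched dilution: {inhibition:.3f} (mild matrix inhibition)")
    print(f"week-old calibrator: uncorrected estimate {naive:.5f} overstates the true "
          f"amount {true_conc}; decay-corrected estimate {corrected:.5f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
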