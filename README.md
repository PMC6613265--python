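# lucikit

Kinetic modelling and analysis of luciferase protein-fusion reporters.

Bioluminescent reporters are the workhorse of plant chronobiology: a
luciferase coding sequence fused in frame to a clock protein makes light
output track fusion-protein abundance over days of free-running rhythms.
But the two common enzymes behave very differently — firefly luciferase
(FLUC) is post-translationally unstable in planta, while NanoLUC is so
stable that its signal integrates over the history of expression. `lucikit`
is a quantitative companion for interpreting such experiments. It provides:

- **a forced linear ODE model** of the two reporter channels,
- **first-order enzyme-stability kinetics** with Q10 temperature transfer
  and calibrator decay correction,
- **log-log calibration curves** from serial dilutions, with linearity and
  matrix-inhibition diagnostics,
- **rhythm analysis** (period, phase, amplitude) via an FFT-seeded cosine
  least-squares fit, and
- **a seeded synthetic plate-reader generator** so every stage is testable
  without laboratory data.

## The model

Each reporter channel is a single state (enzymatically active fusion
protein, in plate-reader counts per second) driven by a shared periodic
translation input and removed by first-order decay:

```
dc_NL/dt   = k1 exp(sin(2π t / 25 + 10)) − (k2 + k3) c_NL
dc_FLUC/dt = k1 exp(sin(2π t / 25 + 10)) − (k2 + k4) c_FLUC
```

with `k1` the translation rate (cps h⁻¹), `k2` the degradation rate of the
fused clock protein (BOA), and `k3`, `k4` the activity decay rates of
NanoLUC and FLUC (h⁻¹). The observed NL signal is additionally damped by
slow substrate (furimazine) depletion, `obs_NL = c_NL e^(−a t)`. Reference
values: k1 = 50, k2 = 0.08, k3 = 0.0121, k4 = 0.15, a = 0.004.

Because the system is linear, each channel is a first-order low-pass filter
of the same input with gain `δ/√(δ² + ω²)` at the forcing frequency
`ω = 2π/25`, where `δ = k2 + k_reporter`. The FLUC channel (δ = 0.23 h⁻¹,
gain ≈ 0.675) therefore shows high-amplitude rhythms while the NanoLUC
channel (δ = 0.0921 h⁻¹, gain ≈ 0.344) is rhythmic but flattened — the
half-lives behind this are ln2/k2 = 8.66 h for the fusion partner,
ln2/k3 ≈ 57 h for NanoLUC activity and ln2/k4 ≈ 4.6 h for FLUC.

## Worked example

```python
import numpy as np
from lucikit import ReporterParams, simulate, estimate_rhythm, relative_amplitude

params = ReporterParams()                  # reference constants
t = np.arange(145) * 0.5                   # 72 h at 30-min sampling
tr = simulate(params, t)                   # starts on the periodic steady state

for name, signal in [("NL", tr.observed_NL), ("FLUC", tr.observed_FLUC)]:
    fit = estimate_rhythm(t, signal)
    print(name, round(fit.period_h, 2), round(relative_amplitude(fit), 3))
```

prints

```
NL 25.0 0.306
FLUC 25.05 0.602
```

— both channels oscillate at the 25 h forcing period (a linear system
cannot change its input period), and the unstable FLUC fusion has roughly
twice the relative amplitude of the stable NanoLUC fusion, which is exactly
the filter-gain prediction above.

The numbered scripts under `analysis/` run the full story and write their
tables to `results/`: `01_simulate_reporters.py` (model traces and derived
half-lives), `02_enzyme_stability.py` (37.2-day calibrator half-life fit,
storage-retention fractions, Q10 transfer to 21 °C),
`03_calibration_curves.py` (dilution-ladder linearity, ~0.9 extract/buffer
inhibition ratio, aged-calibrator decay correction) and
`04_rhythm_analysis.py` (per-well rhythm fits on a noisy synthetic plate
and a parameter refit recovering k1, k2, k4). There is also a CLI:

```
lucikit run --config examples/demo.yaml --outdir results/demo
lucikit fit-decay my_decay.csv
lucikit rhythm my_traces.csv
```

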