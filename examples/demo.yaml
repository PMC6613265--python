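# Demo pipeline configuration: run with
#   lucikit run --config examples/demo.yaml --outdir results/demo
seed: 7
stages: [generate, fit-decay, calibrate, rhythm]

# reference model constants (1/h except k1 in cps/h); omit to use defaults
model:
  k1: 50.0
  k2: 0.08
  k3: 0.0121
  k4: 0.15
  a: 0.004
  period_h: 25.0
  phase_rad: 10.0

noise:
  multiplicative_cv: 0.02
  counting_integration_s: 1.5

design:
  - {reporter: NL, genotype: BOA-NL, replicate: 1}
  - {reporter: NL, genotype: BOA-NL, replicate: 2}
  - {reporter: FLUC, genotype: BOA-FLUC, replicate: 1}
  - {reporter: FLUC, genotype: BOA-FLUC, replicate: 2}

duration_h: 72
sampling_interval_h: 0.5

decay: {half_life_days: 37.2, span_days: 28, interval_days: 1}
dilution: {top_concentration: 0.1, fold: 10, n_steps: 6, inhibition: 0.9}
period_bounds: [15, 35]
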