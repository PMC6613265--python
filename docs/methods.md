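# Methods

## Reporter model

Each fusion-reporter channel is modelled as one state variable, the
abundance of enzymatically active fusion protein expressed on the
plate-reader's counts-per-second scale, with linear dynamics

    dc/dt = F(t) − δ c,      F(t) = k1 exp(sin(2π t / P + φ)),

where the total removal rate is δ = k2 + k3 for the NanoLUC channel and
δ = k2 + k4 for the FLUC channel. The two channels share the translation
input F(t) exactly; only δ differs. The exp(sin) forcing is a convenient
strictly positive periodic waveform with one dominant harmonic; its phase
φ = 10 is interpreted in radians exactly as it appears inside the sine, and
no wrapping is applied. P = 25 h and φ = 10 are fixed constants of the
model, with model time t = 0 anchored at transfer to constant light.

Assumptions worth keeping in mind: translation is the only source term (no
transcription dynamics), removal is first-order, and the two transgenic
lines differ only in reporter decay rate. Entrainment history and insertion
site effects are outside the model.

Substrate depletion: furimazine slowly decays in the assay medium, so the
observed NL signal is `c_NL · exp(−a t)`. Whether such a depletion term
should act on the state, the forcing or the observation is not decidable
from signal shape alone at these scales; applying it to the observed signal
only is this package's documented convention, chosen because substrate
availability affects light yield, not fusion-protein abundance. The FLUC
channel uses a chemically distinct substrate with its own configurable rate
(default 0).

### Parameters

| name | meaning | unit | default |
|------|---------|------|---------|
| k1 | translation rate | cps·h⁻¹ | 50 |
| k2 | fusion-partner (BOA) degradation | h⁻¹ | 0.08 |
| k3 | NanoLUC activity decay | h⁻¹ | 0.0121 |
| k4 | FLUC activity decay | h⁻¹ | 0.15 |
| a | furimazine depletion (observed NL) | h⁻¹ | 0.004 |
| period_h | forcing period | h | 25 |
| phase_rad | forcing phase | rad | 10 |

The reference table for these constants prints the fusion-partner decay
rate as 0.8 h⁻¹, but the half-life reported for the same protein (8.66 h)
forces k2 = ln2/8.66 = 0.08 h⁻¹. The package treats the printed 0.8 as a
typographic slip: 0.08 is the default, 0.8 remains selectable
(`table1_params(use_printed_k2=True)`), and loading the reference set logs
the discrepancy so it is never silent.

Similarly, k3 = 0.0121 h⁻¹ is the independently measured in-vitro NanoLUC
decay rate transferred to assay temperature, not a fitted value. A naive
Q10 transfer of the 4 °C storage rate (ln2/(37.2 d) ≈ 7.76×10⁻⁴ h⁻¹) to
21 °C with Q10 = 2.5 gives 3.69×10⁻³ h⁻¹, a factor ~3 below 0.0121 (which
corresponds to a 30 °C span, i.e. 2.5³). The package exposes the formulaic
scaling (`q10_scale_rate`) and the reference constant separately and does
not guess which the original fit intended; the fitted dynamics are
insensitive to this choice because k2 ≫ k3 either way.

### Numerics

`simulate` integrates with SciPy's adaptive RK45 at rtol 1e-9 (the system
is non-stiff at reference scales); accuracy is verified in the tests
against an integrating-factor quadrature oracle
c(t) = c0·e^(−δt) + ∫ e^(−δ(t−s)) F(s) ds to better than 1e-6 relative
over 100 h. Initial conditions are not observable in entrained plants, so
the default start is the periodic steady state at t0, computed from the
one-period fixed point c* = r/(1 − e^(−δP)) where r is the zero-start
one-period response — exact for a linear channel and needing a single
one-period integration. A zero-start option exists for transient studies.
`periodic_steady_state` instead iterates period over period until
successive traces agree to 1e-8 relative, which doubles as an independent
check of the fixed-point construction.

Useful closed forms used as test anchors: the period-mean of the steady
state is k1·I₀(1)/δ (I₀ the modified Bessel function, the mean of
exp(sin)), and the relative-amplitude transfer at the fundamental is the
first-order filter gain δ/√(δ² + ω²), ω = 2π/P — 0.675 for the FLUC
channel and 0.344 for the NL channel at reference values.

### Fitting

`fit_model` minimises the joint sum of squared residuals of both observed
channels over a chosen free-parameter subset (default k1, k2, k4 with k3
fixed to its measured value, mirroring the original procedure) using
bounded trust-region least squares, all rates constrained non-negative.
Finite-difference steps are set to 1e-4 relative — well above the
integrator tolerance — so Jacobians are not dominated by solver noise.
With one channel only the total rate δ is structurally identifiable;
near-perfect parameter correlations (|r| > 0.999, or an exactly singular
normal matrix) are reported as `degenerate_pairs` rather than hidden, and
optimizer non-convergence is flagged in the result, not raised.

## Enzyme stability and calibration

The stability estimator is ordinary least squares of ln(activity) on time
(rate = −slope, half-life = ln2/rate), deliberately matching the standard
log-linear analysis; the regression is unweighted because no error model is
asserted for the activity measurements, and a nonlinear exponential fit is
provided for comparison only. A fitted rate ≤ 0 yields an infinite
half-life with a `no_decay` flag instead of an exception, since flat series
are a legitimate outcome for a stable enzyme. Rates are stored in h⁻¹; day
conversion happens only at presentation.

Calibration fits log10(signal) on log10(relative concentration) after
excluding zero and saturated readings (the ceiling is user-supplied; there
is no default because saturation is instrument-specific). Inference inverts
the fitted line; signals outside the fitted range are flagged as
extrapolation but still inverted. When the calibrator ladder was measured
at age t, its active content was only f = e^(−kt) of nominal, so the curve
over-reads fresh unknowns by 1/f irrespective of the fitted slope; the
corrected estimate multiplies the raw inversion by f. The direction of this
correction is pinned by an executable end-to-end test (aged ladder →
curve → fresh unknown → recovery of the true amount) rather than prose.

## Rhythm analysis

`estimate_rhythm` is a single-component functional analogue of the
FFT-NLLS family: linear detrend, period seed from the maximum of an
8×zero-padded discrete Fourier spectrum within the period bounds (default
15–35 h, the circadian band), then nonlinear least squares of
mean + trend·t + A·cos(2πt/period + φ). One cosine suffices because the
traces analysed here have a single dominant circadian component over ≤ 4
cycles; exponential damping terms and multi-component fits are deliberately
out of scope. Uniform sampling is required and irregular grids are rejected
rather than silently resampled. Phase is reported at t = 0 on the cosine
convention in (−π, π], with circular wrapping for phase differences. A
spectral peak below 1e-9 of the signal scale is numerical noise on a flat
trace and yields a non-converged result (amplitude 0) instead of an
exception, so batch analyses of arrhythmic wells keep running. Note that a
linear detrend of a finite cosine segment leaves a small residual line
(the t·cos integral does not vanish over whole cycles); the NLS stage
absorbs this because trend and cosine are fit jointly.

## Synthetic data generator

The generator emulates a 96-well luminometer experiment: 30-min sampling
with 1.5 s photon-counting integration per well, signals in cps, replicate
wells sharing one time grid. Noise is applied per timepoint in three
stages — Poisson counts over the integration window, a unit-mean
log-normal multiplicative factor with stated CV (pipetting/position
variation; default CVs of 2% for in-vitro assays and 5% for plant wells),
then an additive background — with one explicitly seeded RNG stream per
generated object and no global state. Stability series are exact
exponentials and dilution ladders exact power laws before noise, so
noiseless generation followed by the corresponding fit recovers generating
parameters to numerical tolerance; this round trip is the backbone of the
test suite.

What the generator does not emulate: spatial plate effects (edge wells,
optical crosstalk), camera imaging, entrainment transients, damping of
rhythm amplitude over long runs, and well-to-well biological variance
beyond the multiplicative noise. Passing tests therefore demonstrate
correctness of the estimators on data satisfying the model assumptions,
not robustness to every artefact of real plates.

Replicate counts per line are configurable (default 4 for the plate
demonstrations, 2 in the pipeline demo) since no fixed experimental design
is asserted.

## Problem sizes

Default analyses use 72–96 h traces at 0.5 h sampling (145–193 points),
29-point stability series, 6-step ladders, and Monte-Carlo suites of
50–200 seeds — sizes chosen so every property is measured with comfortable
statistical margin while the whole suite stays quick on a laptop.

## Known limitations

- The ODE model has no transcription stage, so it cannot separate
  transcriptional from translational regulation.
- Absolute protein amounts are out of scope; calibration is on the
  relative dilution-factor scale.
- The rhythm fitter assumes one dominant periodic component; strongly
  damped or multi-periodic traces need a richer model.
- Q10 transfer is a coarse two-point rule, not Arrhenius fitting.
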