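# Methods

## Models

All three exchange networks are linear, first-order compartmental systems
driven by a pyruvate delivery function P_in(t) and damped by *effective*
relaxation rates r_i that absorb both longitudinal T1 decay and the
polarization spent by RF excitation:

- **2-site**: dP/dt = P_in − (r_P + k_PL)P + k_LP·L;
  dL/dt = k_PL·P − (r_L + k_LP)L.
- **3-site**: pyruvate exchanges with *intracellular* lactate L_I, which
  is transported to/from an extracellular pool L_E at rates k_LE (efflux)
  and k_EL (influx); both lactate pools share one r_L, and the observed
  lactate is L_I + L_E. Pyruvate uptake (MCT1) is treated as
  instantaneous, lactate transport (MCT4) as a measurable process — the
  transporters' relative affinities justify the asymmetry.
- **Alanine-extended 2-site**: adds dA/dt = k_PA·P − (r_A + k_AP)A with
  matching terms in the pyruvate equation. By default k_AP = 0 (fitted
  only on request): the reverse flux is generally starved of substrate on
  the experiment's timescale, and freeing it degrades identifiability.

Initial conditions are zero in every compartment: no hyperpolarized
product exists before the bolus. The in vitro "missing first points"
regime is produced by *truncating* simulated records, never by nonzero
initial states.

### RF loss

The continuous-loss form r = 1/T1 − ln(cos θ)/TR converts the per-pulse
survival factor cos θ into an exponential rate, which is what lets a
single effective r_i appear in the rate equations. A discrete-pulse
simulator mode (intrinsic 1/T1 between pulses, ×cos θ at each
excitation) is provided as a cross-check; at the 10–20° flip angles and
TR ≈ 2 s used here the two conventions differ by a few percent on the
curves and negligibly on AUC ratios. The difference is a property of the
approximation and is documented rather than asserted.

### Integration

Because the systems are LTI, the engine diagonalises the (2–3
dimensional) rate matrix once and evaluates the driven solution through
closed-form convolution integrals of each eigenmode with the input shape
(instantaneous bolus, rectangle, raised cosine). The result is exact at
the sample points up to eigensolver round-off (~1e-14 relative), so
grid-refinement and linearity checks pass trivially and fitting is fast
(~10⁻⁴ s per simulation). Degenerate or zero eigenvalues — possible only
on a measure-zero set of rate combinations — are nudged by a
deterministic 1e-9 relative perturbation of the decay rates, far below
every tolerance used anywhere in the package. Tabulated (`sampled`)
inputs fall back to LSODA at rtol 1e-8.

## AUC ratio

The discrete estimator is the plain ratio of sample sums (the uniform
spacing cancels), matching how summed peak areas are used in practice; a
trapezoidal option covers non-uniform grids. Numerical caveats:

- For *smooth* inputs starting inside the grid, both curves begin and end
  at ~0 and the sum is effectively a trapezoidal rule; at TR = 2 s the
  discretization error on the ratio is ≪ 0.5%.
- For an *instantaneous* bolus the pyruvate curve jumps, and the plain
  sum over-counts by ~λ_P·dt/2. Identity tests that mix a delta input
  with smooth ones therefore run on a dt = 0.05 s grid; in vitro-style
  records (delta bolus, TR 2 s) carry this bias in their *raw* ratio,
  which is precisely the situation the model-derived corrected ratio
  addresses.
- "Full decay" for validity tests means integrating to ~32 e-foldings of
  the slowest eigenmode (computed from the rate matrix, not guessed).

The closed-form predictions are k_PL/(r_L + k_LP) (2-site; also the
alanine-extended model, whose branch never enters the lactate equation)
and k_PL/(r_L + γ·k_LP) with γ = (k_EL + r_L)/(k_LE + k_EL + r_L)
(3-site). γ ∈ (0, 1], decreasing in efflux, increasing in influx, and
exactly 1 without transport, where the 3-site expression reverts to the
2-site one identically.

## Fitting

Maximum likelihood under independent, equal-variance Gaussian noise per
timepoint reduces to (weighted) least squares on the concatenated
metabolite channels. Choices that matter:

- **Log-rates**: all rate constants are optimised as logarithms (bounds
  1e-6–10 /s), keeping iterates positive without constraints.
- **Multi-start**: 8 starts (trust-region reflective least squares)
  around moment-based guesses — k_PL from the raw ratio times the
  nominal denominator, input scale from the pyruvate sum times its decay
  rate — with seeded log-normal perturbations; deterministic for a fixed
  seed.
- **r_P is fixed** from the acquisition (T1 + RF loss) by default
  because it trades off against the input shape; r_L is fitted by
  default since it sits in the ratio denominator. Both are switchable.
- **Input handling**: in vitro fits use an instantaneous bolus at a
  fitted lead time (0–60 s) before the first retained sample, which is
  how the fit "interpolates back" through truncated records; in vivo
  fits co-estimate a raised-cosine bolus (amplitude, onset, duration);
  a known input can be fixed.
- **Cost schemes**: `least_squares` is plain SSR. `modified` divides
  each channel by its peak absolute value so the small lactate (and
  alanine) signals are not swamped by pyruvate — this is the package's
  own reconstruction of a variance-stabilising in vitro weighting, kept
  pluggable and versioned; it coincides with plain SSR when channels
  share a scale.
- **Uncertainties** are Gauss–Newton standard errors from the Jacobian
  at the optimum, propagated from log- to natural units.
- A record with an identically zero lactate channel is flagged
  non-converged (k_PL unidentifiable) instead of returning arbitrary
  numbers.

## Synthetic data

The generator reproduces the statistical structure the analyses assume,
with defaults fixed to the two experimental regimes:

- **in vitro**: 10° flip, TR 2 s, 128 spectra; T1(P/L/A) = 65/45/30 s
  (solution values at high field), giving effective r_P ≈ 0.023 /s and
  r_L ≈ 0.030 /s; instantaneous bolus 4–12 s before acquisition
  (injection happens outside the magnet, with jittered handling delay);
  first ~3–5 samples optionally truncated.
- **in vivo**: 20° flip, TR 2 s, 128 spectra; shorter T1s (40/27/25 s);
  raised-cosine bolus over ~5 s; alanine present.

Noise is additive white Gaussian per timepoint, with σ expressed as a
fraction of the pyruvate peak (default 1% for cohorts). Spectra use
unit-area Lorentzian lineshapes (default linewidth 0.2 ppm — a plausible
placeholder; real linewidths and SNR are not specified by the
experiments being emulated) at 171 (pyruvate), 177 (alanine), 179
(pyruvate hydrate, a non-exchanging spectator tracking 6% of the
pyruvate curve) and 183 ppm (lactate), on a descending ppm axis. Peak
integration windows default to ±5 linewidths with an analytic correction
for the Lorentzian tail mass outside the window, so render→integrate
round-trips close to within ~2% (the residue being cross-peak bleed).
Spectral noise is Gaussian, not Rician: peak *areas* are linear sums, so
the Gaussian model is the relevant one.

Cohorts draw k_PL uniformly from a range (default 0.005–0.04 /s) with a
near-constant denominator (k_LP = 0.008, r_L = 0.030 /s fixed), which is
the regime in which the AUC ratio is a useful linear proxy for k_PL; the
per-subject truth table records all generating parameters and the
closed-form true ratio.

What the generator does **not** emulate: B₀/B₁ artifacts, phasing and
baseline errors, Rician magnitude noise, saturable (non-first-order)
enzyme kinetics, physiological drift, or inflow of labelled metabolites
from surrounding tissue. Passing tests therefore demonstrate correctness
of the estimators and fits under the stated model assumptions, not
robustness to every artifact of real spectra.

## Problem sizes

Tests and the validation suite run 128-point records at TR 2 s (the
standard dynamic series), identity checks on ≥20 randomized rate sets
per model, noisy parameter recovery over 20 replicates, and cohorts of
n = 24 subjects — sizes chosen to match the emulated experiments while
keeping the whole suite interactive (~15 s plus a few seconds of fits).

## Known limitations

- The 2-site model approximates 3-site total-lactate curves to ~3×10⁻⁴
  relative, so distinguishing the models by residual structure requires
  very high SNR; the residual-diagnostic tests run near that regime.
- Three-site fits from total lactate alone recover k_PL well but k_LE
  and k_EL only loosely (they are weakly identifiable without separate
  intra/extracellular measurements).
- The linear-extrapolation correction for missing first points (as
  opposed to the model-derived correction) is deliberately not
  implemented.
- Peak-maximum ratio methods are out of scope beyond the AUC machinery.
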