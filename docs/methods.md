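# Methods

## The three-state sensor model

States: S1 unbound/bright, S2 ligand-bound/bright, S3 dark conformer.
Occupancies `x = (f1, f2, f3)` evolve as `dx/dt = Q(c) x` with

```
Q(c) = [[-k12·c,        k21,       0  ],
        [ k12·c, -(k21+k23),      k32 ],
        [     0,        k23,     -k32 ]]
```

at fixed molar concentration `c`. The chain satisfies detailed
balance, so `Q` is similar to a symmetric matrix and its spectrum is
real: one zero mode (conservation) and two negative relaxation rates.
`propagate` uses the eigendecomposition analytically; a dense matrix
exponential and a fine-step Euler integrator serve as independent
oracles in the tests, not as the default path.

Assumptions: S1 and S2 are equally and fully bright and only S3 is
dimmed, to relative brightness ε — the intensity change is attributed
to the conformational step, not to binding. Whether S2 is partially
dimmed cannot be decided from summary kinetics alone; applying ε to S3
only is a package decision. Fluorescence is
`F = f_base · (1 + ΔF/F)` with `ΔF/F = −(1−ε)·f3`. No desensitization,
internalization or downstream coupling is modelled.

Closed forms used throughout:

- steady state by detailed balance: `f2/f1 = (k12/k21)·c`,
  `f3/f2 = k23/k32`;
- apparent affinity `K_app = (k21/k12)·k32/(k23+k32)`;
- saturating dark fraction `f3_max = k23/(k23+k32)`;
- washout (OFF) rate = slow eigenvalue of the 2×2 block
  `[[−(k21+k23), k32], [k23, −k32]]`, independent of the application
  concentration.

## The reference parameter set

`REFERENCE_SCHEME` / `REFERENCE_FLUOR` freeze one parameter set used
by the acceptance checks and examples:

| parameter | value | provenance |
|---|---|---|
| k23 | 20 s⁻¹ | experimentally fitted isomerization rate |
| k32 | 4 s⁻¹ | experimentally fitted isomerization rate |
| k12/k21 | 1.5×10⁶ M⁻¹ | midpoint of the fitted 1–2×10⁶ M⁻¹ range |
| k12 | 10⁸ M⁻¹ s⁻¹ | a choice above the experimental lower bound of 3×10⁷ M⁻¹s⁻¹; the data bound k12 from below only |
| ε | 0.124 | solves (1−ε)·f3_max = 0.73, the measured saturating \|ΔF/F\| |

With these values the model reproduces the measured characteristics it
was checked against: K_app = 111 nM (~100 nM at 1 s.f.), slow
eigenvalues giving τ_ON ≈ 41.9 ms at 100 µM and τ_OFF ≈ 328.6 ms
(measured: 43.5 ± 9.7 ms and 323 ± 61.5 ms).

## Synthetic-data generators

Every generator is a pure function of (config, seed) and emits ground
truth (occupancies, latent concentration, per-ROI traces) alongside
the observations, so downstream recovery is testable quantitatively.

- **Patch sweeps**: 91 Hz sampling (10 ms exposure; 194 Hz available
  via `SamplingConfig`), 1 s applications (longer for low
  concentrations), 6–8 sweeps — the design of fast-perfusion
  fluorometry. Solution exchange is instantaneous (experimentally
  sub-millisecond, i.e. faster than one frame). Camera sampling is
  instantaneous at frame times; exposure integration is not modelled —
  at 91 Hz its effect on a 42 ms exponential is far below the fit
  tolerances used here.
- **Titrations**: closed-form steady states plus i.i.d. Gaussian
  replicate noise; 20 replicates by default, matching typical
  titration group sizes.
- **Pulse trains**: each pulse adds a fixed latent-concentration
  increment that clears mono-exponentially; the summed latent c(t)
  drives the sensor through a piecewise-constant analytic propagation
  at 0.5 ms internal resolution.
- **In vivo sessions** (~30.3 fps): alternating exponential run/rest
  bouts; latent serotonin = tonic baseline (80 nM, near K_app so both
  signs of modulation are visible) + biphasic stimulation transients
  (difference-of-exponentials with a slow opposite lobe — a modelling
  choice to produce the dip-then-overshoot shape, not a measured
  kernel) + reward transients + a locomotion term that is high at rest
  and low while running, relaxing with a 1 s time constant. Default
  stimulation trains: 9 pulses spaced 20 s.
- **ROI stacks**: uniform background plus per-ROI traces inside
  disk/annulus masks (0-based, row-major, inclusive); overlapping ROIs
  warn and sum.

Noise defaults: Gaussian s.d. 1% of baseline, no drift, no bleaching —
recordings of this kind do not come with published noise magnitudes,
so these are explicit, overridable choices. What passing tests on
these data do **not** show: robustness to motion artifacts, hemodynamic
or focus drift, photobleaching nonstationarity, or non-Gaussian camera
noise, none of which the generators emulate.

## Trace analysis

- ΔF/F = (F−F₀)/F₀ with F₀ the mean over the annotated pre-application
  window (the whole pre-application segment by default); a
  non-positive F₀ raises, signalling missing background subtraction.
- Baseline correction subtracts a linear fit over the pre-application
  segment (the onset sample itself is excluded).
- Exponential fits are least-squares `offset + A·exp(−t/τ)` (lmfit).
  The ON window starts at the first sample after application onset —
  exchange is faster than one frame, so that sample already carries
  signal. Deliberately single-exponential: minor slow phases seen in
  real recordings are ignored. The `converged` flag is honest: a fit
  whose amplitude is indistinguishable from the residual noise
  (|A| < max(2·RMS, 10⁻⁶·scale)) is reported non-converged rather than
  returning a meaningless τ.
- Hill fits use `max·cⁿ/(cⁿ+K_dⁿ)` with n free by default (fixable);
  they require ≥ 4 distinct concentrations actually spanning the
  transition. Internally ΔF/F is signed (negative = darkening);
  `DoseResponseData` stores the positive magnitude −ΔF/F, and the two
  conventions never mix.

## Global scheme fitting

The fit operates at the summary level — τ_ON(c), τ_OFF, steady |ΔF/F|
per concentration — matching what such experiments report, not raw
traces. Objective: weighted least squares with inverse reported
uncertainties (unit block weights scaled by each observable's typical
magnitude when uncertainties are absent); the objective choice is a
package decision since no canonical one exists for this problem.
Parameters are optimized in log space as (k12, K_A = k12/k21, k23,
k32) plus linear ε, with 8 seeded multi-starts (one heuristic start
built from the data, the rest log-uniform in the bounds).

Identifiability: at the protocol concentrations the binding relaxation
(k12·c + k21) is several-fold faster than the isomerization step, so
the data determine K_A, k23, k32 and ε but bound k12 only from below.
`fit_scheme` probes this by refitting with k12 pinned one decade
higher; `profile_identifiability` does the full profile. A direction
counts as flat when the cost rise per decade is below
max(2% of the optimum, the cost of a 2% rms shift of the weighted
observables) — the second term handles noise-free data whose optimum
is numerically zero. Because of the flat k12 direction, k21 = k12/K_A
is a point estimate only in the `fix_k12` mode; with k12 free the
invariant quantity is the binding ratio.

## In vivo analysis

- Detrend (linear by default, polynomial optional) then optional
  centred moving-average smoothing; the speed channel is never touched.
- z-score with the **population** s.d. of the whole processed trace —
  at session lengths the sample/population difference is immaterial,
  but fixing it makes outputs deterministic.
- Event-triggered averages use a −1.5/+2.5 s window; events not fully
  covered are excluded with a log entry.
- Reward comparison: baseline = mean of the 6 samples immediately
  preceding delivery (−0.198 to 0 s at 30.3 Hz), post = mean over
  +0.5 to +0.7 s; paired medians and a Wilcoxon signed-rank test.
- Speed gate: running means speed strictly > 3 cm/s; samples exactly
  at threshold count as rest. Empty classes flag rather than raise.
- Movement stops: ≥ 4 s continuous running, then a sub-threshold
  sample followed by ≥ 4 s without any supra-threshold sample.
- Stop decay: stop-triggered average over 4 s, min–max scaled to
  [0,1], second-degree polynomial fit; τ is the time at which the
  fitted curve first crosses one half of its range. The half-crossing
  convention is a documented choice — a quadratic has no intrinsic
  time constant — and for an exponential of τ = 1.24 s it returns
  0.89 s, within 10% of the exponential half-time τ·ln 2 = 0.86 s.

## Numerical choices and degenerate inputs

- Concentrations in molar and times in seconds everywhere; conversion
  only at I/O boundaries (column names carry units).
- Occupancy conservation holds to 1e−10; propagation agrees with the
  matrix-exponential oracle to better than 1e−6.
- Exponential-fit τ bounds: [0.01 frame, 100× window]; Hill K_d
  bounds: 4 decades beyond the sampled range; ties in the stop
  detector and speed gate resolved as stated above.
- Degenerate inputs raise early with specific messages: constant
  traces for z-scoring, empty ROI masks, < 4 Hill concentrations,
  < 3 fit concentrations, non-uniform time grids.

## Problem sizes

Tests and the acceptance script use the protocol-scale designs above
(410-sample sweeps, 6-concentration summaries, 8-point titrations,
4-minute sessions); they complete in seconds and the results quoted in
the README are the scripts' actual output.

## Known limitations

- k12 (and hence k21) is not a point estimate from summary kinetics;
  only its lower bound and the binding ratio are.
- The in vivo generator's serotonin kernels are phenomenological;
  recovered event shapes validate the pipeline, not the biology.
- The raw-trace global fit (`fit_scheme_raw`, fitting the model
  directly to dF/F samples) is an optional mode; the summary-level fit
  is the supported default and the only one with identifiability
  probing.
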