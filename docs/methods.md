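# Methods

## The model

`movelements` analyses upper-limb movement recordings under the hypothesis
that continuous movement is composed of discrete, bell-shaped velocity pulses
("movement elements"). The quantitative backbone is cost-of-time optimal
control: a point-to-point movement of displacement D that minimises

    I = t_f + K * ∫ (jerk)^2 dt

with rest boundary conditions has closed-form consequences

* duration law: `t_f = (60 D)^(1/3) * K^(1/6)`
* velocity profile: `v(t) = D (30 s^4 − 60 s^3 + 30 s^2) / t_f`, `s = t/t_f`
  (position is the quintic `D (6 s^5 − 15 s^4 + 10 s^3)`)
* mean-speed law: `v̄ = D^(2/3) / (60^(1/3) K^(1/6))`

K, the cost-of-time constant, prices duration against smoothness. Since
`v̄ = D / t_f`, the duration law forces mean element speed to scale with
displacement to the power 2/3. On a log-log plot of v̄ against |D| the model
therefore predicts a straight line of slope α = 2/3, and the fitted slope is
the package's central statistic. The variational problem itself is not solved
here; only these closed forms are implemented.

For planar drawing the package also fits the classical kinematic laws
`v ≈ k_v r^(1/3)` (speed vs. radius of curvature) and the equivalent
`|dθ/dt| ≈ k_θ C^(2/3)` (angular speed vs. curvature). A harmonic ellipse
(x = a cos ωt, y = b sin ωt) satisfies both exactly and serves as the
canonical validation input.

## Pipeline

1. **Read** a delimited trajectory table (time + x/y/z position columns;
   internal units mm and s, conversions applied on read). Uniform sampling,
   monotone time and axis lengths are validated with specific error types.
2. **Low-pass** each axis with a 4th-order Butterworth at 10 Hz, applied
   forward–backward (`sosfiltfilt`, even-reflection padding). Zero phase is
   essential: a causal filter would delay every zero crossing and corrupt
   t_f, hence K ∝ t_f^6. Cutoff and order are configurable.
3. **Differentiate** by central differences (one-sided at the series ends).
   The scalar step 1/rate is used rather than the time vector: the
   non-uniform-spacing weights of a general gradient turn exactly constant
   rest into ±1e-13 velocity chatter that fragments rest periods into
   spurious micro-elements.
4. **Segment** each axis's velocity at zero crossings. Sign changes between
   nonzero samples are interpolated linearly. An isolated exact-zero sample
   is itself a crossing. A run of two or more exact zeros is a rest period:
   it contributes boundaries at both ends and the span in between is dropped.
5. **Filter** elements with task thresholds (below).
6. **Fit** each kept element against its own theoretical profile (Pearson
   correlation; no free parameters — D and t_f come from the segmentation),
   invert the duration law for per-element K, regress log10 v̄ on log10 |D|
   for α, and summarise per task (mean ± sample SD).

### Sub-sample rest boundaries

K ∝ t_f^6 makes crossing-time accuracy the dominant error source. Central
differences smear a rest-to-movement junction: the two moving samples whose
difference window straddles the boundary are biased, and wherever the window
does not straddle it the estimate carries a constant offset (dt²/6)·v″.
A movement leaving rest smoothly has v ≈ c·τ² near the boundary, so the
boundary time is estimated by solving `v = c((t − t0)² + dt²/3)` on the two
nearest bias-free samples (the two straddling samples are dropped; plain
secant extrapolation is the fallback when fewer samples exist). This reduces
the systematic t_f error from ≈2·dt to well under dt/10, which is what makes
mean K recoverable to a few percent at 100 Hz for sub-second elements. The
cost is that the smear sliver at each rest junction (≈1e-3 mm) is assigned to
neither element, so summed signed displacement matches the whole-series
integral exactly only for sign-change crossings and to ~0.1 mm per recording
across rest junctions.

### Element acceptance thresholds

Task-specific minima for displacement, duration and peak speed discard
elements that could not be detected reliably at realistic signal-to-noise:

| task | min |D| | min t_f | min peak speed |
|---|---|---|---|
| drawing, handwriting | 5 mm | 100 ms | 10 mm/s |
| 3-D reaching | 3 mm | 100 ms | 10 mm/s |
| 1-D ruler movements | 20 mm | 200 ms | 10 mm/s |

The speed threshold is applied to the peak |v| within the element; a
mean-speed test would duplicate the displacement and duration criteria
through v̄ = |D|/t_f. Boundary elements (truncated by the recording's start
or end rather than two crossings) are kept but flagged, and excluded from
scaling fits by default because their t_f is undefined.

## Curvature analyses

Speed, curvature `C = |ẋÿ − ẏẍ| / v³`, radius r = 1/C and the unwrapped
tangent angle are computed with the same central-difference operator.
Samples with v < 10 mm/s or C < 1e-6 mm⁻¹ are masked from log-domain fits
(log blow-ups at near-stationary or near-straight samples). The first and
last two samples are always masked (one-sided stencils), and when the
recording metadata shows a zero-phase low-pass was applied, the guard grows
to 2.5 settling lengths (2.5·rate/cutoff samples) per end — filter-edge
transients on a circle otherwise masquerade as radius variation. A power-law
fit whose regressor spans less than 0.02 decades is reported as degenerate
(a numerically traced circle leaves ~0.1–1% radius spread, so exact zero
variance never occurs). The discrete identity |dθ/dt| = v·C holds to
O((ω·dt)²) — about 1e-3 relative at 100 Hz for the default ellipse — and is
tested together with its quadratic convergence in dt, since no finite-
difference implementation can reach the continuous identity exactly.

## The synthetic task battery

The simulator generates motion-capture-like recordings for each task from
minimum-jerk primitives, with a ground-truth element table alongside every
recording. Every generator is a pure function of its parameters and seed.

* **element / sequence_1d_targets** — chains of min-jerk arches whose
  durations follow the duration law with one shared K, separated by exact
  rest (default 0.3 s; exact rest guarantees clean crossings). The default
  cue sequence emulates pointing at 45 randomly cued marks on a 60-mark
  ruler with 25 mm spacing. Default K = 1e-9 mm⁻²s⁶, which yields 0.27–0.98 s
  elements for 10–500 mm displacements — ordinary human point-to-point
  timing.
* **sequence_1d_no_targets** — near-constant-speed sweeps reversing at cued
  times (intervals uniform in [0.5, 3] s), modelling uncued back-and-forth
  movement where displacement is speed × interval and thus decoupled from
  mean speed. Two deliberate realism choices matter here: a seeded 5%
  lognormal per-segment speed jitter (humans do not hold speed exactly; with
  zero jitter the tiny ramp-induced v̄ shortfall is a deterministic function
  of interval length and the scaling correlation is spuriously ≈1 despite a
  near-zero slope), and per-segment renormalisation so each inter-crossing
  span's mean |v| equals exactly its drawn speed (reversal ramps otherwise
  shave a duration-dependent fraction off v̄, re-coupling the variables the
  scenario exists to decouple).
* **ellipse** — harmonic mode traces x = a cos ωt, y = b sin ωt with the
  half-period set by the duration law for displacement 2a; each repetition
  yields two x-axis elements and the trace satisfies the one-third law
  exactly. Note the y arches share the x timing, so they obey the duration
  law with K·(a/b)², not K: pooling axes mixes two parallel slope-2/3 lines
  offset by (1/3)log10(a/b) and biases a joint OLS slope low. Scaling
  analyses on ellipses are therefore per-axis. A `minjerk_composition` mode
  chains profile-exact arches instead, for exercising the element-fit path.
* **pure_frequency** — shapes with sinusoidal log radius of curvature,
  log r(θ) = ε·sin(νθ), traced at constant affine velocity (v = k·r^{1/3},
  k set so the largest x excursion obeys the duration law). ν = 0 gives a
  circle traced at constant speed.
* **random_3d** — independent per-axis chains of alternating-sign arches
  with log-uniform magnitudes and seeded pauses, desynchronised across axes
  (scribbling in the air).
* **add_noise** — seeded i.i.d. Gaussian position noise per sample and axis;
  0.5 mm emulates optical marker noise.

Generated elements are framed by exact rest so decomposition recovers them
as crossing-bounded; any element spanning fewer than 5 samples raises a
resolution error instead of silently aliasing.

### What the simulator does not emulate

Real recordings contain soft-tissue artefact, marker occlusions and gap
fills, drift, correlated (non-white) noise, overlapping sub-movements
without intervening rest, and within-subject variability of K. Passing
tests on this substrate demonstrates that the measurement pipeline is
unbiased and noise-robust under the model's own assumptions; it does not by
itself establish that human data follow the model.

## Numerical choices and degenerate inputs

* Regressions are OLS on log10-transformed values (`scipy.stats.linregress`);
  summaries use sample (n−1) SDs, reported NaN for a single element.
* Scaling fits need ≥ 3 elements with |D| > 0 and nonzero spread in log|D|.
* All-zero velocity series segment to an empty list with a warning; unknown
  task names, non-monotone or non-uniform time, sub-Nyquist violations and
  zero-variance correlations raise typed errors.
* Problem sizes in the validation suite — 120-element 1D sequences, 3-cycle
  ellipses, 20 elements per axis in 3-D, 5 pooled no-target recordings —
  are chosen so every stage runs in seconds while leaving estimator noise
  well below the tolerances being asserted.

## Known limitations

* K is reported in internal units (mm⁻²s⁶); `convert_K` rescales (e.g. ×1e6
  to m⁻²s⁶) for comparison with reports using other conventions.
* Boundary-element durations are not meaningful; they are excluded from
  scaling by default rather than corrected.
* The angular-law fit inherits differentiation noise twice (θ is computed
  from first derivatives, its rate from a second pass); its exponent is
  ~3–7e-4 off at 100 Hz where the speed-law fit is exact to machine
  precision on the same trace.
* Segmentation operates per axis on velocity components, not on the speed
  magnitude; movements confined to an oblique direction project onto several
  axes and are counted once per axis.
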