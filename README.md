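# movelements

Movement-element decomposition of motion-capture hand trajectories.

Smooth, continuous arm movement may be built from discrete submovements. A
long-standing way to look for them is to segment each axis of a marker
trajectory's velocity at its zero crossings; the resulting sign-uniform
segments — *movement elements* — are candidate motor primitives. This
package implements that decomposition together with the quantitative theory
that makes it testable, for movement scientists analysing drawing,
handwriting, pointing and reaching recordings (and for anyone who wants a
fully controlled synthetic substrate for such analyses).

## The model

Cost-of-time optimal control (movement duration t_f penalised against
integrated squared jerk with weight K) gives closed forms for a
point-to-point movement of displacement D:

* duration law: `t_f = (60 D)^(1/3) K^(1/6)`
* bell-shaped velocity profile: `v(t) = D (30 s^4 − 60 s^3 + 30 s^2) / t_f`,
  `s = t / t_f`
* mean-speed law: `v̄ = D^(2/3) / (60^(1/3) K^(1/6))`

Because `v̄ = D / t_f`, the model predicts that mean element speed scales
with displacement as a power law with exponent **α = 2/3** — a straight
line of slope 2/3 on a log-log plot. The package measures α by OLS over
decomposed elements, correlates every element with its own theoretical
profile (no free parameters), and inverts the duration law for a per-element
K. For planar drawing it also fits the classical one-third power law
`v ≈ k_v r^(1/3)` and its angular form `|dθ/dt| ≈ k_θ C^(2/3)`.

## Worked example

Decompose a simulated 1-D pointing sequence (45 cued ruler movements sharing
K = 1e-9 mm⁻²s⁶) and fit the scaling law:

```python
from movelements import synthetic as syn, preprocess as pp, decompose as dec
from movelements import minjerk as mj, scaling as sc

res = syn.gen_sequence_1d(seed=42)          # 45 cued ruler movements
vel = pp.differentiate(res.recording)
elements = dec.segment(vel, "x")
kept, discarded = dec.apply_filters(elements, dec.task_criteria("movement_1d"))
for el in kept:
    el.fit_r = mj.fit_element(el)
    el.K = mj.estimate_K(abs(el.D), el.t_f)
fit = sc.fit_scaling(kept)
summary = sc.summarize_task(kept, fit, "movement_1d", len(discarded))
print(f"kept {summary.n_kept} elements, discarded {summary.n_discarded}")
print(f"alpha = {fit.alpha:.4f} (r = {fit.pearson_r:.4f})")
print(f"profile fit r = {summary.fit_r_mean:.4f} +/- {summary.fit_r_sd:.4f}")
print(f"K = {summary.K_mean:.3g} +/- {summary.K_sd:.2g} mm^-2 s^6")
```

prints

```
kept 45 elements, discarded 0
alpha = 0.6684 (r = 1.0000)
profile fit r = 1.0000 +/- 0.0000
K = 1.01e-09 +/- 1.3e-11 mm^-2 s^6
```

The measured slope sits on the predicted 2/3 (the 0.002 excess is
finite-sampling bias at 100 Hz), every element matches the bell profile, and
the per-element K estimates recover the generator's shared K to ~1%.

The same pipeline runs from the shell on any delimited trajectory table
(`time,x,y,z` columns, or a declared sampling rate):

```
movelements simulate --scenario ellipse --param a=60 --param b=30 --seed 7 -o run/
movelements decompose run/recording.csv --task drawing -o run/
movelements curvature run/recording.csv -o run/
movelements report run/decompose_summary.json -o run/report.csv
```

`decompose` writes an element table (one row per element: timing, D, v̄,
peak speed, profile-fit r, K, kept/discard reason) and a JSON summary with
the resolved configuration and the scaling fit; `curvature` writes the
per-sample curvature series and both power-law fits.

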