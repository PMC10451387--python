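# Methods

This document defines the models, algorithms, units, defaults and known
limitations of the `ictsib` package. All numeric claims here are either
definitions (closed-form choices) or quantities recomputed by the test
suite (`tests/`) and the acceptance script (`scripts/acceptance.py`).

## 1. Coordinate conventions and data model

A trial is a center-of-pressure (CoP) trajectory `CopTrial(time, x, y, fs)`:

- `x` — anterior–posterior (AP) displacement, cm, positive forward;
- `y` — medio-lateral (ML) displacement, cm;
- origin at the device center; `fs` defaults to 23 Hz; the standard trial
  is 30 s = 690 samples.

Seven i-CTSIB conditions are modeled: `EO-firm`, `EO-firm-DC` (visual
conflict dome), `EO-foam1`, `EO-foam2`, `EC-firm`, `EC-foam1`, `EC-foam2`.

## 2. CoP extraction

### Pressure-sensor grid

Default geometry (`GridGeometry`): 68 columns × 48 rows, 22.5 mm pitch
along x, 37.9 mm along y, row 0 on the positive-y side. The CoP of each
frame is the load-weighted centroid of the cell centers. Frames whose total
load is below `min_total_load_kgf` (default 10 kgf) are treated as invalid:
leading/trailing invalid runs are dropped (time is re-zeroed), interior
gaps up to 3 frames are linearly interpolated, and longer interior gaps
raise an error rather than silently inventing data.

### Four-corner load-cell board

Default board 43.3 × 22.8 cm. With corner loads `tl, tr, bl, br` (kgf,
viewed from above, `t` = positive-y side) and total load `T`:

```
x = (L/2) · ((tr + br) − (tl + bl)) / T
y = (W/2) · ((tl + tr) − (bl + br)) / T
```

Frames with non-positive total load raise an error.

## 3. Preprocessing

1. **Detrending**: per axis, least-squares removal of an affine trend
   (projection onto span{1, t}).
2. **Band-pass**: Butterworth `FilterSpec(order=4, f_low=0.1, f_high=4.0)`.
   `order` is the single-pass analog prototype order; the digital band-pass
   is designed with `scipy.signal.butter(order // 2, [f_low, f_high],
   "bandpass")` (bilinear transform with prewarping), and applied
   zero-phase with `sosfiltfilt` (odd-extension padding). The single-pass
   amplitude response crosses −3 dB at the band edges; because of bilinear
   prewarping the crossings are at 0.1 Hz and 4.0 Hz to well within the
   ±0.01 / ±0.1 Hz tolerances verified by the acceptance tests. The
   two-pass (zero-phase) power response is `|H(f)|⁴`.

`filter_gain` evaluates the single-pass gain in dB at one frequency;
`halfpower_crossings` locates the −3 dB crossings numerically on a dense
geometric frequency grid with linear interpolation.

## 4. Sway features

Ten features, computed on the detrended + filtered trajectory, in canonical
order (`FEATURE_NAMES`). `d_i = sqrt(Δx_i² + Δy_i²)` is the i-th
point-to-point chord, `r_i = sqrt(x_i² + y_i²)` the distance from center,
`T` the trial duration, `n` the sample count:

| Feature | Definition | Units |
|---|---|---|
| `mean_cm` | mean of `r_i` | cm |
| `mean_path_cm_s` | total path length / T = `Σ d_i / T` | cm/s |
| `mean_velocity_cm_s` | mean chord speed `mean(d_i · fs)` | cm/s |
| `mean_distance_cm` | mean chord length `mean(d_i)` | cm |
| `mean_acc_cm_s2` | signed mean of the second-difference resultant | cm/s² |
| `ellipse_area_cm2` | 95% confidence ellipse, `π · 5.99146 · sqrt(λ₁λ₂)` with λ the eigenvalues of the x–y sample covariance | cm² |
| `freq_low5_hz` | 5% power quantile | Hz |
| `freq_center_hz` | spectral centroid `∫f·P df / ∫P df` | Hz |
| `freq_median_hz` | 50% power quantile | Hz |
| `freq_high5_hz` | 95% power quantile | Hz |

Note that `mean_path_cm_s ≡ mean_velocity_cm_s` for uniformly sampled data
(both equal `Σ d_i / T` up to the n/(n−1) endpoint convention) and
`mean_distance_cm = mean_velocity_cm_s / fs`. All three are kept because
each appears in the classical posturography feature set, but they are
exactly collinear; see §7.

Spectral features use the Welch periodogram of the **resultant** spectrum
`P = Pxx + Pyy`: Hann window, 8 s segments (184 samples at 23 Hz), 50%
overlap, restricted to 0.1–4 Hz. Quantiles are read off the trapezoid
cumulative power with linear interpolation. Trials shorter than 64 samples,
or with numerically zero in-band power, have the spectral features set to
NaN (and a constant raw trajectory is detected before filtering, so filter
round-off cannot masquerade as sway). `SwayFeatures.is_complete` reports
whether all ten are finite.

## 5. Stability-index models

One model per condition, mapping the ten features to the SI.

- **Split**: `split_dataset` splits by *subject* (default 70/30), never by
  trial, so no subject contributes to both sides. 103 subjects → 72 train /
  31 test.
- **Model types**: `linear` (ridge on standardized features), `svm` (RBF
  SVR), `gam` (B-spline GAM), `tree` (depth-limited regression tree).
- **Hyperparameters** are chosen by Gaussian-process Bayesian optimization
  (`bayesian_optimize`): Latin-hypercube initial design, Matérn-5/2 + white
  kernel GP surrogate, probability-of-improvement acquisition over random
  candidates, deterministic for a fixed `BOConfig.seed`. Defaults: 10
  initial points + 30 iterations. A degenerate (fixed) search space costs a
  single evaluation.
- **Evaluation**: Pearson r and RMSE on the held-out subjects.
- **Export**: linear models serialize to a plain JSON formula
  (per-condition coefficients on the raw feature scale plus a bias), which
  `predict`/`session` reload without scikit-learn state.

Session scoring (`run_ictsib_session`) computes one SI per provided
condition; the overall SI is the arithmetic mean of the per-condition SIs
(enforced to 1e-9 in the report type). Conditions whose features are
incomplete are reported as missing rather than scored.

## 6. Sample size

`sample_size_finite_population(N, confidence, margin, p)` implements the
normal-approximation formula with finite-population correction:
`n₀ = z² p(1−p)/e²`, `n = ⌈n₀ / (1 + (n₀−1)/N)⌉`, clamped to `[1, N]`.
For N = 108, 95% confidence, 5% margin, p = 0.5 it returns 85; for an
unbounded population, 385.

## 7. Synthetic sway generator

### Process model

Each axis is an independent stationary Gaussian process with power-law
spectrum `S(f) ∝ f^(−α)` on the analysis band (0.1–4 Hz), synthesized
exactly on the trial's FFT grid (circular embedding), so every spectral
moment of the generated process is known in closed form.

### Calibration

The generator is calibrated so that the **expected value of the features
this package itself computes** — after detrending, zero-phase filtering and
Welch estimation — matches per-condition targets. The closed-form
expectation propagates, per frequency bin:

- the two-pass filter power response `|H(f)|⁴`;
- the chord-velocity gain `2(1 − cos(2πf/fs))` (finite differencing,
  including its sinc attenuation);
- the variance removed by linear detrending (projection of the circulant
  covariance onto span{1, t});
- the exact expected Welch spectrum of the synthesized process (Hann-window
  smoothing kernel);
- the first-order downward bias of `sqrt(det(sample covariance))` for an
  autocorrelated series (factor `1 − q/2`, with `q` the spectral
  concentration), used for the expected ellipse area.

The spectrum shape (α) and per-axis scale are solved per condition with a
bracketing root find so the targets are met exactly in expectation; the
test suite verifies `expected_features` against the targets at 1e-6 and the
Monte-Carlo trial means at 3 standard errors.

### Feasible target sets

Each condition binds **mean velocity plus one of** median frequency or
ellipse area. For a stationary Gaussian process the three are coupled by a
spectral-moment inequality (the RMS frequency of any spectrum is at least
its median over √2, up to band effects), and typical published norms
violate the joint constraint; requesting all three raises
`CalibrationError` naming the conflicting targets. Defaults: velocity +
median frequency for the firm, dual-task and single-foam conditions;
velocity + ellipse area for the double-foam conditions (where amplitude is
the defining characteristic). Default targets include 1.20 cm/s and
1.44 Hz for `EO-firm` and 2.94 cm/s and 6.28 cm² for `EC-foam2`; the
acceptance script recomputes all four from 76 fresh trials per condition.

### Cohorts and the SI link

`generate_cohort` draws a per-subject log-normal severity multiplier
(log-sd `severity_sigma = 0.3`, unit mean) that scales sway amplitude
across all of a subject's trials. The reference SI is an affine link on the
computed features plus Gaussian noise:
`SI = 0.4 + 1.0·velocity + 0.25·area + 0.8·mean_cm + ε`, floored at 0. The
noise SD is derived per condition so the link explains a declared R²
(default 0.95) of the SI variance. Because `mean_path`, `mean_velocity`
and `mean_distance` are exactly collinear (§4), only the combination
`β_path + β_vel + β_dist/fs` is identifiable by any regression; the test
suite checks recovery of that combination and of every other coefficient
to 1e-2 on a noiseless cohort.

### What the generator does and does not emulate

Emulated: condition-specific sway magnitude and spectral content,
between-subject severity dispersion, measurement-chain effects (filtering,
finite differencing, Welch smoothing, covariance bias), device physics
(below). Not emulated: non-stationarity within a trial (fatigue, transient
corrections), non-Gaussian sway (intermittent control, saccadic resets),
AP–ML cross-correlation, learning effects across conditions, or any
diagnosis-specific sway signature. Reference SIs come from a known link,
not from human raters; model-accuracy results on synthetic cohorts
demonstrate *recoverability of the link*, not clinical validity.

## 8. Device emulation

`emulate_devices` renders one CoP trajectory through both device models:

- **Pressure grid**: two bivariate-Gaussian foot blobs (AP sd 4 cm, ML sd
  2 cm, stance half-width 8 cm) whose combined centroid tracks the CoP
  exactly; cell values are exact integrals of the footprint over each cell
  (error-function differences); total load 60 kgf. Gaussian sensor noise
  (default sd 0.02 kgf) is added per cell, then a 3σ dead band zeroes
  sub-threshold cells — including background cells, whose rare
  above-threshold noise survivors are drawn from the exact upper-tail
  conditional distribution.
- **Corner board**: exact lever-equation loads for the same CoP and total
  load via bilinear corner weights, plus Gaussian noise (default sd
  0.05 kgf).

Trajectories leaving the physical surface raise an error.

**Zero-noise inversion accuracy** (verified by tests): corner-board CoP
round-trips to better than 1e-9 cm; grid CoP to better than 1/20 of a cell
pitch. The grid's finite pitch (37.9 mm in ML) quantizes the footprint, so
even with zero sensor noise the dual-device SI agreement is not exactly
r = 1; the acceptance test asserts `r ≥ 1 − 1e-4` on a zero-noise emulated
cohort, and `r ≥ 0.96` with the default noise levels across 30-subject
cohorts in at least 9 of 10 seeds.

## 9. Numerical choices

- Zero-phase filtering uses `sosfiltfilt` with odd extension; all filter
  math is in second-order sections for stability at the narrow normalized
  band (0.1 Hz at 23 Hz sampling).
- Spectral quantiles interpolate the trapezoid cumulative power rather than
  taking the nearest bin, making them continuous in the spectrum.
- The generator synthesizes in the frequency domain (one FFT per axis), so
  trial cost is O(n log n) and exactly reproducible per seed
  (`numpy.random.default_rng`).
- All randomness flows through explicit seeds or `Generator` instances;
  cohort generation, model fitting, Bayesian optimization and the
  acceptance script are bit-reproducible for a fixed seed.
- Seeds derived inside the acceptance script come from
  `numpy.random.SeedSequence` reduced mod 2³¹.

## 10. Limitations

- The synthetic cohort is a *validation instrument*, not a clinical
  dataset; accuracy figures on it bound pipeline correctness, not clinical
  performance.
- The linear SI link plus collinear feature triple means individual
  coefficients of the path/velocity/distance group are not interpretable
  (only their combination is identifiable).
- The sway model is stationary and Gaussian per axis; features sensitive to
  higher-order temporal structure would need a richer generator.
- Device emulation assumes a static, symmetric two-foot stance and
  load-independent additive sensor noise; it does not model cell
  saturation, hysteresis, cross-talk or temperature drift.
- The −3 dB band-edge guarantee applies to the single-pass response; the
  effective two-pass attenuation at the edges is 6 dB, which is intrinsic
  to zero-phase filtering.
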