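# ictsib — instrumented CTSIB balance assessment

`ictsib` is a Python package for quantitative standing-balance assessment
with the instrumented Clinical Test of Sensory Interaction on Balance
(i-CTSIB). It turns raw recordings from low-cost force platforms into a
clinically interpretable **stability index (SI)** per test condition, and
ships a fully calibrated synthetic-data generator so the entire pipeline can
be exercised and validated end to end without access to clinical data.

## The scientific problem

The CTSIB probes how a person integrates visual, somatosensory and
vestibular input by having them stand still under conditions that
selectively degrade each channel. This package uses the seven-condition
protocol:

| Condition    | Vision        | Surface          |
|--------------|---------------|------------------|
| `EO-firm`    | eyes open     | firm             |
| `EO-firm-DC` | eyes open, dome (visual conflict) | firm |
| `EO-foam1`   | eyes open     | foam pad 1       |
| `EO-foam2`   | eyes open     | foam pad 2       |
| `EC-firm`    | eyes closed   | firm             |
| `EC-foam1`   | eyes closed   | foam pad 1       |
| `EC-foam2`   | eyes closed   | foam pad 2       |

Each trial records the **center of pressure (CoP)** for 30 s at 23 Hz
(690 samples), with x = anterior–posterior and y = medio-lateral
displacement in cm from the device center. Traditionally the SI is assigned
by a trained rater; this package instead *estimates* it from objective sway
features via per-condition regression models, so that inexpensive devices
(a pressure-sensor mat or a four-load-cell balance board) can produce
rater-comparable scores.

## What the package provides

- **CoP extraction** (`ictsib.cop`) from two device families: a 68 × 48
  pressure-sensor grid (weighted centroid with load thresholding and short
  gap bridging) and a four-corner load-cell board (lever-arm formulas).
- **Preprocessing** (`ictsib.preprocessing`): least-squares linear
  detrending and a zero-phase 4th-order Butterworth band-pass (0.1–4 Hz).
- **Ten classical sway features** (`ictsib.features`): mean distance from
  center, sway-path length, mean velocity, mean point-to-point distance,
  signed mean acceleration, 95% confidence-ellipse area, and four spectral
  descriptors (centroid frequency and the 5%, 50%, 95% power quantiles of
  the Welch spectrum in 0.1–4 Hz).
- **SI models** (`ictsib.model`): per-condition linear ridge, SVR, GAM and
  regression-tree models with subject-level train/test splitting and
  Gaussian-process Bayesian hyperparameter optimization; linear models can
  be exported to / reloaded from a plain JSON formula.
- **Session scoring and device agreement** (`ictsib.pipeline`): the
  seven-condition report (overall SI = mean of per-condition SIs), Pearson
  inter-device agreement, and finite-population sample-size calculation.
- **Calibrated synthetic data** (`ictsib.synth`): a band-limited Gaussian
  sway process whose variance and spectral shape are solved in closed form
  so that published per-condition feature means are reproduced *after* the
  full filtering and feature pipeline, plus a physical device emulator
  (foot-pressure blobs on the grid, lever-arm corner loads, sensor noise
  with a dead band) for dual-device experiments.
- **A CLI** (`ictsib`): `simulate`, `extract-cop`, `features`, `train`,
  `predict`, `session`, `agreement`, `sample-size`.

See [docs/methods.md](docs/methods.md) for precise definitions, units,
defaults and limitations.

## Worked example

Generate a synthetic cohort, fit per-condition linear SI models, and score
a new session:

```python
import ictsib as ic
from ictsib.model import BOConfig

cfg = ic.default_generator_config()
cohort = ic.generate_cohort(cfg, n_subjects=40, seed=7)
train, test = ic.split_dataset(cohort.training_table(), 0.7, seed=0)

models = {}
for cond in ic.ALL_CONDITIONS:
    models[cond] = ic.fit_condition_model(
        train.for_condition(cond), "linear",
        bo=BOConfig(n_iterations=10, n_initial=5, seed=0),
    )
    ev = ic.evaluate_model(models[cond], test.for_condition(cond))
    print(f"{cond.value:12s}  r = {ev.r:.3f}  rmse = {ev.rmse:.3f}  (n = {ev.n})")
```

```text
EO-firm       r = 0.971  rmse = 0.084  (n = 12)
EO-firm-DC    r = 0.982  rmse = 0.103  (n = 12)
EO-foam1      r = 0.970  rmse = 0.105  (n = 12)
EO-foam2      r = 0.975  rmse = 0.263  (n = 12)
EC-firm       r = 0.952  rmse = 0.124  (n = 12)
EC-foam1      r = 0.988  rmse = 0.094  (n = 12)
EC-foam2      r = 0.977  rmse = 0.420  (n = 12)
```

```python
trials = {c: ic.generate_cop_trial(cfg, c, seed=100 + i, subject_id="demo")
          for i, c in enumerate(ic.ALL_CONDITIONS)}
report = ic.run_ictsib_session(trials, models)
for cond, si in report.per_condition_si.items():
    print(f"{cond.value:12s}  SI = {si:.3f}")
print(f"overall SI = {report.overall_si:.3f}")
```

```text
EO-firm       SI = 1.690
EO-firm-DC    SI = 2.411
EO-foam1      SI = 2.051
EO-foam2      SI = 4.250
EC-firm       SI = 2.230
EC-foam1      SI = 2.800
EC-foam2      SI = 5.453
overall SI = 2.983
```

Individual trial features:

```python
feats = ic.compute_sway_features(trials[ic.Condition.EO_FIRM])
print(f"mean velocity = {feats.mean_velocity_cm_s:.3f} cm/s")
print(f"ellipse area  = {feats.ellipse_area_cm2:.3f} cm^2")
print(f"median freq   = {feats.freq_median_hz:.3f} Hz")
```

```text
mean velocity = 1.162 cm/s
ellipse area  = 0.138 cm^2
median freq   = 1.347 Hz
```

The same workflow from the command line:

```bash
ictsib simulate work --n-subjects 20 --seed 3 --write-trials
ictsib train work/training_table.csv --out work/formula.json --seed 0
ictsib session work/formula.json work/trials/S005_*.csv
ictsib sample-size 108           # -> 85
```

The `session` command prints, for this cohort and seed:

```json
{
  "subject_id": "S005",
  "per_condition_si": {
    "EC-firm": 1.9890777780575575,
    "EC-foam1": 2.5803456667424536,
    "EC-foam2": 4.977431895569211,
    "EO-firm-DC": 1.9314723430626732,
    "EO-firm": 1.5755829176655864,
    "EO-foam1": 1.852728155935921,
    "EO-foam2": 3.8188143308012013
  },
  "missing_conditions": [],
  "overall_si": 2.6750647268335146
}
```

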