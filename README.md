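# pubsitar

SITAR growth modelling and indicator-based pubertal-timing analysis.

Pubertal timing varies by years between children and matters for
life-course health, but it can be measured many ways: from repeated
anthropometry (ages at peak height, weight and bone-mineral-content
velocity), from ordinal development scales (Tanner stages of pubic hair,
breast and genitalia; voice breaking; axillary hair) and from recalled
events (menarche).  `pubsitar` is a Python library for epidemiologists
who want to derive such indicator-based pubertal ages from longitudinal
cohort data, compare them, and relate them to genetic risk scores and
childhood body composition — together with a synthetic-cohort generator
with known ground truth, so every estimator in the pipeline can be
validated end to end.

## The model

The core is SITAR (SuperImposition by Translation And Rotation), a
shape-invariant nonlinear mixed-effects growth model.  For individual
*i* at age *t*:

```
y_it = α_i + h( e^{γ_i} (t − c − β_i) + c ) + δ_i (t − t_adult)_+ + ε_it
```

One natural cubic spline *h* (knots at age quantiles) describes the
population curve; each individual differs from it by a vertical shift
α (*size*), a horizontal shift β (*timing*, years), a stretch of the age
scale γ (*intensity*, pivoting at the centre *c* of the age window) and
optionally an adult slope δ (*post-growth*).  (α, β, γ, δ) are jointly
Gaussian with unstructured covariance; estimation is iterated penalized
Gauss–Newton with profiled marginal-likelihood variance-component
updates, batched so thousands of individuals fit in seconds.  Height
uses three effects; weight and BMC four; ordinal scales use the reduced
(timing, intensity) model.  An individual's pubertal age for an
indicator is the population landmark age (peak of the analytic velocity
curve, or the mean curve's crossing of the landmark stage) plus their
timing effect β̂.  Details: [docs/methods.md](docs/methods.md).

## Worked example

```python
from pubsitar import (SimConfig, SitarSpec, age_at_peak_velocity,
                      fit_sitar, simulate_cohort)

config = SimConfig(n_per_sex=200, seed=2).with_measures(["height"])
cohort = simulate_cohort(config)
data = cohort.measurements[cohort.measurements["sex"] == "F"]
fit = fit_sitar(data, SitarSpec(outcome="height", n_knots=4))
```

Running [examples/02_fit_height_sitar.py](examples/02_fit_height_sitar.py)
(the above plus reporting) prints:

```
converged: True after 4 iterations
residual SD: 0.79 cm (generator used 0.8 cm)
  size      SD = 2.872 cm
  timing    SD = 1.055 y
  intensity SD = 0.160 log
age at peak height velocity: 11.47 y (generator curve peaks at 11.48 y)
correlation between true and predicted individual timing: 0.992
```

The fit recovers the generator's variance components (size 3 cm, timing
1 y, intensity 0.15, residual 0.8 cm), places the population age at peak
height velocity within 0.01 y of the generator curve's analytic peak,
and predicts each child's timing shift almost perfectly — which is what
makes `landmark + β̂` a usable individual pubertal age.  The other
examples cover cohort simulation, derivation of all nine measures with
their timing/sequence summary, and the GRS / body-composition
associations (e.g. `+0.249 y` APHV per SD of puberty GRS against a
generator target of `+0.25`).

A thin CLI mirrors the pipeline stages:

```
pubsitar simulate --n-per-sex 200 --seed 1 --out cohort/
pubsitar fit --measurements cohort/measurements.csv --measure height --sex F \
             --knots 2:5 --effects size,timing,intensity --out fit.json
pubsitar derive --measurements cohort/measurements.csv --out derived/
pubsitar run --config pipeline.yaml
```

## Layout

```
src/pubsitar/     basis, curves, simulate, sitar, derive, assoc, io,
                  pipeline, cli
examples/         one short narrative script per capability
tests/            pytest suite (unit, property and end-to-end recovery)
scripts/          acceptance.py
docs/methods.md   model, estimation, generator design, limitations
```
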