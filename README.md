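# heartwoodkit

Tools for analysing the timing, rate and drivers of heartwood formation
in trees, built around the cross-sectional "felled-tree" study design:
stem discs collected along the trunks and branches of two cohorts of the
same species growing at contrasting rates (e.g. shaded understorey vs
sun-exposed trees), with ring counts, heartwood/sapwood geometry, xylem
vessel anatomy, leaf and stomatal samples.

The package answers three questions about a species' heartwood ontogeny:

1. **When does heartwood formation start?** The probability that a disc
   of diameter *D* (or cambial age *t*) already contains heartwood is
   modelled as a logistic in the log of size or age, optionally with a
   site or growth-rate covariate,

   P = exp(a + b·ln x + c·z) / [1 + exp(a + b·ln x + c·z)],

   and the onset threshold is the inflection point x₅₀ = exp(−(a+c·z)/b),
   with delta-method or bootstrap confidence intervals and
   likelihood-ratio tests for covariates.

2. **How fast does heartwood accumulate?** Heartwood area, areal
   proportion and ring count are regressed on diameter or age with four
   candidate mean functions (linear, quadratic, power y = a·x^b, and the
   three-parameter asymptotic exponential y = a₀ + (a₁−a₀)e^(−a₂x));
   the family with the lowest residual standard error is selected,
   cohort differences are tested with Gaussian likelihood ratios, and
   the x-intercept of the linear ring-count fit dates the first ring
   converted to heartwood.

3. **Is it ageing or hydraulics?** A recursive path model decomposes
   the standardized effect of age and of a hydraulic variable (total
   conductive vessel area TCVA at the trunk, total leaf area A_L at
   branches) on heartwood/sapwood area into a direct path and an
   indirect path through stem diameter, with Wald contrasts between
   effects.

Around these sit the supporting trait computations (hydraulically
weighted vessel diameter for elliptical conduits, quadratic-mean radii,
sapwood/heartwood areas, vessel lumen fraction, anatomical maximum
stomatal conductance g_max), standardized major axis (SMA) regression
with common-slope tests for tapering allometries, Kruskal–Wallis cohort
contrasts, and a fully seeded synthetic data generator that mirrors the
two-cohort sampling design and emits its generating truth for
parameter-recovery testing.

The statistical cores are scikit-learn-style estimators
(`OccurrenceModel`, `SMARegressor`, `CandidateCurve`, `PathAnalyzer`)
with plain-function wrappers, so they compose with sklearn tooling.

## Worked example

```python
from heartwoodkit import generate_study, derive_discs, fit_occurrence, onset_threshold
import numpy as np

dataset, truth = generate_study(seed=1)          # two cohorts, 17 trees
discs = derive_discs(dataset["discs"], dataset["vessels"], dataset["leaves"])

fit = fit_occurrence(discs, "logAge+logGR")      # P(heartwood | age, growth rate)
gr = discs["GR"]
slow = onset_threshold(fit, float(np.log(gr[gr < 0.55].median())))
fast = onset_threshold(fit, float(np.log(gr[gr >= 0.55].median())))
print(f"slow growers: {slow.point:.1f} [{slow.ci_low:.1f}-{slow.ci_high:.1f}] yr")
print(f"fast growers: {fast.point:.1f} [{fast.ci_low:.1f}-{fast.ci_high:.1f}] yr")
```

prints

```
slow growers: 15.1 [13.8-16.5] yr
fast growers: 10.7 [8.7-13.1] yr
```

i.e. in this synthetic study the faster-growing stems start forming
heartwood about four years earlier than the slower-growing stems —
the threshold is the age at which the fitted occurrence probability
crosses 0.5, evaluated at each growth-rate class median.

The full pipeline (simulate → derive → onset → dynamics → SMA → path
models → report tables) runs from the command line:

```bash
heartwoodkit all --seed 1 --out results/run1
```

writing `trait_summary.csv`, `onset_results.csv`, `dynamics_results.csv`,
`ring_conversion.csv`, `sma_results.csv`, `path_results.csv`,
`path_contrasts.csv` and a run manifest; identical seed and
configuration reproduce the tables byte for byte.

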