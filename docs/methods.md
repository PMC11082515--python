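# Methods

This note records the models the package implements, the defaults of the
synthetic-data generator, the numerical choices, and the limits of what
the test suite demonstrates.

## Study design being emulated

The package targets cross-sectional heartwood studies in which trees of
similar age but contrasting growth rate are felled and sectioned: a
slower-growing shaded cohort (7 trees, trunk discs every 1 m) and a
faster-growing sun-exposed cohort (10 trees, trunk discs every 2 m),
plus branch discs carrying leaf samples, vessel measurements on every
trunk disc, and stomatal samples per tree. Every disc records eight
stem radii, eight heartwood radii, the pith-to-bark ring count (cambial
age), and the split of rings between heartwood and sapwood.

## Derived traits

* **Quadratic-mean radii.** Stem (S_R) and heartwood (HW_R) radii are
  the root-mean-square of the eight measured radii, which preserves
  cross-sectional area under eccentricity; sapwood width is
  SW_R = S_R − HW_R.
* **Areas.** CSa = πS_R², HWa = πHW_R², SWa = CSa − HWa. Closure
  SWa + HWa = CSa is enforced to 1e-9 relative. A pass-through mode
  accepts externally measured (image-analysis) areas and checks them
  against the radius-derived values at 25 % relative tolerance.
* **Hydraulic vessel diameter.** For elliptical lumina with major/minor
  diameters (aᵢ, bᵢ): D_H = [ (1/n) Σ 2aᵢ³bᵢ³/(aᵢ²+bᵢ²) ]^¼, the
  elliptical generalisation of the fourth-power mean; it reduces to
  (mean d⁴)^¼ for circles.
* **Vessel composites.** A_V is the mean elliptical lumen area (mm²),
  F_V = A_V·N_V·100 (%), TCVA = A_V·N_V·SWa (cm²). Units are enforced
  at the module boundary (µm for vessel axes, mm⁻² for densities, cm
  for radii); a computed F_V ≥ 100 % is rejected as a unit
  inconsistency rather than reported. Branch discs carry no vessel
  sample, so their vessel-dependent traits are missing, not zero.
* **g_max.** Anatomical maximum stomatal conductance
  g = (d_w/v)·D_s·a_max / (pd + (π/2)√(a_max/π)) with
  d_w = 2.49e-5 m² s⁻¹, v = 0.0245 m³ mol⁻¹, maximal pore area
  a_max = 0.12·S_stomata, and pore depth pd = √(a_max/π) by default
  (circular-pore rule); all constants and the depth rule are
  configuration, since conventions differ between protocols. g is
  exactly linear in stomatal density.

## Occurrence model and onset thresholds

Heartwood presence is fitted by maximum likelihood (IRLS via
statsmodels GLM, binomial family, deviance tolerance 1e-10, ≤ 100
iterations) under four predictor specifications: ln diameter, ln age,
ln diameter + site (shaded = 0, sun-exposed = 1), ln age + ln growth
rate. Complete separation is flagged as a non-converged fit with a
diagnostic (detected via the fitter's separation warning, diverging
coefficients, or exploding variances). The onset threshold is
exp(−(a+c·z)/b); its CI is computed by the delta method on the
log-threshold (default) or a parametric bootstrap from N(θ̂, V̂), and
the method used is recorded. Thresholds for growth-rate classes are
evaluated at user-supplied representative values, by default the class
medians of the 0.55 cm yr⁻¹ split used for display. Covariate
significance uses the likelihood-ratio chi-square.

## Dynamics models

Candidate mean functions: linear, quadratic, power (a·x^b), and the
asymptotic exponential a₀ + (a₁−a₀)e^(−a₂x) with a₂ fitted on the log
scale to keep it positive. Nonlinear fits use Levenberg–Marquardt from
five deterministic data-driven starts (e.g. the power exponent from a
ln–ln OLS fit), so they are reproducible without a seed. Selection is
by lowest residual standard error √(RSS/(n−p)); ties within an absolute
floor of 1e-10 resolve toward fewer parameters, then a fixed family
order, so that exact fits of nested families resolve to the simpler
one. Cohort differences use the Gaussian likelihood ratio
n·ln(RSS_shared/RSS_group) with df equal to the extra parameters. The
first-heartwood-ring age is the x-intercept −a₀/a₁ of the linear
ring-count fit (a crossing-1 option treats "one full ring" as the
event), with a delta-method CI.

## SMA allometry

SMA slope = sign(r)·sd(y)/sd(x), line through the bivariate mean,
slope CI slope·(√(B+1) ± √B) with B = F₁₋α(1, n−2)(1−r²)/(n−2); natural
logs throughout ("tapering" = ln–ln slope against distance from the
top). Because ln L degenerates at the tree tip, discs with L < 0.5 m
are excluded from ln–ln tapering fits. The common-slope test minimises
LR(b) = −Σ (nᵢ−2.5)·ln(1−rᵢ²(b)) over b, where rᵢ is the within-group
correlation of the residual and axis scores u = y−bx, v = y+bx (zero at
the group's own SMA slope); LR(b̂) is compared to χ²(g−1). The n−2.5
weighting is the usual Bartlett-type small-sample correction; with it
the test's type-I error is 4–6 % at n = 30–100 per group. A
residual-rotation permutation reference (permuting u against v within
groups, reconstructing the data, re-minimising) is available as a
finite-sample cross-check and agrees with the chi-square p to < 0.01
at n = 100 per group.

## Path model

The recursive system M = p₁·Age + p₂·Hyd + e₁,
Y = p₃·M + p₄·Age + p₅·Hyd + e₂ is estimated on z-scored variables by
equation-wise least squares (ML for a recursive Gaussian system).
Indirect effects are exact products (p₁p₃, p₂p₃), totals are direct +
indirect, and contrasts between any two effects are Wald chi-squares.

The coefficient covariance is **not** the per-equation OLS covariance:
because the coefficients are standardized, their sampling variability
includes the randomness of the standardizing scales, and the naive OLS
covariance made the Wald contrast reject true nulls at ~8 % instead of
5 % — an error that does not shrink with n. The covariance is instead
obtained by normal-theory propagation: the five coefficients are a
smooth function of the 4×4 sample covariance matrix S, whose asymptotic
covariance under normality is cov(s_ij, s_kl) = (s_ik·s_jl +
s_il·s_jk)/n; a central-difference Jacobian of the coefficient map
through this matrix gives the joint 5×5 covariance (the same treatment
SEM software applies). With it the Wald contrast's type-I error is
5.2–5.5 % at n = 300–600. The exogenous correlation is estimated, not
assumed zero. Collinearity (condition number > 1e8 or |r| ≈ 1 among
predictors) is an error naming the offending pair.

The path model is fitted on the raw (z-scored) variables, not on logs:
with the strongly coupled definitions of this domain (SWa = CSa − HWa
inside TCVA), the log transform amplifies the mechanical coupling of
the hydraulic predictor with the outcome and produces a spurious
negative direct effect; on the raw scale the coupling is weaker.

## Synthetic-data generator

Defaults encode the study conditions the analysis assumes; they are the
package's definition of the simulated experiment, not tuning knobs.

* Cohort diameter growth rates 0.30 (shaded) and 1.02 (sun) cm yr⁻¹,
  lognormal between trees (sd 0.06 / 0.18); tree ages uniform on
  45–58 yr; tree height H = 2.6·dbh^0.6 m; trunk discs from the base
  to 0.65·H at 1 m / 2 m intervals, with cambial age declining
  linearly toward the top (linear height growth), so each disc's
  diameter-to-age ratio reproduces the tree's growth rate.
* Heartwood presence follows the truth logistic
  logit P = −19.903 + 8.0·ln(age) + 1.8·ln(GR), whose inflection is
  15.8 yr at GR = 0.30 and 12.0 yr at GR = 1.02. Where present, ring
  counts are round(rate·(age − onset age)) clipped to [1, age−1] with
  rates 1.04 (shaded) and 0.96 (sun) rings yr⁻¹, so the slower cohort
  converts rings faster and starts later — the study's central
  contrast.
* Heartwood area follows cohort power laws in age (exponents 2.8
  shaded, 2.15 sun; shaded steeper) times a relative-size factor
  (GR_tree/GR_cohort)^1.5 that gives stem diameter a genuine causal
  channel, so indirect age effects through diameter are positive.
  Scatter is mostly a tree-level allometric deviation (cv 0.15) with
  small disc-level noise (cv 0.05): disc-level heartwood noise leaks
  mechanically into TCVA through SWa = CSa − HWa and would masquerade
  as a direct hydraulic effect in the cohort generated without one.
  Only the shaded cohort carries a true direct hydraulic channel: a
  per-disc latent loads on vessel density (+0.12) and, for shaded
  trees, on heartwood area (−0.25), and analogously on branch leaf
  area, producing the "hydraulics matter directly only under limiting
  conditions" pattern.
* Vessel diameters are calibrated to cohort means 101.33/123.55 µm
  (sd 9.67/8.81) with within-tree taper exponents −0.29/+0.15 along
  the distance from the top (normalised within tree to preserve the
  cohort mean); individual lognormal lumen diameters are drawn with
  E[d⁴]^¼ equal to the disc target so the fourth-power-mean estimator
  is unbiased; ellipse axes use a fixed minor/major ratio of 0.75.
  Vessel density, leaf sizes (33.82/9.73 cm²), leaf-area accrual
  rates, and stomatal density/size (the latter chosen so g_max
  evaluates near 1.33/1.98 mol m⁻² s⁻¹) complete the trait table.
* All randomness flows from a mandatory integer seed through numpy
  SeedSequences; per-cohort substreams make cohorts independent.
  Identical (config, seed) gives byte-identical CSV output.

What the generator does **not** emulate: spatial/climatic structure,
ring-width time series, measurement of areas from images, asymptotic
height growth (height is allometric in diameter, not sigmoid in time),
and within-disc azimuthal structure beyond multiplicative eccentricity
noise. Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated generative model, not
the biology of any particular species.

## Problem sizes and calibration checks

The test suite verifies, among others: closed-form SMA identities
(1e-12) and covariance-algebra path solutions (1e-10) on random small
datasets; exact analytic limits of D_H and the logistic threshold;
recovery of the occurrence truth (a, b, c) within 3 SE on a doubled
(34-tree, ~580-disc) study and ~95 % Wald CI coverage over 200
replicate studies; threshold CI coverage over 200 replicates at
n = 400; type-I error of the covariate LRT, common-slope test, group
LRT and Wald contrast within 5 % ± 2 over 500 null replicates each;
and the qualitative cohort contrasts on the default 17-tree study.
These sizes keep the full suite under two minutes on one CPU while
leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Discs are pooled within fits; there is no tree-level random effect
  (deliberately out of scope). With only 7–10 trees per cohort,
  tree-level deviations make disc-level standard errors optimistic,
  and chance tree-level correlations can occasionally elevate the
  estimated direct hydraulic effect in the cohort generated without
  one; the acceptance check therefore asserts the cohort asymmetry
  (strong, significant negative effect in shaded; much weaker in sun)
  rather than strict non-significance.
* SMA slopes are inflated by residual noise relative to the generating
  exponent (sd(y)/sd(x) includes noise variance); the conduit-taper
  recovery test uses a low-measurement-noise configuration where the
  exponent is identifiable, and the default-noise taper summaries run
  0.1–0.15 above/below the generating exponents, as expected for SMA.
* The Kruskal–Wallis chi-square p agrees with its permutation
  reference to < 0.02 in the significance tail at n = 12; in the
  middle of the null distribution the asymptotic approximation is
  looser, as is well known for rank tests at small n.
* The asymptotic-exponential family can be weakly identified when the
  data show no curvature plateau; it is then reported with large
  standard errors and loses the RSE selection, which is the intended
  behaviour.
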