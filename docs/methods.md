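# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the limitations of the `owlrsf` pipeline.

## Study system being emulated

The pipeline targets a resident, small-mammal-specialised raptor in an
intensively farmed temperate landscape during the non-breeding season
(September–February).  Five main habitat categories tile the landscape —
crop rotation, intensive grassland, extensive grassland, forest, urban —
with two rare overlay structures: border strips along roads (~1.5% of
cells) and biodiversity structures such as hedges, single trees and
wildflower strips (~1.3%).  Prey is monitored by two complementary
indices: vole-sign counts on walked transects (voles only) and graphite
track-plate traces (all small mammals).  GPS tags record one fix per hour
on two half-nights a week (7–12 p.m. and 0–4 a.m.), about 6.6 retained
locations per week.

## Synthetic data generator

All analyses run on synthetic data with known ground truth; the generator
is first-class, tested code, not a fixture.

**Landscape** (`synthetic.generate_landscape`).  Clustered categorical
patches are produced by per-category Gaussian-smoothed noise fields
(`patch_sigma`, default 4 cells = 100 m; nothing in the field data pins
patch size, so this is a free stylistic parameter).  Cells are assigned by
descending field value until each category reaches its exact target count,
so realised proportions match the requested mix up to rounding.  The
default mix (crop 48.7%, intensive grassland 18.0%, extensive grassland
6.3%, forest 15.0%, urban 12.0%) is the observed non-breeding home-range
composition rescaled to sum to one.  Roads are straight one-cell
transects at 0.6 km/km², biodiversity structures single cells or 3-cell
hedges at 10/km², chosen to reproduce the ~1.6% / ~1.3% rarity of the two
overlay classes.

**Surveys** (`synthetic.simulate_surveys`).  Four regions × four 9 km²
plots × five habitat strata × nine transects gives 720 transects (and 720
track-plates) per two-monthly session.  Counts are Poisson with mean
`λ(habitat, region, day) · exp(γ(T − 10 °C))`.  The intensities are
log-harmonic (order ≤ 2) by construction — post-harvest crash in crop
rotation, non-breeding vole peak in grassland and border structures, late
small-mammal peak in forest and biodiversity structures — so the activity
model's basis can represent the truth exactly and any recovery error is
sampling noise.  The temperature effect defaults to γ = 0.03/°C (small
positive activity response); temperature is a smooth seasonal curve plus
1 °C plot-level noise, averaged over the 10 days before a transect count
and over the 3 plate nights, mirroring the two observation windows.  Each
record carries its true mean as a `true_mean` column.

**GPS deployments** (`synthetic.simulate_deployment`).  Fix slots follow
the half-night schedule; each slot succeeds with probability 0.66, giving
the ~6.6 fixes/week average.  Used locations are drawn by rejection
sampling from an inhomogeneous point process with density
`exp(β·x(s))` over the *exact* weighted focal-area covariates x(s),
restricted to a disc-shaped home range.  A disc is a deliberate
simplification of irregular real ranges: only relative selection within
availability matters to the estimator.  There is no movement model — the
hourly half-night design is treated as yielding independent relocations —
and no multi-year vole cycle or weather beyond the scalar temperature
series.  Optional contamination (2% exact duplicates, 0.5% aberrant fixes
displaced ≥ 10 km, roost clusters of 3–6 fixes within 10 m) exercises
every cleaning rule with known labels.

Because the generator and the analysis share the focal-covariate
definition, passing recovery tests demonstrates the *estimator* is
correct under its own assumptions; they do not certify behaviour under
movement autocorrelation, GPS error, or misspecified availability, none
of which the generator emulates.

## Prey activity model

Transect and track-plate counts are never mixed in one fit.  Each method
gets a Poisson log-link GLM with

* one free intercept per habitat × region stratum,
* a cyclic harmonic seasonal basis (sin/cos pairs, default order 2,
  period 365 d) **interacted with habitat** — the seasonal signal of
  interest is habitat-specific (crop crash vs grassland peak), which an
  additive seasonal term cannot represent,
* a linear temperature term (centred at the training mean).

A stratum whose counts are all zero cannot support a log-scale intercept;
it is excluded from the fit, flagged in `degenerate_strata`, and predicts
an index of exactly 0.  A stratum never seen in training raises an
explicit missing-index error, which the focal-area layer maps to a zero
contribution (this is how unsurveyed urban area is handled).
Overdispersion is reported as the Pearson dispersion statistic rather
than absorbed into a quasi-likelihood fit; there are no plot-level random
effects.  Predictions are periodic in the date by construction and are
evaluated at the training-mean temperature unless a temperature is given.
`rasterize_activity` spreads `index × cell area` over the grid with the
overlays taking precedence over the underlying category, so the raster
total equals Σ_h index_h · area_h exactly.

For recovery checks the stable estimator of a stratum's intensity is the
mean *fitted* value over that stratum's records (`fitted_values`), which
the Poisson score equations tie to the observed stratum mean; the index
evaluated at a single day inherits the full variance of the nearly
saturated harmonic basis (6 design points, 5 parameters per habitat) and
is noisier.

## GPS preprocessing

Rules run in a fixed order and every removal is logged so that
`n_out = n_in − removed` always balances.

1. **Exact duplicates** (same deployment, timestamp, coordinates) keep
   their first occurrence.
2. **Aberrant positions** — undefined in most field protocols — are
   implemented as a speed filter (implied speed from the previous
   *retained* fix > 25 m/s by default) plus a bounding-box sanity check
   against the landscape extent.  The box check matters because a
   displaced fix that lands hours after its neighbour can carry an
   implied speed below any plausible threshold.
3. **Inactivity resampling**: a greedy forward scan per deployment
   anchored at the last retained fix removes a fix lying ≤ 30 m from the
   anchor and ≤ 120 min after it (a bird that did not move more than
   30 m within 120 min).  The greedy scan — rather than all-pairs
   windows — is single-pass, deterministic and idempotent.

Annual-cycle periods split the boundary months as: September belongs to
the non-breeding season (Sep–Feb GPS season), February to the breeding
season (breeding extends from February).  Both are configurable.

## Home ranges

The 95% MCP removes the ⌈0.05·n⌉ fixes farthest from the arithmetic-mean
centroid (computed once, not iteratively — the classical convention) and
hulls the remainder; areas are km².  Saturation uses a bootstrap ladder
(default 10 logarithmic rungs from 10 to n, 100 resamples without
replacement per rung): a range is saturated when none of the last three
relative increases of mean area exceeds 15%.  The ladder shape is a
declared configuration; the 15%-over-last-3 criterion is the fixed part.

Size and centroid-distance comparisons are linear mixed models on the log
scale fitted by REML (random intercept for individual; crossed individual
and nest-box intercepts for distances).  When nest boxes are aliased with
individuals the two variance components are not separable and the model
falls back to the individual-only intercept with a warning.  Fixed
effects are summarised by 1000 draws from the estimator's asymptotic
normal distribution; the mean and the 2.5/97.5% quantiles give the
estimate and interval, and an effect is "meaningful" when the interval
excludes 0.  Both the median (descriptive) and the modelled mean are
reported, since they answer different questions.

## Focal areas and filters

Each location gets a 75 × 75 m square, axis-aligned and centred on the
point (no snapping to the raster), divided into a 3 × 3 block of 25 m
sub-cells weighted 0.2 (centre) and 0.1 (each neighbour).  Sub-cell
composition is computed by *exact* rectangle–cell intersection: for a
piecewise-constant raster the integral over [0,x]×[0,y] is bilinear
inside every cell, so the cumulative-sum surface sampled with bilinear
interpolation yields exact rectangle areas at arbitrary positions, fully
vectorised (`composition.IntegralStack`).  A 1 m brute-force
rasterisation oracle bounds the agreement in the tests.

* `described_fraction` adds the main layer and the two overlays, so
  overlapping description can push it above 1; the coverage filter keeps
  0.50 ≤ described ≤ 1.20 (boundaries inclusive, matching the strict
  "less than"/"more than" exclusion wording).
* The dominant category is the argmax of the *weighted* proportions over
  the five main categories (weighted is the declared choice; the
  weighting scheme exists precisely to define coverage).  Exact ties
  break by fixed priority crop rotation > intensive grassland >
  extensive grassland > urban > forest (most- to less-abundant);
  `unknown` iff all five are zero.
* Structural richness counts distinct described layers (five main
  categories plus the two overlays) in the square.
* The foraging filter drops areas with forest + urban weighted cover
  strictly above 0.80 (equivalently, potential foraging habitat below
  20% of 5625 m²); it applies only to the prey-density models.
* Prey activity per focal area is Σ_h area_h · index_h over the five
  foraging strata (crop, both grasslands, border, biodiversity), with
  the overlays taking precedence over the underlying category; areas are
  the weighted proportions × 5625 m².  Total prey per habitat is
  z(vole_h) + z(smallmammal_h) with z-scores computed over the full
  retained table (the scaling population is a declared choice; nothing
  in the protocol fixes it), and an optional grassland merge pools the
  two grassland areas before scaling.
* Availability is sampled uniformly in the MCP polygon *before* any
  filter at exactly 1:100, so post-filter ratios drift below 1:100
  exactly as the removal accounting implies.

All filter decisions are carried as flags, never applied destructively,
so the cascade can be audited; `CascadeAccounting` reconciles sizes per
case (used/available) by construction.

## RSF estimation

`fit_weighted_logistic` maximises the case-weighted Bernoulli
log-likelihood by iteratively reweighted least squares: convergence at
max |Δβ| < 1e-8 within 100 iterations; covariance from the inverse
weighted information matrix at the optimum.  Separation is flagged when
coefficients diverge (|β| > 50, or a saturated-probability singular
information matrix with |β| > 10) and the fit is marked non-converged.
Rank deficiency raises an error naming the aliased columns (QR with
pivoting); columns constant over a table (single-sex data, absent
categories) are dropped with a warning before fitting.  The
intercept-only fit has the closed form logit(p̂) = log(n_used/(W·n_avail)),
used as an exact oracle.

Two numerical facts worth knowing:

* Rescaling all available weights shifts only the intercept *up to
  O(fitted p)* — exact only in the infinite-weight limit.  At the
  realistic operating point (intercept ≈ −13, p ≈ 10⁻⁶) the slope
  movement is below 1e-6; in small toy designs with large p it is
  visible at ~1e-5.
* In the ratio-sensitivity analysis the intercept moves by exactly
  log(r₂/r₁) between ratios; only slopes are expected to stabilise, so
  the summary statistic excludes the intercept.

Population-level inference is two-stage: per-deployment fixed fits
(deployments with fewer than 30 design rows, rank-deficient designs, or
non-converged fits are skipped) pooled per coefficient by
inverse-variance weighting with a DerSimonian–Laird method-of-moments
between-deployment variance, reported as the random-slope surrogate.
With few fixes per deployment a minority of deployments may support a
converged fit for the habitat model; the pooled estimate is then based on
those and says so via `n_deployments`.  "Posterior" draws everywhere are
simulations from the asymptotic normal of the MLE — a deliberate
frequentist reading of posterior-simulation summaries; `rss` reports both
exp(β̂) and the mean of exp over draws, which differ by Jensen's
inequality in the second decimal for |β| ≈ 0.3 (both are printed rather
than forcing agreement).

**Calibration** follows the observed-vs-expected binned regression under
k-fold cross-validation: held-out locations are binned by predicted
selection score into quantile bins of the available scores, expected used
counts are availability-weighted scores, and observed used counts are
regressed on them.  The check is sharp when scores are continuous; when
the score distribution has large atoms (dominant-category designs, or
many focal areas with identical prey sums) quantile bins merge and the
permutation null retains a positive slope through bin-size variation —
the null is then conservative, and the well-specified continuous design
is the informative benchmark.

## Problem sizes

The test suite and the acceptance script run, as the package's standard
demonstration sizes: a 5 × 5 km landscape (200 × 200 cells); survey
recovery at the full design (720 transects × 6 sessions); IPP recovery
with 2000 used and 200,000 available locations per replicate, 20
replicates; oracle comparisons on 25 random tiny logistic designs and 100
random point sets; the worked analysis uses 12 individuals with paired
breeding/non-breeding deployments.

## Known limitations

* No movement model: fixes are independent draws, so autocorrelation-
  induced pseudo-replication is out of scope (the two-stage pooling
  addresses between-individual, not within-track, dependence).
* The two-stage population estimator is a surrogate for a joint
  random-slopes GLMM; with very few used locations per deployment it
  discards deployments a joint fit would shrink instead.
* The activity model is maximum likelihood with a fixed harmonic basis —
  no smoother selection, no multi-annual cycles, no plot random effects.
* The landscape generator reproduces composition and rarity statistics,
  not the geometry of real field mosaics (field shapes, road networks,
  riparian strips).
* `hr_overlap` and `composition` are cell/polygon counting measures;
  they inherit the raster resolution (one cell-row tolerance).
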