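# Methods

## Scope and quantities

`molaric` analyses crown-diameter data for the three molars of each jaw
in hominid species and modern-human populations.  Molar size is the
crown area, the product of the buccolingual (BL) and mesiodistal (MD)
diameters in mm; the molar row is the sum M1 + M2 + M3; molar
proportions are the ratios M2/M1 and M3/M1 of areas.  Three analyses
are built on these quantities:

1. **log-log allometry** of each tooth's area against the row, with
   OLS, phylogenetic (PGLS) or spatial-lag (lagSAR) regression engines,
   classified against isometry by the 95% CI of the slope;
2. **phylogenetic structure** of sizes and proportions: Blomberg's K
   with a tip-permutation test, and maximum-likelihood Brownian-motion
   ancestral states;
3. **inhibitory-cascade (IC) evaluation**: position of each group in
   the (M2/M1, M3/M1) morphospace and a regression test of the two
   model predictions.

## Aggregation of measurements

Literature-compiled tables usually report per-group mean diameters, so
the default aggregation is `mean_diameters`: area = mean(MD) x
mean(BL) per group, jaw and tooth.  For per-specimen tables,
`mean_areas` (mean of per-specimen MD x BL) is available; the two
differ by the within-group covariance of MD and BL and coincide when
each tooth has one record.  Groups lacking any of M1–M3 for a jaw are
excluded from that jaw's analyses and logged, so per-jaw sample sizes
can differ.  Side (left/right) is accepted as an optional column but
not reconciled: sources mix single-side and side-averaged values and no
rule can recover which.

## The inhibitory-cascade model

The cascade posits that relative molar area at position X in {1,2,3}
is Y = 1 + [(a - i)/i](X - 1), where a/i is the activator/inhibitor
balance; hence M1 = 1, M2 = a/i, M3 = 2a/i - 1, an arithmetic
progression, admissible for a/i > 1/2.  Two consequences are
implemented as testable procedures:

* **Prediction 1** — across groups, M3/M1 = 2(M2/M1) - 1, so a fitted
  line through the ratio points has slope 2 and intercept -1.
  Consistency is scored by whether the 95% CIs of the fitted slope and
  intercept contain 2 and -1; the engine (OLS/PGLS/lagSAR) matches the
  sampling structure of the dataset.
* **Prediction 2** — M2 is exactly one third of the row for every
  admissible a/i.

"Inside the morphospace" is operationalized as a monotone size
pattern (M1 > M2 > M3, M1 < M2 < M3, or all equal), exactly the region
the cascade can generate; it is **not** proximity to the predicted
line.  A perpendicular `distance_to_line` diagnostic is provided but
plays no part in the call.  Pattern comparisons use strict inequalities
by default (`tol = 0`): group means are real-valued, so exact ties are
improbable, and published censuses use strict patterns; a relative
tolerance can be supplied to report `=` for near-ties.

## Regression engines

**OLS** is fitted by the closed-form normal equations with Student-t
CIs on n - 2 df.

**PGLS** assumes residuals with covariance proportional to the
Brownian-motion matrix C (C[i,j] = shared root-to-MRCA path length;
Pagel's lambda fixed at 1 — no lambda optimization, matching the plain
BM covariance the analyses assume).  Estimation whitens the model with
the Cholesky factor of C (no explicit inverses); estimates are
invariant to rescaling C.  sigma^2 uses n - 2 df, CIs Student-t.  R^2
is reported on the whitened scale against the whitened intercept-only
(phylogenetic-mean) fit, which keeps it in [0, 1]; published tables
rarely state their R^2 convention, so this one is documented here.
The implementation is validated against an explicit-inverse GLS oracle
(1e-10) and cross-validated against independent R implementations
(`nlme::gls` with Brownian correlation) on a fixed fixture.

**Blomberg's K** follows the standard ratio form: observed
MSE0/MSE over expected, with the GLS grand mean and the
phylogenetically corrected residual sum; K = 1 is the BM expectation
and K = 1 holds exactly on star trees.  Cross-validated against
`picante::Kcalc` to 1e-9.  The permutation test shuffles tip values,
uses the corrected residual sum as statistic, and reports
p = (1 + #{perm <= obs}) / (n_perm + 1); the seed is a required
argument.

**Ancestral states** are the conditional expectations of internal-node
states under the joint BM Gaussian given the tips (root = phylogenetic
mean); they agree with `ape::ace` on the validation fixture.

**lagSAR** fits y = rho W y + X beta + eps by maximum likelihood.  The
spatial weights are inverse great-circle distances (haversine,
R = 6371 km — ellipsoidal geodesics differ by < 0.5% and are out of
scope), floored at `epsilon_km = 1` to guard co-located populations,
and row-standardized by default (the common default of spatial-lag
software; raw weights are an option — the choice is exposed because
published analyses rarely state it).  rho is found by bounded scalar
maximization of the profile log-likelihood
l(rho) = sum ln(1 - rho*lam_i) - (n/2) ln(SSE(rho)/n) + const on the
eigenvalue interval shrunk by 1e-6 (tolerance 1e-8); eigenvalues of
the row-standardized matrix are computed through the similar symmetric
form, so they are real.  Standard errors come from the observed
information (finite-difference Hessian of the full likelihood); when
that is ill-conditioned (e.g. W = 0) the implementation falls back to
profile curvature for rho and conditional OLS SEs for beta.  W = 0
makes the likelihood flat in rho; rho-hat = 0 by convention and the
fit reduces exactly to OLS.  The reported R^2 is a pseudo-R^2 (squared
correlation of observed and fitted y).

## Allometry conventions

Natural logarithms throughout; the slope and its CI are invariant to
the base since both axes are transformed identically.  Each tooth is
regressed on the **full** row including itself — that is what "molar
size relative to molar row size" means operationally — so the three
slopes are linked through the part–whole sum; no part-whole correction
is applied and users comparing with body-size allometries should keep
the caveat in mind.  Regressions are unweighted (specimen counts per
group are not used as weights).

## Synthetic data

The generators produce the statistical structure each estimator
assumes, with ground truth attached, and are pure functions of their
seeded configuration:

* `gen_ic_dataset` inverts the cascade equations: a/i ~ U(0.7, 1.3) by
  default, lognormal row scale around 300 mm^2, and multiplicative
  lognormal noise (sd 0.05) per area — areas stay positive at any
  noise level.  With zero noise every ratio point is exactly on the
  predicted line.  Note a real property of this noise model: the
  shared M1 denominator correlates the errors of M2/M1 and M3/M1 and
  attenuates the fitted slope below 2 (to ~1.75 at 5% noise for the
  default ratio spread, matching the first-order errors-in-variables
  closed form); the test suite asserts that attenuation against the
  closed form rather than pretending the noisy slope stays at 2.
* `gen_bm_dataset` evolves log row size by Brownian motion on a
  (default 21-taxon, mirroring the interspecific table) Yule tree and
  builds per-tooth log areas as intercept + slope x log(row) + BM
  residual on the same tree, slopes defaulting to (0.82, 1.01, 1.16) —
  the negative/isometric/positive ordering of the published exponents.
* `gen_population_dataset` draws (default 56, mirroring the
  population sample) uniform points on the sphere, filters log-size
  deviations through (I - rho W)^-1 (rho = 0.6), and assigns each
  population a decreasing-cascade or M2-bump archetype with
  probability `frac_decreasing` (default 0.768).  Archetype gaps are
  set above the typical noise displacement so the realized pattern
  census reproduces the configured mixture within a few percent.
* `gen_random_tree` is a forward Yule simulation with exponential
  waiting times (ultrametric, positive terminal branches),
  deterministic per seed.

What the generators do **not** emulate: real measurement error
structure (inter-observer, wear), unbalanced per-group specimen
counts, correlated upper/lower jaws within a group, non-Brownian
evolution (no OU/early-burst), and land-constrained rather than
great-circle population distances.  Passing recovery tests therefore
show the estimators are correct under their own assumptions, not that
those assumptions hold for any particular empirical compilation.

## Numerical choices and degenerate inputs

* Linear solves use Cholesky/triangular solves; explicit inverses
  appear only in test oracles.
* Constant predictors, constant traits, non-positive-definite
  covariances, < 3 (regression) / < 4 (K) / < 5 (SAR) observations,
  empty tree/label intersections, and duplicate tips all raise typed
  errors naming the condition.
* rho estimates within 1e-4 of the admissible interval ends are
  flagged (`boundary=True`) and logged.
* Newick round-trips preserve labels (underscores kept verbatim) and
  branch lengths to 1e-9; missing branch lengths are an error unless
  the reader is told to assign 1.0.

## Problem sizes used in the shipped checks

The statistical acceptance checks run at the sizes the analyses are
dimensioned for: 1000 Brownian replicates on a fixed 21-tip tree for
PGLS CI coverage (expected 93–97%), 200 replicates at n = 100 for the
SAR rho bias (|bias| < 0.05), 1000 replicates on a 64-tip tree for the
mean of K (1 +- 0.05), and exact (machine-precision) checks for the
cascade closed forms and engine equivalences.

## Known limitations

* PGLS has no lambda/OU estimation; misspecified covariance is not
  detected.
* The lagSAR SEs are asymptotic; for n in the tens the rho CI can be
  optimistic.
* Part–whole regression inflates per-tooth R^2; compare slopes, not
  R^2, across studies with different row definitions.
* The full numeric reproduction of published tables requires the
  compiled measurement dataset, phylogeny and coordinates as user
  inputs (`data/supplementary/`); they are not redistributable with
  the package.
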