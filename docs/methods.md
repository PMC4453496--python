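# Methods

## The question and the estimand

A combined risk-allele score — the per-individual count of BMI-increasing
alleles across a panel of 28 scored SNPs, possibly fractional after mean
imputation — is treated as a linear exposure for internally standardized
anthropometric outcomes in a longitudinal family cohort. The quantity of
central interest is how the per-allele effect on weight-for-height z (zWT-HT)
changes with age: the model allows an arbitrary cubic age profile and reports
the linear component of that profile in z-units/allele/year.

## Genotype quality control and the combined score

* **Call rate**: SNPs genotyped in fewer than 95% of individuals are flagged
  (threshold configurable in (0, 1]).
* **Monomorphic SNPs**: markers where only one allele is observed among
  non-missing calls (risk-allele frequency exactly 0 or 1) are removed from
  scoring.
* **Tri-allelic recoding**: allele-pair calls are collapsed to the count of
  the BMI-increasing allele regardless of which other alleles are present, so
  a tri-allelic site enters the score exactly like a biallelic one.
* **Hardy–Weinberg equilibrium**: tested per SNP with a 1-df chi-square
  goodness of fit (no continuity correction) against expectations from the
  sample allele frequency, on **one randomly selected representative per
  sibship** (sibship = same mother; individuals without a pedigree entry are
  their own sibships). Sampling is seeded and the seed recorded. The failure
  threshold is Bonferroni-corrected, alpha / (number of SNPs tested), computed
  from the formula rather than any rounded constant. A conditional exact test
  is available (`method="exact"`) for low-MAF markers. SNPs failing HWE are
  dropped from the score by default (configurable), although under the
  generator's Hardy–Weinberg founders failures occur only at the nominal
  type-I rate.
* **Missingness**: individuals missing more than `max_missing` (default 5, so
  six or more of a 28-SNP panel) scored SNPs are excluded. For the rest, each
  missing genotype is imputed as **twice the risk-allele frequency**, the
  frequency being computed from non-missing calls over the full retained
  sample (not per sibship). Mean imputation preserves each SNP's observed
  mean allele count exactly, and under MCAR missingness the imputed score is
  an unbiased estimator of the true score (both properties are tested).
* **Score**: the row sum over scored SNPs, bounded by [0, 2 × n_snps]. Any
  remaining missing value at scoring time is a contract violation and raises.

## Internal standardization

Discrete outcomes (birthweight; weight and height at ~2 years; adult weight,
height and BMI) are standardized within **age–sex groups**:
z = (x − mean)/SD with the sample mean and SD of the group, logging weight
and height first to tame right skew (birthweight and BMI are left on their
natural scale by default). Group definitions: birthweights by sex; the
~2-year anchors by sex; first adult measurements by sex × 10-year age band,
with the top band open-ended so no band is ever nearly empty. Every group
must have at least two members and positive spread — violations raise with
the group named.

Weight-for-height needs a z-score at *every* age, so its mean and SD are
continuous functions estimated in two stages per sex:

1. least squares of log W on a degree-5 polynomial in age plus a degree-2
   polynomial in centred log height (additive; degrees configurable; ages are
   scaled by their maximum before powers are taken so the design stays well
   conditioned);
2. least squares of the squared stage-1 residuals on a degree-3 polynomial in
   age. The fitted variance is floored at the 1st percentile of its positive
   fitted values (a stage-2 polynomial can go negative; a valid SD needs a
   positive floor), and z = (log W − µ̂)/σ̂.

The same machinery with the height terms dropped (or with log height as the
response) provides continuous weight-for-age and height-for-age calibrations
for the infant growth slopes. Calibrations are sex-separable by construction,
persist to JSON, and flag ages outside the fitted range as extrapolated.

## Growth parameters

* **0–2 years**: per-child OLS of the internal z on age, using records at
  ages ≤ 2. A child is excluded if it has fewer than 5 such records, no
  record in the first year ([0, 1)) or in the second ([1, 2]), zero age
  variance, or a slope SE (classical n−2-df formula) of 0.4 z/year or more.
  Filters are evaluated independently and all violated filters are reported.
* **2–20 years**: the difference between the group-z at the first adult
  measurement (age strictly > 20) and at the measurement nearest age 2 among
  those strictly inside (1.5, 2.5); when two records are equidistant from 2
  the later one is taken (an arbitrary but fixed and logged tie-break).
  Individuals lacking either anchor are excluded, not errors.

## Association models

All models are **maximum likelihood** (REML is not used; ML keeps nested
model comparisons coherent), with Wald inference: p-values from z statistics
and 95% intervals as estimate ± 1.96·SE throughout.

* **Clustered GLS** (one row per individual): random intercept on the
  mother-defined sibship plus residual. A single cluster falls back to OLS
  with a warning; a constant score is an error.
* **Three-level model** (repeated zWT-HT): random intercepts for family and
  for individual-within-family plus an observation residual. Non-nested ids
  (an individual in two families) are rejected.
* **Covariates**: village of residence as a categorical (reference level =
  first alphabetically) and year of birth centred and linear, to absorb
  place and secular-trend differences.
* **Gene-by-age interaction**: the score is interacted with three orthogonal
  polynomials of age built by QR factorization of the Vandermonde matrix of
  the analysis sample's observation ages (one row per observation; columns
  mutually orthogonal and orthogonal to the constant, with signs fixed for
  determinism). Age main effects are included alongside the interactions
  (hierarchy principle; configurable off). The stored triangular map lets any
  basis-scale coefficient vector be re-expressed on raw-age monomials, so the
  linear interaction is reported in z-units/allele/year with a delta-method
  (here exact, since linear) SE, and the identical answer is obtained from a
  raw-polynomial parametrization of the same column space (tested to 1e-8 on
  fitted values). Quadratic and cubic interaction terms get a joint Wald
  test. The per-allele effect curve and its pointwise band come from the
  fixed-effect covariance; ages outside the construction range are flagged.

### Estimation internals

The nested covariance I + r_ind·ZZ' + r_fam·FF' is inverted analytically with
two Sherman–Morrison sweeps (per-individual blocks, then a rank-one family
update), so a likelihood evaluation is O(n·p). The one or two variance
*ratios* are profiled out by Nelder-Mead on the log scale (fixed effects and
the observation variance have closed-form GLS/ML solutions given the ratios),
followed by a finite-difference Newton polish: Nelder-Mead stops once
function differences reach float noise, which still leaves the ratios ~1e-6
loose, and the quadratic step pins them down — it is skipped on likelihood
plateaus (a variance component at zero), where the local model is not convex
and the fixed effects are insensitive to the drifting ratio anyway.
Non-convergence is a hard error. These fits agree with an independent
dense-matrix likelihood maximization to 1e-6 (relative) on fixed effects and
1e-4 (absolute) on variance components, and with an external mixed-model
implementation on nested variance components.

## The synthetic cohort generator

The generator produces exactly the data structure the models assume, with the
truth recorded for recovery scoring:

* **Pedigree**: mother-defined sibships (one implicit father each; the
  clustering unit is the mother), truncated-Poisson sibship sizes (min 1,
  max 8, mean 4 by default — a natural-fertility shape with one parameter),
  three villages, continuous birth dates over 1950–2005, a small twin rate
  (0.004 per birth) with twins sharing an exact birth date.
* **Genotypes**: founder haplotypes at the configured risk-allele frequency
  (Hardy–Weinberg by construction) with Mendelian transmission to offspring;
  the default panel has 28 scored SNPs with frequencies spread over 0.10–0.90
  (one of them tri-allelic, emitted as allele-pair strings) plus two
  monomorphic distractors; missingness is MCAR at 1.5%.
* **Measurements**: one birth record, 12 jittered dense records to age 2,
  then sparse records every ~3 years up to a per-individual follow-up age
  drawn uniformly below 50 — about 20 observations per individual at the
  default size (~400 families, ~1,600 offspring). Heights follow a
  sex-specific exponential approach to adult height (0.50 m at birth,
  ~0.88 m at 2 y, 1.70/1.59 m adult M/F) with lognormal individual scale;
  log-weight follows a piecewise-smooth double-exponential curve
  (2.94 kg at birth, ~12.5 kg at 2 y, 58.7/54.6 kg adult) plus an elasticity
  of 2 on the height deviation, so weight-for-height varies realistically.
* **Signal**: on the z scale,
  `eta = (score − E[score])·(delta0 + delta1·age) + u_family + v_individual +
  e_observation`, injected into log-weight as `sd_log_weight · eta`
  (0.12 log-units per z-unit), so `delta` is interpretable in z-units per
  allele. Defaults: delta0 = 0 (no effect at birth), delta1 = 0.008
  z/allele/year, variance components (family, individual, observation) =
  (0.2, 0.3, 0.5). No empirical decomposition of the three variance levels
  is available, so their magnitudes are free parameters chosen to sum to 1
  with the largest share at the observation level; they are prominent in the
  config and in `truth.json`. `eta` is returned as `z_true`, making the
  generator exactly the model class of the association module — recovery
  tests are therefore well posed.
* **Not emulated**: seasonality, secular trends, mortality, informative
  dropout, assortative mating, population structure. Passing recovery tests
  on this generator shows the estimators are correct for the assumed model;
  it says nothing about robustness to those unmodelled features of real data.

A note on scale: with 28 SNPs the score SD is ≈3.3 alleles, so the default
delta1 implies a genetic z-SD above 1 at age 50 — a deliberately strong
signal for estimator testing, larger than observational studies report. The
fitted standardization absorbs part of the resulting age-dependent variance
into its SD function, which slightly inflates the three fitted variance
components' denominator and is why end-to-end (calibrated) runs report
variance components a little below the generating values while the
interaction slope itself recovers well.

## Pipeline, reproducibility and problem sizes

One master seed fans out (via seed sequences) to child seeds for simulation,
twin exclusion (one random member of each twin pair dropped) and HWE
representative sampling, so each stage is individually reproducible and two
runs with the same config and seed are byte-identical. The run manifest
records, for every stage, input count = output count + exclusions, and this
identity is validated on every run. Ethnicity is carried as metadata and
never filtered on.

The test suite runs its statistical checks at reduced problem sizes chosen so
Monte-Carlo error, not runtime, is the binding constraint: parameter recovery
uses 100 replicates of 250 sibships × ~2 offspring × ~7 observations (a
wide-and-shallow design that keeps the ML variance-component bias an order of
magnitude below the Monte-Carlo standard error); null calibration uses 500
replicates of 120 sibships; HWE type-I calibration uses 500 replicates of 500
sibships at two allele frequencies. The acceptance script runs the pipeline
once at the full default size.

## Known limitations

* ML variance components carry the usual O(p/n) downward bias relative to
  REML; at the default sizes this is well inside Monte-Carlo noise, but for
  very small cohorts a REML option would be the natural extension.
* The two-stage variance calibration is method-of-moments, not a joint
  mean–variance likelihood (e.g. GAMLSS); its flooring rule is ad hoc but
  only engages in near-degenerate data.
* The HWE chi-square is asymptotic; use the exact option for rare alleles.
* Wald inference assumes large samples; no small-sample df corrections are
  applied.
* The effect-by-age curve is a cubic: it cannot represent sharper changes
  (e.g. pubertal spikes) and extrapolates poorly outside the observed ages
  (flagged in the output).
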