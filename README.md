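# grsgrowth

Tools for asking how a polygenic obesity susceptibility score shapes body
size **across the whole life course** in a longitudinal family cohort.

Populations living in nutritionally deprived settings are lean, and measuring
the influence of BMI-associated common variants there requires analysing
growth itself, not just attained adult size. `grsgrowth` implements the full
analysis chain for this question:

1. **Genotype QC and scoring** — call-rate filtering, removal of monomorphic
   markers, recoding of a tri-allelic variant to risk-allele counts, a
   Hardy–Weinberg goodness-of-fit test on one randomly sampled representative
   per sibship (so family structure cannot distort it), mean-allele
   imputation of sporadic missingness (each missing genotype replaced by
   twice the risk-allele frequency; individuals missing too many markers are
   excluded), and the combined score
   *G<sub>i</sub> = Σ<sub>k</sub> g<sub>ik</sub>*, the cumulative count of
   BMI-increasing alleles.
2. **Internal standardization** — z = (x − mean)/SD within age–sex groups
   (weight and height logged first), and for weight-for-height at *all* ages
   a continuous sex-specific calibration: log W regressed on polynomials of
   age and log height, then the squared residuals on a polynomial of age,
   giving smooth mean and SD functions with zWT-HT = (log W − µ̂(age, height)) / σ̂(age).
3. **Growth parameters** — per-child OLS slopes of z on age over 0–2 years
   (kept when the child has ≥5 measurements, coverage of both the first and
   second year, and slope SE < 0.4 z/year), and the 2–20 year change between
   the z-score nearest age 2 (within 1.5–2.5 y) and the first adult
   (>20 y) measurement.
4. **Association models** — cross-sectional outcomes use a random-intercept
   GLS clustered on the mother-defined sibship; repeated zWT-HT uses a
   three-level mixed model (family / individual-within-family / observation),
   all fitted by maximum likelihood with village (categorical) and year of
   birth (linear) as covariates. The change of the genetic effect with age is
   modelled by interacting the score with three orthogonal polynomials of
   age; the fitted linear interaction is re-expressed on the raw-age scale in
   z-units/allele/year, and the per-allele effect curve

   effect(age) = β<sub>G</sub> + Σ<sub>k</sub> γ<sub>k</sub> P<sub>k</sub>(age)

   is returned with a pointwise 95% band from the fixed-effect covariance.

Because cohorts of this kind are not publicly deposited, the package ships a
first-class **synthetic cohort generator** with Mendelian genotype
transmission inside mother-defined sibships, a dense-infant/sparse-adult
measurement schedule, three variance components, and a per-allele
weight-for-height effect that grows linearly with age — with the ground truth
recorded so estimator recovery can be scored.

## Worked example

```python
from grsgrowth import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(n_families=200, seed=0), seed=42)
res = run_pipeline(cfg)
print(res.associations.round(4).to_string(index=False))
```

```
 age_group               outcome   n  coefficient     se  ci_low  ci_high  pvalue
     birth                   zBW 820      -0.0033 0.0112 -0.0252   0.0186  0.7675
   2 years                   zWT 798       0.0205 0.0115 -0.0020   0.0430  0.0747
   2 years                   zHT 798      -0.0025 0.0108 -0.0237   0.0187  0.8192
    Adults                   zWT 467       0.1140 0.0132  0.0881   0.1400  0.0000
    Adults                   zHT 467      -0.0153 0.0140 -0.0428   0.0121  0.2732
<=20 years                zWT-HT 820       0.0302 0.0077  0.0151   0.0452  0.0001
 >20 years                zWT-HT 467       0.1653 0.0094  0.1468   0.1838  0.0000
    Adults                  zBMI 467       0.1452 0.0127  0.1203   0.1700  0.0000
 0-2 years             WT growth 792       0.0075 0.0021  0.0035   0.0115  0.0003
 0-2 years             LG growth 809       0.0014 0.0013 -0.0011   0.0039  0.2775
2-20 years            zWT change 467       0.0954 0.0111  0.0736   0.1172  0.0000
2-20 years            zHT change 467      -0.0051 0.0048 -0.0145   0.0044  0.2927
  all ages zWT-HT x age (linear) 820       0.0084 0.0011  0.0063   0.0106  0.0000
```

Coefficients are the change in z-score per risk allele (cross-sectional
rows) or per allele per year (longitudinal rows); `n` counts individuals.
This cohort was generated with a per-allele effect of 0.008 z/allele/year and
no effect at birth, and the fitted pattern shows exactly that: nothing at
birth, weak childhood signals, strong adult weight and weight-for-height
associations, and a linear age interaction of

```python
slope = res.interaction.linear_slope_raw()
print(f"linear age interaction: {slope.coefficient:.4f} z/allele/year "
      f"(95% CI {slope.ci_low:.4f} to {slope.ci_high:.4f}, p={slope.pvalue:.2g})")
# linear age interaction: 0.0084 z/allele/year (95% CI 0.0063 to 0.0106, p=2.3e-14)
```

recovering the generating 0.008. `res.interaction.predict_effect_by_age(grid)`
returns the per-allele effect curve with its confidence band, and
`res.manifest` holds the per-stage attrition accounting (every stage's input
count equals its output count plus its exclusions).

The same run is available from the shell:

```bash
grsgrowth run-all --config config.yaml --seed 42 --out results/
```

with `simulate`, `score`, `standardize`, `growth` and `associate` subcommands
for the individual stages; inputs and outputs are plain TSV/JSON.

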