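# neighbordep

Individualized multi-scale neighborhood analysis of income inequality and
relative deprivation, and their association with dichotomous neonatal
outcomes.

## The problem

Whether income *distribution* — not just income level — affects health is
usually studied with administrative units (municipalities, census tracts)
whose boundaries are arbitrary for any given resident. An alternative is the
**egocentric neighborhood**: for each person, the k nearest residents by
proximity, built at several scales (here k = 100, 400, 1600, 6400). On a
population grid of 100 m squares, squares are included outward from a
person's home square until the cumulative resident count reaches at least k;
whole squares are included, so realized counts overshoot k.

Within each neighborhood, two exposures are computed from the neighbors'
national income percentiles:

- **Gini index** (neighborhood income inequality):
  `G = Σᵢ Σⱼ |yᵢ − yⱼ| / (2 n² μ)`, in [0, 1);
- **Deaton index** (the mother's relative deprivation): the Yitzhaki index
  `RD = (1/N) Σ_{yⱼ > y} (yⱼ − y)` normalized by the reference-group mean,
  `D = RD / μ`, in [0, 1]. The population mean of D equals the group's G —
  an identity this package tests to machine precision.

Associations with five dichotomized neonatal outcomes — small for
gestational age (< 10th percentile for gestational week), low and very low
birthweight (< 2500 g, < 1500 g), preterm birth (< gestational week 37) and
low 5-minute Apgar score (< 7) — are estimated by multiple logistic
regression with maternal covariates and scale-matched neighborhood
covariates, summarized as **average marginal effects (AME)** of a +0.1
index increment:

    AME = (1/n) Σᵢ [expit(ηᵢ + β·0.1) − expit(ηᵢ)]

with delta-method standard errors and Wald 95% CIs. The default grid —
2 indices × 4 scales × 5 outcomes, as main-effect and income-decile
interaction models — is 80 logistic models.

Because register data of this kind are confidential, the package ships a
seeded synthetic generator that reproduces the assumed data structure
(households on a grid, spatially autocorrelated log-normal incomes,
equivalization by consumption units, outcomes drawn from logistic models
with known coefficients), so every estimator can be validated by parameter
recovery against a ground-truth oracle.

## Worked example

```python
from neighbordep import deaton, gini_exact, yitzhaki

gini_exact([1, 2, 3])   # 0.2222  (mean |pairwise difference| / (2 n² μ))
yitzhaki(1, [1, 2, 3])  # 1.0     (mean shortfall vs the two richer members)
deaton(1, [1, 2, 3])    # 0.5     (Yitzhaki / mean income 2.0)
deaton(3, [1, 2, 3])    # 0.0     (no one richer)
```

End to end (also available as `neighbordep run-all` from a shell):

```python
from neighbordep import RunConfig, SyntheticConfig, run

cfg = RunConfig(
    synthetic=SyntheticConfig(seed=3, n_persons=12_000, n_mothers=2_500,
                              grid_extent=40),
    k_levels=(100, 400),
)
bundle = run(cfg, "my_run")
print(bundle["results"].head())
```

This fits 40 models and writes `results.csv` with one row per model ×
stratum, e.g. (seed 3):

```
index_type  k_level  outcome  ame_per_0.1   ci_low  ci_high  n_used
    deaton      400  preterm     -0.02498 -0.04202 -0.00794    2500
```

read as: a 0.1 higher Deaton index is associated with a 2.5
percentage-point lower preterm probability in this (null-model) demo cohort
— with 40 cells and null effects, an occasional CI excluding zero is the
expected 5% false-positive behavior.

The `examples/` scripts walk through each capability (simulation,
neighborhoods, indices, the model grid, parameter recovery) and print a
line explaining every number they show.

## Command-line pipeline

```bash
neighbordep simulate  --config config.yaml --workdir run/
neighbordep contexts  --config config.yaml --workdir run/
neighbordep indices   --config config.yaml --workdir run/
neighbordep outcomes  --config config.yaml --workdir run/
neighbordep analyze   --config config.yaml --workdir run/
neighbordep report    --workdir run/
```

All stage contracts are plain CSV, so register-style data can replace the
simulator: supply `population.csv` (person_id, square_e, square_n,
household_id, equiv_income, income_percentile) and `births.csv` and start
from `contexts`. Exit codes: 0 ok, 2 config error, 3 data error, 4
non-convergence.

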