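# Methods

## Individualized neighborhoods

Each mother's neighborhood at level k is built on a sparse grid of occupied
100 m squares. Distance is planar Euclidean distance between square
centroids (`(100e+50, 100n+50)` meters); the focal point is the mother's
home-square centroid, since within-square positions are unknown. Squares
are sorted by squared integer distance (so ties are exact, never
floating-point accidents) and included outward until the cumulative
resident count reaches at least k. Equidistant squares form an atomic
batch — all included or none — which makes the result independent of any
arbitrary ordering of tied squares and can only enlarge the overshoot that
whole-square inclusion already implies. Residents of the focal square are
at distance zero and always included first; the mother counts among her own
neighbors by default (she is an adult resident of her square), with
`include_self=False` provided as a sensitivity toggle that removes her from
the count, histogram and income sum before thresholding.

The implementation is a vectorized full sort over occupied squares, cached
per focal square (mothers sharing a square share the expansion). Its
contract is behavioral: it must equal a brute-force sort-all-squares scan,
and a pure-Python oracle of exactly that form is part of the test suite and
the acceptance checks. Aggregates per context: realized neighbor count,
length-100 income-percentile histogram, mean resident distance (count-
weighted square-centroid distance) and mean equivalized income.

## Income percentiles and indices

National percentiles are assigned by stable rank on (income, person id):
percentile p holds ranks ((p−1)n/100, pn/100], so tied incomes split
deterministically across boundaries. Each percentile's representative
income is its within-percentile mean.

Indices are computed on percentile representative incomes by default,
because neighborhoods are characterized by percentile membership; a
raw-income mode (`use_representative_incomes=False`) recomputes both
indices on the exact incomes of the included residents for sensitivity.

The Gini uses the n² denominator, `G = Σᵢⱼ|yᵢ−yⱼ|/(2n²μ)`, evaluated via
the sorted-rank identity (exact under ties). This is the form under which
the mean Deaton index of a population equals its Gini exactly; that duality
is enforced to 1e-10 in tests and typically holds to ~1e-16. The grouped
(histogram) Gini is an exact quadratic form of the histogram in the
|Δ representative income| matrix and equals the expanded-multiset Gini to
1e-12. The Deaton index is mathematically in [0, 1]; the implementation
clamps float round-off at the top bound. Degenerate inputs raise: all-zero
incomes or empty reference groups are undefined-index errors, not NaNs.

## Outcomes

All cutoffs are strict: preterm < 259 days (37 completed weeks × 7), LBW
< 2500 g, VLBW < 1500 g, low Apgar < 7. Gestational age is carried in days;
completed week = floor(days/7). The SGA reference is built within-cohort
(no external growth standard is assumed): per completed week, the empirical
10th percentile is the weight at rank ⌈0.1·n⌉; weeks with fewer than 50
births are pooled with the nearest week, and the threshold curve is made
non-decreasing by a running maximum, since a reference curve cannot fall
with gestational age. Missing continuous fields yield missing flags, which
drop the record from any model fit (complete-case analysis).

## Effect estimation

One logistic model per (index, k-level, outcome) cell, fitted by IRLS
(statsmodels GLM/Binomial, 100 iterations, tolerance 1e-10) on complete
cases, with observed-information covariance. Designs are checked for rank
before fitting; aliased columns are named in the error. A fit whose
coefficients exceed 25 in absolute value is flagged unconverged — at that
magnitude a cell is quasi-separated and its Wald quantities untrustworthy —
and the grid records the failure and continues.

Covariates: categorical sets (age band, education, occupation, civil
status, region of origin, parity) enter as full dummies with the most
frequent level as reference; individual income enters as log1p of the
equivalized value; distance to the labor ward, mean distance to neighbors
and mean neighborhood income (both at the cell's own k-level) are
continuous. Interaction models replace the income term with decile
indicators (deciles ranked within the mother cohort, ties broken by id) and
add index × decile slopes.

The AME of a +0.1 increment uses the discrete-change form — the
counterfactual adds 0.1 to every observation's index and re-derives any
interaction columns — because "per 0.1 increment" is literally a 0.1
change; a derivative mode (`mean(f(η)·∂η/∂x)·0.1`) is available for
comparison and agrees closely at small increments. Standard errors are
delta-method with the analytic gradient of the AME in the full coefficient
vector; tests confirm agreement with a finite-difference gradient (to 1e-5
relative) and with a nonparametric bootstrap (within 15%). CIs are Wald
with z = 1.959964, unadjusted for multiplicity across the grid. Decile AMEs
average the counterfactual change over that decile's observations with CIs
from the joint covariance. The default grid is 80 models: 40 main-effect
(2 indices × 4 k-levels × 5 outcomes) plus the same 40 cells refitted with
income-decile interactions.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated. It emulates: adults in one- or two-adult households (couple
share 0.55, child counts 0–3) placed with density decaying exponentially
from a central square (urban gradient 3); log-normal household income
(log-mean 12.2 ≈ 200 kSEK/year, log-sd 0.45) around a spatial field built
as box-smoothed white noise (range 4 squares, sd 0.30 on the log scale) —
a deliberate approximation of a Gaussian random field that is sufficient to
produce realistic neighborhood income clustering (lag-1 square-mean
correlation ≈ 0.49 at range 5, by simulation); equivalization by a
Statistics-Sweden-like consumption-unit scale (1.0 / 0.51 per additional
adult / 0.60 per child), configurable because the official scale is not
fixed here; equivalized incomes floored at 0 before any percentile or index
computation.

Mothers are sampled uniformly within income deciles among women aged
18–45, guaranteeing decile coverage for the interaction models. Outcome
flags are Bernoulli draws from per-outcome logistic models whose linear
predictor includes the mother's true Deaton and Gini indices at a reference
k-level (default 100) plus configurable covariate effects; default
intercepts match 2019 Swedish singleton prevalences (SGA 2.4%, LBW 3.1%,
VLBW 0.5%, preterm 4.7%, low Apgar 1.6%). VLBW forces LBW, and the LBW draw
is conditionally adjusted so its marginal probability still equals its
model's — both models remain exactly true. Continuous measures are
back-filled from truncated normals consistent with the flags (gestational
age bands split at 259 days; birthweight bands at 1500/2500 g with a slope
of 23 g/day of gestation and an optional mean shift per unit Deaton).

SGA is the one outcome whose flag cannot round-trip exactly: the analysis
reference is a within-cohort empirical percentile, which flags ~10% per
week cell regardless of how many flags the generator drew. Birthweights are
therefore placed on the drawn flag's side of the parametric week-specific
10th-percentile curve, which makes recomputed and drawn flags agree for
almost all births when the drawn prevalence is near 10%; the remaining
disagreement is boundary noise. Validation studies consequently regress the
generator's drawn flags (the ground truth), while the production pipeline
stage uses the recomputed ones, as it must on real data. The other four outcomes round-trip
exactly, and tests assert this.

What the generator does **not** emulate: real geography or road distances,
occupation/education codebooks, migration and temporal dynamics, multiple
or stillbirths, and spatial correlation in the *outcomes* beyond what the
Deaton/Gini terms induce. Passing tests therefore demonstrate that the
estimators are correct under the assumed data structure, not that the
epidemiological associations generalize to register data.

## Verification studies and problem sizes

- **Index identities**: 120 random multisets (n 2–500) for the
  duality check; 120 random histograms for grouped-Gini consistency.
- **Neighborhood oracle**: 50 random grids (≤ 60×60, ≤ 20,000 persons),
  four random (focal, k) probes each, against the pure-Python oracle.
- **Parameter recovery**: 50 replications of cohorts with 100,000 adults on
  an 80×80 grid and 20,000 mothers, SGA generated with Deaton coefficient
  1.5 (baseline intercept −3.9); the fitted model uses a reduced covariate
  set (age band, education, log income, labor-ward distance, and the
  reference-k mean income and distance) so events-per-variable stays
  reasonable; acceptance band 88–100% CI coverage at 50 replications.
- **Type-I error**: 50 null replications (80,000 adults, 16,000 mothers,
  70×70 grid, all four k-levels) of the 40-cell main-effect grid with the
  same reduced covariate set; the share of usable cells whose CI excludes
  zero is compared to the nominal 5%. Cohort size matters here: the Deaton
  index is nearly collinear with own log income (r ≈ −0.95), and at k=6400
  the Gini exposure retains little partial variance on a desk-scale grid,
  so the effective information for the index is far below n and the Wald
  z-statistics are overdispersed in small cohorts (sd ≈ 1.2 at 6,000
  mothers). The default is the largest cohort whose 50-replication study
  still runs in minutes; z variance is near 1 for most cells there, with
  residual mild anticonservatism in the large-k Gini cells — an honest
  small-scale property of Wald inference under low effective information,
  which disappears at register scale. Unconverged (quasi-separated) cells
  are excluded from the share.

These sizes were chosen as the smallest at which the rare outcomes still
yield stable fits; all studies are seeded and reproducible from
`scripts/acceptance.py --seed`.

## Known limitations

- Delta-method CIs ignore the spatial overlap of neighborhoods across
  mothers; no spatial standard-error correction is applied, a deliberate
  design choice of this analysis.
- Quasi-separation handling is a coefficient-magnitude heuristic, not a
  penalized (e.g. Firth) fit.
- The smoothed-noise income field has boxy short-range correlation, not a
  true covariance model; its range parameter is in squares, not meters.
- `results.csv` floats are written with `%.17g` and should be read back
  with round-trip float parsing (the CLI does) for bit-identical stage
  substitution.
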