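"""Seeded synthetic population and birth-cohort generator.

The generator emulates the statistical structure the neighborhood analysis
assumes: adults living in households on a 100 m grid with density decaying
from an urban center, spatially autocorrelated log-normal household incomes,
household equivalization, and dichotomous neonatal outcomes drawn from a
logistic model whose linear predictor includes the mother's *true* Deaton
index at a reference k-level.  Because the true coefficients are known,
effect estimates can be checked by parameter recovery against
:func:`oracle_true_ame`.

Continuous birth measures are back-filled from truncated normals consistent
with the drawn flags, so the dichotomization module recovers the generated
preterm/LBW/VLBW/low-Apgar flags exactly.  The SGA flag is drawn from its
logistic model and birthweights are placed on the matching side of the
parametric week-specific 10th-percentile curve; the within-cohort empirical
SGA reference then reproduces the drawn flag up to boundary-cell noise (an
empirical percentile cannot be pre-committed by the generator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.special import expit
from scipy.stats import truncnorm

from .config import OUTCOMES, EquivalenceScale, OutcomeModel, SyntheticConfig
from .errors import ConfigError, DataError
from .indices import compute_income_percentiles, exposures_for_mothers
from .neighborhoods import build_grid, contexts_for_mothers

Z10 = -1.2815515655446004  # standard-normal 10th-percentile quantile

#: categorical covariate levels and decile tilts (log-linear in the
#: standardized decile); positive tilt = more common in richer deciles
_CATEGORICALS = {
    "education": (("basic", "secondary", "tertiary", "postgrad"),
                  (0.18, 0.40, 0.37, 0.05), (-0.8, -0.2, 0.5, 0.9)),
    "occupation": (("not_employed", "service", "clerk", "professional"),
                   (0.21, 0.30, 0.12, 0.37), (-0.9, -0.2, 0.2, 0.7)),
    "civil_status": (("unmarried", "married", "divorced"),
                     (0.49, 0.47, 0.04), (-0.1, 0.2, -0.3)),
    "region_of_origin": (("sweden", "nordic", "oecd", "non_oecd"),
                         (0.70, 0.01, 0.05, 0.24), (0.3, 0.1, 0.1, -0.6)),
}

_AGE_BANDS = ["<25", "25-29", "30-34", "35-39", ">=40"]


def equivalized_income(
    raw_income: float, n_adults: int, n_children: int, scale: EquivalenceScale
) -> float:
    """Household income per consumption unit.

    Divides the household's raw disposable income by the sum of equivalence
    weights of its members (first adult 1.0, further adults and children per
    the scale).
    """
    if n_adults < 1:
        raise DataError("household must contain at least one adult")
    return raw_income / scale.divisor(n_adults, n_children)


def _spatial_field(rng: np.random.Generator, extent: int, rng_squares: int, sd: float) -> np.ndarray:
    """Smoothed-white-noise approximation of a Gaussian random field on the
    grid, standardized to standard deviation ``sd`` on the log-income scale."""
    white = rng.standard_normal((extent, extent))
    if rng_squares > 0:
        field = uniform_filter(white, size=2 * rng_squares + 1, mode="nearest")
    else:
        field = white
    s = field.std()
    if sd <= 0 or s == 0:
        return np.zeros((extent, extent))
    return field * (sd / s)


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the adult person table.

    Households (one or two adults, a drawn number of children) are placed on
    the grid with density decaying from the central square at the configured
    urban gradient; household raw income is log-normal around a spatially
    autocorrelated field; all members share the household's equivalized
    income.  Columns: ``person_id, household_id, square_e, square_n,
    equiv_income, female, age`` (``income_percentile`` is assigned separately
    by :func:`assign_percentiles`).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.grid_extent
    hm, im = config.household_model, config.income_model

    # households until the adult count reaches n_persons
    n_h_max = config.n_persons
    adults = np.where(rng.random(n_h_max) < hm.couple_share, 2, 1)
    cum = np.cumsum(adults)
    n_h = int(np.searchsorted(cum, config.n_persons)) + 1
    adults = adults[:n_h]
    overshoot = int(cum[n_h - 1]) - config.n_persons
    if overshoot:
        adults[-1] -= overshoot
    probs = np.asarray(hm.child_count_probs, dtype=float)
    children = rng.choice(probs.size, size=n_h, p=probs / probs.sum())

    # placement: density decays with distance from the grid center
    c = (G - 1) / 2.0
    ee, nn = np.meshgrid(np.arange(G), np.arange(G), indexing="ij")
    d = np.hypot(ee - c, nn - c)
    w = np.exp(-im.urban_gradient * d / max(G / 2.0, 1.0)).ravel()
    sq = rng.choice(G * G, size=n_h, p=w / w.sum())
    h_e, h_n = sq // G, sq % G

    field = _spatial_field(rng, G, im.spatial_range, im.spatial_sd)
    log_inc = rng.normal(im.log_mean + field[h_e, h_n], im.log_sd)
    raw = np.exp(log_inc)
    divisor = (
        config.equivalence_scale.first_adult
        + (adults - 1) * config.equivalence_scale.additional_adult
        + children * config.equivalence_scale.child
    )
    equiv = np.maximum(raw / divisor, config.income_floor)

    hh_idx = np.repeat(np.arange(n_h), adults)
    n_p = hh_idx.size
    persons = pd.DataFrame(
        {
            "person_id": np.arange(n_p, dtype=np.int64),
            "household_id": hh_idx.astype(np.int64),
            "square_e": h_e[hh_idx].astype(np.int64),
            "square_n": h_n[hh_idx].astype(np.int64),
            "equiv_income": equiv[hh_idx],
            "female": rng.random(n_p) < 0.5,
            "age": (18 + np.floor(67 * rng.beta(1.2, 1.5, size=n_p))).astype(np.int64),
        }
    )
    return persons


def assign_percentiles(persons: pd.DataFrame):
    """Assign national income percentiles (1..100) in place; returns the scale."""
    pct, scale = compute_income_percentiles(
        persons["equiv_income"].to_numpy(), persons["person_id"].to_numpy()
    )
    persons["income_percentile"] = pct
    return scale


def _tilted_categorical(rng, levels, base, tilt, decile):
    z = (decile - 5.5) / 4.5
    logits = np.log(np.asarray(base)) + np.outer(z, np.asarray(tilt))
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(decile))
    idx = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.asarray(levels)[idx]


def _sample_mothers(rng, persons: pd.DataFrame, n_mothers: int) -> pd.DataFrame:
    """Sample mothers uniformly within income deciles among women aged 18-45."""
    eligible = persons[(persons["female"]) & (persons["age"].between(18, 45))]
    if len(eligible) < n_mothers:
        raise DataError(
            f"only {len(eligible)} eligible women for {n_mothers} mothers"
        )
    decile = (eligible["income_percentile"].to_numpy() - 1) // 10 + 1
    base, extra = divmod(n_mothers, 10)
    picks = []
    for di in range(1, 11):
        want = base + (1 if di <= extra else 0)
        pool = eligible.index[decile == di].to_numpy()
        if len(pool) < want:
            raise DataError(
                f"income decile {di} has only {len(pool)} eligible women, need {want}"
            )
        picks.append(rng.choice(pool, size=want, replace=False))
    rows = np.concatenate(picks)
    return persons.loc[np.sort(rows)].copy()


def linear_predictor(births: pd.DataFrame, model: OutcomeModel) -> np.ndarray:
    """True linear predictor of one outcome model on a mother table with
    ``true_deaton``, ``true_gini``, ``equiv_income`` and covariate columns."""
    eta = np.full(len(births), model.intercept, dtype=float)
    eta += model.beta_deaton * births["true_deaton"].to_numpy()
    eta += model.beta_gini * births["true_gini"].to_numpy()
    eta += model.beta_log_income * np.log1p(births["equiv_income"].to_numpy())
    for cov, effects in model.categorical_effects.items():
        vals = births[cov].astype(str)
        eta += vals.map(lambda v: float(effects.get(v, 0.0))).to_numpy()
    return eta


def sga_weight_threshold(gest_days: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Parametric 10th-percentile birthweight curve by completed week."""
    bm = config.birth_model
    week_mid_days = (np.floor_divide(gest_days, 7) + 0.5) * 7.0
    mean_w = bm.birthweight_mean_g + bm.birthweight_slope_g_per_day * (
        week_mid_days - bm.gest_mean_days
    )
    return mean_w + Z10 * bm.birthweight_sd_g


def _trunc_normal(rng, mean, sd, low, high):
    a = (low - mean) / sd
    b = (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def generate_births(persons: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Sample mothers, compute their true exposures, and draw births.

    Outcome flags are Bernoulli draws from the configured logistic models
    (VLBW forces LBW; the LBW draw is adjusted so its marginal probability
    still equals the model's, keeping both models exactly true).  Continuous
    measures are back-filled consistent with the flags.
    """
    for name in OUTCOMES:
        if name not in config.outcome_model:
            raise ConfigError(f"outcome_model missing outcome {name!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    persons = persons.copy()
    scale = assign_percentiles(persons)
    grid = build_grid(persons)
    mothers = _sample_mothers(rng, persons, config.n_mothers)

    contexts = contexts_for_mothers(grid, mothers, [config.reference_k_level])
    expo = exposures_for_mothers(contexts, scale, mothers)
    expo = expo.set_index("mother_id")
    births = mothers.reset_index(drop=True)
    births["true_deaton"] = expo["deaton"].loc[births["person_id"]].to_numpy()
    births["true_gini"] = expo["gini"].loc[births["person_id"]].to_numpy()
    # reference-k context aggregates, reusable as covariates in truth-level fits
    births["ref_mean_income"] = expo["mean_income"].loc[births["person_id"]].to_numpy()
    births["ref_mean_distance_m"] = expo["mean_distance_m"].loc[births["person_id"]].to_numpy()

    n = len(births)
    decile = (births["income_percentile"].to_numpy() - 1) // 10 + 1
    for cov, (levels, base, tilt) in _CATEGORICALS.items():
        births[cov] = _tilted_categorical(rng, levels, base, tilt, decile)
    births["age_band"] = pd.cut(
        births["age"], bins=[0, 24, 29, 34, 39, 200], labels=_AGE_BANDS
    ).astype(str)
    births["parity"] = 1 + np.minimum(rng.poisson(0.9, size=n), 4)
    c = (config.grid_extent - 1) / 2.0
    d_sq = np.hypot(births["square_e"] - c, births["square_n"] - c)
    births["distance_to_labor_ward"] = 0.1 * d_sq + rng.exponential(1.0, size=n)

    # outcome flags from the true logistic models
    p = {name: expit(linear_predictor(births, config.outcome_model[name]))
         for name in OUTCOMES}
    flags = {}
    flags["sga"] = (rng.random(n) < p["sga"]).astype(np.int64)
    flags["preterm"] = (rng.random(n) < p["preterm"]).astype(np.int64)
    flags["low_apgar"] = (rng.random(n) < p["low_apgar"]).astype(np.int64)
    flags["vlbw"] = (rng.random(n) < p["vlbw"]).astype(np.int64)
    # VLBW implies LBW; adjust the conditional draw so P(lbw) stays exact
    q = np.clip((p["lbw"] - p["vlbw"]) / np.maximum(1 - p["vlbw"], 1e-12), 0, 1)
    flags["lbw"] = np.where(
        flags["vlbw"] == 1, 1, (rng.random(n) < q).astype(np.int64)
    )

    bm = config.birth_model
    # gestational age: preterm < 259 days, term in [259, 315]
    gest = np.empty(n)
    pre = flags["preterm"] == 1
    if pre.any():
        gest[pre] = _trunc_normal(
            rng,
            np.full(pre.sum(), bm.gest_mean_days),
            np.full(pre.sum(), bm.gest_sd_days),
            154.0,
            258.999,
        )
    if (~pre).any():
        gest[~pre] = _trunc_normal(
            rng,
            np.full((~pre).sum(), bm.gest_mean_days),
            np.full((~pre).sum(), bm.gest_sd_days),
            259.0,
            315.999,
        )
    gest = np.floor(gest).astype(np.int64)

    # birthweight bands: VLBW (200, 1500), LBW [1500, 2500), else [2500, 7000)
    low = np.where(flags["vlbw"] == 1, 201.0, np.where(flags["lbw"] == 1, 1500.0, 2500.0))
    high = np.where(flags["vlbw"] == 1, 1499.9, np.where(flags["lbw"] == 1, 2499.9, 6999.0))
    thr = sga_weight_threshold(gest, config)
    sga1 = flags["sga"] == 1
    # SGA side of the parametric threshold where compatible with the LBW band
    new_high = np.where(sga1, np.minimum(high, thr - 0.1), high)
    new_low = np.where(~sga1, np.maximum(low, np.minimum(thr, high - 50.0)), low)
    ok = new_low < new_high
    low = np.where(ok, new_low, low)
    high = np.where(ok, new_high, high)
    mean_w = (
        bm.birthweight_mean_g
        + bm.birthweight_slope_g_per_day * (gest - bm.gest_mean_days)
        + bm.weight_shift_per_deaton * births["true_deaton"].to_numpy()
    )
    weight = _trunc_normal(rng, mean_w, np.full(n, bm.birthweight_sd_g), low, high)

    apgar = np.where(
        flags["low_apgar"] == 1,
        rng.choice(7, size=n, p=[0.02, 0.03, 0.05, 0.10, 0.20, 0.25, 0.35]),
        rng.choice(np.arange(7, 11), size=n, p=[0.03, 0.07, 0.25, 0.65]),
    )

    births["gest_age_days"] = gest
    births["birthweight_g"] = np.round(weight, 1)
    births["apgar5"] = apgar.astype(np.int64)
    for name in OUTCOMES:
        births[name] = flags[name]
    return births.drop(columns=["female"])


def oracle_true_ame(
    births: pd.DataFrame,
    outcome_model: OutcomeModel,
    var: str = "deaton",
    delta: float = 0.1,
) -> float:
    """True-population average marginal effect of a +``delta`` increment.

    Mean over mothers of ``expit(eta + beta*delta) - expit(eta)`` computed
    from the *true* coefficients — the parameter-recovery target for the
    fitted AMEs.
    """
    beta = {"deaton": outcome_model.beta_deaton, "gini": outcome_model.beta_gini}[var]
    eta = linear_predictor(births, outcome_model)
    return float(np.mean(expit(eta + beta * delta) - expit(eta)))
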