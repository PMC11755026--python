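"""Configuration objects for the synthetic generator and the pipeline.

All configuration is plain dataclasses so a run is fully described by a
single YAML mapping; :func:`SyntheticConfig.from_dict` /
:meth:`SyntheticConfig.to_dict` round-trip losslessly, which is what makes
seeded runs reproducible and hashable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError

#: The five dichotomous neonatal outcomes, in canonical order.
OUTCOMES = ("sga", "lbw", "vlbw", "preterm", "low_apgar")

#: Default neighborhood size levels (approximate nearest-neighbor counts).
DEFAULT_K_LEVELS = (100, 400, 1600, 6400)


@dataclass
class IncomeModel:
    """Log-normal household income with a spatially autocorrelated field.

    ``log_mean``/``log_sd`` parameterize log household disposable income in
    SEK/year.  The spatial field is smoothed white noise with box-smoothing
    half-width ``spatial_range`` (grid squares) scaled to standard deviation
    ``spatial_sd`` on the log scale; ``urban_gradient`` controls how strongly
    residential density decays away from the urban center.
    """

    log_mean: float = 12.2  # exp ~ 200 kSEK/year household income
    log_sd: float = 0.45
    spatial_range: int = 4
    spatial_sd: float = 0.30
    urban_gradient: float = 3.0


@dataclass
class HouseholdModel:
    couple_share: float = 0.55
    #: probabilities for 0, 1, 2, ... children per household
    child_count_probs: tuple[float, ...] = (0.45, 0.22, 0.24, 0.09)


@dataclass
class EquivalenceScale:
    """Consumption-unit weights: first adult, each additional adult, each child.

    First-adult weight is 1.0 by convention; the additional-adult and child
    weights default to a Statistics-Sweden-like scale.
    """

    first_adult: float = 1.0
    additional_adult: float = 0.51
    child: float = 0.60

    def divisor(self, n_adults: int, n_children: int) -> float:
        if n_adults < 1:
            raise ConfigError("household must contain at least one adult")
        return (
            self.first_adult
            + (n_adults - 1) * self.additional_adult
            + n_children * self.child
        )


@dataclass
class OutcomeModel:
    """True logistic model for one dichotomous outcome.

    The linear predictor is
    ``intercept + beta_deaton * D + beta_gini * G + beta_log_income *
    log1p(equivalized income) + categorical level effects``, with D and G the
    mother's Deaton and neighborhood Gini index at the generator's reference
    k-level.
    """

    intercept: float = -3.0
    beta_deaton: float = 0.0
    beta_gini: float = 0.0
    beta_log_income: float = 0.0
    #: covariate -> {level -> coefficient}; unlisted levels get 0
    categorical_effects: dict = field(default_factory=dict)


@dataclass
class BirthModel:
    """Continuous birth measures consistent with the drawn outcome flags."""

    gest_mean_days: float = 280.0
    gest_sd_days: float = 9.0
    birthweight_mean_g: float = 3500.0
    birthweight_sd_g: float = 450.0
    #: g per day of gestation, applied around the mean gestational age
    birthweight_slope_g_per_day: float = 23.0
    #: shift of mean birthweight (g) per unit of the mother's Deaton index
    weight_shift_per_deaton: float = 0.0


def _default_outcome_models() -> dict:
    # Baseline prevalences follow the national 2019 singleton cohort rates.
    return {
        "sga": OutcomeModel(intercept=-3.70),
        "lbw": OutcomeModel(intercept=-3.43),
        "vlbw": OutcomeModel(intercept=-5.29),
        "preterm": OutcomeModel(intercept=-3.01),
        "low_apgar": OutcomeModel(intercept=-4.12),
    }


@dataclass
class SyntheticConfig:
    """Full description of one synthetic population + birth cohort."""

    seed: int = 0
    grid_extent: int = 50
    n_persons: int = 20_000
    n_mothers: int = 4_000
    income_model: IncomeModel = field(default_factory=IncomeModel)
    household_model: HouseholdModel = field(default_factory=HouseholdModel)
    equivalence_scale: EquivalenceScale = field(default_factory=EquivalenceScale)
    outcome_model: dict = field(default_factory=_default_outcome_models)
    birth_model: BirthModel = field(default_factory=BirthModel)
    #: k-level at which the generator computes the true Deaton/Gini exposures
    reference_k_level: int = 100
    income_floor: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.grid_extent <= 0:
            raise ConfigError("grid_extent must be positive")
        if self.n_persons <= 0:
            raise ConfigError("n_persons must be positive")
        if self.n_mothers > self.n_persons:
            raise ConfigError("n_mothers cannot exceed n_persons")
        if self.equivalence_scale.first_adult != 1.0:
            raise ConfigError("first-adult equivalence weight must be 1.0")
        if (
            self.equivalence_scale.additional_adult <= 0
            or self.equivalence_scale.child <= 0
        ):
            raise ConfigError("equivalence-scale weights must be positive")
        for name in OUTCOMES:
            if name not in self.outcome_model:
                raise ConfigError(f"outcome_model missing outcome {name!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "income_model" in d and isinstance(d["income_model"], Mapping):
            d["income_model"] = IncomeModel(**d["income_model"])
        if "household_model" in d and isinstance(d["household_model"], Mapping):
            hm = dict(d["household_model"])
            if "child_count_probs" in hm:
                hm["child_count_probs"] = tuple(hm["child_count_probs"])
            d["household_model"] = HouseholdModel(**hm)
        if "equivalence_scale" in d and isinstance(d["equivalence_scale"], Mapping):
            d["equivalence_scale"] = EquivalenceScale(**d["equivalence_scale"])
        if "birth_model" in d and isinstance(d["birth_model"], Mapping):
            d["birth_model"] = BirthModel(**d["birth_model"])
        if "outcome_model" in d:
            om = {}
            for k, v in d["outcome_model"].items():
                om[k] = OutcomeModel(**v) if isinstance(v, Mapping) else v
            d["outcome_model"] = om
        return cls(**d)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunConfig:
    """End-to-end pipeline run: synthetic config plus analysis options."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    k_levels: tuple[int, ...] = DEFAULT_K_LEVELS
    #: compute indices on percentile representative incomes (default) or raw
    use_representative_incomes: bool = True
    #: count the mother among her own neighbors (default) or exclude her
    include_self: bool = True
    #: discrete-change (+0.1 counterfactual) AME or derivative * 0.1
    ame_mode: str = "discrete"
    ame_delta: float = 0.1
    n_deciles: int = 10
    workdir: str = "neighbordep_run"
    log_level: str = "INFO"

    def __post_init__(self):
        ks = tuple(int(k) for k in self.k_levels)
        if not ks or list(ks) != sorted(ks):
            raise ConfigError("k_levels must be non-empty and ascending")
        self.k_levels = ks
        if self.ame_mode not in ("discrete", "derivative"):
            raise ConfigError("ame_mode must be 'discrete' or 'derivative'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], Mapping):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "k_levels" in d:
            d["k_levels"] = tuple(d["k_levels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
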