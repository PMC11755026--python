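"""End-to-end orchestration: simulate -> grid -> contexts -> indices ->
outcomes -> effects, with CSV contracts between stages and a run manifest.

Each stage is a pure function of its declared inputs, so external data can
replace the simulator: supply your own ``population.csv`` / ``births.csv``
with the documented columns and start from the contexts stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .effects import count_model_records, run_model_grid
from .errors import PipelineError
from .indices import (
    PercentileScale,
    exposures_for_mothers,
    raw_exposures_for_mothers,
)
from .neighborhoods import (
    build_grid,
    contexts_for_mothers,
    contexts_to_frame,
    frame_to_contexts,
)
from .outcomes import derive_outcomes
from .synthetic import assign_percentiles, generate_births, generate_population

log = logging.getLogger("neighbordep")

#: float64 values survive the CSV round trip bit-exactly with this format
FLOAT_FMT = "%.17g"

POPULATION_CSV = "population.csv"
BIRTHS_CSV = "births.csv"
SCALE_CSV = "percentile_scale.csv"
CONTEXTS_CSV = "contexts.csv"
EXPOSURES_CSV = "exposures.csv"
OUTCOMES_CSV = "outcomes.csv"
RESULTS_CSV = "results.csv"
MANIFEST_JSON = "manifest.json"


def stage_simulate(config: RunConfig):
    """Generate population + births; returns (population, births, scale)."""
    persons = generate_population(config.synthetic)
    scale = assign_percentiles(persons)
    births = generate_births(persons, config.synthetic)
    log.info("simulate: %d persons, %d births", len(persons), len(births))
    return persons, births, scale


def stage_contexts(population: pd.DataFrame, births: pd.DataFrame, config: RunConfig):
    """Individualized neighborhoods for every mother at every k-level."""
    grid = build_grid(population)
    mothers = births[["person_id", "square_e", "square_n"]].copy()
    extra = population.set_index("person_id")
    mothers["income_percentile"] = extra["income_percentile"].loc[mothers["person_id"]].to_numpy()
    mothers["equiv_income"] = extra["equiv_income"].loc[mothers["person_id"]].to_numpy()
    contexts = contexts_for_mothers(
        grid, mothers, config.k_levels, include_self=config.include_self
    )
    log.info("contexts: %d (mothers x k-levels)", len(contexts))
    return contexts, grid


def stage_indices(contexts, grid, scale: PercentileScale,
                  population: pd.DataFrame, births: pd.DataFrame,
                  config: RunConfig) -> pd.DataFrame:
    """Exposure table (Gini + Deaton per mother x k-level)."""
    mothers = population[population["person_id"].isin(births["person_id"])]
    if config.use_representative_incomes:
        expo = exposures_for_mothers(contexts, scale, mothers)
    else:
        expo = raw_exposures_for_mothers(contexts, grid, mothers)
    log.info("indices: %d exposure records", len(expo))
    return expo


def stage_outcomes(births: pd.DataFrame) -> pd.DataFrame:
    out = derive_outcomes(births)
    n_missing = int(out[["sga", "lbw", "vlbw", "preterm", "low_apgar"]].isna().sum().sum())
    log.info("outcomes: %d records, %d missing flags", len(out), n_missing)
    return out


def stage_analyze(exposures: pd.DataFrame, outcome_table: pd.DataFrame,
                  births: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    results = run_model_grid(
        exposures,
        outcome_table,
        births,
        k_levels=config.k_levels,
        delta=config.ame_delta,
        mode=config.ame_mode,
        n_deciles=config.n_deciles,
    )
    log.info(
        "analyze: %d model records, %d result rows",
        count_model_records(results), len(results),
    )
    return results


def run(config: RunConfig, workdir: str | Path | None = None) -> dict:
    """Execute all stages, writing the CSV contracts and a manifest.

    Returns a dict with the in-memory tables and the manifest.  Identical
    config (same seed) yields byte-identical CSVs.
    """
    wd = Path(workdir if workdir is not None else config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.synthetic.seed,
        "version": __version__,
        "row_counts": {},
    }

    def _fail(stage, exc):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    try:
        population, births, scale = stage_simulate(config)
    except Exception as exc:
        _fail("simulate", exc)
    population.to_csv(wd / POPULATION_CSV, index=False, float_format=FLOAT_FMT)
    births.to_csv(wd / BIRTHS_CSV, index=False, float_format=FLOAT_FMT)
    scale.to_frame().to_csv(wd / SCALE_CSV, index=False, float_format=FLOAT_FMT)
    manifest["row_counts"]["population"] = len(population)
    manifest["row_counts"]["births"] = len(births)

    try:
        contexts, grid = stage_contexts(population, births, config)
    except Exception as exc:
        _fail("contexts", exc)
    contexts_to_frame(contexts).to_csv(wd / CONTEXTS_CSV, index=False, float_format=FLOAT_FMT)
    manifest["row_counts"]["contexts"] = len(contexts)

    try:
        exposures = stage_indices(contexts, grid, scale, population, births, config)
    except Exception as exc:
        _fail("indices", exc)
    exposures.to_csv(wd / EXPOSURES_CSV, index=False, float_format=FLOAT_FMT)
    manifest["row_counts"]["exposures"] = len(exposures)

    try:
        outcome_table = stage_outcomes(births)
    except Exception as exc:
        _fail("outcomes", exc)
    outcome_table.to_csv(wd / OUTCOMES_CSV, index=False, float_format=FLOAT_FMT)
    manifest["row_counts"]["outcomes"] = len(outcome_table)

    try:
        results = stage_analyze(exposures, outcome_table, births, config)
    except Exception as exc:
        _fail("analyze", exc)
    results.to_csv(wd / RESULTS_CSV, index=False, float_format=FLOAT_FMT)
    manifest["row_counts"]["results"] = len(results)
    manifest["model_records"] = count_model_records(results)

    with open(wd / MANIFEST_JSON, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "population": population,
        "births": births,
        "scale": scale,
        "contexts": contexts,
        "exposures": exposures,
        "outcomes": outcome_table,
        "results": results,
        "manifest": manifest,
    }
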