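"""Logistic model grid and average marginal effects per 0.1 index increment.

For each combination of index (Gini or Deaton), neighborhood scale k and
dichotomous outcome, a multiple logistic regression is fitted on complete
cases with the maternal covariates, the mean distance to neighbors and the
mean neighborhood income at the same k-level.  The association is summarized
as the average marginal effect (AME) of a +0.1 increment of the index:

    AME = (1/n) sum_i [ expit(eta_i + beta_v * 0.1) - expit(eta_i) ]

(the discrete-change form; a derivative mode ``dp/dx * 0.1`` is available),
with a delta-method standard error from the analytic gradient of the AME in
the full coefficient vector and Wald 95% confidence intervals
(z = 1.959964).  The default grid — 2 indices x 4 k-levels x 5 outcomes,
each as a main-effect model and as an income-decile interaction model — has
80 models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import DataError, DesignError, NonConvergenceError

Z95 = 1.959964

DEFAULT_COVARIATES = (
    "age_band",
    "education",
    "occupation",
    "civil_status",
    "region_of_origin",
    "parity",
    "income",
    "distance_to_labor_ward",
    "mean_distance_m",
    "mean_income",
)

_CATEGORICAL = ("age_band", "education", "occupation", "civil_status",
                "region_of_origin", "parity")

#: absolute coefficient beyond which a "converged" fit is treated as
#: separated and flagged unconverged
_SEPARATION_BOUND = 25.0


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid."""

    index_type: str  # 'gini' | 'deaton'
    k_level: int
    outcome: str
    interaction: str = "none"  # 'none' | 'income_decile'
    covariates: tuple = DEFAULT_COVARIATES

    def __post_init__(self):
        if self.index_type not in ("gini", "deaton"):
            raise DataError(f"unknown index type {self.index_type!r}")
        if self.interaction not in ("none", "income_decile"):
            raise DataError(f"unknown interaction {self.interaction!r}")


@dataclass
class AmeResult:
    """AME of a +delta index increment for one model (and stratum)."""

    index_type: str
    k_level: int
    outcome: str
    model_type: str  # 'main' | 'interaction'
    stratum: str  # 'overall' | 'd1'..'d10'
    ame: float
    se: float
    ci_low: float
    ci_high: float
    n_used: int
    converged: bool


@dataclass
class FittedLogit:
    params: pd.Series
    cov: pd.DataFrame
    n_used: int
    converged: bool
    llf: float


def assign_income_deciles(data: pd.DataFrame, n_deciles: int = 10,
                          id_col: str = "person_id") -> pd.Series:
    """Decile (1..n) of equivalized income ranked within the mother cohort,
    ties broken by id for determinism."""
    y = data["equiv_income"].to_numpy(dtype=float)
    pid = data[id_col].to_numpy()
    order = np.lexsort((pid, y))
    ranks = np.empty(len(data), dtype=np.int64)
    ranks[order] = np.arange(1, len(data) + 1)
    dec = -(-ranks * n_deciles // len(data))
    return pd.Series(dec, index=data.index, name="income_decile")


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix for one model; a pure function of ``data`` so that the
    +delta counterfactual design is built by perturbing the index column.

    Categorical covariates enter as full dummy sets with the most frequent
    level as reference; individual income enters as log1p of the equivalized
    value in main-effect models and as decile indicators in interaction
    models; the interaction adds ``index x decile`` columns.
    """
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["index"] = data[spec.index_type].astype(float)

    for cov in spec.covariates:
        if cov in _CATEGORICAL:
            vals = data[cov].astype(str)
            ref = vals.value_counts().idxmax()
            for lvl in sorted(vals.dropna().unique()):
                if lvl == ref:
                    continue
                X[f"{cov}[{lvl}]"] = (vals == lvl).astype(float)
        elif cov == "income":
            if spec.interaction == "none":
                X["log_income"] = np.log1p(data["equiv_income"].astype(float))
            # decile indicators added below for interaction models
        elif cov == "mean_income":
            X["mean_nbhd_income_100k"] = data["mean_income"].astype(float) / 1e5
        elif cov == "mean_distance_m":
            X["mean_distance_km"] = data["mean_distance_m"].astype(float) / 1e3
        else:
            X[cov] = data[cov].astype(float)

    if spec.interaction == "income_decile":
        dec = data["income_decile"].astype(int)
        ref = int(dec.value_counts().idxmax())
        for d in sorted(dec.unique()):
            if d != ref:
                X[f"decile[{d}]"] = (dec == d).astype(float)
            # full set of index-by-decile slopes (reference slope = 'index')
            if d != ref:
                X[f"index:decile[{d}]"] = X["index"] * (dec == d).astype(float)
    return X


def _model_columns(data: pd.DataFrame, spec: ModelSpec) -> list[str]:
    cols = [spec.index_type, spec.outcome]
    for cov in spec.covariates:
        if cov == "income":
            cols.append("equiv_income")
        else:
            cols.append(cov)
    if spec.interaction == "income_decile":
        cols.append("income_decile")
    return [c for c in dict.fromkeys(cols) if c in data.columns]


def complete_cases(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Rows with every model variable observed (missing data are excluded)."""
    cols = _model_columns(data, spec)
    missing = set([spec.index_type, spec.outcome]) - set(cols)
    if missing:
        raise DataError(f"data lacks model columns: {sorted(missing)}")
    return data.dropna(subset=cols)


def fit_logistic(X: pd.DataFrame, y) -> FittedLogit:
    """Maximum-likelihood logistic fit (IRLS) with rank checks.

    Raises :class:`DesignError` naming aliased columns on rank deficiency and
    :class:`NonConvergenceError` if IRLS does not converge in 100 iterations.
    """
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if Xv.shape[0] != yv.shape[0]:
        raise DataError("design and response lengths differ")
    # drop-free rank check: name aliased columns via QR
    q, r = np.linalg.qr(Xv / np.maximum(np.abs(Xv).max(axis=0), 1e-300))
    diag = np.abs(np.diag(r))
    bad = diag < 1e-9 * max(diag.max(), 1.0)
    if bad.any():
        names = [X.columns[i] for i in np.nonzero(bad)[0]]
        raise DesignError(f"design is rank deficient; aliased columns: {names}")

    model = sm.GLM(yv, Xv, family=sm.families.Binomial())
    try:
        # quasi-separated cells are detected below via the coefficient bound;
        # silence the fit-time warnings they trigger
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.filterwarnings("ignore", message=".*[Ss]eparation.*")
            res = model.fit(maxiter=100, tol=1e-10)
            llf = float(res.llf)  # lazy property; keep it under the filter
    except Exception as exc:  # perfect separation etc.
        raise NonConvergenceError(f"logistic fit failed: {exc}") from exc
    if not getattr(res, "converged", True):
        raise NonConvergenceError(
            "IRLS did not converge within 100 iterations",
            diagnostics={"deviance": float(res.deviance)},
        )
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    converged = bool(np.all(np.abs(params.to_numpy()) < _SEPARATION_BOUND))
    return FittedLogit(
        params=params, cov=cov, n_used=len(X), converged=converged, llf=llf,
    )


def _discrete_change(fit: FittedLogit, X0: pd.DataFrame, X1: pd.DataFrame,
                     rows: np.ndarray | None = None) -> tuple[float, float]:
    """AME and delta-method SE of the counterfactual change X0 -> X1 averaged
    over ``rows`` (all rows if None)."""
    b = fit.params.to_numpy()
    A0 = X0.to_numpy(dtype=float)
    A1 = X1.to_numpy(dtype=float)
    if rows is not None:
        A0, A1 = A0[rows], A1[rows]
    p0 = expit(A0 @ b)
    p1 = expit(A1 @ b)
    ame = float(np.mean(p1 - p0))
    f0 = p0 * (1 - p0)
    f1 = p1 * (1 - p1)
    grad = (f1[:, None] * A1 - f0[:, None] * A0).mean(axis=0)
    var = float(grad @ fit.cov.to_numpy() @ grad)
    return ame, float(np.sqrt(max(var, 0.0)))


def _derivative_change(fit: FittedLogit, X0: pd.DataFrame, X1: pd.DataFrame,
                       delta: float, rows: np.ndarray | None = None
                       ) -> tuple[float, float]:
    """Derivative-form AME ``mean(f(eta) * d eta/d index) * delta`` with its
    delta-method SE; the index slope per row is read off ``(X1-X0)/delta``."""
    b = fit.params.to_numpy()
    A0 = X0.to_numpy(dtype=float)
    D = (X1.to_numpy(dtype=float) - A0) / delta
    if rows is not None:
        A0, D = A0[rows], D[rows]
    eta = A0 @ b
    p = expit(eta)
    f = p * (1 - p)
    slope = D @ b
    ame = float(np.mean(f * slope)) * delta
    fprime = f * (1 - 2 * p)
    grad = (f[:, None] * D + (fprime * slope)[:, None] * A0).mean(axis=0) * delta
    var = float(grad @ fit.cov.to_numpy() @ grad)
    return ame, float(np.sqrt(max(var, 0.0)))


def ame_increment(fit: FittedLogit, data: pd.DataFrame, spec: ModelSpec,
                  delta: float = 0.1, mode: str = "discrete",
                  stratum: str = "overall",
                  rows: np.ndarray | None = None) -> AmeResult:
    """AME of a +``delta`` increment of the model's index for one stratum."""
    if spec.index_type not in data.columns:
        raise DataError(f"index column {spec.index_type!r} absent from data")
    X0 = build_design(data, spec)
    X1 = build_design(data.assign(**{spec.index_type: data[spec.index_type] + delta}), spec)
    X1 = X1[X0.columns]
    if mode == "discrete":
        ame, se = _discrete_change(fit, X0, X1, rows)
    elif mode == "derivative":
        ame, se = _derivative_change(fit, X0, X1, delta, rows)
    else:
        raise DataError(f"unknown AME mode {mode!r}")
    n = int(rows.sum()) if rows is not None else len(data)
    return AmeResult(
        index_type=spec.index_type,
        k_level=spec.k_level,
        outcome=spec.outcome,
        model_type="main" if spec.interaction == "none" else "interaction",
        stratum=stratum,
        ame=ame,
        se=se,
        ci_low=ame - Z95 * se,
        ci_high=ame + Z95 * se,
        n_used=fit.n_used,
        converged=fit.converged,
    )


def decile_interaction_ames(fit: FittedLogit, data: pd.DataFrame,
                            spec: ModelSpec, delta: float = 0.1,
                            mode: str = "discrete",
                            n_deciles: int = 10) -> list[AmeResult]:
    """Per-income-decile AMEs from an index-by-decile interaction model.

    The AME for decile d averages the counterfactual change over that
    decile's observations, with CIs from the joint coefficient covariance.
    Empty deciles yield a record with missing estimates.
    """
    out = []
    dec = data["income_decile"].to_numpy(dtype=int)
    for d in range(1, n_deciles + 1):
        rows = dec == d
        if rows.sum() == 0:
            out.append(AmeResult(
                index_type=spec.index_type, k_level=spec.k_level,
                outcome=spec.outcome, model_type="interaction",
                stratum=f"d{d}", ame=np.nan, se=np.nan, ci_low=np.nan,
                ci_high=np.nan, n_used=0, converged=fit.converged,
            ))
            continue
        out.append(ame_increment(fit, data, spec, delta=delta, mode=mode,
                                 stratum=f"d{d}", rows=rows))
    return out


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> tuple[FittedLogit, pd.DataFrame]:
    """Complete-case filter + design build + logistic fit for one spec."""
    cc = complete_cases(data, spec)
    if len(cc) == 0:
        raise DataError(f"no complete cases for {spec}")
    X = build_design(cc, spec)
    y = cc[spec.outcome].astype(float)
    fit = fit_logistic(X, y)
    return fit, cc


def run_model_grid(
    exposures: pd.DataFrame,
    outcome_table: pd.DataFrame,
    mothers: pd.DataFrame,
    k_levels,
    index_types=("gini", "deaton"),
    outcomes=("sga", "lbw", "vlbw", "preterm", "low_apgar"),
    covariates: tuple = DEFAULT_COVARIATES,
    delta: float = 0.1,
    mode: str = "discrete",
    n_deciles: int = 10,
    with_interactions: bool = True,
) -> pd.DataFrame:
    """Fit every (index, k-level, outcome) model, main effect and (optionally)
    income-decile interaction, and return the long results table.

    The returned frame has one row per main model (stratum 'overall') and one
    per decile for interaction models; model failures are recorded in-place
    (``converged`` False, missing estimates) and the grid continues.
    """
    mothers = mothers.copy()
    if "income_decile" not in mothers.columns:
        mothers["income_decile"] = assign_income_deciles(mothers, n_deciles)
    out_cols = [c for c in outcome_table.columns if c != "mother_id"]
    mothers = mothers.drop(columns=[c for c in out_cols if c in mothers.columns])
    base = mothers.merge(
        outcome_table, left_on="person_id", right_on="mother_id", how="inner"
    ).drop(columns=["mother_id"])

    results: list[AmeResult] = []
    for k in k_levels:
        expo_k = exposures[exposures["k_level"] == k]
        cols = ["mother_id", "gini", "deaton", "mean_income", "mean_distance_m"]
        data_k = base.drop(
            columns=[c for c in ("gini", "deaton", "mean_income", "mean_distance_m")
                     if c in base.columns]
        ).merge(expo_k[cols], left_on="person_id", right_on="mother_id", how="inner")
        for index_type in index_types:
            for outcome in outcomes:
                specs = [ModelSpec(index_type, int(k), outcome, "none", covariates)]
                if with_interactions:
                    specs.append(
                        ModelSpec(index_type, int(k), outcome, "income_decile", covariates)
                    )
                for spec in specs:
                    try:
                        fit, cc = fit_model(data_k, spec)
                        if spec.interaction == "none":
                            results.append(
                                ame_increment(fit, cc, spec, delta=delta, mode=mode)
                            )
                        else:
                            results.extend(
                                decile_interaction_ames(
                                    fit, cc, spec, delta=delta, mode=mode,
                                    n_deciles=n_deciles,
                                )
                            )
                    except (DesignError, NonConvergenceError, DataError):
                        results.append(AmeResult(
                            index_type=index_type, k_level=int(k),
                            outcome=outcome,
                            model_type="main" if spec.interaction == "none" else "interaction",
                            stratum="overall" if spec.interaction == "none" else "d1",
                            ame=np.nan, se=np.nan, ci_low=np.nan,
                            ci_high=np.nan, n_used=0, converged=False,
                        ))
    return results_to_frame(results)


def results_to_frame(results: list[AmeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index_type": [r.index_type for r in results],
            "k_level": [r.k_level for r in results],
            "outcome": [r.outcome for r in results],
            "model_type": [r.model_type for r in results],
            "stratum": [r.stratum for r in results],
            "ame_per_0.1": [r.ame for r in results],
            "se": [r.se for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "n_used": [r.n_used for r in results],
            "converged": [r.converged for r in results],
        }
    )


def count_model_records(results: pd.DataFrame) -> int:
    """Number of distinct fitted models in a results table."""
    return results.groupby(
        ["index_type", "k_level", "outcome", "model_type"]
    ).ngroups
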