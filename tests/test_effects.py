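"""Logistic fits, average marginal effects and the model grid."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import spearmanr

from neighbordep.effects import (
    DEFAULT_COVARIATES,
    FittedLogit,
    ModelSpec,
    ame_increment,
    assign_income_deciles,
    build_design,
    complete_cases,
    count_model_records,
    decile_interaction_ames,
    fit_logistic,
    fit_model,
    run_model_grid,
)
from neighbordep.errors import DesignError


def _bare_spec(index_type="deaton", interaction="none"):
    return ModelSpec(index_type, 100, "sga", interaction, covariates=())


def _sim_logistic(rng, n, beta0, beta1):
    x = rng.uniform(0, 1, n)
    y = (rng.random(n) < expit(beta0 + beta1 * x)).astype(float)
    return pd.DataFrame({"deaton": x, "sga": y})


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        X = pd.DataFrame({"const": np.ones(100)})
        fit = fit_logistic(X, y)
        assert fit.params["const"] == pytest.approx(float(logit(0.3)), abs=1e-8)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        # exposed: 4 events / 6 non-events; unexposed: 2 / 8 -> OR = 32/12
        x = np.repeat([1.0, 0.0], 10)
        y = np.array([1] * 4 + [0] * 6 + [1] * 2 + [0] * 8, dtype=float)
        X = pd.DataFrame({"const": np.ones(20), "x": x})
        fit = fit_logistic(X, y)
        assert fit.params["x"] == pytest.approx(np.log(32 / 12), abs=1e-8)

    def test_recovers_known_coefficients_within_3_se(self):
        rng = np.random.default_rng(12)
        data = _sim_logistic(rng, 50_000, -2.0, 1.5)
        X = pd.DataFrame({"const": 1.0, "x": data["deaton"]})
        fit = fit_logistic(X, data["sga"])
        for name, truth in [("const", -2.0), ("x", 1.5)]:
            se = np.sqrt(fit.cov.loc[name, name])
            assert abs(fit.params[name] - truth) < 3 * se

    def test_rank_deficiency_names_aliased_column(self):
        X = pd.DataFrame({"const": np.ones(50), "a": np.arange(50.0)})
        X["b"] = 2 * X["a"]
        with pytest.raises(DesignError, match="aliased"):
            fit_logistic(X, np.repeat([0.0, 1.0], 25))


class TestAmeIncrement:
    def test_closed_form_single_observation(self):
        """eta = 0, beta = 1, delta = 0.1 -> expit(0.1) - 0.5 = 0.0249792."""
        data = pd.DataFrame({"deaton": [0.0], "sga": [0.0]})
        spec = _bare_spec()
        fit = FittedLogit(
            params=pd.Series({"const": 0.0, "index": 1.0}),
            cov=pd.DataFrame(np.zeros((2, 2)), index=["const", "index"],
                             columns=["const", "index"]),
            n_used=1, converged=True, llf=0.0,
        )
        res = ame_increment(fit, data, spec, delta=0.1)
        assert res.ame == pytest.approx(0.0249792, abs=1e-6)

    def test_zero_coefficient_gives_exact_zero(self):
        data = pd.DataFrame({"deaton": np.linspace(0, 1, 9), "sga": 0.0})
        spec = _bare_spec()
        fit = FittedLogit(
            params=pd.Series({"const": -1.3, "index": 0.0}),
            cov=pd.DataFrame(np.eye(2) * 1e-4, index=["const", "index"],
                             columns=["const", "index"]),
            n_used=9, converged=True, llf=0.0,
        )
        res = ame_increment(fit, data, spec)
        assert res.ame == 0.0

    def test_ci_brackets_ame_with_z(self):
        rng = np.random.default_rng(3)
        data = _sim_logistic(rng, 5_000, -2.0, 1.0)
        spec = _bare_spec()
        fit, cc = fit_model(data, spec)
        res = ame_increment(fit, cc, spec)
        assert res.ci_low <= res.ame <= res.ci_high
        assert res.ci_high - res.ame == pytest.approx(1.959964 * res.se, rel=1e-9)

    def test_se_matches_numeric_gradient_and_bootstrap(self):
        """Delta-method SE: analytic gradient vs central finite differences
        (tight) and vs a nonparametric bootstrap (within 15%)."""
        rng = np.random.default_rng(7)
        data = _sim_logistic(rng, 20_000, -2.5, 1.2)
        spec = _bare_spec()
        fit, cc = fit_model(data, spec)
        res = ame_increment(fit, cc, spec)

        X0 = build_design(cc, spec).to_numpy()
        X1 = build_design(cc.assign(deaton=cc.deaton + 0.1), spec).to_numpy()

        def ame_of(beta):
            return np.mean(expit(X1 @ beta) - expit(X0 @ beta))

        b = fit.params.to_numpy()
        eps = 1e-6
        grad = np.array([
            (ame_of(b + eps * np.eye(len(b))[j]) - ame_of(b - eps * np.eye(len(b))[j]))
            / (2 * eps)
            for j in range(len(b))
        ])
        se_numeric = float(np.sqrt(grad @ fit.cov.to_numpy() @ grad))
        assert res.se == pytest.approx(se_numeric, rel=1e-5)

        boot = []
        for _ in range(200):
            idx = rng.integers(0, len(cc), len(cc))
            bs = cc.iloc[idx]
            f, c2 = fit_model(bs, spec)
            boot.append(ame_increment(f, c2, spec).ame)
        assert res.se == pytest.approx(np.std(boot, ddof=1), rel=0.15)

    def test_ame_sign_follows_coefficient(self):
        rng = np.random.default_rng(5)
        for beta in (-1.5, -0.2, 0.4, 2.0):
            data = _sim_logistic(rng, 4_000, -1.5, beta)
            spec = _bare_spec()
            fit, cc = fit_model(data, spec)
            res = ame_increment(fit, cc, spec)
            assert np.sign(res.ame) == np.sign(fit.params["index"])

    def test_derivative_mode_close_to_discrete_for_small_delta(self):
        rng = np.random.default_rng(6)
        data = _sim_logistic(rng, 10_000, -2.0, 1.0)
        spec = _bare_spec()
        fit, cc = fit_model(data, spec)
        a = ame_increment(fit, cc, spec, delta=0.01, mode="discrete")
        d = ame_increment(fit, cc, spec, delta=0.01, mode="derivative")
        assert a.ame == pytest.approx(d.ame, rel=0.02)


class TestDecileInteractions:
    @staticmethod
    def _interaction_data(rng, n, slopes):
        decile = rng.integers(1, 11, n)
        x = rng.uniform(0, 1, n)
        eta = -2.5 + slopes[decile - 1] * x
        y = (rng.random(n) < expit(eta)).astype(float)
        return pd.DataFrame(
            {"deaton": x, "sga": y, "income_decile": decile,
             "person_id": np.arange(n), "equiv_income": decile + rng.random(n)}
        )

    def test_all_zero_coefficients_give_zero_ames(self):
        rng = np.random.default_rng(1)
        data = self._interaction_data(rng, 500, np.zeros(10))
        spec = _bare_spec(interaction="income_decile")
        X = build_design(data, spec)
        params = pd.Series(0.0, index=X.columns)
        params["const"] = -2.0
        fit = FittedLogit(params=params,
                          cov=pd.DataFrame(np.zeros((len(params),) * 2),
                                           index=X.columns, columns=X.columns),
                          n_used=len(data), converged=True, llf=0.0)
        for res in decile_interaction_ames(fit, data, spec):
            assert res.ame == 0.0

    def test_recovers_monotone_effect_gradient(self):
        rng = np.random.default_rng(2)
        slopes = np.linspace(0.0, 2.0, 10)
        data = self._interaction_data(rng, 60_000, slopes)
        spec = _bare_spec(interaction="income_decile")
        fit, cc = fit_model(data, spec)
        ames = [r.ame for r in decile_interaction_ames(fit, cc, spec)]
        rho = spearmanr(np.arange(10), ames).statistic
        assert rho > 0.5

    def test_null_interaction_wald_mostly_nonsignificant(self):
        """Under no true interaction the joint Wald test on the interaction
        terms rejects at ~5%."""
        from scipy.stats import chi2

        rng = np.random.default_rng(4)
        rejected = 0
        reps = 20
        for _ in range(reps):
            data = self._interaction_data(rng, 5_000, np.full(10, 0.8))
            spec = _bare_spec(interaction="income_decile")
            fit, cc = fit_model(data, spec)
            names = [c for c in fit.params.index if c.startswith("index:")]
            b = fit.params[names].to_numpy()
            V = fit.cov.loc[names, names].to_numpy()
            stat = float(b @ np.linalg.solve(V, b))
            rejected += stat > chi2.ppf(0.95, len(names))
        assert rejected <= reps - 15  # non-significant in >= 75% of reps


@pytest.fixture(scope="module")
def grid_inputs():
    rng = np.random.default_rng(9)
    n = 1_500
    mothers = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "equiv_income": rng.lognormal(12, 0.5, n),
            "age_band": rng.choice(["<25", "25-29", "30-34"], n),
            "education": rng.choice(["basic", "secondary", "tertiary"], n),
            "occupation": rng.choice(["a", "b"], n),
            "civil_status": rng.choice(["m", "u"], n),
            "region_of_origin": rng.choice(["swe", "other"], n),
            "parity": rng.integers(1, 4, n),
            "distance_to_labor_ward": rng.exponential(10, n),
        }
    )
    expo = pd.concat(
        [
            pd.DataFrame(
                {
                    "mother_id": np.arange(n),
                    "k_level": k,
                    "gini": rng.uniform(0.1, 0.4, n),
                    "deaton": rng.uniform(0, 0.5, n),
                    "mean_income": rng.lognormal(12, 0.2, n),
                    "mean_distance_m": rng.uniform(50, 800, n),
                }
            )
            for k in (100, 400)
        ]
    )
    out = pd.DataFrame({"mother_id": np.arange(n)})
    for o in ("sga", "lbw", "vlbw", "preterm", "low_apgar"):
        out[o] = (rng.random(n) < 0.08).astype(int)
    return expo, out, mothers


class TestModelGrid:
    def test_single_k_level_emits_twenty_model_records(self, grid_inputs):
        expo, out, mothers = grid_inputs
        res = run_model_grid(expo, out, mothers, k_levels=[100])
        assert count_model_records(res) == 20  # 2 indices x 1 k x 5 outcomes x 2

    def test_two_k_levels_emit_forty_model_records(self, grid_inputs):
        expo, out, mothers = grid_inputs
        res = run_model_grid(expo, out, mothers, k_levels=[100, 400])
        assert count_model_records(res) == 40
        main = res[res.model_type == "main"]
        inter = res[res.model_type == "interaction"]
        assert len(main) == 20
        assert set(inter.stratum) <= {f"d{i}" for i in range(1, 11)}

    def test_complete_case_counts(self, grid_inputs):
        expo, out, mothers = grid_inputs
        mothers = mothers.copy()
        mothers.loc[mothers.index[:100], "education"] = np.nan
        spec = ModelSpec("deaton", 100, "sga", "none")
        data = mothers.merge(out, left_on="person_id", right_on="mother_id").merge(
            expo[expo.k_level == 100], on="mother_id"
        )
        cc = complete_cases(data, spec)
        expected = data.dropna(
            subset=["deaton", "sga", "education"]
        )
        assert len(cc) == len(expected) == len(data) - 100
        fit, used = fit_model(data, spec)
        assert fit.n_used == len(expected)


class TestIncomeDeciles:
    def test_balanced_assignment(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"person_id": np.arange(1000), "equiv_income": rng.lognormal(12, 0.5, 1000)}
        )
        dec = assign_income_deciles(df)
        assert np.bincount(dec, minlength=11)[1:].tolist() == [100] * 10
        # richer mothers in higher deciles
        assert (
            df.equiv_income[dec == 10].min() >= df.equiv_income[dec == 1].max()
        )
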