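"""AR(1) regression, AICc selection and effect-size combination."""

import numpy as np
import pytest
import statsmodels.api as sm

from democlim import popfit


def ar1_data(rng, n, beta=(0.05, 0.3, -0.1), rho=0.5, sd=0.1):
    P, T = rng.normal(size=n), rng.normal(size=n)
    eps = np.zeros(n)
    eps[0] = rng.normal(0, sd / np.sqrt(1 - rho**2)) if sd > 0 else 0.0
    for t in range(1, n):
        eps[t] = rho * eps[t - 1] + rng.normal(0, sd)
    y = beta[0] + beta[1] * P + beta[2] * T + eps
    return y, P, T


class TestFitAr1:
    def test_rho_zero_reproduces_ols(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [0.1, 0.3, -0.2] + rng.normal(0, 0.1, n)
        fit = popfit.fit_ar1(y, X, term_names=["intercept", "P", "T"], rho_fixed=0.0)
        ols = sm.OLS(y, X).fit()
        assert np.allclose(list(fit.params.values()), ols.params, atol=1e-6)
        assert np.allclose(list(fit.bse.values()), ols.bse, atol=1e-6)

    def test_noiseless_exact_recovery(self, rng):
        n = 20
        P, T = rng.normal(size=n), rng.normal(size=n)
        y = 0.02 + 0.25 * P - 0.07 * T
        X = np.column_stack([np.ones(n), P, T])
        fit = popfit.fit_ar1(y, X, term_names=["intercept", "P", "T"])
        assert fit.params["P"] == pytest.approx(0.25, abs=1e-8)
        assert fit.params["T"] == pytest.approx(-0.07, abs=1e-8)

    def test_long_series_recovers_beta_and_rho(self, rng):
        y, P, T = ar1_data(rng, 500, rho=0.5, sd=0.1)
        X = np.column_stack([np.ones(500), P, T])
        fit = popfit.fit_ar1(y, X, term_names=["intercept", "P", "T"])
        assert abs(fit.params["P"] - 0.3) < 3 * fit.bse["P"]
        assert abs(fit.rho["0"] - 0.5) < 0.1

    def test_matches_arima_maximum_likelihood(self, rng):
        y, P, T = ar1_data(rng, 200, rho=0.4, sd=0.08)
        X = np.column_stack([np.ones(200), P, T])
        fit = popfit.fit_ar1(y, X, term_names=["intercept", "P", "T"])
        oracle = sm.tsa.arima.ARIMA(
            y, exog=np.column_stack([P, T]), order=(1, 0, 0), trend="c"
        ).fit(method="innovations_mle")
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)
        assert fit.params["P"] == pytest.approx(oracle.params[1], abs=1e-4)
        assert fit.rho["0"] == pytest.approx(oracle.params[3], abs=1e-3)

    def test_per_replicate_rho_shared_coefficients(self, rng):
        # two contiguous replicates with different error autocorrelation
        n = 150
        parts = []
        for rho in (0.1, 0.7):
            y, P, T = ar1_data(rng, n, rho=rho, sd=0.1)
            parts.append((y, P, T))
        y = np.concatenate([p[0] for p in parts])
        P = np.concatenate([p[1] for p in parts])
        T = np.concatenate([p[2] for p in parts])
        rep = np.repeat(["a", "b"], n)
        X = np.column_stack([np.ones(2 * n), P, T])
        fit = popfit.fit_ar1(y, X, term_names=["intercept", "P", "T"], replicate_ids=rep)
        assert set(fit.rho) == {"a", "b"}
        assert fit.rho["b"] > fit.rho["a"]
        assert abs(fit.params["P"] - 0.3) < 3 * fit.bse["P"]

    def test_too_short_series_rejected(self, rng):
        X = np.column_stack([np.ones(5), rng.normal(size=5), rng.normal(size=5)])
        with pytest.raises(ValueError, match="too short"):
            popfit.fit_ar1(rng.normal(size=5), X)

    def test_collinear_design_rejected(self, rng):
        n = 20
        P = rng.normal(size=n)
        X = np.column_stack([np.ones(n), P, 2 * P])
        with pytest.raises(ValueError, match="collinear"):
            popfit.fit_ar1(rng.normal(size=n), X)


class TestAicc:
    def test_hand_value(self):
        # -2(-5) + 2*2 + 2*2*3/(10-3) = 14 + 12/7
        assert popfit.aicc(-5.0, 2, 10) == pytest.approx(14 + 12 / 7)

    def test_monotone_in_k(self):
        assert popfit.aicc(-5.0, 3, 20) > popfit.aicc(-5.0, 2, 20)

    def test_limits_to_aic(self):
        n = 10**8
        aic = -2 * (-5.0) + 2 * 4
        assert abs(popfit.aicc(-5.0, 4, n) - aic) < 1e-6

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            popfit.aicc(-5.0, 4, 5)


class TestCandidateSet:
    def test_short_series_baseline_only(self):
        models = popfit.candidate_set(12, has_covariate=False)
        assert [m.model_id for m in models] == ["baseline"]

    def test_long_series_with_covariate_gives_six(self):
        models = popfit.candidate_set(20, has_covariate=True, covariate_varies=True)
        assert [m.model_id for m in models] == list(popfit.MODEL_IDS)

    def test_constant_covariate_drops_interactions(self):
        models = popfit.candidate_set(20, has_covariate=True, covariate_varies=False)
        assert [m.model_id for m in models] == [
            "baseline", "quad_P", "quad_T", "quad_both",
        ]

    def test_threshold_is_strict(self):
        assert len(popfit.candidate_set(14, has_covariate=False)) == 1
        assert len(popfit.candidate_set(15, has_covariate=False)) == 4

    def test_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            popfit.candidate_set(5, has_covariate=False)


class TestSelectModel:
    def test_single_candidate_returned(self, rng):
        y, P, T = ar1_data(rng, 12, rho=0.0, sd=0.05)
        fits = popfit.fit_candidates(y, P, T)
        assert popfit.select_model(fits) is fits[0]

    def test_tie_broken_toward_fewest_parameters(self):
        a = popfit.ModelFit(
            "quad_P", ("intercept", "P", "T", "P2"), {}, {}, {"0": 0.0}, 0.1,
            loglik=-10.0, n=30, k=6, aicc=popfit.aicc(-10.0, 6, 30),
        )
        b = popfit.ModelFit(
            "baseline", ("intercept", "P", "T"), {}, {}, {"0": 0.0}, 0.1,
            loglik=-10.0, n=30, k=5, aicc=popfit.aicc(-10.0, 6, 30),
        )
        assert popfit.select_model([a, b]).model_id == "baseline"

    def test_quadratic_signal_selected_in_majority(self):
        hits = 0
        master = np.random.SeedSequence(314)
        for ss in master.spawn(100):
            rng = np.random.default_rng(ss)
            P, T = rng.normal(size=30), rng.normal(size=30)
            y = 0.05 + 0.1 * P - 0.05 * T - 0.25 * P**2 + rng.normal(0, 0.05, 30)
            best = popfit.select_model(popfit.fit_candidates(y, P, T))
            hits += best.model_id == "quad_P"
        assert hits > 50

    def test_baseline_data_prefers_baseline(self):
        counts = {}
        master = np.random.SeedSequence(2718)
        for ss in master.spawn(100):
            rng = np.random.default_rng(ss)
            P, T = rng.normal(size=30), rng.normal(size=30)
            y = 0.05 + 0.2 * P - 0.1 * T + rng.normal(0, 0.05, 30)
            best = popfit.select_model(popfit.fit_candidates(y, P, T))
            counts[best.model_id] = counts.get(best.model_id, 0) + 1
        assert counts["baseline"] == max(counts.values())


class TestCombineEffect:
    def _fit(self, params, bse, model_id="baseline"):
        terms = tuple(params)
        return popfit.ModelFit(
            model_id, terms, params, bse, {"0": 0.0}, 0.1,
            loglik=-5.0, n=30, k=len(terms) + 2,
            aicc=popfit.aicc(-5.0, len(terms) + 2, 30),
        )

    def test_baseline_idempotent(self):
        fit = self._fit({"intercept": 0.0, "P": 0.2, "T": -0.1},
                        {"intercept": 0.01, "P": 0.02, "T": 0.03})
        assert popfit.combine_effect(fit, "precip") == (0.2, 0.02)
        assert popfit.combine_effect(fit, "temp") == (-0.1, 0.03)

    def test_quadratic_sum(self):
        fit = self._fit(
            {"intercept": 0.0, "P": 0.2, "T": -0.1, "P2": -0.05},
            {"intercept": 0.01, "P": 0.02, "T": 0.03, "P2": 0.03},
            model_id="quad_P",
        )
        beta, se = popfit.combine_effect(fit, "precip")
        assert beta == pytest.approx(0.15)
        assert se == pytest.approx(0.05)  # literal SE addition

    def test_quadrature_switch(self):
        fit = self._fit(
            {"intercept": 0.0, "P": 0.2, "T": -0.1, "P2": -0.05},
            {"intercept": 0.01, "P": 0.03, "T": 0.03, "P2": 0.04},
            model_id="quad_P",
        )
        _, se = popfit.combine_effect(fit, "precip", se_combine="quadrature")
        assert se == pytest.approx(0.05)

    def test_continuous_interaction_at_mean_covariate(self):
        fit = self._fit(
            {"intercept": 0.0, "P": 0.1, "T": 0.10, "C": 0.0, "TxC": 0.20},
            {"intercept": 0.01, "P": 0.02, "T": 0.02, "C": 0.01, "TxC": 0.01},
            model_id="inter_TxC",
        )
        beta, se = popfit.combine_effect(
            fit, "temp", covariate_mean=0.5, covariate_kind="continuous"
        )
        assert beta == pytest.approx(0.20)
        assert se == pytest.approx(0.03)

    def test_categorical_interaction_at_half(self):
        fit = self._fit(
            {"intercept": 0.0, "P": 0.1, "T": 0.0, "C": 0.0, "PxC": 0.3},
            {"intercept": 0.01, "P": 0.02, "T": 0.02, "C": 0.01, "PxC": 0.02},
            model_id="inter_PxC",
        )
        beta, se = popfit.combine_effect(fit, "precip", covariate_kind="discrete")
        assert beta == pytest.approx(0.1 + 0.15)
        assert se == pytest.approx(0.04)

    def test_missing_variable_rejected(self):
        fit = self._fit({"intercept": 0.0, "P": 0.2}, {"intercept": 0.01, "P": 0.02})
        with pytest.raises(ValueError, match="temp"):
            popfit.combine_effect(fit, "temp")

    def test_percent_change_of_effect(self):
        change = popfit.percent_change_of_effect(-0.189, -0.158)
        assert change == pytest.approx(-16.4, abs=0.05)
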