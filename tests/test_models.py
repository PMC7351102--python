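"""Covariate / outcome / competing-event model fitting, prediction,
simulation draws, and RMSE."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import truncnorm

from gformula.config import CovariateSpec, OutcomeSpec
from gformula.formulas import design_matrix, rcs
from gformula.models import (
    FittedCovariateModel,
    FittingError,
    _GlmFit,
    categorical_time_value,
    draw_covariate,
    fit_compevent_model,
    fit_covariate_model,
    fit_outcome_model,
    predict_probability,
)

RNG = np.random.default_rng(2024)


def _frame(n=4000, seed=5):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "t0": np.ones(n, dtype=int),
        "x1": rng.normal(size=n),
        "x2": (rng.random(n) < 0.4).astype(float),
    })


def _manual_fit(formula_rhs: str, frame: pd.DataFrame, coefs: list[float],
                family: str = "binomial_logit", sd: float = 1.0) -> _GlmFit:
    X = design_matrix(formula_rhs, frame)
    return _GlmFit(
        coefficients=pd.Series(coefs, index=list(X.columns)),
        vcov=pd.DataFrame(np.eye(len(coefs)), index=X.columns,
                          columns=X.columns),
        design_info=X.design_info, family=family, residual_scale=sd,
    )


class TestPredictProbability:
    def test_zero_coefficients_give_half(self):
        frame = _frame(50)
        fit = _manual_fit("x1 + x2", frame, [0.0, 0.0, 0.0])
        assert np.allclose(predict_probability(fit, frame), 0.5)

    def test_intercept_only(self):
        frame = _frame(50)
        fit = _manual_fit("1", frame, [logit(0.2)])
        assert np.allclose(predict_probability(fit, frame), 0.2)

    def test_saturated_fit_reproduces_stratum_means(self):
        # oracle: closed-form saturated logistic fit on a 2x2 table equals
        # the empirical mean of Y within each stratum of X
        rng = np.random.default_rng(3)
        x = (rng.random(500) < 0.5).astype(float)
        y = (rng.random(500) < np.where(x == 1, 0.7, 0.2)).astype(float)
        df = pd.DataFrame({"t0": 1, "Z": y, "x": x})
        spec = CovariateSpec("Z", "binary", "Z ~ x")
        model = fit_covariate_model(spec, df, "t0")
        pred = predict_probability(model, df)
        for lvl in (0.0, 1.0):
            assert pred[x == lvl][0] == pytest.approx(y[x == lvl].mean(),
                                                      abs=1e-8)

    def test_missing_feature_is_named(self):
        frame = _frame(10)
        fit = _manual_fit("x1 + x2", frame, [0.0, 1.0, 1.0])
        with pytest.raises(Exception, match="x2"):
            predict_probability(fit, frame.drop(columns=["x2"]))


class TestFamilies:
    """Sampling/fit consistency: draws from a model with known parameters,
    refitted, recover those parameters."""

    def _roundtrip(self, covtype, coefs, sd=0.8, type_params=None,
                   observed_range=(-np.inf, np.inf), zero_coefs=None,
                   n=6000):
        frame = _frame(n)
        spec = CovariateSpec("Z", covtype, "Z ~ x1 + x2",
                             type_params=type_params or {})
        family = ("binomial_logit"
                  if covtype in ("binary", "absorbing") else "gaussian_identity")
        fit = _manual_fit("x1 + x2", frame, coefs, family=family, sd=sd)
        model = FittedCovariateModel(
            spec=spec, fit=fit, observed_range=observed_range,
            zero_model=(None if zero_coefs is None
                        else _manual_fit("x1 + x2", frame, zero_coefs)),
            nonzero_range=(-100.0, 100.0),
        )
        prev = np.zeros(n)
        draws = draw_covariate(model, frame, np.random.default_rng(99),
                               prev=prev)
        refit_frame = frame.assign(Z=draws)
        if covtype == "absorbing":
            refit_frame["lag1_Z"] = 0.0
        refit = fit_covariate_model(spec, refit_frame, "t0")
        return model, draws, refit

    @pytest.mark.parametrize("covtype", ["binary", "absorbing"])
    def test_logistic_families_recover(self, covtype):
        coefs = [-0.4, 0.8, -0.6]
        _, _, refit = self._roundtrip(covtype, coefs)
        est = refit.coefficients.to_numpy()
        se = np.sqrt(np.diag(refit.vcov.to_numpy()))
        assert np.all(np.abs(est - coefs) < 3 * se)

    def test_normal_recovers_scale_and_coefficients(self):
        coefs = [0.5, 1.2, -0.7]
        _, _, refit = self._roundtrip("normal", coefs, sd=0.8)
        est = refit.coefficients.to_numpy()
        se = np.sqrt(np.diag(refit.vcov.to_numpy()))
        assert np.all(np.abs(est - coefs) < 3 * se)
        assert refit.residual_scale == pytest.approx(0.8, rel=0.05)

    def test_bounded_normal_draws_respect_bounds(self):
        coefs = [0.5, 0.3, -0.2]
        model, draws, refit = self._roundtrip(
            "bounded_normal", coefs, sd=0.2, observed_range=(0.0, 1.0))
        assert draws.min() >= 0.0 and draws.max() <= 1.0
        est = refit.coefficients.to_numpy()
        # mildly wider tolerance: clipping at the bounds biases slightly
        assert np.all(np.abs(est - coefs) < 0.05 + 3 * np.sqrt(
            np.diag(refit.vcov.to_numpy())))

    def test_zero_inflated_recovers_both_parts(self):
        coefs = [1.0, 0.5, -0.4]
        zero_coefs = [0.3, 0.6, -0.5]
        _, draws, refit = self._roundtrip(
            "zero_inflated_normal", coefs, sd=0.7, zero_coefs=zero_coefs)
        assert (draws == 0).any() and (draws != 0).any()
        est = refit.coefficients.to_numpy()
        se = np.sqrt(np.diag(refit.vcov.to_numpy()))
        assert np.all(np.abs(est - coefs) < 3 * se)
        zest = refit.zero_model.coefficients.to_numpy()
        zse = np.sqrt(np.diag(refit.zero_model.vcov.to_numpy()))
        assert np.all(np.abs(zest - zero_coefs) < 3 * zse)

    def test_truncated_normal_draws_respect_truncation(self):
        frame = _frame(5000)
        spec = CovariateSpec("Z", "truncated_normal", "Z ~ x1 + x2",
                             type_params={"direction": "left", "point": 0.0})
        fit = _manual_fit("x1 + x2", frame, [0.5, 0.0, 0.0],
                          family="gaussian_identity", sd=1.0)
        model = FittedCovariateModel(spec=spec, fit=fit,
                                     observed_range=(-10, 10))
        draws = draw_covariate(model, frame, np.random.default_rng(4))
        assert draws.min() >= 0.0
        # oracle: scipy's truncated-normal mean at mu=0.5, sd=1, left at 0
        expected = truncnorm.mean(-0.5, np.inf, loc=0.5, scale=1.0)
        assert draws.mean() == pytest.approx(expected, rel=0.02)

    def test_categorical_probabilities_and_recovery(self):
        rng = np.random.default_rng(8)
        x = (rng.random(6000) < 0.5).astype(float)
        logits1 = 0.4 - 0.8 * x
        logits2 = -0.2 + 0.6 * x
        denom = 1 + np.exp(logits1) + np.exp(logits2)
        u = rng.random(6000)
        p1 = np.exp(logits1) / denom
        p2 = np.exp(logits2) / denom
        z = np.where(u < p1, 1.0, np.where(u < p1 + p2, 2.0, 0.0))
        df = pd.DataFrame({"t0": 1, "Z": z, "x": x})
        spec = CovariateSpec("Z", "categorical", "Z ~ x")
        model = fit_covariate_model(spec, df, "t0")
        from gformula.models import _multinomial_probs
        probs = _multinomial_probs(model.fit, df)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        # saturated fit: class probabilities equal empirical frequencies
        for lvl in (0.0, 1.0):
            sub = probs[x == lvl][0]
            emp = [np.mean(z[x == lvl] == c) for c in (0.0, 1.0, 2.0)]
            assert np.allclose(sub, emp, atol=1e-6)
        draws = draw_covariate(model, df, np.random.default_rng(1))
        assert set(np.unique(draws)) <= {0.0, 1.0, 2.0}

    def test_categorical_time_is_deterministic(self):
        spec = CovariateSpec("period", "categorical_time",
                             type_params={"cuts": [2, 5]})
        assert categorical_time_value(spec, 0) == 0
        assert categorical_time_value(spec, 2) == 1
        assert categorical_time_value(spec, 6) == 2
        model = fit_covariate_model(spec, _frame(10), "t0")
        draws = draw_covariate(model, _frame(10), np.random.default_rng(0), k=3)
        assert np.all(draws == 1.0)


class TestDraws:
    def test_binary_degenerate_probability(self):
        frame = _frame(200)
        spec = CovariateSpec("Z", "binary", "Z ~ x1")
        fit = _manual_fit("x1", frame, [-50.0, 0.0])
        model = FittedCovariateModel(spec=spec, fit=fit,
                                     observed_range=(0.0, 1.0))
        draws = draw_covariate(model, frame, np.random.default_rng(0))
        assert np.all(draws == 0.0)

    def test_absorbing_stays_absorbed(self):
        frame = _frame(200)
        spec = CovariateSpec("Z", "absorbing", "Z ~ x1")
        fit = _manual_fit("x1", frame, [-50.0, 0.0])
        model = FittedCovariateModel(spec=spec, fit=fit,
                                     observed_range=(0.0, 1.0))
        draws = draw_covariate(model, frame, np.random.default_rng(0),
                               prev=np.ones(200))
        assert np.all(draws == 1.0)

    def test_zero_inflated_degenerate_is_deterministic(self):
        frame = _frame(100)
        spec = CovariateSpec("Z", "zero_inflated_normal", "Z ~ x1")
        lin = _manual_fit("x1", frame, [2.0, 1.0],
                          family="gaussian_identity", sd=0.0)
        zero = _manual_fit("x1", frame, [50.0, 0.0])
        model = FittedCovariateModel(spec=spec, fit=lin,
                                     observed_range=(-100, 100),
                                     zero_model=zero,
                                     nonzero_range=(-100.0, 100.0))
        draws = draw_covariate(model, frame, np.random.default_rng(0))
        assert np.allclose(draws, 2.0 + frame["x1"].to_numpy())

    def test_constant_covariate_simulated_as_constant(self):
        frame = _frame(50)
        spec = CovariateSpec("Z", "normal", "Z ~ x1")
        model = FittedCovariateModel(spec=spec, fit=None,
                                     observed_range=(3.5, 3.5))
        draws = draw_covariate(model, frame, np.random.default_rng(0))
        assert np.all(draws == 3.5)


class TestOutcomeAndCompeting:
    def test_survival_pooled_fit_uses_all_rows(self, basic_dgp, basic_table):
        from gformula.pipeline import prepare_history_table
        cfg = basic_dgp.analysis_config()
        hist = prepare_history_table(basic_table, cfg)
        model = fit_outcome_model(cfg.outcome, cfg.ymodel, hist, "t0",
                                  basic_table.K)
        assert model.family == "binomial_logit"
        assert model.n_fit == basic_table.data["Y"].notna().sum()
        # intercept + A + L1 + L2 + L3 + t0
        assert len(model.fit.coefficients) == 6
        assert model.rmse > 0

    def test_continuous_eof_fit_is_cross_sectional(self):
        rng = np.random.default_rng(0)
        n = 400
        rows = []
        for k in range(3):
            y = rng.normal(2.0, 1.0, n) if k == 2 else np.full(n, np.nan)
            rows.append(pd.DataFrame({
                "id": np.arange(n), "t0": k, "x1": rng.normal(size=n), "Y": y
            }))
        df = pd.concat(rows)
        ospec = OutcomeSpec("continuous_eof", "Y")
        model = fit_outcome_model(ospec, "Y ~ x1", df, "t0", K=2)
        assert model.family == "gaussian_identity"
        assert model.n_fit == n

    def test_all_zero_outcome_rejected(self):
        df = pd.DataFrame({"id": range(50), "t0": 0, "x1": 0.5,
                           "Y": np.zeros(50)})
        with pytest.raises(FittingError, match="degenerate"):
            fit_outcome_model(OutcomeSpec("survival", "Y"), "Y ~ x1", df,
                              "t0", K=0)

    def test_constant_compevent_rejected(self):
        df = pd.DataFrame({"id": range(50), "t0": 0, "x1": 0.5,
                           "D": np.zeros(50)})
        with pytest.raises(FittingError, match="degenerate"):
            fit_compevent_model("D ~ x1", df, "t0", "D")

    def test_singular_design_names_collinear_terms(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"t0": 1, "x1": rng.normal(size=200)})
        df["x2"] = 2 * df["x1"]
        df["Z"] = (rng.random(200) < 0.5).astype(float)
        spec = CovariateSpec("Z", "binary", "Z ~ x1 + x2")
        with pytest.raises(FittingError, match="singular"):
            fit_covariate_model(spec, df, "t0")


class TestRmse:
    def test_perfect_fit_is_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"t0": 1, "x1": rng.normal(size=300)})
        df["Z"] = 1.0 + 2.0 * df["x1"]
        spec = CovariateSpec("Z", "normal", "Z ~ x1")
        model = fit_covariate_model(spec, df, "t0")
        assert model.rmse == pytest.approx(0.0, abs=1e-10)
        assert model.residual_scale == pytest.approx(0.0, abs=1e-10)

    def test_constant_model_rmse_is_population_sd(self):
        # oracle: direct residual computation around the sample mean
        rng = np.random.default_rng(1)
        z = rng.normal(2.0, 1.5, 500)
        df = pd.DataFrame({"t0": 1, "Z": z})
        spec = CovariateSpec("Z", "normal", "Z ~ 1")
        model = fit_covariate_model(spec, df, "t0")
        assert model.rmse == pytest.approx(np.sqrt(np.mean((z - z.mean()) ** 2)))

    def test_rmse_invariant_to_row_order(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"t0": 1, "x1": rng.normal(size=300)})
        df["Z"] = (rng.random(300) < expit(df["x1"])).astype(float)
        spec = CovariateSpec("Z", "binary", "Z ~ x1")
        m1 = fit_covariate_model(spec, df, "t0")
        m2 = fit_covariate_model(spec, df.sample(frac=1, random_state=0), "t0")
        assert m1.rmse == pytest.approx(m2.rmse)


class TestSpline:
    def test_rcs_is_linear_beyond_outer_knots(self):
        knots = (-1.0, 0.0, 1.0)
        x = np.array([2.0, 3.0, 4.0])
        basis = rcs(x, knots)
        slopes = np.diff(basis[:, 0])
        assert slopes[0] == pytest.approx(slopes[1])

    def test_rcs_usable_in_formula(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"t0": 1, "x1": rng.normal(size=500)})
        df["Z"] = np.sin(df["x1"]) + rng.normal(0, 0.1, 500)
        spec = CovariateSpec(
            "Z", "normal", "Z ~ x1 + rcs(x1, knots=(-2, -1, 0, 1, 2))")
        model = fit_covariate_model(spec, df, "t0")
        assert len(model.fit.coefficients) == 5
        linear = fit_covariate_model(
            CovariateSpec("Z", "normal", "Z ~ x1"), df, "t0")
        assert model.rmse < 0.5 * linear.rmse
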