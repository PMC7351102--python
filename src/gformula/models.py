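"""Step 1 of the algorithm: fitting conditional distributions.

Each time-varying covariate gets a parametric model for its distribution at
time ``k`` given history (the joint covariate distribution is factorized in
the user-specified covariate order).  The outcome gets a pooled-over-time
logistic hazard model (survival) or a single end-of-follow-up regression;
competing events, when modelled, get their own pooled logistic hazard.

Eight covariate families are supported:

==================  ============================================  =========================================
covtype             fit                                           simulation draw
==================  ============================================  =========================================
binary              logistic regression                           Bernoulli(p-hat)
normal              OLS + residual SD                             Normal, clipped to the observed range
categorical         multinomial logistic (reference level =       inverse-CDF draw over fitted class
                    first observed level)                         probabilities
bounded_normal      response scaled to [0,1] by observed           Normal on the [0,1] scale, clipped,
                    (min, max), then OLS                          back-transformed
zero_inflated_      logistic for I(Z != 0) plus OLS on the        Bernoulli nonzero indicator x Normal
normal              nonzero rows                                  draw clipped to the nonzero range
truncated_normal    OLS                                           one-sided truncated normal at the stated
                                                                  point/direction
absorbing           logistic on rows with previous value 0        stays 1 forever once 1, else Bernoulli
categorical_time    none (deterministic recode of k)              interval index of k in the cut points
==================  ============================================  =========================================

Covariate models are fitted on follow-up rows with ``k >= 1`` only: at
``k = 0`` the simulator resamples the observed baseline rather than
simulating from a model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import truncnorm

from .config import ConfigurationError, CovariateSpec, OutcomeSpec
from .formulas import build_design, design_response

__all__ = [
    "FittingError",
    "FittedCovariateModel",
    "FittedOutcomeModel",
    "FittedCompeventModel",
    "fit_covariate_model",
    "fit_outcome_model",
    "fit_compevent_model",
    "predict_probability",
    "predict_mean",
    "draw_covariate",
    "compute_rmse",
    "categorical_time_value",
]


class FittingError(RuntimeError):
    """Raised when a step-1 model cannot be fitted."""


@dataclass
class _GlmFit:
    """A single fitted regression component."""
    coefficients: pd.Series
    vcov: pd.DataFrame
    design_info: object
    family: str  # "binomial_logit" | "gaussian_identity" | "multinomial_logit"
    residual_scale: float = 0.0
    levels: Optional[np.ndarray] = None  # multinomial class values, fitted order


@dataclass
class FittedCovariateModel:
    spec: CovariateSpec
    fit: Optional[_GlmFit]
    observed_range: tuple[float, float]
    zero_model: Optional[_GlmFit] = None
    nonzero_range: Optional[tuple[float, float]] = None
    rmse: float = float("nan")
    n_fit: int = 0

    @property
    def coefficients(self) -> Optional[pd.Series]:
        return None if self.fit is None else self.fit.coefficients

    @property
    def vcov(self) -> Optional[pd.DataFrame]:
        return None if self.fit is None else self.fit.vcov

    @property
    def residual_scale(self) -> float:
        return 0.0 if self.fit is None else self.fit.residual_scale


@dataclass
class FittedOutcomeModel:
    formula: str
    fit: _GlmFit
    rmse: float
    n_fit: int

    @property
    def family(self) -> str:
        return self.fit.family


@dataclass
class FittedCompeventModel:
    formula: str
    fit: _GlmFit
    rmse: float
    n_fit: int


def _check_response_variation(y: np.ndarray, name: str) -> None:
    if np.unique(y[~np.isnan(y)]).size < 2:
        raise FittingError(f"degenerate response for model of {name!r}: no variation")


def _check_rank(X: pd.DataFrame, name: str) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns whose removal does not reduce the rank
        collinear = []
        for j, col in enumerate(X.columns):
            if np.linalg.matrix_rank(np.delete(arr, j, axis=1)) == rank:
                collinear.append(str(col))
        raise FittingError(
            f"singular design for model of {name!r} "
            f"(rank {rank} < {arr.shape[1]}); collinear terms: {collinear}"
        )


def _fit_logistic(formula: str, data: pd.DataFrame, name: str) -> _GlmFit:
    y, X = design_response(formula, data)
    yv = np.asarray(y).ravel()
    _check_response_variation(yv, name)
    _check_rank(X, name)
    try:
        res = sm.GLM(yv, np.asarray(X), family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels failure paths
        raise FittingError(f"logistic fit failed for {name!r}: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FittingError(f"logistic fit for {name!r} did not converge "
                           f"(non-finite coefficients)")
    cols = list(X.columns)
    return _GlmFit(
        coefficients=pd.Series(res.params, index=cols),
        vcov=pd.DataFrame(res.cov_params(), index=cols, columns=cols),
        design_info=X.design_info,
        family="binomial_logit",
    )


def _fit_linear(formula: str, data: pd.DataFrame, name: str) -> _GlmFit:
    y, X = design_response(formula, data)
    yv = np.asarray(y).ravel()
    _check_rank(X, name)
    res = sm.OLS(yv, np.asarray(X)).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    cols = list(X.columns)
    return _GlmFit(
        coefficients=pd.Series(res.params, index=cols),
        vcov=pd.DataFrame(res.cov_params(), index=cols, columns=cols),
        design_info=X.design_info,
        family="gaussian_identity",
        residual_scale=resid_sd,
    )


def _fit_multinomial(formula: str, data: pd.DataFrame, name: str) -> _GlmFit:
    resp = formula.split("~", 1)[0].strip()
    yraw = data[resp].to_numpy()
    levels = np.unique(yraw)
    if levels.size < 2:
        raise FittingError(f"degenerate response for model of {name!r}: no variation")
    codes = np.searchsorted(levels, yraw)
    rhs = formula.split("~", 1)[1]
    _, X = design_response(f"{resp} ~ {rhs}", data)
    _check_rank(X, name)
    try:
        res = sm.MNLogit(codes, np.asarray(X)).fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover
        raise FittingError(f"multinomial fit failed for {name!r}: {exc}") from exc
    cols = list(X.columns)
    params = np.asarray(res.params)  # (p, m-1)
    coef = pd.Series(
        params.ravel(order="F"),
        index=[f"{c}[{levels[j + 1]}]" for j in range(params.shape[1]) for c in cols],
    )
    cov = np.asarray(res.cov_params())
    return _GlmFit(
        coefficients=coef,
        vcov=pd.DataFrame(cov, index=coef.index[: cov.shape[0]],
                          columns=coef.index[: cov.shape[1]]),
        design_info=X.design_info,
        family="multinomial_logit",
        levels=levels,
    )


def categorical_time_value(spec: CovariateSpec, k) -> np.ndarray:
    """Deterministic recode of the time index into intervals.

    ``type_params['cuts']`` gives increasing interior cut points; the value
    is the (0-based) index of the interval containing ``k``, with intervals
    closed on the left: ``[..., cut_1), [cut_1, cut_2), ...``.
    """
    cuts = np.asarray(spec.type_params["cuts"], dtype=float)
    return np.searchsorted(cuts, np.asarray(k, dtype=float), side="right").astype(float)


def fit_covariate_model(spec: CovariateSpec, table: pd.DataFrame,
                        time_col: str) -> FittedCovariateModel:
    """Fit the conditional model for one time-varying covariate.

    ``table`` must already contain the history columns referenced by the
    formula.  Fitting rows are follow-up rows with ``k >= 1`` (further
    restricted per family).
    """
    if spec.covtype == "categorical_time":
        return FittedCovariateModel(spec=spec, fit=None,
                                    observed_range=(np.nan, np.nan))

    rows = table[table[time_col] >= 1]
    rows = rows[rows[spec.name].notna()]
    if spec.covtype == "absorbing":
        lag_col = f"lag1_{spec.name}"
        if lag_col not in rows.columns:
            raise ConfigurationError(
                f"absorbing covariate {spec.name!r} requires its own {lag_col}"
            )
        rows = rows[rows[lag_col] == 0]
    if rows.empty:
        raise FittingError(f"zero usable fitting rows for covariate {spec.name!r}")

    z = rows[spec.name].to_numpy(dtype=float)
    obs_range = (float(np.min(z)), float(np.max(z)))
    n_fit = len(rows)
    zero_model = None
    nonzero_range = None

    if spec.covtype in ("binary", "absorbing"):
        _check_response_variation(z, spec.name)
        fit = _fit_logistic(spec.formula, rows, spec.name)
    elif spec.covtype in ("normal", "truncated_normal"):
        fit = _fit_linear(spec.formula, rows, spec.name)
    elif spec.covtype == "bounded_normal":
        lo, hi = obs_range
        if hi == lo:
            fit = None
        else:
            scaled = rows.copy()
            scaled[spec.name] = (z - lo) / (hi - lo)
            fit = _fit_linear(spec.formula, scaled, spec.name)
    elif spec.covtype == "zero_inflated_normal":
        nz = rows.copy()
        indicator_col = f"_nonzero_{spec.name}"
        nz[indicator_col] = (nz[spec.name] != 0).astype(float)
        rhs = spec.formula.split("~", 1)[1]
        zero_model = _fit_logistic(f"{indicator_col} ~ {rhs}", nz,
                                   f"{spec.name} (nonzero indicator)")
        nonzero_rows = rows[rows[spec.name] != 0]
        if nonzero_rows.empty:
            raise FittingError(
                f"zero usable nonzero rows for zero-inflated covariate {spec.name!r}"
            )
        fit = _fit_linear(spec.formula, nonzero_rows, spec.name)
        nzv = nonzero_rows[spec.name].to_numpy(dtype=float)
        nonzero_range = (float(np.min(nzv)), float(np.max(nzv)))
    elif spec.covtype == "categorical":
        fit = _fit_multinomial(spec.formula, rows, spec.name)
    else:  # pragma: no cover - guarded by CovariateSpec validation
        raise ConfigurationError(f"unknown covtype {spec.covtype!r}")

    model = FittedCovariateModel(
        spec=spec, fit=fit, observed_range=obs_range,
        zero_model=zero_model, nonzero_range=nonzero_range, n_fit=n_fit,
    )
    model.rmse = compute_rmse(model, rows)
    return model


def fit_outcome_model(ospec: OutcomeSpec, formula: str, table: pd.DataFrame,
                      time_col: str, K: int) -> FittedOutcomeModel:
    """Fit the pooled discrete-time hazard (survival) or the
    end-of-follow-up mean model (eof outcomes)."""
    yname = ospec.outcome_name
    if ospec.outcome_type == "survival":
        rows = table[(table[time_col] >= 0) & table[yname].notna()]
    else:
        rows = table[(table[time_col] == K) & table[yname].notna()]
    if rows.empty:
        raise FittingError(f"zero usable fitting rows for outcome {yname!r}")
    if ospec.outcome_type == "continuous_eof":
        fit = _fit_linear(formula, rows, yname)
    else:
        _check_response_variation(rows[yname].to_numpy(dtype=float), yname)
        fit = _fit_logistic(formula, rows, yname)
    X = build_design(fit.design_info, rows)
    pred = X @ fit.coefficients.to_numpy()
    if fit.family == "binomial_logit":
        pred = expit(pred)
    rmse = float(np.sqrt(np.mean((rows[yname].to_numpy(dtype=float) - pred) ** 2)))
    return FittedOutcomeModel(formula=formula, fit=fit, rmse=rmse, n_fit=len(rows))


def fit_compevent_model(formula: str, table: pd.DataFrame, time_col: str,
                        compevent_col: str) -> FittedCompeventModel:
    """Fit the pooled logistic hazard of the competing event."""
    rows = table[(table[time_col] >= 0) & table[compevent_col].notna()]
    if rows.empty:
        raise FittingError(f"zero usable rows for competing-event model "
                           f"({compevent_col!r})")
    _check_response_variation(rows[compevent_col].to_numpy(dtype=float),
                              compevent_col)
    fit = _fit_logistic(formula, rows, compevent_col)
    X = build_design(fit.design_info, rows)
    pred = expit(X @ fit.coefficients.to_numpy())
    rmse = float(np.sqrt(np.mean(
        (rows[compevent_col].to_numpy(dtype=float) - pred) ** 2)))
    return FittedCompeventModel(formula=formula, fit=fit, rmse=rmse, n_fit=len(rows))


def _linear_predictor(fit: _GlmFit, frame: pd.DataFrame) -> np.ndarray:
    X = build_design(fit.design_info, frame)
    return X @ fit.coefficients.to_numpy()


def predict_probability(model, frame: pd.DataFrame) -> np.ndarray:
    """Inverse-logit of the linear predictor of a logistic component."""
    fit = model.fit if hasattr(model, "fit") else model
    if fit.family != "binomial_logit":
        raise ValueError(f"predict_probability requires a logistic model, "
                         f"got {fit.family}")
    try:
        return expit(_linear_predictor(fit, frame))
    except (patsy.PatsyError, KeyError) as exc:
        raise FittingError(f"missing feature during prediction: {exc}") from exc


def predict_mean(model: FittedOutcomeModel, frame: pd.DataFrame) -> np.ndarray:
    """Predicted outcome mean: probability for logistic families, the linear
    predictor for gaussian."""
    lp = _linear_predictor(model.fit, frame)
    return expit(lp) if model.fit.family == "binomial_logit" else lp


def _multinomial_probs(fit: _GlmFit, frame: pd.DataFrame) -> np.ndarray:
    X = build_design(fit.design_info, frame)
    p = X.shape[1]
    m = len(fit.levels)
    beta = fit.coefficients.to_numpy().reshape(p, m - 1, order="F")
    eta = np.column_stack([np.zeros(X.shape[0]), X @ beta])
    eta -= eta.max(axis=1, keepdims=True)
    w = np.exp(eta)
    return w / w.sum(axis=1, keepdims=True)


def draw_covariate(model: FittedCovariateModel, frame: pd.DataFrame,
                   rng: np.random.Generator, k: int = 0,
                   prev: Optional[np.ndarray] = None) -> np.ndarray:
    """Simulate one value of the covariate for every row of ``frame``."""
    spec = model.spec
    s = len(frame)
    if spec.covtype == "categorical_time":
        return np.full(s, categorical_time_value(spec, k))

    lo, hi = model.observed_range
    if model.fit is None or lo == hi:
        # degenerate: constant in the fitting data
        return np.full(s, lo)

    if spec.covtype == "binary":
        p = expit(_linear_predictor(model.fit, frame))
        return (rng.random(s) < p).astype(float)
    if spec.covtype == "absorbing":
        if prev is None:
            raise ValueError("absorbing draw requires the previous value")
        p = expit(_linear_predictor(model.fit, frame))
        new = (rng.random(s) < p).astype(float)
        return np.where(prev == 1, 1.0, new)
    if spec.covtype == "normal":
        mu = _linear_predictor(model.fit, frame)
        return np.clip(rng.normal(mu, model.fit.residual_scale), lo, hi)
    if spec.covtype == "bounded_normal":
        mu = _linear_predictor(model.fit, frame)
        z = np.clip(rng.normal(mu, model.fit.residual_scale), 0.0, 1.0)
        return lo + z * (hi - lo)
    if spec.covtype == "truncated_normal":
        mu = _linear_predictor(model.fit, frame)
        sd = max(model.fit.residual_scale, 1e-12)
        point = float(spec.type_params["point"])
        if spec.type_params["direction"] == "left":
            a, b = (point - mu) / sd, np.full(s, np.inf)
        else:
            a, b = np.full(s, -np.inf), (point - mu) / sd
        u = rng.random(s)
        return truncnorm.ppf(u, a, b, loc=mu, scale=sd)
    if spec.covtype == "zero_inflated_normal":
        p_nonzero = expit(_linear_predictor(model.zero_model, frame))
        nonzero = (rng.random(s) < p_nonzero).astype(float)
        mu = _linear_predictor(model.fit, frame)
        val = rng.normal(mu, model.fit.residual_scale)
        nlo, nhi = model.nonzero_range
        return nonzero * np.clip(val, nlo, nhi)
    if spec.covtype == "categorical":
        probs = _multinomial_probs(model.fit, frame)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(s)
        idx = (u[:, None] > cum).sum(axis=1)
        return model.fit.levels[idx].astype(float)
    raise RuntimeError(f"unknown covariate family {spec.covtype!r}")


def compute_rmse(model: FittedCovariateModel, rows: pd.DataFrame) -> float:
    """Root mean squared error of the fitted covariate model on its fitting
    rows.

    Continuous families: residual RMSE of the (composite, for zero-inflated)
    mean prediction.  Binary: observed minus fitted probability.
    Categorical: one minus the fitted probability of the observed class.
    """
    spec = model.spec
    if model.fit is None:
        return 0.0
    z = rows[spec.name].to_numpy(dtype=float)
    if spec.covtype in ("binary", "absorbing"):
        p = expit(_linear_predictor(model.fit, rows))
        return float(np.sqrt(np.mean((z - p) ** 2)))
    if spec.covtype == "categorical":
        probs = _multinomial_probs(model.fit, rows)
        idx = np.searchsorted(model.fit.levels, z)
        p_obs = probs[np.arange(len(z)), idx]
        return float(np.sqrt(np.mean((1.0 - p_obs) ** 2)))
    if spec.covtype == "bounded_normal":
        lo, hi = model.observed_range
        mu = lo + _linear_predictor(model.fit, rows) * (hi - lo)
        return float(np.sqrt(np.mean((z - mu) ** 2)))
    if spec.covtype == "zero_inflated_normal":
        p_nonzero = expit(_linear_predictor(model.zero_model, rows))
        mu = _linear_predictor(model.fit, rows)
        return float(np.sqrt(np.mean((z - p_nonzero * mu) ** 2)))
    mu = _linear_predictor(model.fit, rows)
    return float(np.sqrt(np.mean((z - mu) ** 2)))
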