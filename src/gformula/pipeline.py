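"""End-to-end orchestration: load, validate, fit, simulate, summarize.

``run_gformula`` is the library entry point (the analog of calling the
estimator on a prepared table); ``run_pipeline`` is the file-based wrapper
used by the command-line interface.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ConfigurationError, GFormulaConfig, load_config
from .data import LongitudinalTable, load_table, resolve_horizon, \
    validate_longitudinal_table
from .history import apply_histories, infer_max_lags
from .inference import BootstrapResult, bootstrap, contrasts
from .interventions import build_intervention_set
from .models import (
    FittedCompeventModel,
    FittedCovariateModel,
    FittedOutcomeModel,
    categorical_time_value,
    fit_compevent_model,
    fit_covariate_model,
    fit_outcome_model,
)
from .natural_course import compute_np_benchmarks
from .results import GFormulaResults, assemble_results, render_summary
from .simulate import estimate_intervention, sample_baseline, simulate_cohort

logger = logging.getLogger("gformula")

__all__ = ["FittedModels", "PointEstimates", "fit_all_models",
           "point_estimates", "run_gformula", "run_pipeline"]


@dataclass
class FittedModels:
    covariate_models: list[FittedCovariateModel]
    outcome_model: FittedOutcomeModel
    compevent_model: Optional[FittedCompeventModel]
    max_lag: dict[str, int]
    history_table: pd.DataFrame


@dataclass
class PointEstimates:
    estimates: dict[int, np.ndarray]
    ref_int: int
    legend: list[tuple[int, str]]
    models: FittedModels
    k_star: int
    nsimul: int
    mode: str
    outcome_type: str = "survival"
    cohorts: Optional[dict[int, object]] = None

    @property
    def k_values(self) -> np.ndarray:
        """Time labels of the estimate vectors: every interval for survival,
        the final interval only for end-of-follow-up outcomes."""
        if self.outcome_type == "survival":
            return np.arange(self.k_star)
        return np.array([self.k_star - 1])


def _all_formulas(config: GFormulaConfig) -> list[str]:
    formulas = [c.formula for c in config.covariates if c.formula]
    formulas.append(config.ymodel)
    if config.compevent_model:
        formulas.append(config.compevent_model)
    return formulas


def _tracker_max_lag(config: GFormulaConfig) -> dict[str, int]:
    spec = infer_max_lags(_all_formulas(config))
    out: dict[str, int] = {}
    for var, r in spec["lagged"].items():
        out[var] = max(out.get(var, 0), r)
    for var, r in spec["lagavg"].items():
        out[var] = max(out.get(var, 0), r)
    for c in config.covariates:
        if c.covtype == "absorbing":
            out[c.name] = max(out.get(c.name, 0), 1)
    return out


def prepare_history_table(table: LongitudinalTable,
                          config: GFormulaConfig) -> pd.DataFrame:
    """Observed table augmented with every referenced history column and
    derived deterministic time covariates."""
    df = table.data.copy()
    for c in config.covariates:
        if c.covtype == "categorical_time":
            df[c.name] = categorical_time_value(c, df[config.time_name])
    extra = {c.name: 1 for c in config.covariates if c.covtype == "absorbing"}
    return apply_histories(df, config.id, config.time_name,
                           _all_formulas(config), extra_lagged=extra)


def fit_all_models(table: LongitudinalTable, config: GFormulaConfig,
                   k_star: int) -> FittedModels:
    """Step 1: fit covariate, outcome, and competing-event models on the
    follow-up rows through ``k* - 1``."""
    # lag columns pad with 0 before a subject's first record, so a lagged
    # categorical covariate whose levels exclude 0 would silently gain a level
    for c in config.covariates:
        if c.covtype == "categorical":
            levels = set(np.unique(table.data[c.name].dropna()))
            if 0 not in levels and _tracker_max_lag(config).get(c.name, 0) > 0:
                import warnings
                warnings.warn(
                    f"categorical covariate {c.name!r} has no level 0 but is "
                    "lagged; the 0 padding on early rows will act as an "
                    "extra level"
                )
    hist = prepare_history_table(table, config)
    fit_rows = hist[hist[config.time_name] < k_star]
    covariate_models = [
        fit_covariate_model(spec, fit_rows, config.time_name)
        for spec in config.covariates
    ]
    outcome_model = fit_outcome_model(config.outcome, config.ymodel, fit_rows,
                                      config.time_name, table.K)
    compevent_model = None
    if config.outcome.compevent_modeled:
        if config.outcome.compevent_name not in hist.columns:
            raise ConfigurationError(
                f"compevent column {config.outcome.compevent_name!r} not in data"
            )
        compevent_model = fit_compevent_model(
            config.compevent_model, fit_rows, config.time_name,
            config.outcome.compevent_name,
        )
    return FittedModels(
        covariate_models=covariate_models, outcome_model=outcome_model,
        compevent_model=compevent_model, max_lag=_tracker_max_lag(config),
        history_table=hist,
    )


def _risk_mode(config: GFormulaConfig) -> str:
    if config.outcome.compevent_modeled:
        return "compevent_modeled"
    if config.outcome.treat_compevent_as_censoring:
        return "compevent_censored"
    return "no_compevent"


def point_estimates(table: LongitudinalTable, config: GFormulaConfig,
                    seed: int, keep_cohorts: bool = False) -> PointEstimates:
    """Fit all models and run the Monte Carlo simulation for every strategy.

    Every strategy's simulation starts from the same baseline resample and
    the same random substream, so threshold rules with infinite bounds
    reproduce the natural course exactly.
    """
    k_star = resolve_horizon(table, config.outcome)
    models = fit_all_models(table, config, k_star)
    specs, ref_int = build_intervention_set(
        config.interventions, config.covnames, k_star, config.ref_int
    )
    s = config.nsimul if config.nsimul is not None else table.n

    root = np.random.SeedSequence(seed)
    baseline_seq, sim_seq = root.spawn(2)
    baseline = sample_baseline(table, s, np.random.default_rng(baseline_seq))

    mode = _risk_mode(config)
    estimates: dict[int, np.ndarray] = {}
    cohorts: dict[int, object] = {}
    for idx, spec in enumerate(specs):
        rng = np.random.default_rng(sim_seq)  # identical stream per strategy
        cohort = simulate_cohort(
            baseline, models.covariate_models, models.outcome_model, spec,
            config.outcome, k_star, rng, config.time_name, models.max_lag,
            compevent_model=models.compevent_model, basecovs=config.basecovs,
        )
        estimates[idx] = estimate_intervention(cohort, config.outcome, mode)
        if keep_cohorts:
            cohorts[idx] = cohort
    legend = [(i, sp.description) for i, sp in enumerate(specs)]
    return PointEstimates(
        estimates=estimates, ref_int=ref_int, legend=legend, models=models,
        k_star=k_star, nsimul=s, mode=mode,
        outcome_type=config.outcome.outcome_type,
        cohorts=cohorts if keep_cohorts else None,
    )


def _model_summary_frame(models: FittedModels) -> pd.DataFrame:
    rows = []

    def add(name: str, fit, rmse: float, n_fit: int) -> None:
        if fit is None:
            return
        se = np.sqrt(np.diag(fit.vcov.to_numpy())) if fit.vcov is not None \
            else np.full(len(fit.coefficients), np.nan)
        for (term, coef), s_e in zip(fit.coefficients.items(), se):
            rows.append({"model": name, "term": term, "estimate": coef,
                         "se": s_e, "rmse": rmse, "n_fit": n_fit})

    for m in models.covariate_models:
        if m.fit is not None:
            add(m.spec.name, m.fit, m.rmse, m.n_fit)
        if m.zero_model is not None:
            add(f"{m.spec.name} (nonzero indicator)", m.zero_model, m.rmse,
                m.n_fit)
    add("outcome", models.outcome_model.fit, models.outcome_model.rmse,
        models.outcome_model.n_fit)
    if models.compevent_model is not None:
        add("competing event", models.compevent_model.fit,
            models.compevent_model.rmse, models.compevent_model.n_fit)
    return pd.DataFrame(rows)


def run_gformula(table: LongitudinalTable, config: GFormulaConfig,
                 validate: bool = True) -> GFormulaResults:
    """Full analysis: validation, point estimation, nonparametric
    benchmarks, contrasts, and (optionally) bootstrap inference."""
    t0 = time.time()
    if validate:
        report = validate_longitudinal_table(table, config.outcome)
        if not report.passed:
            raise ValueError(str(report))
    k_star = resolve_horizon(table, config.outcome)
    logger.info("run: n=%d K=%d k*=%d seed=%d nsimul=%s B=%d workers=%d",
                table.n, table.K, k_star, config.seed, config.nsimul,
                config.nsamples, config.ncores)

    point = point_estimates(table, config, seed=config.seed, keep_cohorts=True)
    contrast_table = contrasts(point.estimates, point.ref_int,
                               k_values=point.k_values)
    np_bench = compute_np_benchmarks(table, config.outcome, k_star)

    boot: Optional[BootstrapResult] = None
    if config.nsamples > 0:
        boot_seed = int(np.random.SeedSequence(config.seed).spawn(3)[2]
                        .generate_state(1)[0] % (2**31 - 1))
        boot = bootstrap(table, config, config.nsamples, boot_seed,
                         workers=config.ncores)

    nc = point.cohorts[0]
    cov_means = pd.DataFrame(
        {var: paths.mean(axis=0) for var, paths in nc.covariates.items()},
        index=pd.RangeIndex(point.k_star, name=table.time_col),
    )
    nc_risk = None
    if config.outcome.outcome_type == "survival":
        from .simulate import history_risk
        nc_risk = pd.Series(
            history_risk(nc.hazards, nc.comp_hazards, point.mode).mean(axis=0),
            index=pd.RangeIndex(point.k_star, name="k"), name="g-form risk",
        )

    results = assemble_results(
        outcome_type=config.outcome.outcome_type, n=table.n,
        nsimul=point.nsimul, nsamples=config.nsamples, ref_int=point.ref_int,
        k_star=point.k_star, legend=point.legend,
        contrast_table=contrast_table, np_benchmarks=np_bench,
        model_summaries=_model_summary_frame(point.models), boot=boot,
        nc_parametric_cov_means=cov_means, nc_parametric_risk=nc_risk,
        seed=config.seed,
    )
    logger.info("run finished in %.1fs", time.time() - t0)
    return results


def run_pipeline(config_path: str | Path, data_path: str | Path,
                 out_dir: str | Path, overrides: Optional[dict] = None,
                 make_plots: bool = True) -> GFormulaResults:
    """File-based pipeline: read config + CSV, run, write artifacts.

    Writes ``results.csv``, ``results.json``, ``models.csv``,
    ``summary.txt``, and natural-course diagnostic plots into ``out_dir``.
    """
    config = load_config(config_path)
    if overrides:
        for key, val in overrides.items():
            if val is None:
                continue
            if key == "time_points":
                config.outcome.time_points = val
            elif hasattr(config, key):
                setattr(config, key, val)
            else:
                raise ConfigurationError(f"unknown override {key!r}")
    table = load_table(data_path, config)
    results = run_gformula(table, config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.csv")
    results.to_json(out / "results.json")
    results.model_summaries.to_csv(out / "models.csv", index=False)
    (out / "summary.txt").write_text(render_summary(results))
    if make_plots:
        from .plots import plot_natural_course
        plot_natural_course(results, out_dir=out)
    logger.info("artifacts written to %s", out)
    return results
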