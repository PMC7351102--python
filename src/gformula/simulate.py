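"""Step 2 of the algorithm: Monte Carlo standardization.

``s`` covariate/treatment histories are generated per strategy by iterating
the fitted conditional models forward from a resampled baseline.  At each
follow-up time the covariates are simulated one at a time in factorization
order (each conditional on already-simulated same-time covariates earlier in
the order and on history features of all covariates); treatment values are
then replaced according to the strategy.  Risks are computed from the
predicted discrete-time hazards along each history — event indicators are
never simulated, which removes one layer of Monte Carlo noise without
changing the estimand — and averaged over histories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ConfigurationError, OutcomeSpec
from .data import LongitudinalTable
from .history import HistoryTracker
from .interventions import InterventionSpec, apply_interventions
from .models import (
    FittedCompeventModel,
    FittedCovariateModel,
    FittedOutcomeModel,
    draw_covariate,
    predict_mean,
    predict_probability,
)

__all__ = [
    "BaselineSample",
    "SimulatedCohort",
    "sample_baseline",
    "simulate_cohort",
    "history_risk",
    "estimate_intervention",
    "export_histories",
]


@dataclass
class BaselineSample:
    """``s`` baseline draws: covariates at ``k = 0`` plus any pre-baseline
    history, resampled jointly from the observed baseline rows."""

    frame: pd.DataFrame  # one row per simulated history
    prebaseline: dict[str, np.ndarray]  # var -> (s, i) values at times -i..-1
    source_ids: np.ndarray

    @property
    def s(self) -> int:
        return len(self.frame)


@dataclass
class SimulatedCohort:
    """Simulated histories for one strategy, with per-time hazards."""

    spec: InterventionSpec
    covariates: dict[str, np.ndarray]  # var -> (s, k*) assigned values
    natural: dict[str, np.ndarray]  # natural values of treated vars
    hazards: Optional[np.ndarray] = None  # (s, k*) outcome hazards p-hat
    comp_hazards: Optional[np.ndarray] = None  # (s, k*) competing q-hat
    eof_pred: Optional[np.ndarray] = None  # (s,) end-of-follow-up predictions

    @property
    def s(self) -> int:
        return next(iter(self.covariates.values())).shape[0]


def export_histories(cohorts: dict[int, "SimulatedCohort"], path) -> None:
    """Write simulated histories to CSV: one row per (strategy, history, k)
    with assigned covariates, natural treatment values, and hazards."""
    frames = []
    for idx, cohort in cohorts.items():
        s, k_star = next(iter(cohort.covariates.values())).shape
        for k in range(k_star):
            block = {"intervention": idx, "history": np.arange(s), "k": k}
            for var, paths in cohort.covariates.items():
                block[var] = paths[:, k]
            for var, paths in cohort.natural.items():
                block[f"natural_{var}"] = paths[:, k]
            if cohort.hazards is not None:
                block["p_hazard"] = cohort.hazards[:, k]
            if cohort.comp_hazards is not None:
                block["q_hazard"] = cohort.comp_hazards[:, k]
            frames.append(pd.DataFrame(block))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def sample_baseline(table: LongitudinalTable, s: int,
                    rng: np.random.Generator) -> BaselineSample:
    """Draw ``s`` baseline rows from the observed baseline distribution.

    With ``s`` equal to the observed sample size each subject's baseline is
    used exactly once; otherwise baselines are resampled with replacement.
    Pre-baseline covariate values travel with their subject.
    """
    if s < 1:
        raise ConfigurationError(f"number of simulated histories must be >= 1, got {s}")
    df = table.data
    t = table.time_col
    base = df[df[t] == 0].set_index(table.id_col)
    ids = base.index.to_numpy()
    n = len(ids)
    cols = table.basecovs + table.covnames
    base = base[[c for c in cols if c in base.columns]]

    depth = table.max_prebaseline
    pre_by_var: dict[str, np.ndarray] = {}
    if depth > 0:
        pre = df[df[t] < 0]
        for var in table.covnames:
            mat = np.full((n, depth), np.nan)
            piv = pre.pivot_table(index=table.id_col, columns=t, values=var,
                                  aggfunc="first")
            for j, time in enumerate(range(-depth, 0)):
                if time in piv.columns:
                    aligned = piv[time].reindex(ids)
                    mat[:, j] = aligned.to_numpy()
            pre_by_var[var] = mat

    if s == n:
        idx = np.arange(n)
    else:
        idx = rng.integers(0, n, size=s)
    frame = base.iloc[idx].reset_index(drop=True)
    prebaseline = {v: m[idx] for v, m in pre_by_var.items()}
    return BaselineSample(frame=frame, prebaseline=prebaseline,
                          source_ids=ids[idx])


def simulate_cohort(
    baseline: BaselineSample,
    covmodels: list[FittedCovariateModel],
    outcome_model: FittedOutcomeModel,
    spec: InterventionSpec,
    ospec: OutcomeSpec,
    k_star: int,
    rng: np.random.Generator,
    time_col: str,
    max_lag: dict[str, int],
    compevent_model: Optional[FittedCompeventModel] = None,
    basecovs: Optional[list[str]] = None,
) -> SimulatedCohort:
    """Generate ``s`` histories under one strategy and record hazards.

    The natural value of every covariate is always drawn first (consuming
    the same random numbers under every strategy), then treatments are
    replaced per the strategy; identical seeds therefore give aligned
    streams across strategies.
    """
    s = baseline.s
    covnames = [m.spec.name for m in covmodels]
    treated = set(spec.treated_variables)
    tracker = HistoryTracker(covnames, max_lag, s,
                             prebaseline=baseline.prebaseline or None)

    assigned_paths = {v: np.empty((s, k_star)) for v in covnames}
    natural_paths = {v: np.empty((s, k_star)) for v in treated}
    p_haz = np.empty((s, k_star)) if ospec.outcome_type == "survival" else None
    q_haz = np.empty((s, k_star)) if compevent_model is not None else None
    eof_pred = None

    base_frame = baseline.frame.reset_index(drop=True)
    survival = ospec.outcome_type == "survival"

    for k in range(k_star):
        frame = pd.DataFrame(index=range(s))
        for b in basecovs or []:
            frame[b] = base_frame[b].to_numpy()
        frame[time_col] = k
        for name, vals in tracker.lag_features().items():
            frame[name] = vals

        natural_now: dict[str, np.ndarray] = {}
        for model in covmodels:
            var = model.spec.name
            if k == 0 and model.spec.covtype != "categorical_time":
                nat = base_frame[var].to_numpy(dtype=float)
            else:
                prev = tracker.lag(var, 1) if model.spec.covtype == "absorbing" else None
                try:
                    nat = draw_covariate(model, frame, rng, k=k, prev=prev)
                except KeyError as exc:
                    raise ConfigurationError(
                        f"cannot resolve feature {exc} for covariate {var!r} "
                        f"at time {k}; check the factorization order"
                    ) from exc
            natural_now[var] = nat
            if var in treated:
                assigned = apply_interventions(
                    spec, k, {var: nat}, history=assigned_paths, rng=rng
                )[var]
            else:
                assigned = nat
            tracker.set_current(var, assigned)
            frame[var] = assigned
            frame[f"cumavg_{var}"] = tracker.cumavg(var)
            assigned_paths[var][:, k] = assigned
            if var in treated:
                natural_paths[var][:, k] = nat

        if survival:
            p_haz[:, k] = predict_probability(outcome_model, frame)
            if compevent_model is not None:
                q_haz[:, k] = predict_probability(compevent_model, frame)
        elif k == k_star - 1:
            eof_pred = predict_mean(outcome_model, frame)

        tracker.commit()

    return SimulatedCohort(
        spec=spec, covariates=assigned_paths, natural=natural_paths,
        hazards=p_haz, comp_hazards=q_haz, eof_pred=eof_pred,
    )


def history_risk(p: np.ndarray, q: Optional[np.ndarray] = None,
                 mode: str = "no_compevent") -> np.ndarray:
    """Cumulative risk by each interval from discrete-time hazards.

    With no (or censored) competing events,

        R(k) = sum_{t<=k} p_t * prod_{j<t} (1 - p_j).

    With modelled competing events the competing event is resolved first
    within each interval:

        R(k) = sum_{t<=k} (1 - q_t) p_t prod_{j<t} (1 - p_j)(1 - q_j),

    the (cause-specific) cumulative incidence.  Accepts a single hazard
    sequence or an (s, T) matrix; risks are nondecreasing and in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if mode not in ("no_compevent", "compevent_censored", "compevent_modeled"):
        raise ValueError(f"unknown competing-event mode {mode!r}")
    if mode == "compevent_modeled":
        if q is None:
            raise ValueError("modelled competing events require hazards q")
        q = np.asarray(q, dtype=float)
        if q.shape != p.shape:
            raise ValueError(f"hazard shapes differ: {p.shape} vs {q.shape}")
        interval_event = (1.0 - q) * p
        interval_survival = (1.0 - p) * (1.0 - q)
    else:
        interval_event = p
        interval_survival = 1.0 - p
    surv_before = np.ones_like(p)
    surv_before[..., 1:] = np.cumprod(interval_survival[..., :-1], axis=-1)
    return np.cumsum(interval_event * surv_before, axis=-1)


def estimate_intervention(cohort: SimulatedCohort, ospec: OutcomeSpec,
                          mode: str = "no_compevent") -> np.ndarray:
    """Average the per-history risks (survival) or predicted outcome means
    (end of follow-up) over the simulated histories.

    Survival: returns the risk by each interval ``k = 0..k*-1``.
    End of follow-up: returns a length-1 array with the mean.
    """
    if ospec.outcome_type == "survival":
        risks = history_risk(cohort.hazards, cohort.comp_hazards, mode=mode)
        return risks.mean(axis=0)
    return np.atleast_1d(float(np.mean(cohort.eof_pred)))
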