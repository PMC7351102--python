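"""Synthetic longitudinal data with known counterfactual truth.

Each :class:`StructuralDGP` is a small structural-equation system with
treatment-confounder feedback: time-varying covariates drawn sequentially
at each follow-up time from logistic / linear / multinomial equations in
the previous time's values (and running averages), a treatment equation,
and a discrete-time outcome hazard or an end-of-follow-up outcome equation.
Because the equations are known, the counterfactual risk or mean under any
treatment strategy can be computed exactly (by enumerating all paths, for
fully discrete systems) or to arbitrary Monte Carlo precision (by
simulating from the true equations under the strategy) — independently of
the estimation engine, which only ever sees the generated person-time
table.

Equations are declared as coefficient dictionaries over a feature
vocabulary: covariate names (current time), baseline covariate names,
``lag1_X``, ``cumavg_X``, the time index ``t``, and level indicators
written ``"X==v"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import GFormulaConfig, load_config
from .data import LongitudinalTable
from .interventions import InterventionSpec, apply_interventions

__all__ = [
    "DGPCovariate",
    "StructuralDGP",
    "generate_dataset",
    "true_counterfactual",
    "get_dgp",
    "DGP_NAMES",
]

Coefs = dict[str, float]


def _feature(feats: dict[str, np.ndarray], name: str) -> np.ndarray:
    if "*" in name:
        parts = [part.strip() for part in name.split("*")]
        out = _feature(feats, parts[0])
        for part in parts[1:]:
            out = out * _feature(feats, part)
        return out
    if "==" in name:
        var, lvl = (part.strip() for part in name.split("=="))
        return (np.asarray(feats[var]) == float(lvl)).astype(float)
    return np.asarray(feats[name], dtype=float)


def _linpred(coefs: Coefs, feats: dict[str, np.ndarray], size: int) -> np.ndarray:
    lp = np.full(size, float(coefs.get("const", 0.0)))
    for name, c in coefs.items():
        if name != "const":
            lp = lp + c * _feature(feats, name)
    return lp


@dataclass
class DGPCovariate:
    """One structural equation.  ``eq0`` is used at ``k = 0``, ``eq`` at
    ``k >= 1`` (equations may reference only same-time covariates earlier in
    the order, lagged values, and running averages — no anticipation)."""

    name: str
    kind: str  # binary | normal | categorical | zero_inflated_normal
    eq0: Coefs | list[Coefs]
    eq: Coefs | list[Coefs]
    sd: float = 1.0
    levels: tuple = (0.0, 1.0)
    zero_eq0: Optional[Coefs] = None  # zero-inflated: P(nonzero) logits
    zero_eq: Optional[Coefs] = None


@dataclass
class StructuralDGP:
    name: str
    n: int
    K: int
    outcome_type: str
    covariates: list[DGPCovariate]
    outcome_eq: Coefs
    basecovs: dict[str, tuple[float, float]] = field(default_factory=dict)
    outcome_sd: float = 1.0
    compevent_eq: Optional[Coefs] = None
    id_col: str = "id"
    time_col: str = "t0"
    outcome_col: str = "Y"
    compevent_col: str = "D"
    config: dict = field(default_factory=dict)

    @property
    def covnames(self) -> list[str]:
        return [c.name for c in self.covariates]

    def analysis_config(self, **overrides) -> GFormulaConfig:
        """A correctly specified engine configuration for this system."""
        raw = dict(self.config)
        raw.update(overrides)
        return load_config(raw)


class _DGPState:
    """Running lag-1 values and cumulative sums during forward simulation."""

    def __init__(self, covnames: list[str], size: int):
        self.lag1 = {v: np.zeros(size) for v in covnames}
        self.cumsum = {v: np.zeros(size) for v in covnames}
        self.count = 0

    def features(self, base: dict[str, np.ndarray], k: int,
                 size: int) -> dict[str, np.ndarray]:
        feats: dict[str, np.ndarray] = dict(base)
        feats["t"] = np.full(size, float(k))
        for v, val in self.lag1.items():
            feats[f"lag1_{v}"] = val
        return feats

    def set_current(self, feats: dict[str, np.ndarray], var: str,
                    values: np.ndarray) -> None:
        feats[var] = values
        feats[f"cumavg_{var}"] = (self.cumsum[var] + values) / (self.count + 1)

    def commit(self, feats: dict[str, np.ndarray], covnames: list[str]) -> None:
        for v in covnames:
            self.lag1[v] = feats[v]
            self.cumsum[v] = self.cumsum[v] + feats[v]
        self.count += 1


def _draw_covariate(cov: DGPCovariate, k: int, feats: dict[str, np.ndarray],
                    size: int, rng: np.random.Generator) -> np.ndarray:
    eq = cov.eq0 if k == 0 else cov.eq
    if cov.kind == "binary":
        return (rng.random(size) < expit(_linpred(eq, feats, size))).astype(float)
    if cov.kind == "normal":
        return rng.normal(_linpred(eq, feats, size), cov.sd)
    if cov.kind == "zero_inflated_normal":
        zeq = cov.zero_eq0 if k == 0 else cov.zero_eq
        nonzero = (rng.random(size) < expit(_linpred(zeq, feats, size)))
        return np.where(nonzero, rng.normal(_linpred(eq, feats, size), cov.sd), 0.0)
    if cov.kind == "categorical":
        logits = np.column_stack(
            [np.zeros(size)] + [_linpred(e, feats, size) for e in eq]
        )
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(size)
        idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        return np.asarray(cov.levels, dtype=float)[idx]
    raise ValueError(f"unknown DGP covariate kind {cov.kind!r}")


def generate_dataset(dgp: StructuralDGP, seed: int = 0) -> LongitudinalTable:
    """Simulate one observed person-time table from the structural system.

    Survival: a subject's records stop at the first interval with an event
    (``Y = 1`` on the last row) or competing event (``D = 1``, ``Y`` missing).
    End of follow-up: every subject has ``K + 1`` rows and the outcome is
    written only on the final row.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = dgp.n
    base = {name: rng.normal(mu, sd, n)
            for name, (mu, sd) in dgp.basecovs.items()}
    state = _DGPState(dgp.covnames, n)
    survival = dgp.outcome_type == "survival"
    alive = np.ones(n, dtype=bool)
    blocks = []
    for k in range(dgp.K + 1):
        feats = state.features(base, k, n)
        for cov in dgp.covariates:
            state.set_current(feats, cov.name, _draw_covariate(cov, k, feats, n, rng))
        block = {dgp.id_col: np.arange(n), dgp.time_col: k}
        block.update({b: base[b] for b in dgp.basecovs})
        block.update({v: feats[v] for v in dgp.covnames})
        if survival:
            y = np.full(n, np.nan)
            if dgp.compevent_eq is not None:
                q = expit(_linpred(dgp.compevent_eq, feats, n))
                d = (rng.random(n) < q).astype(float)
            else:
                d = np.zeros(n)
            p = expit(_linpred(dgp.outcome_eq, feats, n))
            event = (rng.random(n) < p) & (d == 0)
            y[d == 0] = event[d == 0].astype(float)
            block[dgp.outcome_col] = y
            if dgp.compevent_eq is not None:
                block[dgp.compevent_col] = d
            keep = alive
            alive = alive & (d == 0) & ~event
        else:
            if k == dgp.K:
                lp = _linpred(dgp.outcome_eq, feats, n)
                if dgp.outcome_type == "continuous_eof":
                    y = rng.normal(lp, dgp.outcome_sd)
                else:
                    y = (rng.random(n) < expit(lp)).astype(float)
            else:
                y = np.full(n, np.nan)
            block[dgp.outcome_col] = y
            keep = np.ones(n, dtype=bool)
        frame = pd.DataFrame(block)
        blocks.append(frame[keep])
        state.commit(feats, dgp.covnames)
    df = pd.concat(blocks, ignore_index=True)
    return LongitudinalTable(
        data=df, id_col=dgp.id_col, time_col=dgp.time_col,
        covnames=dgp.covnames,
        basecovs=list(dgp.basecovs),
        outcome_col=dgp.outcome_col,
        compevent_col=dgp.compevent_col if dgp.compevent_eq is not None else None,
    )


def _truth_mc(dgp: StructuralDGP, spec: InterventionSpec, k_star: int,
              s: int, seed: int, mode: str):
    rng = np.random.default_rng(seed)
    base = {name: rng.normal(mu, sd, s)
            for name, (mu, sd) in dgp.basecovs.items()}
    state = _DGPState(dgp.covnames, s)
    treated = set(spec.treated_variables)
    survival = dgp.outcome_type == "survival"
    surv = np.ones(s)
    risk = np.zeros((s, k_star)) if survival else None
    cum = np.zeros(s)
    final_pred = None
    for k in range(k_star):
        feats = state.features(base, k, s)
        for cov in dgp.covariates:
            nat = _draw_covariate(cov, k, feats, s, rng)
            if cov.name in treated:
                nat = apply_interventions(spec, k, {cov.name: nat}, rng=rng)[cov.name]
            state.set_current(feats, cov.name, nat)
        if survival:
            p = expit(_linpred(dgp.outcome_eq, feats, s))
            if mode == "compevent_modeled":
                if dgp.compevent_eq is None:
                    raise ValueError("DGP has no competing-event equation")
                q = expit(_linpred(dgp.compevent_eq, feats, s))
                cum = cum + surv * (1 - q) * p
                surv = surv * (1 - p) * (1 - q)
            else:
                cum = cum + surv * p
                surv = surv * (1 - p)
            risk[:, k] = cum
        elif k == k_star - 1:
            lp = _linpred(dgp.outcome_eq, feats, s)
            final_pred = expit(lp) if dgp.outcome_type == "binary_eof" else lp
        state.commit(feats, dgp.covnames)
    if survival:
        est = risk.mean(axis=0)
        se = risk.std(axis=0, ddof=1) / np.sqrt(s)
    else:
        est = np.atleast_1d(final_pred.mean())
        se = np.atleast_1d(final_pred.std(ddof=1) / np.sqrt(s))
    return est, se


def _truth_enumeration(dgp: StructuralDGP, spec: InterventionSpec,
                       k_star: int, mode: str):
    if any(c.kind != "binary" for c in dgp.covariates) or dgp.basecovs:
        raise ValueError(
            "exact enumeration requires a fully discrete system "
            "(binary covariates, no continuous baseline covariates)"
        )
    if dgp.outcome_type != "survival":
        raise ValueError("enumeration truth is implemented for survival systems")
    treated = set(spec.treated_variables)
    # path state, vectorized over an expanding set of weighted paths
    w = np.ones(1)
    state = _DGPState(dgp.covnames, 1)
    surv = np.ones(1)
    cum = np.zeros(1)
    risks = np.zeros(k_star)
    for k in range(k_star):
        feats = state.features({}, k, len(w))
        for cov in dgp.covariates:
            eq = cov.eq0 if k == 0 else cov.eq
            p1 = expit(_linpred(eq, feats, len(w)))
            # branch every path on the natural value 0 / 1
            feats = {name: np.concatenate([v, v]) for name, v in feats.items()}
            nat = np.concatenate([np.zeros(len(p1)), np.ones(len(p1))])
            w = np.concatenate([w * (1 - p1), w * p1])
            surv = np.concatenate([surv, surv])
            cum = np.concatenate([cum, cum])
            state.lag1 = {v: np.concatenate([a, a]) for v, a in state.lag1.items()}
            state.cumsum = {v: np.concatenate([a, a]) for v, a in state.cumsum.items()}
            if cov.name in treated:
                nat = apply_interventions(spec, k, {cov.name: nat})[cov.name]
            state.set_current(feats, cov.name, nat)
        p = expit(_linpred(dgp.outcome_eq, feats, len(w)))
        if mode == "compevent_modeled":
            q = expit(_linpred(dgp.compevent_eq, feats, len(w)))
            cum = cum + surv * (1 - q) * p
            surv = surv * (1 - p) * (1 - q)
        else:
            cum = cum + surv * p
            surv = surv * (1 - p)
        risks[k] = float(np.sum(w * cum))
        state.commit(feats, dgp.covnames)
    return risks, np.zeros(k_star)


def true_counterfactual(dgp: StructuralDGP, spec: InterventionSpec,
                        method: str = "large_mc", k_star: Optional[int] = None,
                        s: int = 1_000_000, seed: int = 0,
                        mode: str = "no_compevent"):
    """True risk (by interval) or end-of-follow-up mean under a strategy.

    ``method="enumeration"`` sums exactly over all covariate/treatment paths
    (fully discrete systems only); ``method="large_mc"`` simulates ``s``
    paths from the true equations under the strategy and accumulates risks
    from the true hazards.  Returns ``(estimate, mc_standard_error)``; the
    standard error is zero for enumeration.
    """
    if k_star is None:
        k_star = dgp.K + 1
    if method == "enumeration":
        return _truth_enumeration(dgp, spec, k_star, mode)
    if method == "large_mc":
        return _truth_mc(dgp, spec, k_star, s, seed, mode)
    raise ValueError(f"unknown truth method {method!r}")


# ---------------------------------------------------------------------------
# Named systems.  Coefficients are fixed once: hazards sized so that natural
# course cumulative risks land in roughly 0.2-0.7 over seven intervals, a
# protective treatment, and end-of-follow-up outcome means near 0.1 (binary)
# so strategy contrasts are well separated.
# ---------------------------------------------------------------------------


def _survival_basic(n: int = 2500, K: int = 6) -> StructuralDGP:
    covs = [
        DGPCovariate(
            "L1", "binary",
            eq0={"const": -0.8, "L3": 0.5},
            eq={"const": -0.6, "lag1_A": -0.9, "lag1_L1": 1.2, "L3": 0.4},
        ),
        DGPCovariate(
            "L2", "normal",
            eq0={"const": 0.0, "L3": 0.3},
            eq={"const": 0.2, "lag1_A": -0.5, "L1": 0.6, "lag1_L2": 0.5,
                "L3": 0.2},
            sd=0.8,
        ),
        DGPCovariate(
            "A", "binary",
            eq0={"const": -0.5, "L1": 0.8, "L2": 0.4, "L3": 0.3},
            eq={"const": -0.4, "lag1_A": 1.8, "L1": 0.7, "L2": 0.3, "L3": 0.2},
        ),
    ]
    outcome = {"const": -2.2, "A": -0.8, "L1": 0.9, "L2": 0.5, "L3": 0.3,
               "t": 0.05}
    config = {
        "id": "id", "time_name": "t0", "outcome_name": "Y",
        "outcome_type": "survival",
        "covnames": ["L1", "L2", "A"],
        "covtypes": ["binary", "normal", "binary"],
        "covmodels": [
            "L1 ~ lag1_A + lag1_L1 + L3",
            "L2 ~ lag1_A + L1 + lag1_L2 + L3",
            "A ~ lag1_A + L1 + L2 + L3",
        ],
        "basecovs": ["L3"],
        "ymodel": "Y ~ A + L1 + L2 + L3 + t0",
        "interventions": [
            {"description": "Never treat",
             "components": [{"variable": "A", "rule": "static", "values": [0.0]}]},
            {"description": "Always treat",
             "components": [{"variable": "A", "rule": "static", "values": [1.0]}]},
        ],
    }
    return StructuralDGP(
        name="survival_basic", n=n, K=K, outcome_type="survival",
        covariates=covs, outcome_eq=outcome, basecovs={"L3": (0.0, 1.0)},
        config=config,
    )


def _survival_compevent(n: int = 2500, K: int = 6) -> StructuralDGP:
    dgp = _survival_basic(n, K)
    dgp.name = "survival_compevent"
    dgp.compevent_eq = {"const": -3.2, "A": 0.3, "L1": 0.3, "L3": 0.4,
                        "t": 0.03}
    dgp.config = dict(dgp.config)
    dgp.config.update({
        "compevent_name": "D",
        "compevent_model": "D ~ A + L1 + L3 + t0",
    })
    return dgp


def _binary_eof(n: int = 2500, K: int = 6) -> StructuralDGP:
    covs = [
        DGPCovariate(
            "cov1", "binary",
            eq0={"const": -0.5, "cov3": 0.4},
            eq={"const": -0.8, "lag1_treat": 0.4, "lag1_cov1": 0.9,
                "cov3": 0.3},
        ),
        DGPCovariate(
            "cov2", "zero_inflated_normal",
            eq0={"const": 0.5, "cov3": 0.3},
            eq={"const": 0.3, "lag1_treat": -0.2, "cov1": 0.4, "cov3": 0.3},
            zero_eq0={"const": 0.3, "cov3": 0.3},
            zero_eq={"const": 0.2, "lag1_treat": -0.3, "cov1": 0.5,
                     "cov3": 0.2},
            sd=0.9,
        ),
        DGPCovariate(
            "treat", "normal",
            eq0={"const": 0.4, "cov1": 0.3, "cov2": 0.2, "cov3": 0.2},
            eq={"const": 0.3, "lag1_treat": 0.5, "cumavg_cov1": 0.3,
                "cumavg_cov2": 0.2, "cov3": 0.2},
            sd=0.7,
        ),
    ]
    outcome = {"const": -2.6, "treat": -0.4, "cov1": 0.5, "cov2": 0.3,
               "lag1_cov1": 0.3, "lag1_cov2": 0.2, "cov3": 0.3}
    config = {
        "id": "id_num", "time_name": "time", "outcome_name": "outcome",
        "outcome_type": "binary_eof",
        "covnames": ["cov1", "cov2", "treat"],
        "covtypes": ["binary", "zero_inflated_normal", "normal"],
        "covmodels": [
            "cov1 ~ lag1_treat + lag1_cov1 + cov3",
            "cov2 ~ lag1_treat + cov1 + cov3",
            "treat ~ lag1_treat + cumavg_cov1 + cumavg_cov2 + cov3",
        ],
        "basecovs": ["cov3"],
        "ymodel": "outcome ~ treat + cov1 + cov2 + lag1_cov1 + lag1_cov2 + cov3",
        "interventions": [
            {"description": "Never treat",
             "components": [{"variable": "treat", "rule": "static",
                             "values": [0.0]}]},
            {"description": "Threshold - lower bound 1",
             "components": [{"variable": "treat", "rule": "threshold",
                             "min": 1.0}]},
        ],
    }
    return StructuralDGP(
        name="binary_eof", n=n, K=K, outcome_type="binary_eof",
        covariates=covs, outcome_eq=outcome, basecovs={"cov3": (0.0, 1.0)},
        id_col="id_num", time_col="time", outcome_col="outcome",
        config=config,
    )


def _continuous_eof_categorical(n: int = 2500, K: int = 6) -> StructuralDGP:
    covs = [
        DGPCovariate(
            "L1", "categorical", levels=(0.0, 1.0, 2.0),
            eq0=[{"const": 0.2, "L3": 0.3}, {"const": -0.3, "L3": 0.4}],
            eq=[
                {"const": 0.3, "lag1_L1==1": 0.5, "lag1_L1==2": 0.2,
                 "lag1_A": -0.3, "L3": 0.2},
                {"const": -0.2, "lag1_L1==1": 0.3, "lag1_L1==2": 0.8,
                 "lag1_A": -0.4, "L3": 0.3},
            ],
        ),
        DGPCovariate(
            "L2", "normal",
            eq0={"const": 0.0, "L1==1": 0.2, "L1==2": 0.4, "L3": 0.3},
            eq={"const": 0.2, "lag1_A": -0.4, "L1==1": 0.3, "L1==2": 0.5,
                "lag1_L2": 0.4, "L3": 0.2},
            sd=0.9,
        ),
        DGPCovariate(
            "A", "binary",
            eq0={"const": -0.3, "L1==1": 0.4, "L1==2": 0.7, "L2": 0.3,
                 "L3": 0.2},
            eq={"const": -0.3, "lag1_A": 1.5, "L1==1": 0.4, "L1==2": 0.7,
                "L2": 0.3, "L3": 0.2},
        ),
    ]
    outcome = {"const": -1.0, "A": -1.2, "L1==1": 0.5, "L1==2": 0.8,
               "L2": 0.6, "lag1_A": -0.5, "lag1_L2": 0.3, "L3": 0.4}
    config = {
        "id": "id", "time_name": "t0", "outcome_name": "Y",
        "outcome_type": "continuous_eof",
        "covnames": ["L1", "L2", "A"],
        "covtypes": ["categorical", "normal", "binary"],
        "covmodels": [
            "L1 ~ C(lag1_L1) + lag1_A + L3",
            "L2 ~ lag1_A + C(L1) + lag1_L2 + L3",
            "A ~ lag1_A + C(L1) + L2 + L3",
        ],
        "basecovs": ["L3"],
        "ymodel": "Y ~ A + C(L1) + L2 + lag1_A + lag1_L2 + L3",
        "interventions": [
            {"description": "Never treat",
             "components": [{"variable": "A", "rule": "static",
                             "values": [0.0]}]},
            {"description": "Always treat",
             "components": [{"variable": "A", "rule": "static",
                             "values": [1.0]}]},
        ],
    }
    return StructuralDGP(
        name="continuous_eof_categorical", n=n, K=K,
        outcome_type="continuous_eof", covariates=covs, outcome_eq=outcome,
        outcome_sd=1.2, basecovs={"L3": (0.0, 1.0)}, config=config,
    )


def _survival_toy(n: int = 2500, K: int = 2) -> StructuralDGP:
    covs = [
        DGPCovariate(
            "L", "binary",
            eq0={"const": 0.0},
            eq={"const": -0.4, "lag1_A": -0.7, "lag1_L": 0.9},
        ),
        DGPCovariate(
            "A", "binary",
            eq0={"const": -0.3, "L": 0.6},
            eq={"const": -0.5, "lag1_A": 1.2, "L": 0.8},
        ),
    ]
    # hazard includes a treatment-confounder interaction, so saturated
    # engine models are a meaningful check on a small discrete state space
    outcome = {"const": -1.6, "A": -0.7, "L": 0.9, "A*L": 0.5, "t": 0.15}
    config = {
        "id": "id", "time_name": "t0", "outcome_name": "Y",
        "outcome_type": "survival",
        "covnames": ["L", "A"],
        "covtypes": ["binary", "binary"],
        "covmodels": [
            "L ~ lag1_A + lag1_L",
            "A ~ lag1_A + L",
        ],
        "ymodel": "Y ~ A + L + A:L + t0",
        "interventions": [
            {"description": "Never treat",
             "components": [{"variable": "A", "rule": "static",
                             "values": [0.0]}]},
            {"description": "Always treat",
             "components": [{"variable": "A", "rule": "static",
                             "values": [1.0]}]},
            {"description": "Threshold - lower bound 1",
             "components": [{"variable": "A", "rule": "threshold",
                             "min": 1.0}]},
        ],
    }
    return StructuralDGP(
        name="survival_toy", n=n, K=K, outcome_type="survival",
        covariates=covs, outcome_eq=outcome, config=config,
    )


_REGISTRY = {
    "survival_basic": _survival_basic,
    "survival_compevent": _survival_compevent,
    "binary_eof": _binary_eof,
    "continuous_eof_categorical": _continuous_eof_categorical,
    "survival_toy": _survival_toy,
}

DGP_NAMES = tuple(_REGISTRY)


def get_dgp(name: str, **kwargs) -> StructuralDGP:
    """Retrieve a named structural system (optionally overriding n / K)."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown DGP {name!r}; available: {DGP_NAMES}")
    return _REGISTRY[name](**kwargs)
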