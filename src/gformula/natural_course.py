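"""Nonparametric natural-course benchmarks for model diagnostics.

The parametric g-formula's natural-course estimate should be close to these
model-free quantities; gross disagreement signals misspecification of the
covariate or outcome models (closeness supports, but does not guarantee,
their adequacy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import OutcomeSpec
from .data import LongitudinalTable

__all__ = ["NPBenchmarks", "np_risk", "np_covariate_means", "np_eof_mean",
           "compute_np_benchmarks"]


@dataclass
class NPBenchmarks:
    risks: Optional[pd.Series] = None  # survival: risk by k
    covariate_means: Optional[pd.DataFrame] = None  # k x covariate
    eof_mean: Optional[float] = None
    at_risk: Optional[pd.Series] = None


def np_risk(table: LongitudinalTable, ospec: OutcomeSpec,
            k_star: Optional[int] = None) -> pd.Series:
    """Discrete-time product-limit risk under the natural course.

    The interval hazard is the number of events at ``k`` over the number of
    subjects with a record at ``k``; censored subjects leave the risk set
    after their last record.  With modelled competing events the
    Aalen-Johansen form is used:

        R(k) = sum_{t<=k} h_t * prod_{j<t} (1 - h_j - hD_j),

    with ``hD`` the competing-event interval proportion.  With no censoring
    or competing events this reduces to the empirical cumulative proportion
    failed.
    """
    if ospec.outcome_type != "survival":
        raise ValueError("np_risk is defined for survival outcomes only")
    if k_star is None:
        k_star = table.K + 1
    df = table.followup
    t, y = table.time_col, table.outcome_col
    modeled = ospec.compevent_modeled

    risks = np.full(k_star, np.nan)
    surv = 1.0
    cum = 0.0
    for k in range(k_star):
        rows = df[df[t] == k]
        at_risk = len(rows)
        if at_risk == 0:
            warnings.warn(
                f"no subjects at risk at time {k}; nonparametric risk "
                f"reported as missing from there on"
            )
            break
        h = float((rows[y] == 1).sum()) / at_risk
        hd = (float((rows[table.compevent_col] == 1).sum()) / at_risk
              if modeled else 0.0)
        cum += surv * h
        risks[k] = cum
        surv *= (1.0 - h - hd) if modeled else (1.0 - h)
    return pd.Series(risks, index=pd.RangeIndex(k_star, name="k"), name="np_risk")


def np_covariate_means(table: LongitudinalTable) -> pd.DataFrame:
    """Mean of each time-varying covariate at each ``k`` among subjects with
    a record at ``k`` (no censoring weights)."""
    df = table.followup
    return df.groupby(table.time_col)[table.covnames].mean()


def np_eof_mean(table: LongitudinalTable, ospec: OutcomeSpec) -> float:
    """Mean outcome over subjects uncensored through end of follow-up."""
    if ospec.outcome_type == "survival":
        raise ValueError("np_eof_mean is defined for end-of-follow-up outcomes")
    df = table.followup
    rows = df[(df[table.time_col] == table.K) & df[table.outcome_col].notna()]
    if rows.empty:
        raise ValueError("no uncensored subjects with an observed outcome at K")
    return float(rows[table.outcome_col].mean())


def compute_np_benchmarks(table: LongitudinalTable, ospec: OutcomeSpec,
                          k_star: Optional[int] = None) -> NPBenchmarks:
    bench = NPBenchmarks()
    df = table.followup
    bench.at_risk = df.groupby(table.time_col).size().rename("at_risk")
    bench.covariate_means = np_covariate_means(table)
    if ospec.outcome_type == "survival":
        bench.risks = np_risk(table, ospec, k_star)
    else:
        bench.eof_mean = np_eof_mean(table, ospec)
    return bench
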