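"""Deterministic functions of covariate history.

Three pre-coded history features are supported, with a fixed column-name
scheme that is part of the public formula vocabulary:

* ``lag{i}_Z``        — value of ``Z`` at time ``k - i`` (0 when the subject
  has no record that far back; pre-baseline rows count as records).
* ``cumavg_Z``        — mean of ``Z`` over follow-up times ``0..k``
  (equal to ``Z`` itself at ``k = 0``; pre-baseline values are excluded).
* ``lag_cumavg{i}_Z`` — ``cumavg_Z`` evaluated at ``k - i`` (0 for ``k < i``).

The same features are computed two ways: batch (on the observed table, for
model fitting) and incrementally (inside the Monte Carlo simulator).  The
two are equivalent by construction and property-tested for it.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError

__all__ = [
    "add_lagged",
    "add_cumavg",
    "add_lag_cumavg",
    "apply_histories",
    "infer_max_lags",
    "history_columns_needed",
    "HistoryTracker",
]

_LAG_RE = re.compile(r"\blag(\d+)_([A-Za-z_][A-Za-z0-9_]*)")
_LAGAVG_RE = re.compile(r"\blag_cumavg(\d+)_([A-Za-z_][A-Za-z0-9_]*)")
_CUMAVG_RE = re.compile(r"\bcumavg_([A-Za-z_][A-Za-z0-9_]*)")


def _check_vars(df: pd.DataFrame, variables: Iterable[str]) -> None:
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ConfigurationError(f"unknown history variables: {missing}")


def add_lagged(df: pd.DataFrame, id_col: str, time_col: str,
               variables: Sequence[str], r: int) -> pd.DataFrame:
    """Add ``lag{i}_Z`` columns for ``i = 1..r``.

    Pre-baseline rows (negative times) participate: the lag at ``k = 0`` of a
    subject with a record at ``k = -1`` is that pre-baseline value.
    """
    _check_vars(df, variables)
    if r < 1:
        raise ConfigurationError("number of lags r must be >= 1")
    out = df.sort_values([id_col, time_col], kind="stable").copy()
    g = out.groupby(id_col, sort=False)
    for var in variables:
        for i in range(1, r + 1):
            out[f"lag{i}_{var}"] = g[var].shift(i).fillna(0.0)
    return out


def _grouped_cumavg(out: pd.DataFrame, id_col: str, time_col: str,
                    var: str) -> pd.Series:
    """Cumulative average of `var` over follow-up rows (k >= 0) per subject."""
    mask = out[time_col] >= 0
    sub = out.loc[mask, [id_col, var]]
    avg = sub.groupby(id_col, sort=False)[var].expanding().mean()
    avg.index = avg.index.get_level_values(-1)
    full = pd.Series(np.nan, index=out.index)
    full.loc[avg.index] = avg
    return full


def add_cumavg(df: pd.DataFrame, id_col: str, time_col: str,
               variables: Sequence[str]) -> pd.DataFrame:
    """Add ``cumavg_Z`` columns (running mean over ``0..k``, NaN on k<0 rows)."""
    _check_vars(df, variables)
    out = df.sort_values([id_col, time_col], kind="stable").copy()
    for var in variables:
        out[f"cumavg_{var}"] = _grouped_cumavg(out, id_col, time_col, var)
    return out


def add_lag_cumavg(df: pd.DataFrame, id_col: str, time_col: str,
                   variables: Sequence[str], r: int) -> pd.DataFrame:
    """Add ``lag_cumavg{i}_Z`` columns for ``i = 1..r`` (0 on rows with k<i)."""
    _check_vars(df, variables)
    if r < 1:
        raise ConfigurationError("number of lags r must be >= 1")
    out = df.sort_values([id_col, time_col], kind="stable").copy()
    mask = out[time_col] >= 0
    for var in variables:
        ca = _grouped_cumavg(out, id_col, time_col, var)
        tmp = out.loc[mask, [id_col]].copy()
        tmp["_ca"] = ca.loc[mask]
        g = tmp.groupby(id_col, sort=False)["_ca"]
        for i in range(1, r + 1):
            shifted = g.shift(i).fillna(0.0)
            col = pd.Series(np.nan, index=out.index)
            col.loc[shifted.index] = shifted
            out[f"lag_cumavg{i}_{var}"] = col
    return out


def infer_max_lags(formulas: Iterable[str]) -> dict[str, dict[str, int]]:
    """Infer, per variable, the largest ``lag{i}_`` / ``lag_cumavg{i}_`` index
    referenced in any model formula.

    Returns ``{"lagged": {var: r}, "lagavg": {var: r}, "cumavg": {var: 0}}``.
    """
    lagged: dict[str, int] = {}
    lagavg: dict[str, int] = {}
    cumavg: dict[str, int] = {}
    for f in formulas:
        if not f:
            continue
        for m in _LAGAVG_RE.finditer(f):
            i, var = int(m.group(1)), m.group(2)
            lagavg[var] = max(lagavg.get(var, 0), i)
        stripped = _LAGAVG_RE.sub("", f)
        for m in _LAG_RE.finditer(stripped):
            i, var = int(m.group(1)), m.group(2)
            lagged[var] = max(lagged.get(var, 0), i)
        for m in _CUMAVG_RE.finditer(stripped):
            cumavg[m.group(1)] = 0
    return {"lagged": lagged, "lagavg": lagavg, "cumavg": cumavg}


def history_columns_needed(formulas: Iterable[str]) -> list[str]:
    """All history column names referenced across the given formulas."""
    cols: list[str] = []
    spec = infer_max_lags(formulas)
    for var, r in spec["lagged"].items():
        cols += [f"lag{i}_{var}" for i in range(1, r + 1)]
    for var, r in spec["lagavg"].items():
        cols += [f"lag_cumavg{i}_{var}" for i in range(1, r + 1)]
    cols += [f"cumavg_{var}" for var in spec["cumavg"]]
    return cols


def apply_histories(df: pd.DataFrame, id_col: str, time_col: str,
                    formulas: Iterable[str],
                    extra_lagged: dict[str, int] | None = None) -> pd.DataFrame:
    """Add every history column referenced by the model formulas.

    ``extra_lagged`` forces additional lags (e.g. ``lag1`` of an absorbing
    covariate, needed to restrict its fitting rows).
    """
    spec = infer_max_lags(formulas)
    lagged = dict(spec["lagged"])
    for var, r in (extra_lagged or {}).items():
        lagged[var] = max(lagged.get(var, 0), r)
    out = df
    for var, r in lagged.items():
        out = add_lagged(out, id_col, time_col, [var], r)
    for var, r in spec["lagavg"].items():
        out = add_lag_cumavg(out, id_col, time_col, [var], r)
    for var in spec["cumavg"]:
        out = add_cumavg(out, id_col, time_col, [var])
    return out


class HistoryTracker:
    """Incremental history features for a vector of simulated subjects.

    Maintains, for each tracked variable, ring buffers of the last ``r``
    values and cumulative averages, vectorized across ``s`` parallel
    histories.  Feeding it the rows of an observed subject reproduces the
    batch columns exactly.

    Parameters
    ----------
    variables : list of variable names to track.
    max_lag : dict var -> largest lag needed (0 if only cumavg).
    s : number of parallel histories.
    prebaseline : optional dict var -> array of shape (s, i) with values at
        times ``-i .. -1`` (NaN where a history has no record at that time;
        missing entries behave as the 0 padding of the batch operations).
    """

    def __init__(self, variables: Sequence[str], max_lag: dict[str, int],
                 s: int, prebaseline: dict[str, np.ndarray] | None = None):
        self.variables = list(variables)
        self.s = s
        self.max_lag = {v: int(max_lag.get(v, 0)) for v in self.variables}
        # value buffers indexed [var][lag-1] = value at time k-lag
        self._vals: dict[str, list[np.ndarray]] = {}
        self._cumavg: dict[str, list[np.ndarray]] = {}
        self._cumsum = {v: np.zeros(s) for v in self.variables}
        self._count = 0  # number of committed follow-up times
        self.current: dict[str, np.ndarray] = {}
        for v in self.variables:
            r = self.max_lag[v]
            buf = [np.zeros(s) for _ in range(r)]
            if prebaseline and v in prebaseline and r > 0:
                pre = np.asarray(prebaseline[v], dtype=float)
                depth = pre.shape[1]
                for i in range(1, min(r, depth) + 1):
                    # value at time -i is column depth - i
                    buf[i - 1] = np.nan_to_num(pre[:, depth - i], nan=0.0)
            self._vals[v] = buf
            self._cumavg[v] = [np.zeros(s) for _ in range(r)]

    def lag(self, var: str, i: int) -> np.ndarray:
        return self._vals[var][i - 1]

    def lag_cumavg(self, var: str, i: int) -> np.ndarray:
        return self._cumavg[var][i - 1]

    def cumavg(self, var: str) -> np.ndarray:
        """Cumulative average through the current time (requires the current
        value to have been set via :meth:`set_current`)."""
        cur = self.current[var]
        return (self._cumsum[var] + cur) / (self._count + 1)

    def set_current(self, var: str, values: np.ndarray) -> None:
        self.current[var] = np.asarray(values, dtype=float)

    def lag_features(self) -> dict[str, np.ndarray]:
        """All lag / lagged-cumavg columns available before any assignment
        at the current time step."""
        feats: dict[str, np.ndarray] = {}
        for v in self.variables:
            for i in range(1, self.max_lag[v] + 1):
                feats[f"lag{i}_{v}"] = self.lag(v, i)
                feats[f"lag_cumavg{i}_{v}"] = self.lag_cumavg(v, i)
        return feats

    def commit(self) -> None:
        """Finish the current time step: push current values into the lag
        buffers and update running sums."""
        for v in self.variables:
            cur = self.current.get(v)
            if cur is None:
                raise RuntimeError(f"no current value set for {v!r} before commit")
            ca = (self._cumsum[v] + cur) / (self._count + 1)
            if self.max_lag[v] > 0:
                self._vals[v] = [cur] + self._vals[v][:-1]
                self._cumavg[v] = [ca] + self._cumavg[v][:-1]
            self._cumsum[v] = self._cumsum[v] + cur
        self._count += 1
        self.current = {}
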