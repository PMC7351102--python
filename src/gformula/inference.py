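"""Contrasts versus the reference strategy and bootstrap inference.

Bootstrap replicates resample whole subjects (all of a subject's rows) with
replacement, refit every step-1 model, and rerun the simulation for every
strategy.  Standard errors are replicate standard deviations; confidence
intervals are percentile intervals, which the replicate distribution of
ratios in particular makes preferable to symmetric normal-approximation
intervals.  Replicates carry replicate-indexed random substreams, so the
result is invariant to the number of workers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

__all__ = ["contrasts", "bootstrap", "BootstrapResult"]


def contrasts(estimates: dict[int, np.ndarray], ref: int,
              k_values: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-strategy, per-time ratios and differences versus the reference.

    The reference rows have ratio exactly 1 and difference exactly 0.  A
    zero reference estimate makes the ratio undefined (reported missing
    with a warning); the difference is still computed.
    """
    if ref not in estimates:
        raise KeyError(f"reference strategy {ref} not among estimates")
    ref_est = np.asarray(estimates[ref], dtype=float)
    rows = []
    zero_ref = ref_est == 0
    if np.any(zero_ref):
        warnings.warn("reference estimate is 0 at some time points; "
                      "ratios there are reported as missing")
    for idx, est in estimates.items():
        est = np.asarray(est, dtype=float)
        if idx == ref:
            ratio = np.ones_like(est)
            diff = np.zeros_like(est)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(zero_ref, np.nan, est / ref_est)
            diff = est - ref_est
        ks = range(len(est)) if k_values is None else k_values
        for j, k in enumerate(ks):
            rows.append({"intervention": idx, "k": int(k), "estimate": est[j],
                         "ratio": ratio[j], "difference": diff[j]})
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    B: int
    n_failed: int = 0
    replicates: Optional[pd.DataFrame] = None  # long: replicate x quantity
    summary: Optional[pd.DataFrame] = None  # per (intervention, k): se, ci

    @property
    def n_ok(self) -> int:
        return self.B - self.n_failed


def _one_replicate(b: int, table, config, seed_seq) -> Optional[pd.DataFrame]:
    from .pipeline import point_estimates  # local import: avoids a cycle

    rng = np.random.default_rng(seed_seq)
    df = table.data
    ids = df[table.id_col].unique()
    take = rng.choice(len(ids), size=len(ids), replace=True)
    parts = []
    groups = {sid: g for sid, g in df.groupby(table.id_col, sort=False)}
    for new_id, j in enumerate(take):
        g = groups[ids[j]].copy()
        g[table.id_col] = new_id
        parts.append(g)
    boot_df = pd.concat(parts, ignore_index=True)
    boot_table = type(table)(
        data=boot_df, id_col=table.id_col, time_col=table.time_col,
        covnames=table.covnames, basecovs=table.basecovs,
        outcome_col=table.outcome_col, compevent_col=table.compevent_col,
    )
    sim_seed = int(rng.integers(0, 2**31 - 1))
    try:
        point = point_estimates(boot_table, config, seed=sim_seed)
    except Exception as exc:
        warnings.warn(f"bootstrap replicate {b} failed and was excluded: {exc}")
        return None
    tab = contrasts(point.estimates, point.ref_int, k_values=point.k_values)
    tab.insert(0, "replicate", b)
    return tab


def bootstrap(table, config, B: int, seed: int,
              workers: int = 1) -> BootstrapResult:
    """Nonparametric subject-level bootstrap of all estimates and contrasts.

    With ``B = 0`` no resampling is done and no SE/CI fields are produced.
    """
    if B < 0:
        raise ValueError("number of bootstrap samples must be >= 0")
    if B == 0:
        return BootstrapResult(B=0)
    children = np.random.SeedSequence(seed).spawn(B)
    tabs = Parallel(n_jobs=max(1, workers))(
        delayed(_one_replicate)(b, table, config, children[b]) for b in range(B)
    )
    ok = [t for t in tabs if t is not None]
    n_failed = B - len(ok)
    if not ok:
        return BootstrapResult(B=B, n_failed=n_failed)
    reps = pd.concat(ok, ignore_index=True)
    grouped = reps.groupby(["intervention", "k"])
    pieces = []
    for quantity in ("estimate", "ratio", "difference"):
        agg = grouped[quantity].agg(
            se="std",
            ci_lower=lambda x: float(np.nanquantile(x, 0.025)),
            ci_upper=lambda x: float(np.nanquantile(x, 0.975)),
        )
        agg.columns = [f"{quantity}_{c}" for c in agg.columns]
        pieces.append(agg)
    summary = pd.concat(pieces, axis=1).reset_index()
    return BootstrapResult(B=B, n_failed=n_failed, replicates=reps,
                           summary=summary)
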