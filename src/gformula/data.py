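"""Long-format person-time data: loading, coding rules, and validation.

The input is one row per subject per follow-up interval.  Row ``k`` carries
the covariates measured at time ``k`` and, for survival outcomes, the
indicator ``Y_{k+1}`` of failure in interval ``(k, k+1]`` (plus, when
competing events are modelled, the indicator ``D_{k+1}``).  Censoring is
encoded implicitly by record termination without an event; no censoring
column is used.  Rows with negative time indices carry pre-baseline
covariate measurements used only to build history features at ``k >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ConfigurationError, GFormulaConfig, OutcomeSpec

__all__ = [
    "LongitudinalTable",
    "ValidationReport",
    "load_table",
    "validate_longitudinal_table",
    "resolve_horizon",
]


@dataclass
class LongitudinalTable:
    """A validated long-format person-time table.

    Attributes
    ----------
    data
        The underlying DataFrame, sorted by (id, time).
    id_col, time_col
        Column names of the subject identifier and integer time index.
    covnames
        Time-varying covariate columns, in factorization order.
    basecovs
        Baseline (time-fixed) covariate columns.
    outcome_col
        Outcome column (``Y``).
    compevent_col
        Optional competing-event indicator column (``D``).
    """

    data: pd.DataFrame
    id_col: str
    time_col: str
    covnames: list[str]
    basecovs: list[str] = field(default_factory=list)
    outcome_col: str = "Y"
    compevent_col: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = self.data.sort_values(
            [self.id_col, self.time_col], kind="stable"
        ).reset_index(drop=True)

    @property
    def n(self) -> int:
        """Baseline sample size (number of unique subjects)."""
        return self.data[self.id_col].nunique()

    @property
    def K(self) -> int:
        """Maximum follow-up time index present in the data."""
        return int(self.data[self.time_col].max())

    @property
    def max_prebaseline(self) -> int:
        """Maximum number of pre-baseline records ``i`` (0 when none)."""
        tmin = int(self.data[self.time_col].min())
        return max(0, -tmin)

    @property
    def followup(self) -> pd.DataFrame:
        """Rows with ``k >= 0`` (model-fitting rows)."""
        return self.data[self.data[self.time_col] >= 0]

    def subject_groups(self):
        return self.data.groupby(self.id_col, sort=False)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class ValidationReport:
    violations: list[dict] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def add(self, subject, row, rule: str, message: str) -> None:
        self.violations.append(
            {"subject": subject, "row": row, "rule": rule, "message": message}
        )

    def __str__(self) -> str:
        if self.passed:
            return "validation passed (0 violations)"
        lines = [f"validation failed ({len(self.violations)} violations):"]
        for v in self.violations[:50]:
            lines.append(
                f"  subject {v['subject']!r} row {v['row']}: [{v['rule']}] {v['message']}"
            )
        if len(self.violations) > 50:
            lines.append(f"  ... and {len(self.violations) - 50} more")
        return "\n".join(lines)


def load_table(path: str | Path, config: GFormulaConfig) -> LongitudinalTable:
    """Read a person-time CSV and return a typed :class:`LongitudinalTable`.

    Missing outcome values (empty fields or ``NA``) are preserved as missing,
    never coerced to 0.  The time column must be integer-valued.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"data file not found: {path}")
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if df.empty:
        raise ValueError(f"data file {path} contains no rows")

    needed = (
        [config.id, config.time_name, config.outcome.outcome_name]
        + config.covnames
        + config.basecovs
    )
    if config.outcome.compevent_name:
        needed.append(config.outcome.compevent_name)
    # categorical_time columns are derived, not read from the file
    derived = {c.name for c in config.covariates if c.covtype == "categorical_time"}
    missing = [c for c in needed if c not in df.columns and c not in derived]
    if missing:
        raise ConfigurationError(f"missing columns in {path.name}: {missing}")

    tvals = df[config.time_name]
    if not np.allclose(tvals, np.round(tvals), equal_nan=False):
        raise ValueError(f"time column {config.time_name!r} has non-integer values")
    df[config.time_name] = tvals.astype(int)

    return LongitudinalTable(
        data=df,
        id_col=config.id,
        time_col=config.time_name,
        covnames=config.covnames,
        basecovs=config.basecovs,
        outcome_col=config.outcome.outcome_name,
        compevent_col=config.outcome.compevent_name,
    )


def validate_longitudinal_table(
    table: LongitudinalTable, ospec: OutcomeSpec
) -> ValidationReport:
    """Check every coding rule of the long-format layout.

    All violations are collected (the check is not fail-fast): consecutive
    integer time indices starting at 0 (or ``-i`` with pre-baseline rows),
    constant baseline covariates within subject, survival outcome/competing
    event placement, and end-of-follow-up outcome coding.
    """
    report = ValidationReport()
    t, y = table.time_col, table.outcome_col
    K = table.K

    for sid, g in table.subject_groups():
        times = g[t].to_numpy()
        rows = g.index.to_numpy()
        diffs = np.diff(times)
        if len(times) and not np.all(diffs == 1):
            report.add(sid, int(rows[np.argmax(diffs != 1)]),
                       "non-consecutive time index",
                       f"time values {times.tolist()} do not increase in increments of 1")
        first = times[0] if len(times) else None
        if first is not None and first > 0:
            report.add(sid, int(rows[0]), "baseline missing",
                       f"follow-up must start at 0 (or -i with pre-baseline rows); "
                       f"starts at {first}")

        for b in table.basecovs:
            vals = g[b]
            if vals.nunique(dropna=False) > 1:
                report.add(sid, int(rows[0]), "baseline covariate varies",
                           f"baseline covariate {b!r} is not constant within subject")

        fg = g[g[t] >= 0]
        if fg.empty:
            continue
        yvals = fg[y].to_numpy(dtype=float)

        if ospec.outcome_type == "survival":
            events = np.flatnonzero(yvals == 1)
            if events.size and events[0] != len(yvals) - 1:
                report.add(sid, int(fg.index[events[0]]), "records after event",
                           "Y=1 must appear only on a subject's last follow-up row")
            if table.compevent_col is not None:
                dvals = fg[table.compevent_col].to_numpy(dtype=float)
                comp = np.flatnonzero(dvals == 1)
                if comp.size:
                    if comp[0] != len(dvals) - 1:
                        report.add(sid, int(fg.index[comp[0]]),
                                   "records after competing event",
                                   "D=1 must appear only on a subject's last row")
                    elif not np.isnan(yvals[comp[0]]):
                        report.add(sid, int(fg.index[comp[0]]),
                                   "outcome not missing at competing event",
                                   "Y must be coded NA on a row with D=1")
        else:
            # end of follow-up: Y is read only on row k=K
            last_t = int(fg[t].iloc[-1])
            if last_t < K and len(fg) != last_t + 1:
                report.add(sid, int(fg.index[-1]), "row count mismatch",
                           "censored subjects must have one row per interval "
                           "through their last time")

    return report


def resolve_horizon(
    table: LongitudinalTable, ospec: OutcomeSpec,
    time_points: Optional[int] = None,
) -> int:
    """Return the follow-up horizon ``k*`` (defaults to ``K + 1``)."""
    if time_points is None:
        time_points = ospec.time_points
    K = table.K
    if time_points is None:
        return K + 1
    k_star = int(time_points)
    if k_star <= 0 or k_star > K + 1:
        raise ConfigurationError(
            f"time_points must be in 1..K+1 = {K + 1}; got {k_star}"
        )
    return k_star
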