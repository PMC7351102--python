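"""Assembled results of a g-formula run and the printed-summary layout."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .inference import BootstrapResult
from .natural_course import NPBenchmarks

__all__ = ["GFormulaResults", "assemble_results", "render_summary"]


@dataclass
class GFormulaResults:
    """Everything one run produces.

    ``table`` holds one row per (k, intervention) with the nonparametric
    benchmark (natural course only), the parametric estimate, and the
    ratio/difference versus the reference; SE and percentile 95% CI columns
    are present when bootstrap samples were drawn.
    """

    outcome_type: str
    n: int
    nsimul: int
    nsamples: int
    ref_int: int
    k_star: int
    legend: list[tuple[int, str]]
    table: pd.DataFrame
    model_summaries: pd.DataFrame
    np_benchmarks: NPBenchmarks
    bootstrap: Optional[BootstrapResult] = None
    nc_parametric_cov_means: Optional[pd.DataFrame] = None
    nc_parametric_risk: Optional[pd.Series] = None
    seed: int = 0

    @property
    def display_k(self) -> int:
        """Survival results are reported at ``k = k* - 1`` by default."""
        return self.k_star - 1

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "outcome_type": self.outcome_type,
            "n": self.n,
            "nsimul": self.nsimul,
            "nsamples": self.nsamples,
            "ref_int": self.ref_int,
            "k_star": self.k_star,
            "seed": self.seed,
            "legend": [{"intervention": i, "description": d}
                       for i, d in self.legend],
            "table": json.loads(self.table.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def assemble_results(
    *,
    outcome_type: str,
    n: int,
    nsimul: int,
    nsamples: int,
    ref_int: int,
    k_star: int,
    legend: list[tuple[int, str]],
    contrast_table: pd.DataFrame,
    np_benchmarks: NPBenchmarks,
    model_summaries: pd.DataFrame,
    boot: Optional[BootstrapResult] = None,
    nc_parametric_cov_means: Optional[pd.DataFrame] = None,
    nc_parametric_risk: Optional[pd.Series] = None,
    seed: int = 0,
) -> GFormulaResults:
    """Merge estimates, contrasts, benchmarks, and bootstrap summaries into
    one coherent results object."""
    desc = dict(legend)
    missing = set(contrast_table["intervention"].unique()) - set(desc)
    if missing:
        raise RuntimeError(f"interventions {sorted(missing)} missing from legend")
    tab = contrast_table.copy()
    tab["description"] = tab["intervention"].map(desc)

    if outcome_type == "survival" and np_benchmarks.risks is not None:
        np_map = np_benchmarks.risks
        tab["np_estimate"] = [
            float(np_map.iloc[k]) if i == 0 and k < len(np_map) else np.nan
            for i, k in zip(tab["intervention"], tab["k"])
        ]
    elif np_benchmarks.eof_mean is not None:
        tab["np_estimate"] = [
            np_benchmarks.eof_mean if i == 0 else np.nan
            for i in tab["intervention"]
        ]
    else:
        tab["np_estimate"] = np.nan

    if boot is not None and boot.summary is not None:
        tab = tab.merge(boot.summary, on=["intervention", "k"], how="left")
        tab = tab.rename(columns={
            "estimate_se": "se", "estimate_ci_lower": "ci_lower",
            "estimate_ci_upper": "ci_upper",
        })

    cols = ["k", "intervention", "description", "np_estimate", "estimate",
            "ratio", "difference"]
    cols += [c for c in tab.columns if c not in cols]
    tab = tab[cols].sort_values(["k", "intervention"]).reset_index(drop=True)

    return GFormulaResults(
        outcome_type=outcome_type, n=n, nsimul=nsimul, nsamples=nsamples,
        ref_int=ref_int, k_star=k_star, legend=legend, table=tab,
        model_summaries=model_summaries, np_benchmarks=np_benchmarks,
        bootstrap=boot, nc_parametric_cov_means=nc_parametric_cov_means,
        nc_parametric_risk=nc_parametric_risk, seed=seed,
    )


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.7g}"


def render_summary(results: GFormulaResults) -> str:
    """Human-readable summary: banner, strategy legend, header lines, and
    the results table (risk columns for survival, mean columns otherwise).

    A pure function of the results object: printed at 7 significant digits;
    full precision lives in the CSV/JSON exports.
    """
    survival = results.outcome_type == "survival"
    lines = ["PREDICTED RISK UNDER MULTIPLE INTERVENTIONS", ""]
    lines.append("Intervention \tDescription")
    for idx, desc in results.legend:
        lines.append(f"{idx}\t{desc}")
    lines.append("")
    lines.append(f"Sample size = {results.n}, "
                 f"Monte Carlo sample size = {results.nsimul}")
    lines.append(f"Number of bootstrap samples = {results.nsamples}")
    ref_desc = dict(results.legend)[results.ref_int]
    if results.ref_int == 0:
        lines.append("Reference intervention = natural course (0)")
    else:
        lines.append(f"Reference intervention = {ref_desc} ({results.ref_int})")
    lines.append("")

    word = "risk" if survival else "mean"
    headers = ["k", "Interv.", f"NP {word}", f"g-form {word}",
               f"{word.capitalize()} ratio", f"{word.capitalize()} difference"]
    has_boot = "se" in results.table.columns and results.nsamples > 0
    if has_boot:
        headers += [f"{word.capitalize()} SE", "Lower 95% CI", "Upper 95% CI"]
    lines.append("  ".join(headers))
    tab = results.table
    show = tab[tab["k"] == results.display_k] if survival else tab
    for _, row in show.iterrows():
        cells = [str(int(row["k"])), str(int(row["intervention"])),
                 _fmt(row["np_estimate"]), _fmt(row["estimate"]),
                 _fmt(row["ratio"]), _fmt(row["difference"])]
        if has_boot:
            cells += [_fmt(row.get("se")), _fmt(row.get("ci_lower")),
                      _fmt(row.get("ci_upper"))]
        lines.append("  ".join(cells))
    return "\n".join(lines) + "\n"
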