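"""Natural-course diagnostic plots.

One panel per time-varying covariate comparing nonparametric and parametric
(simulated) covariate means by follow-up time under the natural course,
plus, for survival outcomes, a risk-by-time panel.  Visual agreement
supports (but does not guarantee) the absence of gross model
misspecification.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .results import GFormulaResults

__all__ = ["plot_natural_course"]


def plot_natural_course(results: GFormulaResults,
                        out_dir: Optional[str | Path] = None,
                        filename: str = "natural_course.png") -> plt.Figure:
    """Build the diagnostic figure; optionally save it under ``out_dir``."""
    cov_means = results.nc_parametric_cov_means
    np_means = results.np_benchmarks.covariate_means
    covs = [] if cov_means is None else list(cov_means.columns)
    survival = results.outcome_type == "survival" \
        and results.nc_parametric_risk is not None
    n_panels = len(covs) + (1 if survival else 0)
    ncols = min(2, max(1, n_panels))
    nrows = (n_panels + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 3.2 * nrows),
                             squeeze=False)
    flat = axes.ravel()

    panel = 0
    if survival:
        ax = flat[panel]
        panel += 1
        risks = results.np_benchmarks.risks
        ax.plot(risks.index, risks.to_numpy(), "o-", label="nonparametric")
        par = results.nc_parametric_risk
        ax.plot(par.index, par.to_numpy(), "s--", label="parametric g-formula")
        ax.set_title("risk")
        ax.set_xlabel("follow-up time k")
        ax.set_ylabel("cumulative risk")
        ax.legend(fontsize=8)

    for cov in covs:
        ax = flat[panel]
        panel += 1
        if np_means is not None and cov in np_means.columns:
            sub = np_means[cov].iloc[: results.k_star]
            ax.plot(sub.index, sub.to_numpy(), "o-", label="nonparametric")
        ax.plot(cov_means.index, cov_means[cov].to_numpy(), "s--",
                label="parametric g-formula")
        ax.set_title(cov)
        ax.set_xlabel("follow-up time k")
        ax.set_ylabel("mean")
        ax.legend(fontsize=8)

    for ax in flat[panel:]:
        ax.set_visible(False)
    fig.tight_layout()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fig.savefig(out / filename, dpi=120)
        plt.close(fig)
    return fig
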