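"""Formula evaluation helpers shared by model fitting and simulation.

Model statements use patsy grammar.  In addition to the patsy builtins
(``C``, ``I``, ``standardize``, ...), formulas may use numpy functions and a
restricted cubic spline basis ``rcs(x, knots=(...))`` with user-supplied
knots, so that nonlinear functions of continuous covariates can enter any
model without arbitrary code execution.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import patsy

__all__ = ["rcs", "design_response", "design_matrix", "build_design", "FORMULA_NAMESPACE"]


def rcs(x, knots: Sequence[float]) -> np.ndarray:
    """Restricted (natural) cubic spline basis with fixed knots.

    Returns the ``m - 2`` nonlinear basis columns for knots
    ``t_1 < ... < t_m`` (the linear term belongs in the formula itself),
    normalized by the squared distance between the outer knots.  The basis
    is linear beyond the outer knots.  Stateless: identical output for
    identical inputs, so fitted models can be re-evaluated on simulated data.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(sorted(knots), dtype=float)
    m = len(t)
    if m < 3:
        raise ValueError("rcs requires at least 3 knots")
    norm = (t[-1] - t[0]) ** 2

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = []
    for j in range(m - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[m - 2]) * (t[-1] - t[j]) / (t[-1] - t[m - 2])
            + pos3(x - t[-1]) * (t[m - 2] - t[j]) / (t[-1] - t[m - 2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


FORMULA_NAMESPACE = {
    "rcs": rcs,
    "np": np,
    "log": np.log,
    "exp": np.exp,
    "sqrt": np.sqrt,
}

_EVAL_ENV = patsy.EvalEnvironment([FORMULA_NAMESPACE])


def design_response(formula: str, data: pd.DataFrame):
    """Build response vector and design matrix for a two-sided formula.

    Rows with missing values anywhere in the design raise, since fitting
    rows are expected to be pre-filtered.
    """
    y, X = patsy.dmatrices(
        formula, data, eval_env=_EVAL_ENV, return_type="dataframe",
        NA_action=patsy.NAAction(on_NA="raise"),
    )
    return y, X


def design_matrix(formula: str, data: pd.DataFrame) -> pd.DataFrame:
    """Design matrix for the right-hand side of a formula."""
    rhs = formula.split("~", 1)[1] if "~" in formula else formula
    return patsy.dmatrix(
        rhs, data, eval_env=_EVAL_ENV,
        return_type="dataframe", NA_action=patsy.NAAction(on_NA="raise"),
    )


def build_design(design_info, data: pd.DataFrame) -> np.ndarray:
    """Evaluate a fitted model's design on new (e.g. simulated) data."""
    (X,) = patsy.build_design_matrices(
        [design_info], data, NA_action=patsy.NAAction(on_NA="raise")
    )
    return np.asarray(X)
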