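"""Configuration objects for a parametric g-formula analysis.

The configuration mirrors the argument vocabulary that practitioners of the
parametric g-formula use: an id column, an integer follow-up time index, a
vector of time-varying covariates with per-covariate distribution families
(``covtypes``) and model formulas (``covmodels``), baseline covariates, an
outcome model, optional competing-event model, and a list of interventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = [
    "COVTYPES",
    "OUTCOME_TYPES",
    "ConfigurationError",
    "OutcomeSpec",
    "CovariateSpec",
    "GFormulaConfig",
    "load_config",
]

COVTYPES = (
    "binary",
    "normal",
    "categorical",
    "bounded_normal",
    "zero_inflated_normal",
    "truncated_normal",
    "absorbing",
    "categorical_time",
)

OUTCOME_TYPES = ("survival", "continuous_eof", "binary_eof")


class ConfigurationError(ValueError):
    """Raised when the analysis configuration is internally inconsistent."""


@dataclass
class OutcomeSpec:
    """What the outcome is and how competing events are handled.

    Parameters
    ----------
    outcome_type
        ``"survival"`` for a time-varying failure indicator ``Y_{k+1}``,
        ``"continuous_eof"`` / ``"binary_eof"`` for a fixed outcome measured
        in the final interval ``K+1``.
    outcome_name
        Column holding the outcome.
    compevent_name
        Optional column with the competing-event indicator ``D_{k+1}``.
        May only be set for survival outcomes when competing events are
        modelled (not treated as censoring).
    treat_compevent_as_censoring
        If true, competing events are handled like censoring (targets a
        direct effect); the competing-event hazard is then not modelled.
    time_points
        Follow-up horizon ``k*`` (risks are reported through interval
        ``k* - 1``).  Defaults to ``K + 1`` when omitted.
    """

    outcome_type: str
    outcome_name: str
    compevent_name: Optional[str] = None
    treat_compevent_as_censoring: bool = False
    time_points: Optional[int] = None

    def __post_init__(self) -> None:
        if self.outcome_type not in OUTCOME_TYPES:
            raise ConfigurationError(
                f"unknown outcome_type {self.outcome_type!r}; "
                f"allowed: {', '.join(OUTCOME_TYPES)}"
            )
        if self.compevent_name is not None:
            if self.outcome_type != "survival":
                raise ConfigurationError(
                    "compevent_name may only be set for survival outcomes"
                )
            if self.treat_compevent_as_censoring:
                raise ConfigurationError(
                    "compevent_name should only be specified when competing "
                    "events are not treated as censoring events"
                )

    @property
    def compevent_modeled(self) -> bool:
        return self.compevent_name is not None and not self.treat_compevent_as_censoring


@dataclass
class CovariateSpec:
    """One time-varying covariate: its distribution family and model formula.

    ``covtype`` selects both how parameters are estimated in step 1 of the
    algorithm and how values are simulated in step 2.  The order of the
    CovariateSpecs in the configuration defines the factorization order of
    the joint covariate distribution: the formula for covariate *j* may
    reference current-time values only of covariates earlier in the order,
    plus history features (``lag{i}_X``, ``cumavg_X``, ``lag_cumavg{i}_X``)
    of any covariate, baseline covariates, and the time index.
    """

    name: str
    covtype: str
    formula: Optional[str] = None
    type_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.covtype not in COVTYPES:
            raise ConfigurationError(
                f"unknown covtype {self.covtype!r} for covariate "
                f"{self.name!r}; allowed: {', '.join(COVTYPES)}"
            )
        if self.covtype == "categorical_time":
            if "cuts" not in self.type_params:
                raise ConfigurationError(
                    f"categorical_time covariate {self.name!r} requires "
                    "type_params['cuts'] (interval cut points on the time index)"
                )
        elif self.formula is None:
            raise ConfigurationError(
                f"covariate {self.name!r} ({self.covtype}) requires a model formula"
            )
        if self.covtype == "truncated_normal":
            missing = {"direction", "point"} - set(self.type_params)
            if missing:
                raise ConfigurationError(
                    f"truncated_normal covariate {self.name!r} requires "
                    f"type_params {sorted(missing)}"
                )
            if self.type_params["direction"] not in ("left", "right"):
                raise ConfigurationError(
                    "truncated_normal direction must be 'left' or 'right'"
                )


@dataclass
class GFormulaConfig:
    """Full analysis configuration."""

    id: str
    time_name: str
    outcome: OutcomeSpec
    covariates: list[CovariateSpec]
    basecovs: list[str] = field(default_factory=list)
    ymodel: str = ""
    compevent_model: Optional[str] = None
    interventions: list[dict[str, Any]] = field(default_factory=list)
    ref_int: int = 0
    nsimul: Optional[int] = None
    nsamples: int = 0
    seed: int = 0
    ncores: int = 1

    def __post_init__(self) -> None:
        if not self.ymodel:
            raise ConfigurationError("an outcome model formula (ymodel) is required")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names in covnames")
        if self.compevent_model is not None and not self.outcome.compevent_modeled:
            raise ConfigurationError(
                "compevent_model should only be specified for survival outcomes "
                "when the competing event is not treated as a censoring event"
            )
        if self.outcome.compevent_modeled and self.compevent_model is None:
            raise ConfigurationError(
                "compevent_name is set but no compevent_model was given"
            )

    @property
    def covnames(self) -> list[str]:
        return [c.name for c in self.covariates]


def _build_config(raw: dict[str, Any]) -> GFormulaConfig:
    required = ["id", "time_name", "outcome_name", "outcome_type", "covnames",
                "covtypes", "ymodel"]
    missing = [key for key in required if key not in raw]
    if missing:
        raise ConfigurationError(f"missing configuration keys: {missing}")

    covnames = list(raw["covnames"])
    covtypes = [str(t).replace(" ", "_").replace("-", "_") for t in raw["covtypes"]]
    covmodels = list(raw.get("covmodels", [None] * len(covnames)))
    covparams = raw.get("covparams", [{}] * len(covnames))
    if not (len(covnames) == len(covtypes) == len(covmodels) == len(covparams)):
        raise ConfigurationError(
            "covnames, covtypes, covmodels, and covparams must be the same length"
        )
    covariates = [
        CovariateSpec(name=n, covtype=t, formula=m, type_params=dict(p or {}))
        for n, t, m, p in zip(covnames, covtypes, covmodels, covparams)
    ]
    outcome = OutcomeSpec(
        outcome_type=raw["outcome_type"],
        outcome_name=raw["outcome_name"],
        compevent_name=raw.get("compevent_name"),
        treat_compevent_as_censoring=bool(raw.get("treat_compevent_as_censoring", False)),
        time_points=raw.get("time_points"),
    )
    return GFormulaConfig(
        id=raw["id"],
        time_name=raw["time_name"],
        outcome=outcome,
        covariates=covariates,
        basecovs=list(raw.get("basecovs", [])),
        ymodel=raw["ymodel"],
        compevent_model=raw.get("compevent_model"),
        interventions=list(raw.get("interventions", [])),
        ref_int=int(raw.get("ref_int", 0)),
        nsimul=raw.get("nsimul"),
        nsamples=int(raw.get("nsamples", 0)),
        seed=int(raw.get("seed", 0)),
        ncores=int(raw.get("ncores", 1)),
    )


def load_config(source: str | Path | dict[str, Any]) -> GFormulaConfig:
    """Load a configuration from a YAML/JSON file path or a plain dict."""
    if isinstance(source, dict):
        return _build_config(source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"configuration file {path} did not parse to a mapping")
    return _build_config(raw)
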