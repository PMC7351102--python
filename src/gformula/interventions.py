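"""Treatment strategies: static, threshold, natural course, and custom rules.

A strategy (intervention) is a list of components, one per treated
variable, each with a rule and the set of follow-up times at which it
applies.  At every time step the *natural* value of each treatment — the
value its fitted model would have produced had the intervention been
discontinued directly before — is drawn first, so that threshold and other
natural-value-dependent rules are well defined and runs under different
strategies consume identical random-number streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np

from .config import ConfigurationError

__all__ = [
    "InterventionRule",
    "InterventionComponent",
    "InterventionSpec",
    "evaluate_rule",
    "apply_interventions",
    "build_intervention_set",
    "static",
    "threshold",
    "natural",
]


@dataclass
class InterventionRule:
    """One treatment rule.

    kind
        ``static``: assign ``values[k]`` (a vector of length ``k*``, or a
        scalar recycled to all times).
        ``threshold``: keep the natural value if it lies in
        ``[minimum, maximum]``, otherwise assign the violated bound.
        ``natural``: always assign the natural value.
        ``custom``: call ``func(k, history, natural, rng)``; must be a pure
        function returning an array of assigned values.
    """

    kind: str
    values: Optional[np.ndarray] = None
    minimum: float = -np.inf
    maximum: float = np.inf
    func: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.kind not in ("static", "threshold", "natural", "custom"):
            raise ConfigurationError(f"unknown intervention rule kind {self.kind!r}")
        if self.kind == "static":
            if self.values is None:
                raise ConfigurationError("static rule requires a value vector")
            self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.kind == "threshold" and self.minimum > self.maximum:
            raise ConfigurationError("threshold minimum must be <= maximum")
        if self.kind == "custom" and self.func is None:
            raise ConfigurationError("custom rule requires a callable")


def static(values) -> InterventionRule:
    return InterventionRule(kind="static", values=np.asarray(values, dtype=float))


def threshold(minimum: float, maximum: float) -> InterventionRule:
    return InterventionRule(kind="threshold", minimum=float(minimum),
                            maximum=float(maximum))


def natural() -> InterventionRule:
    return InterventionRule(kind="natural")


@dataclass
class InterventionComponent:
    variable: str
    rule: InterventionRule
    times: Optional[set[int]] = None  # None = all follow-up times

    def applies_at(self, k: int) -> bool:
        return self.times is None or k in self.times


@dataclass
class InterventionSpec:
    description: str
    components: list[InterventionComponent] = field(default_factory=list)

    @property
    def treated_variables(self) -> list[str]:
        return [c.variable for c in self.components]


def evaluate_rule(rule: InterventionRule, k: int, natural_value: np.ndarray,
                  history: Any = None,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Assigned treatment values at time ``k`` for a vector of histories."""
    natural_value = np.asarray(natural_value, dtype=float)
    if rule.kind == "static":
        if len(rule.values) == 1:
            val = rule.values[0]
        elif k < len(rule.values):
            val = rule.values[k]
        else:
            raise ConfigurationError(
                f"static value vector of length {len(rule.values)} has no "
                f"entry for time {k}"
            )
        return np.full_like(natural_value, val)
    if rule.kind == "threshold":
        return np.clip(natural_value, rule.minimum, rule.maximum)
    if rule.kind == "natural":
        return natural_value
    out = np.asarray(rule.func(k, history, natural_value, rng), dtype=float)
    if out.shape != natural_value.shape:
        raise ValueError("custom intervention rule returned wrong shape")
    return out


def apply_interventions(spec: InterventionSpec, k: int,
                        natural_values: dict[str, np.ndarray],
                        history: Any = None,
                        rng: Optional[np.random.Generator] = None,
                        ) -> dict[str, np.ndarray]:
    """Replace natural treatment values at time ``k`` per the strategy.

    Returns the assigned value for each treated variable; variables without
    an applicable component keep their natural values.  Natural values are
    never modified in place (they are retained for reporting and for
    natural-value-dependent rules).
    """
    assigned = {var: np.asarray(v, dtype=float)
                for var, v in natural_values.items()}
    for comp in spec.components:
        if comp.variable not in natural_values:
            raise ConfigurationError(
                f"intervention targets {comp.variable!r} which has no "
                "simulated natural value"
            )
        if comp.applies_at(k):
            assigned[comp.variable] = evaluate_rule(
                comp.rule, k, natural_values[comp.variable], history, rng
            )
    return assigned


def _rule_from_config(raw: dict[str, Any]) -> InterventionRule:
    kind = str(raw.get("rule", "natural")).replace("-", "_")
    if kind == "static":
        return static(raw["values"])
    if kind == "threshold":
        lo = raw.get("min", -np.inf)
        hi = raw.get("max", np.inf)
        lo = -np.inf if lo in ("-Inf", "-inf", None) else float(lo)
        hi = np.inf if hi in ("Inf", "inf", None) else float(hi)
        return threshold(lo, hi)
    if kind == "natural":
        return natural()
    if kind == "custom":
        func = raw.get("func")
        if not callable(func):
            raise ConfigurationError("custom intervention requires a callable "
                                     "under key 'func'")
        return InterventionRule(kind="custom", func=func)
    raise ConfigurationError(
        f"unknown intervention rule {kind!r}; allowed: static, threshold, "
        "natural, custom"
    )


def build_intervention_set(interventions: Sequence[dict[str, Any]],
                           covnames: Sequence[str], k_star: int,
                           ref_int: int = 0) -> tuple[list[InterventionSpec], int]:
    """Build the full strategy list: the natural course (always index 0,
    computed by default) followed by the user-specified strategies.

    ``ref_int`` indexes into the returned list (0 = natural course) and
    names the denominator of the ratio/difference contrasts.
    """
    specs = [InterventionSpec(description="Natural course")]
    for raw in interventions:
        comps = []
        for c in raw.get("components", []):
            var = c["variable"]
            if var not in covnames:
                raise ConfigurationError(
                    f"intervention variable {var!r} is not a declared "
                    "time-varying covariate"
                )
            rule = _rule_from_config(c)
            if rule.kind == "static" and len(rule.values) > 1 \
                    and len(rule.values) < k_star:
                raise ConfigurationError(
                    f"static value vector for {var!r} has length "
                    f"{len(rule.values)} < time_points {k_star}"
                )
            times = c.get("times")
            times = None if times is None else {int(t) for t in times}
            comps.append(InterventionComponent(variable=var, rule=rule,
                                               times=times))
        specs.append(InterventionSpec(
            description=raw.get("description", f"Intervention {len(specs)}"),
            components=comps,
        ))
    if not 0 <= ref_int < len(specs):
        raise ConfigurationError(
            f"ref_int {ref_int} out of range (0..{len(specs) - 1})"
        )
    return specs, ref_int
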