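"""Named simulation scenarios: the baseline game, the eight qualitative
variants that realize each stability Condition, and the seven sensitivity
pairs probing convergence speed.

Each scenario records its parameter overrides *and* the qualitative outcome
it is expected to produce (satisfied Conditions, ESS set, endpoints per
initial state, or the faster variant of a sensitivity pair) as plain data,
so drivers and tests read expectations from the registry instead of
hard-coding them.

Scenario chaining is resolved explicitly: later variants build on earlier
ones (e.g. ``fig6`` is ``fig5`` plus ``R32 = 2``), and the sensitivity pairs
``fig9``–``fig11`` use the ``fig5`` regime as their base because that is the
only base under which their quoted expression transitions are arithmetically
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .dynamics import (
    CONVERGENCE_EPSILON,
    DEFAULT_HORIZON,
    classify_endpoint,
    convergence_time,
    simulate,
)
from .parameters import ParameterSet, baseline_parameters, validate_parameters
from .payoffs import expression_values
from .stability import check_conditions, classify_equilibria

__all__ = [
    "Scenario",
    "SensitivityPair",
    "SCENARIOS",
    "load_scenario",
    "resolve_parameters",
    "ScenarioReport",
    "run_scenario",
    "LOW_INIT",
    "HIGH_INIT",
    "MID_INIT",
]

#: Canonical initial states: the qualitative analyses state only "below 0.5"
#: / "above 0.5", so symmetric representatives are used.
LOW_INIT: tuple[float, float, float, float] = (0.3, 0.3, 0.3, 0.3)
HIGH_INIT: tuple[float, float, float, float] = (0.7, 0.7, 0.7, 0.7)
#: Init used for speed comparisons (both variants of a pair, same start).
MID_INIT: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)


@dataclass(frozen=True)
class SensitivityPair:
    """One speed experiment: the same game with a single parameter at a
    slower and a faster setting, watching one component's settling time."""

    parameter: str
    slow_value: float
    fast_value: float
    component: str
    expression: str  # which of e1..e7 the parameter moves


@dataclass(frozen=True)
class Scenario:
    """A named experiment: overrides on the baseline plus expected outcome."""

    id: str
    overrides: dict[str, float] = field(default_factory=dict)
    description: str = ""
    expected_conditions: Optional[frozenset[int]] = None
    expected_ess: Optional[frozenset[str]] = None
    # endpoint corner expected from the low / high canonical inits
    expected_endpoint_low: Optional[str] = None
    expected_endpoint_high: Optional[str] = None
    sensitivity: Optional[SensitivityPair] = None
    # expression values quoted for this scenario, for cross-checking
    quoted_expressions: dict[str, float] = field(default_factory=dict)


def _s(**kw) -> Scenario:
    return Scenario(**kw)


_FIG5 = {"R22": 1.8, "R42": 1.5}

SCENARIOS: dict[str, Scenario] = {
    s.id: s
    for s in [
        _s(
            id="baseline",
            description="canonical parameter set; dual ESS {E1, E12}",
            expected_conditions=frozenset({1, 9}),
            expected_ess=frozenset({"E1", "E12"}),
            expected_endpoint_low="E1",
            expected_endpoint_high="E12",
            quoted_expressions={"e1": -0.6, "e2": -0.1, "e4": -0.59, "e6": -0.1},
        ),
        _s(
            id="fig1",
            description="alias of the baseline dual-ESS run",
            expected_conditions=frozenset({1, 9}),
            expected_ess=frozenset({"E1", "E12"}),
            expected_endpoint_low="E1",
            expected_endpoint_high="E12",
            quoted_expressions={"e1": -0.6, "e2": -0.1, "e4": -0.59, "e6": -0.1},
        ),
        _s(
            id="fig2",
            overrides={"R32": 2.0},
            description="leasing pays off against Internet-preference patients",
            expected_conditions=frozenset({2, 9}),
            expected_ess=frozenset({"E3", "E12"}),
            expected_endpoint_low="E3",
            expected_endpoint_high="E12",
            quoted_expressions={"e1": -0.6, "e2": 0.4, "e4": -0.59, "e6": -0.1},
        ),
        _s(
            id="fig3",
            overrides={"R13": 2.0},
            description="self-built online platform beats relying-on (full-time regime)",
            expected_conditions=frozenset({4, 9}),
            expected_ess=frozenset({"E5", "E12"}),
            expected_endpoint_low="E5",
            expected_endpoint_high="E12",
            quoted_expressions={"e1": -0.6, "e2": -0.1, "e4": 0.11},
        ),
        _s(
            id="fig4",
            overrides={"R32": 2.0, "R13": 2.0},
            description="both previous changes combined",
            expected_conditions=frozenset({7, 9}),
            expected_ess=frozenset({"E10", "E12"}),
            expected_endpoint_low="E10",
            expected_endpoint_high="E12",
            quoted_expressions={"e1": -0.6, "e2": 0.4, "e4": 0.11},
        ),
        _s(
            id="fig5",
            overrides=dict(_FIG5),
            description="part-time mode and online care both pay: unique ESS E4",
            expected_conditions=frozenset({3}),
            expected_ess=frozenset({"E4"}),
            expected_endpoint_low="E4",
            expected_endpoint_high="E4",
            quoted_expressions={"e1": 0.1, "e2": -0.1, "e5": -0.5, "e7": -0.1},
        ),
        _s(
            id="fig6",
            overrides={**_FIG5, "R32": 2.0},
            description="fig5 regime with profitable leasing: unique ESS E9",
            expected_conditions=frozenset({6}),
            expected_ess=frozenset({"E9"}),
            expected_endpoint_low="E9",
            expected_endpoint_high="E9",
            quoted_expressions={"e1": 0.1, "e2": 0.4, "e5": -0.5, "e7": -0.1},
        ),
        _s(
            id="fig7",
            overrides={**_FIG5, "R13": 2.0},
            description="fig5 regime with self-built favoured: unique ESS E11",
            expected_conditions=frozenset({8}),
            expected_ess=frozenset({"E11"}),
            expected_endpoint_low="E11",
            expected_endpoint_high="E11",
            quoted_expressions={"e1": 0.1, "e2": -0.1, "e5": 0.2, "e7": -0.1},
        ),
        _s(
            id="fig8",
            overrides={**_FIG5, "R13": 2.0, "R32": 2.0},
            description="fig7 regime with profitable leasing: unique ESS E15",
            expected_conditions=frozenset({10}),
            expected_ess=frozenset({"E15"}),
            expected_endpoint_low="E15",
            expected_endpoint_high="E15",
            quoted_expressions={"e1": 0.1, "e2": 0.4, "e5": 0.2, "e7": -0.1},
        ),
        _s(
            id="fig9",
            overrides=dict(_FIG5),
            description="cheaper part-time platform visits speed up patient evolution",
            sensitivity=SensitivityPair("C43", 0.9, 0.5, "p", "e7"),
            quoted_expressions={"e7": -0.1},
        ),
        _s(
            id="fig10",
            overrides=dict(_FIG5),
            description="higher part-time platform benefit speeds up patient evolution",
            sensitivity=SensitivityPair("R42", 1.5, 1.9, "p", "e7"),
            quoted_expressions={"e7": -0.1},
        ),
        _s(
            id="fig11",
            overrides=dict(_FIG5),
            description="higher kept share alpha speeds up institution evolution",
            sensitivity=SensitivityPair("alpha", 0.5, 0.9, "x", "e5"),
        ),
        _s(
            id="fig12",
            overrides={"R22": 1.8},
            description="higher part-time benefit speeds up platform evolution",
            sensitivity=SensitivityPair("R21", 1.3, 1.7, "y", "e1"),
        ),
        _s(
            id="fig13",
            overrides={"R22": 1.8, "R21": 1.3},
            description="cheaper part-time doctors speed up platform evolution",
            sensitivity=SensitivityPair("C21", 0.5, 0.1, "y", "e1"),
        ),
        _s(
            id="fig14",
            overrides={"R32": 2.0},
            description="higher leasing benefit speeds up provider evolution",
            sensitivity=SensitivityPair("R32", 2.0, 2.4, "z", "e2"),
            quoted_expressions={"e2": 0.4},
        ),
        _s(
            id="fig15",
            overrides={"R32": 2.0, "C31": 0.9},
            description="cheaper leasing operation speeds up provider evolution",
            sensitivity=SensitivityPair("C31", 0.9, 0.6, "z", "e2"),
            quoted_expressions={"e2": 0.2},
        ),
    ]
}


def load_scenario(scenario_id: str) -> Scenario:
    """Look up a scenario by id (``baseline`` or ``fig1``..``fig15``)."""
    try:
        return SCENARIOS[scenario_id]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; known: {sorted(SCENARIOS)}"
        ) from None


def resolve_parameters(scenario: Scenario | str) -> ParameterSet:
    """Fully resolved parameter set for a scenario (baseline + overrides)."""
    if isinstance(scenario, str):
        scenario = load_scenario(scenario)
    return baseline_parameters(**scenario.overrides)


@dataclass(frozen=True)
class ScenarioReport:
    """End-to-end result of one scenario run."""

    scenario: str
    parameters: dict[str, float]
    expressions: dict[str, float]
    expression_signs: dict[str, str]
    satisfied_conditions: tuple[int, ...]
    ess: tuple[str, ...]
    endpoints: dict[str, Optional[str]]  # init label -> corner id (or None)
    endpoint_distances: dict[str, float]
    convergence_times: dict[str, Optional[float]]  # "param=value" -> time

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "parameters": self.parameters,
            "expressions": self.expressions,
            "expression_signs": self.expression_signs,
            "satisfied_conditions": list(self.satisfied_conditions),
            "ess": list(self.ess),
            "endpoints": dict(self.endpoints),
            "endpoint_distances": dict(self.endpoint_distances),
            "convergence_times": dict(self.convergence_times),
        }


def run_scenario(
    scenario: Scenario | str,
    inits: tuple[tuple[float, float, float, float], ...] = (LOW_INIT, HIGH_INIT),
    horizon: float = DEFAULT_HORIZON,
    epsilon: float = CONVERGENCE_EPSILON,
    **solver_kwargs: float,
) -> ScenarioReport:
    """Run a scenario end-to-end: expressions, conditions, ESS classification
    and trajectory endpoints; for sensitivity scenarios additionally the
    settling times of the watched component under both parameter values,
    started from the same mid-cube state."""
    if isinstance(scenario, str):
        scenario = load_scenario(scenario)
    params = resolve_parameters(scenario)
    validate_parameters(params, mode="warn")
    exprs = expression_values(params)
    satisfied, _ = check_conditions(params)
    ess = tuple(
        r.corner for r in classify_equilibria(params) if r.verdict == "ESS"
    )
    endpoints: dict[str, Optional[str]] = {}
    distances: dict[str, float] = {}
    for init in inits:
        traj = simulate(params, init, horizon=horizon, **solver_kwargs)
        verdict = classify_endpoint(traj, epsilon)
        label = ",".join(f"{v:g}" for v in init)
        endpoints[label] = verdict.corner
        distances[label] = verdict.distance
    times: dict[str, Optional[float]] = {}
    if scenario.sensitivity is not None:
        pair = scenario.sensitivity
        for value in (pair.slow_value, pair.fast_value):
            variant = params.with_overrides(**{pair.parameter: value})
            times[f"{pair.parameter}={value:g}"] = convergence_time(
                variant, MID_INIT, pair.component, epsilon=epsilon, horizon=horizon
            )
    return ScenarioReport(
        scenario=scenario.id,
        parameters=params.as_dict(),
        expressions=exprs.as_dict(),
        expression_signs=exprs.signs(),
        satisfied_conditions=tuple(sorted(satisfied)),
        ess=ess,
        endpoints=endpoints,
        endpoint_distances=distances,
        convergence_times=times,
    )
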