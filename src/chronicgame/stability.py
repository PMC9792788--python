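"""Corner equilibria: eigenvalues, evolutionary-stability classification,
stability conditions, and their mutual-compatibility logic.

In a multi-population game every evolutionarily stable strategy (ESS) of the
replicator system is a strict, pure-strategy Nash equilibrium, so only the 16
corners of the unit hypercube are candidates. At a corner the Jacobian of the
replicator system is diagonal; by Lyapunov's first method the corner is an
ESS iff all four eigenvalues are strictly negative. Ten corners can be
stable, each under a named Condition (1-10) expressed as required signs of
the seven expressions; the other six are unstable whenever the model's
ordering assumptions hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional

import numpy as np

from .parameters import ParameterSet, PopulationState
from .payoffs import classify_sign, expression_values, payoff_deltas

__all__ = [
    "CORNERS",
    "corner_id_for",
    "CONDITION_CORNER",
    "CONDITION_SIGNS",
    "corner_eigenvalues",
    "numeric_jacobian",
    "EquilibriumReport",
    "classify_equilibria",
    "check_conditions",
    "CompatibilityRule",
    "compatibility_matrix",
    "permitted",
    "NEVER_STABLE",
]

#: Corner ids and coordinates (x, y, z, p).
CORNERS: dict[str, tuple[int, int, int, int]] = {
    "E1": (0, 0, 0, 0),
    "E2": (0, 0, 0, 1),
    "E3": (0, 0, 1, 0),
    "E4": (0, 1, 0, 0),
    "E5": (1, 0, 0, 0),
    "E6": (0, 0, 1, 1),
    "E7": (0, 1, 0, 1),
    "E8": (1, 0, 0, 1),
    "E9": (0, 1, 1, 0),
    "E10": (1, 0, 1, 0),
    "E11": (1, 1, 0, 0),
    "E12": (0, 1, 1, 1),
    "E13": (1, 0, 1, 1),
    "E14": (1, 1, 0, 1),
    "E15": (1, 1, 1, 0),
    "E16": (1, 1, 1, 1),
}

_COORD_TO_ID = {coords: eid for eid, coords in CORNERS.items()}

#: Stable-capable corners and their governing Condition id.
CONDITION_CORNER: dict[int, str] = {
    1: "E1", 2: "E3", 3: "E4", 4: "E5", 5: "E7",
    6: "E9", 7: "E10", 8: "E11", 9: "E12", 10: "E15",
}
CORNER_CONDITION: dict[str, int] = {v: k for k, v in CONDITION_CORNER.items()}

#: Corners whose eigenvalue list contains C22 - C21 > 0 or C11 - C12 > 0
#: under the ordering assumptions: never stable.
NEVER_STABLE: tuple[str, ...] = ("E2", "E6", "E8", "E13", "E14", "E16")

#: Reference row order of the eigenvalues per corner: which group's
#: eigenvalue appears in each of the four slots.
_EIG_ORDER: dict[str, tuple[str, str, str, str]] = {
    eid: ("y", "z", "x", "p") if eid in ("E1", "E3", "E4", "E9")
    else ("x", "y", "z", "p")
    for eid in CORNERS
}

_GROUP_INDEX = {"x": 0, "y": 1, "z": 2, "p": 3}


def corner_id_for(coords: Iterable[int]) -> str:
    """Corner id (E1..E16) for 0/1 coordinates (x, y, z, p)."""
    key = tuple(int(c) for c in coords)
    if key not in _COORD_TO_ID:
        raise KeyError(f"not a corner: {key}")
    return _COORD_TO_ID[key]


def corner_eigenvalues(params: ParameterSet, corner: str) -> tuple[float, ...]:
    """Closed-form Jacobian eigenvalues at a corner, in reference row order.

    At a corner the Jacobian of the replicator system is diagonal; the
    eigenvalue for group ``v`` equals ``+delta_v`` when the corner has
    ``v = 0`` and ``-delta_v`` when ``v = 1``, with the payoff difference
    evaluated at the corner. (A strategy absent from the population invades
    when it has positive payoff advantage; a fixated strategy is stable in
    its own coordinate when its advantage is positive.)
    """
    if corner not in CORNERS:
        raise KeyError(f"unknown corner id: {corner}")
    coords = CORNERS[corner]
    state = PopulationState(*map(float, coords))
    deltas = payoff_deltas(params, state).as_array()
    signed = np.where(np.array(coords) == 0, deltas, -deltas)
    return tuple(float(signed[_GROUP_INDEX[g]]) for g in _EIG_ORDER[corner])


def numeric_jacobian(
    params: ParameterSet,
    state: PopulationState | tuple[float, float, float, float],
    step: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference Jacobian of the replicator RHS.

    At corners it is diagonal and its diagonal reproduces
    :func:`corner_eigenvalues` (in group order x, y, z, p); at interior
    states it is generally full.

    The differencing evaluates the polynomial right-hand side just outside
    the unit hypercube (no clamping), so corner derivatives are genuine
    central differences.
    """
    if not isinstance(state, PopulationState):
        state = PopulationState(*state)
    s0 = state.as_array()

    def rhs(arr: np.ndarray) -> np.ndarray:
        deltas = payoff_deltas(params, tuple(arr)).as_array()
        return arr * (1.0 - arr) * deltas

    jac = np.empty((4, 4))
    for j in range(4):
        hi = s0.copy()
        lo = s0.copy()
        hi[j] += step
        lo[j] -= step
        jac[:, j] = (rhs(hi) - rhs(lo)) / (2 * step)
    return jac


@dataclass(frozen=True)
class EquilibriumReport:
    """Stability summary of one corner rest point."""

    corner: str
    coordinates: tuple[int, int, int, int]
    eigenvalues: tuple[float, ...]
    eigenvalue_order: tuple[str, ...]
    signs: tuple[str, ...]
    verdict: str  # "ESS" | "unstable" | "inconclusive"
    condition: Optional[int]

    def as_dict(self) -> dict:
        return {
            "corner": self.corner,
            "coordinates": list(self.coordinates),
            "eigenvalues": list(self.eigenvalues),
            "eigenvalue_order": list(self.eigenvalue_order),
            "signs": list(self.signs),
            "verdict": self.verdict,
            "condition": self.condition,
        }


def classify_equilibria(
    params: ParameterSet,
    boundary_tol: float = 1e-12,
) -> list[EquilibriumReport]:
    """Classify all 16 corners by the signs of their Jacobian eigenvalues.

    ESS iff all four eigenvalues strictly negative; any eigenvalue within
    ``boundary_tol`` of zero (and none positive) makes the corner
    inconclusive — the linearization is silent there, and the corner is never
    silently promoted to ESS.
    """
    reports = []
    for eid in sorted(CORNERS, key=lambda s: int(s[1:])):
        eigs = corner_eigenvalues(params, eid)
        signs = tuple(classify_sign(v, boundary_tol) for v in eigs)
        if all(s == "-" for s in signs):
            verdict = "ESS"
        elif any(s == "+" for s in signs):
            verdict = "unstable"
        else:
            verdict = "inconclusive"
        reports.append(
            EquilibriumReport(
                corner=eid,
                coordinates=CORNERS[eid],
                eigenvalues=eigs,
                eigenvalue_order=_EIG_ORDER[eid],
                signs=signs,
                verdict=verdict,
                condition=CORNER_CONDITION.get(eid),
            )
        )
    return reports


def ess_set(params: ParameterSet, boundary_tol: float = 1e-12) -> set[str]:
    """Ids of the corners classified as ESS."""
    return {r.corner for r in classify_equilibria(params, boundary_tol) if r.verdict == "ESS"}


#: Required sign of each expression per Condition; expressions not listed are
#: irrelevant to that Condition.
CONDITION_SIGNS: dict[int, dict[str, str]] = {
    1: {"e1": "-", "e2": "-", "e4": "-", "e6": "-"},
    2: {"e1": "-", "e2": "+", "e4": "-", "e6": "-"},
    3: {"e1": "+", "e2": "-", "e5": "-", "e7": "-"},
    4: {"e1": "-", "e2": "-", "e4": "+", "e6": "-"},
    5: {"e3": "-", "e7": "+"},
    6: {"e1": "+", "e2": "+", "e5": "-", "e7": "-"},
    7: {"e1": "-", "e2": "+", "e4": "+", "e6": "-"},
    8: {"e1": "+", "e2": "-", "e5": "+", "e7": "-"},
    9: {"e3": "+", "e7": "+"},
    10: {"e1": "+", "e2": "+", "e5": "+", "e7": "-"},
}


@dataclass(frozen=True)
class CompatibilityRule:
    """Sign requirements of one Condition over the seven expressions."""

    condition: int
    corner: str
    signs: dict[str, str]


def check_conditions(
    params: ParameterSet,
    boundary_tol: float = 1e-12,
) -> tuple[set[int], set[int]]:
    """Conditions satisfied by (and boundary-ambiguous for) a parameter set.

    A Condition holds iff every required expression has the required strict
    sign. A Condition whose required expressions include one classified as
    "boundary" (within ``boundary_tol`` of zero) while all others match is
    reported separately rather than decided.
    """
    signs = expression_values(params).signs(boundary_tol)
    satisfied, boundary = set(), set()
    for cond, required in CONDITION_SIGNS.items():
        observed = {k: signs[k] for k in required}
        if observed == required:
            satisfied.add(cond)
        elif all(observed[k] in (required[k], "boundary") for k in required):
            boundary.add(cond)
    return satisfied, boundary


def compatibility_matrix() -> list[CompatibilityRule]:
    """The full Condition-to-expression sign table."""
    return [
        CompatibilityRule(cond, CONDITION_CORNER[cond], dict(signs))
        for cond, signs in CONDITION_SIGNS.items()
    ]


def permitted(conditions: Iterable[int]) -> bool:
    """Whether a set of Conditions can hold simultaneously.

    True iff the union of their sign requirements is consistent (no
    expression required to be both positive and negative). Conditions 3, 6,
    8 and 10 are consequently compatible with no other Condition: each pins
    the sign of an expression that every other Condition constrains
    oppositely.
    """
    merged: dict[str, str] = {}
    for cond in conditions:
        if cond not in CONDITION_SIGNS:
            raise KeyError(f"unknown condition id: {cond}")
        for expr, sign in CONDITION_SIGNS[cond].items():
            if merged.setdefault(expr, sign) != sign:
                return False
    return True


def permitted_condition_sets(max_size: int = 2) -> set[frozenset[int]]:
    """All sign-consistent Condition combinations up to ``max_size``."""
    out: set[frozenset[int]] = set()
    conds = sorted(CONDITION_SIGNS)
    for size in range(1, max_size + 1):
        for combo in product(conds, repeat=size):
            s = frozenset(combo)
            if len(s) == size and permitted(s):
                out.add(s)
    return out
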