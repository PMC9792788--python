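"""Replicator dynamics: right-hand side, trajectory integration, endpoint
classification, and convergence-time measurement.

Each strategy share ``v`` follows dv/dt = v (1 - v) (U1 - U2): a strategy's
share grows in proportion to its payoff advantage over the group mean. The
unit hypercube is forward-invariant and its 16 corners are rest points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import ParameterSet, PopulationState
from .payoffs import payoff_deltas

__all__ = [
    "replicator_rhs",
    "Trajectory",
    "simulate",
    "IntegrationError",
    "EndpointVerdict",
    "classify_endpoint",
    "convergence_time",
    "DEFAULT_HORIZON",
    "CONVERGENCE_EPSILON",
]

#: Default integration horizon (time units of the replicator clock; the
#: model's payoffs are unitless, so the time scale is conventional).
DEFAULT_HORIZON: float = 200.0
#: Default max-norm radius for calling an endpoint "converged" to a corner.
CONVERGENCE_EPSILON: float = 1e-3

STATE_COMPONENTS: tuple[str, ...] = ("x", "y", "z", "p")


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the solver's diagnostic message."""


def replicator_rhs(state: PopulationState | np.ndarray, params: ParameterSet) -> np.ndarray:
    """Growth rates (dx/dt, dy/dt, dz/dt, dp/dt) at ``state``.

    Identically zero at every corner of the unit hypercube because of the
    logistic factor v(1 - v).
    """
    if not isinstance(state, PopulationState):
        arr = np.clip(np.asarray(state, dtype=float), 0.0, 1.0)
        state = PopulationState(*arr)
    v = state.as_array()
    deltas = payoff_deltas(params, state).as_array()
    return v * (1.0 - v) * deltas


@dataclass(frozen=True)
class Trajectory:
    """A sampled solution of the replicator system.

    ``times`` is strictly increasing; ``states`` holds one row per sample,
    clamped to [0, 1] (the dynamics preserve the hypercube analytically;
    clamping only absorbs floating-point drift).
    """

    times: np.ndarray
    states: np.ndarray
    params: ParameterSet
    rel_tol: float
    abs_tol: float
    horizon: float

    def __post_init__(self) -> None:
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 4):
            raise ValueError("trajectory shape mismatch")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(*self.states[-1])

    @property
    def final_time(self) -> float:
        return float(self.times[-1])

    def component(self, name: str) -> np.ndarray:
        return self.states[:, STATE_COMPONENTS.index(name)]


def simulate(
    params: ParameterSet,
    init: PopulationState | tuple[float, float, float, float],
    horizon: float = DEFAULT_HORIZON,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    n_samples: int = 2001,
) -> Trajectory:
    """Integrate the replicator system from ``init`` over ``horizon``.

    The interior components are integrated in logit coordinates
    ``u = log(v / (1 - v))``, where the replicator equation takes the
    boundary-free form du/dt = U1 - U2. This preserves the exact dynamics'
    key structural fact that the hypercube faces are invariant — an interior
    trajectory never reaches a face in finite time — so a component can
    neither be absorbed at 0/1 by floating-point rounding nor freeze at an
    unstable corner during a close saddle passage. Components that start
    exactly on a face are held there (faces are invariant sets).

    Uses adaptive explicit Runge-Kutta (RK45); the right-hand side is smooth
    and non-stiff. Deterministic for identical inputs.
    """
    if not isinstance(init, PopulationState):
        init = PopulationState(*init)
    y0 = init.as_array()
    free = (y0 > 0.0) & (y0 < 1.0)
    t_eval = np.linspace(0.0, horizon, n_samples)

    if not free.any():  # a corner: exact rest point
        states = np.broadcast_to(y0, (t_eval.size, 4)).copy()
        return Trajectory(times=t_eval, states=states, params=params,
                          rel_tol=rel_tol, abs_tol=abs_tol, horizon=horizon)

    from scipy.special import expit, logit

    def full_state(u: np.ndarray) -> np.ndarray:
        v = y0.copy()
        v[free] = expit(u)
        return v

    def rhs(t: float, u: np.ndarray) -> np.ndarray:
        deltas = payoff_deltas(params, tuple(full_state(u))).as_array()
        return deltas[free]

    sol = solve_ivp(
        rhs, (0.0, horizon), logit(y0[free]), method="RK45",
        rtol=rel_tol, atol=abs_tol, t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    states = np.empty((sol.t.size, 4))
    for i, u in enumerate(sol.y.T):
        states[i] = full_state(u)
    return Trajectory(
        times=sol.t,
        states=np.clip(states, 0.0, 1.0),
        params=params,
        rel_tol=rel_tol,
        abs_tol=abs_tol,
        horizon=horizon,
    )


def corner_coordinates() -> np.ndarray:
    """All 16 corners of the unit hypercube in E1..E16 order."""
    from .stability import CORNERS  # local import to avoid a cycle

    return np.array([CORNERS[eid] for eid in sorted(CORNERS, key=lambda s: int(s[1:]))])


@dataclass(frozen=True)
class EndpointVerdict:
    """Where a trajectory ended up, relative to the 16 corner rest points."""

    converged: bool
    corner: Optional[str]
    distance: float
    final_time: float
    component_times: dict[str, Optional[float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "converged": self.converged,
            "corner": self.corner,
            "distance": self.distance,
            "final_time": self.final_time,
            "component_times": dict(self.component_times),
        }


def classify_endpoint(traj: Trajectory, epsilon: float = CONVERGENCE_EPSILON) -> EndpointVerdict:
    """Identify the corner nearest (max-norm) to the trajectory's endpoint.

    Converged requires, besides the endpoint lying within ``epsilon`` of the
    nearest corner with RHS max-norm below ``epsilon``, that the flow at the
    endpoint actually points *into* the corner: every component sitting at a
    face must have a payoff drift holding it there (positive advantage at
    v=1, negative at v=0). Distance and RHS alone cannot tell a sink from a
    close saddle passage — a trajectory lingering exponentially near an
    unstable corner has a vanishing RHS while one component is already
    (invisibly, below the resolution of double precision) escaping; the
    drift direction at the endpoint is what distinguishes the two.
    Components that start exactly on a face are exempt: faces are invariant
    sets of the replicator flow, so staying there is genuine convergence
    within the face.
    """
    from .payoffs import SIGN_TOLERANCE
    from .stability import corner_id_for

    final = traj.final_state.as_array()
    nearest = np.round(final).astype(int)
    distance = float(np.max(np.abs(final - nearest)))
    rhs_norm = float(np.max(np.abs(replicator_rhs(traj.final_state, traj.params))))
    drift = payoff_deltas(traj.params, tuple(final)).as_array()
    started_on_face = traj.states[0] == nearest
    inward = np.where(nearest == 1, drift > SIGN_TOLERANCE, drift < -SIGN_TOLERANCE)
    settled = bool(np.all(inward | started_on_face))
    converged = distance < epsilon and rhs_norm < epsilon and settled
    corner = corner_id_for(tuple(nearest)) if converged else None
    component_times = {}
    if converged:
        for name in STATE_COMPONENTS:
            component_times[name] = _settling_time(
                traj.times, traj.component(name),
                float(nearest[STATE_COMPONENTS.index(name)]), epsilon,
            )
    return EndpointVerdict(
        converged=converged, corner=corner, distance=distance,
        final_time=traj.final_time, component_times=component_times,
    )


def _settling_time(times: np.ndarray, values: np.ndarray, limit: float,
                   epsilon: float) -> Optional[float]:
    """First sampled time after which |value - limit| stays below epsilon."""
    inside = np.abs(values - limit) < epsilon
    if not inside[-1]:
        return None
    # index of the last sample outside the band
    outside = np.nonzero(~inside)[0]
    idx = outside[-1] + 1 if outside.size else 0
    return float(times[idx])


def convergence_time(
    params: ParameterSet,
    init: PopulationState | tuple[float, float, float, float],
    component: str,
    epsilon: float = CONVERGENCE_EPSILON,
    horizon: float = DEFAULT_HORIZON,
    n_samples: int = 4001,
    **solver_kwargs: float,
) -> Optional[float]:
    """Settling time of one component onto its corner limit.

    Returns the first sampled time after which the component stays within
    ``epsilon`` of its limiting value (0 or 1), or ``None`` when the
    component has not converged by ``horizon``. The sampling grid bounds the
    time resolution at ``horizon / (n_samples - 1)``.
    """
    if component not in STATE_COMPONENTS:
        raise ValueError(f"component must be one of {STATE_COMPONENTS}")
    traj = simulate(params, init, horizon=horizon, n_samples=n_samples, **solver_kwargs)
    values = traj.component(component)
    limit = float(np.round(values[-1]))
    if abs(values[-1] - limit) >= epsilon:
        return None
    return _settling_time(traj.times, values, limit, epsilon)
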