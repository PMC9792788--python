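"""Payoff tensor, expected group payoffs, payoff differences, and the seven
sign-determining expressions.

The 16 pure strategy profiles are indexed by ``(ix, iy, iz, ip)`` where index
0 is each group's *first* strategy (self-built, part-time, leasing, physical
preference) and index 1 the second. Players are ordered (institution,
platform, provider, patient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet, PopulationState

__all__ = [
    "PLAYERS",
    "build_payoff_tensor",
    "GroupPayoffs",
    "group_payoffs",
    "PayoffDeltas",
    "payoff_deltas",
    "ExpressionSet",
    "expression_values",
    "classify_sign",
    "EXPRESSION_MEANINGS",
]

PLAYERS: tuple[str, ...] = ("institution", "platform", "provider", "patient")

#: Numerical half-width of the "boundary" band around zero when classifying
#: the sign of an expression or eigenvalue.
SIGN_TOLERANCE: float = 1e-12


def build_payoff_tensor(params: ParameterSet) -> np.ndarray:
    """Per-player payoffs for all 16 pure strategy profiles.

    Returns an array of shape ``(2, 2, 2, 2, 4)``: axes are the strategy
    indices of institution, platform, provider, patient, and the last axis is
    the player receiving the payoff.
    """
    q = params
    t = np.empty((2, 2, 2, 2, 4), dtype=float)
    for ix in (0, 1):  # 0 self-built, 1 relying-on
        for iy in (0, 1):  # 0 part-time, 1 full-time
            for iz in (0, 1):  # 0 leasing, 1 no-leasing
                for ip in (0, 1):  # 0 physical pref, 1 Internet pref
                    lease_bonus = q.T2 if iz == 0 else 0.0
                    if ip == 0:
                        inst = q.R11 - (q.C11 if ix == 0 else q.C12) + lease_bonus
                    else:
                        if ix == 0:
                            online = q.R12 - (q.F1 if iy == 1 else 0.0)
                            inst = online - q.C11 + q.T3 + lease_bonus
                        else:
                            online = q.alpha * (q.R13 - (q.F1 if iy == 1 else 0.0))
                            inst = online - q.C12 + q.T3 + lease_bonus
                    r_plat, c_plat = (q.R21, q.C21) if iy == 0 else (q.R22, q.C22)
                    if ip == 0:
                        plat = -c_plat
                    else:
                        plat = r_plat - c_plat + (q.T1 if iz == 0 else 0.0)
                    if iz == 0:
                        prov = (q.R31 if ip == 0 else q.R32) - q.C31
                    else:
                        prov = (q.R33 if ip == 0 else q.R34) - q.C32
                    device = q.R44 - q.C41 if iz == 0 else q.R45 - q.C42
                    if ip == 0:
                        pat = q.R41 - q.C45 + device
                    else:
                        if iy == 0:
                            visit = q.beta * (q.R42 - q.C43) + (1 - q.beta) * (q.R41 - q.C46)
                        else:
                            visit = q.theta * (q.R43 - q.C44) + (1 - q.theta) * (q.R41 - q.C46)
                        pat = visit + device
                    t[ix, iy, iz, ip] = (inst, plat, prov, pat)
    return t


@dataclass(frozen=True)
class GroupPayoffs:
    """Expected payoffs per group: first strategy (U1), second (U2), mean.

    The mean satisfies ``mean = v * U1 + (1 - v) * U2`` with ``v`` the
    group's first-strategy share.
    """

    u1: tuple[float, float, float, float]
    u2: tuple[float, float, float, float]
    mean: tuple[float, float, float, float]

    def delta(self) -> tuple[float, float, float, float]:
        return tuple(a - b for a, b in zip(self.u1, self.u2))


def group_payoffs(params: ParameterSet, state: PopulationState) -> GroupPayoffs:
    """Expected payoffs of each group's two strategies at ``state``.

    Computed by weighting the payoff tensor with the *other* groups'
    strategy shares.
    """
    tensor = build_payoff_tensor(params)
    shares = state.as_array()
    # weight vector per axis: P(strategy 0) = share, P(strategy 1) = 1 - share
    w = [np.array([v, 1.0 - v]) for v in shares]
    u1, u2, mean = [], [], []
    for g in range(4):
        # expectation over the other three groups' strategy shares
        expect = tensor[..., g]
        for a in sorted((a for a in range(4) if a != g), reverse=True):
            expect = np.moveaxis(expect, a, -1) @ w[a]
        u1.append(float(expect[0]))
        u2.append(float(expect[1]))
        mean.append(float(shares[g] * expect[0] + (1 - shares[g]) * expect[1]))
    return GroupPayoffs(tuple(u1), tuple(u2), tuple(mean))


@dataclass(frozen=True)
class PayoffDeltas:
    """Per-group payoff advantage U1 - U2 of the first strategy."""

    dx: float
    dy: float
    dz: float
    dp: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz, self.dp])


def payoff_deltas(
    params: ParameterSet,
    state: PopulationState | tuple[float, float, float, float],
) -> PayoffDeltas:
    """Closed-form payoff differences driving the replicator dynamics.

    Only opposing-group shares enter: the institution delta depends on
    ``(y, p)``, the platform delta on ``p``, the provider delta on ``p``, and
    the patient delta on ``y``. None depends on ``z`` — device terms cancel
    between the patient's strategies, and spillovers T1–T3 cancel likewise.
    """
    q = params
    _, y, _, p = state
    dx = (q.C12 - q.C11) + (1 - p) * (q.R12 - q.alpha * q.R13) \
        - (1 - p) * (1 - y) * q.F1 * (1 - q.alpha)
    dy = (1 - p) * (q.R21 - q.R22) + (q.C22 - q.C21)
    dz = (q.C32 - q.C31) + (q.R32 - q.R34) + (q.R31 + q.R34 - q.R32 - q.R33) * p
    online_part = (1 - q.beta) * (q.R41 - q.C46) + q.beta * (q.R42 - q.C43)
    online_full = (1 - q.theta) * (q.R41 - q.C46) + q.theta * (q.R43 - q.C44)
    dp = (q.R41 - q.C45) - (y * online_part + (1 - y) * online_full)
    return PayoffDeltas(dx, dy, dz, dp)


def classify_sign(value: float, tol: float = SIGN_TOLERANCE) -> str:
    """Classify a value as "+", "-", or "boundary" (within ``tol`` of 0)."""
    if abs(value) <= tol:
        return "boundary"
    return "+" if value > 0 else "-"


EXPRESSION_MEANINGS: dict[str, str] = {
    "e1": "platform net benefit: part-time minus full-time doctor mode",
    "e2": "provider net benefit of leasing minus no-leasing, Internet-preference patients",
    "e3": "provider net benefit of leasing minus no-leasing, physical-preference patients",
    "e4": "institution net online benefit: self-built minus relying-on, full-time platform mode",
    "e5": "institution net online benefit: self-built minus relying-on, part-time platform mode",
    "e6": "patient net benefit: offline minus online care, full-time platform mode",
    "e7": "patient net benefit: offline minus online care, part-time platform mode",
}


@dataclass(frozen=True)
class ExpressionSet:
    """The seven net-benefit differences whose signs decide which corner
    equilibria can be evolutionarily stable."""

    e1: float
    e2: float
    e3: float
    e4: float
    e5: float
    e6: float
    e7: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("e1", "e2", "e3", "e4", "e5", "e6", "e7")}

    def signs(self, tol: float = SIGN_TOLERANCE) -> dict[str, str]:
        return {k: classify_sign(v, tol) for k, v in self.as_dict().items()}

    def __getitem__(self, key: str) -> float:
        if key not in EXPRESSION_MEANINGS:
            raise KeyError(key)
        return getattr(self, key)


def expression_values(params: ParameterSet) -> ExpressionSet:
    """Evaluate the seven sign-determining expressions.

    Each is a payoff delta evaluated at a specific opposing-strategy regime:
    e1 is the platform delta at p=0; e2/e3 the provider delta at p=0/p=1;
    e4/e5 the institution delta at (y=0,p=0)/(y=1,p=0); e6/e7 the patient
    delta at y=0/y=1.
    """
    q = params
    return ExpressionSet(
        e1=(q.R21 - q.C21) - (q.R22 - q.C22),
        e2=(q.R32 - q.C31) - (q.R34 - q.C32),
        e3=(q.R31 - q.C31) - (q.R33 - q.C32),
        e4=(q.R12 - q.F1 - q.C11) - (q.alpha * (q.R13 - q.F1) - q.C12),
        e5=(q.R12 - q.C11) - (q.alpha * q.R13 - q.C12),
        e6=(q.R41 - q.C45)
        - ((1 - q.theta) * (q.R41 - q.C46) + q.theta * (q.R43 - q.C44)),
        e7=(q.R41 - q.C45)
        - ((1 - q.beta) * (q.R41 - q.C46) + q.beta * (q.R42 - q.C43)),
    )
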