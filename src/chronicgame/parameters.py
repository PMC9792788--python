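"""Model parameters and population state for the four-group telemedicine game.

The game couples four stakeholder populations of a chronic-disease
diagnosis-and-treatment system:

* physical medical institutions — run their online platform *self-built*
  (share ``x``) or *relying on* a third-party platform (share ``1 - x``),
  keeping only an ``alpha`` fraction of the online benefit in the latter case;
* medical service platforms — staff with *part-time* doctors (share ``y``)
  or *full-time* doctors (``1 - y``), the full-time mode being costlier but
  faster-responding (``theta > beta``);
* intelligent medical device providers — offer device *leasing* (share ``z``)
  or sale only (``1 - z``);
* chronic-disease patients — hold a *physical* (on-site) preference
  (share ``p``) or an *Internet* preference (``1 - p``).

All payoffs are in abstract, unitless "payoff units"; the model is never
calibrated to a currency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Iterator

__all__ = [
    "ParameterSet",
    "PopulationState",
    "ValidationReport",
    "ValidationError",
    "PARAMETER_NAMES",
    "CANCELLED_PARAMETERS",
    "ASSUMPTIONS",
    "baseline_parameters",
    "validate_parameters",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A parameter set violates the model's structural assumptions."""


@dataclass(frozen=True)
class ParameterSet:
    """All constants of the payoff model.

    Costs ``C``, benefits ``R``, share/probability parameters ``alpha``,
    ``beta``, ``theta``, and the coupling effects ``F1`` (full-time staffing
    penalty on institutions' online platforms) and ``T1``–``T3`` (positive
    spillovers of leasing and of Internet preference).

    The eight parameters in :data:`CANCELLED_PARAMETERS` appear identically in
    both strategies of the affected group, cancel from every payoff
    difference, and therefore never influence the dynamics; they default to 0.
    """

    # institution operating costs: self-built vs relying-on
    C11: float
    C12: float
    # platform employment costs: part-time vs full-time doctors
    C21: float
    C22: float
    # provider operational costs: leasing vs no-leasing
    C31: float
    C32: float
    # patient visit costs: platform part-time / full-time, institution
    # offline / online
    C43: float
    C44: float
    C45: float
    C46: float
    # institution online benefits (platform in part-time mode):
    # self-built / relying-on (pre-share)
    R12: float
    R13: float
    # platform benefits: part-time vs full-time mode
    R21: float
    R22: float
    # provider benefits: leasing x (physical | Internet) preference,
    # no-leasing x (physical | Internet) preference
    R31: float
    R32: float
    R33: float
    R34: float
    # patient benefits: institution services, platform part-time / full-time
    R41: float
    R42: float
    R43: float
    # shares / probabilities
    alpha: float
    beta: float
    theta: float
    # full-time staffing penalty on institutions' online platforms
    F1: float
    # dynamically inert parameters (cancel between strategies)
    R11: float = 0.0
    R44: float = 0.0
    R45: float = 0.0
    C41: float = 0.0
    C42: float = 0.0
    T1: float = 0.0
    T2: float = 0.0
    T3: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"parameter {f.name} must be a number, got {v!r}")
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
        for name in ("alpha", "beta", "theta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given parameters replaced."""
        unknown = set(overrides) - PARAMETER_NAMES
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


PARAMETER_NAMES: frozenset[str] = frozenset(f.name for f in fields(ParameterSet))

#: Parameters that cancel between the two strategies of every group and are
#: provably inert for the replicator dynamics.
CANCELLED_PARAMETERS: tuple[str, ...] = (
    "R11", "R44", "R45", "C41", "C42", "T1", "T2", "T3",
)


@dataclass(frozen=True)
class PopulationState:
    """Strategy shares (x, y, z, p), each a proportion in [0, 1]."""

    x: float
    y: float
    z: float
    p: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "p"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"state component {name} is not finite: {v!r}")
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"state component {name}={v} outside [0, 1]")

    def as_array(self):
        import numpy as np

        return np.clip(np.array([self.x, self.y, self.z, self.p], dtype=float), 0.0, 1.0)

    def __iter__(self) -> Iterator[float]:
        return iter((self.x, self.y, self.z, self.p))


#: Structural assumptions on the parameter ordering, as (name, predicate).
ASSUMPTIONS: tuple[tuple[str, object], ...] = (
    ("C11 > C12", lambda q: q.C11 > q.C12),
    ("C21 < C22", lambda q: q.C21 < q.C22),
    ("C31 > C32", lambda q: q.C31 > q.C32),
    ("C41 < C42", lambda q: q.C41 < q.C42),
    ("R21 < R22", lambda q: q.R21 < q.R22),
    ("R31 < R32", lambda q: q.R31 < q.R32),
    ("R33 < R34", lambda q: q.R33 < q.R34),
    ("R32 > R34", lambda q: q.R32 > q.R34),
    ("R31 > R33", lambda q: q.R31 > q.R33),
    ("theta > beta", lambda q: q.theta > q.beta),
)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a parameter set against the model assumptions."""

    violations: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def as_dict(self) -> dict:
        return {"ok": self.ok, "violations": list(self.violations)}


def validate_parameters(
    params: ParameterSet,
    mode: str = "strict",
    skip: Iterable[str] = (),
) -> ValidationReport:
    """Check the ten ordering assumptions of the model.

    ``C41 < C42`` is skipped automatically when both device-acquisition costs
    are left at their inert default of 0 (the ordering is then moot: both
    values cancel from the dynamics anyway).

    Parameters
    ----------
    params
        The parameter set to check.
    mode
        ``"strict"`` raises :class:`ValidationError` on any violation;
        ``"warn"`` logs them and returns the report.
    skip
        Assumption labels to exclude from checking.
    """
    if mode not in ("strict", "warn"):
        raise ValueError(f"mode must be 'strict' or 'warn', got {mode!r}")
    skip = set(skip)
    if params.C41 == 0.0 and params.C42 == 0.0:
        skip.add("C41 < C42")
    violated = tuple(
        name for name, pred in ASSUMPTIONS if name not in skip and not pred(params)
    )
    report = ValidationReport(violated)
    if violated:
        if mode == "strict":
            raise ValidationError(
                "parameter set violates model assumptions: " + ", ".join(violated)
            )
        logger.warning("parameter assumptions violated: %s", ", ".join(violated))
    return report


def baseline_parameters(**overrides: float) -> ParameterSet:
    """The canonical simulation parameter set (dynamically inert parameters 0).

    These are the values used throughout the reference simulations; the
    missing leasing/sale device benefits and costs and the spillovers
    T1–T3 cancel from every payoff difference, so 0 is a safe default.
    """
    base = ParameterSet(
        C11=0.7, C12=0.6,
        C21=0.5, C22=0.7,
        C31=0.7, C32=0.5,
        C43=0.9, C44=1.0, C45=1.0, C46=0.9,
        R12=1.7, R13=3.0,
        R21=1.7, R22=2.5,
        R31=1.4, R32=1.5, R33=1.0, R34=1.4,
        R41=1.5, R42=1.0, R43=1.6,
        alpha=0.7, beta=0.4, theta=0.6, F1=0.3,
    )
    return base.with_overrides(**overrides) if overrides else base
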