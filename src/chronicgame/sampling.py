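"""Seeded random generation of assumption-respecting games.

Supplies random parameter sets and initial states in the magnitude regime of
the canonical game (costs a few tenths to ~1.5, benefits ~0.5 to 3.5), so
property sweeps exercise every pipeline stage without external input.
Ordered parameter pairs are generated constructively — draw the smaller
value, then add a positive gap — rather than by rejection, which would decay
badly with ten simultaneous inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet, PopulationState, validate_parameters

__all__ = ["SamplingSpec", "sample_parameters", "sample_initial_state"]


@dataclass(frozen=True)
class SamplingSpec:
    """Ranges and seeding for random game generation.

    ``cost_range`` and ``benefit_range`` bound the unordered draws; ordered
    pairs draw the smaller end uniformly and add a gap uniform in
    ``(min_gap, gap_max)``. Probabilities are uniform in an open interval
    bounded away from 0 and 1 so strict inequalities are meaningful.
    """

    seed: int = 0
    cost_range: tuple[float, float] = (0.1, 1.5)
    benefit_range: tuple[float, float] = (0.5, 3.5)
    probability_range: tuple[float, float] = (0.05, 0.95)
    min_gap: float = 0.05
    gap_max: float = 0.8

    def __post_init__(self) -> None:
        for name in ("cost_range", "benefit_range", "probability_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} is degenerate: ({lo}, {hi})")
        if not 0 < self.min_gap < self.gap_max:
            raise ValueError("need 0 < min_gap < gap_max")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _ordered_pair(rng: np.random.Generator, spec: SamplingSpec,
                  lo: float, hi: float) -> tuple[float, float]:
    """Draw (small, large) with large - small uniform in (min_gap, gap_max).

    The larger value may overshoot ``hi`` by at most ``gap_max``; the ranges
    describe the regime, not hard bounds.
    """
    small = rng.uniform(lo, hi - spec.min_gap)
    large = small + rng.uniform(spec.min_gap, spec.gap_max)
    return float(small), float(large)


def sample_parameters(spec: SamplingSpec,
                      rng: np.random.Generator | None = None) -> ParameterSet:
    """One random parameter set satisfying all ordering assumptions.

    Construction: cost pairs (C11 > C12, C21 < C22, C31 > C32, C41 < C42) and
    the platform benefit pair (R21 < R22) come from :func:`_ordered_pair`;
    the provider benefits draw four values and assign the minimum to R33 and
    the maximum to R32 (putting R31 and R34 strictly between min and max in
    random order), which yields R33 < R34 < R32 and R33 < R31 < R32 at once;
    theta > beta sorts two probability draws. Deterministic for a fixed
    seed: repeated calls with a fresh ``spec.rng()`` give the same set.
    """
    if rng is None:
        rng = spec.rng()
    clo, chi = spec.cost_range
    blo, bhi = spec.benefit_range
    plo, phi = spec.probability_range

    C12, C11 = _ordered_pair(rng, spec, clo, chi)
    C21, C22 = _ordered_pair(rng, spec, clo, chi)
    C32, C31 = _ordered_pair(rng, spec, clo, chi)
    C41, C42 = _ordered_pair(rng, spec, clo, chi)
    R21, R22 = _ordered_pair(rng, spec, blo, bhi)

    provider = np.sort(rng.uniform(blo, bhi, size=4))
    mids = rng.permutation(provider[1:3])
    R33, R32 = float(provider[0]), float(provider[3])
    R31, R34 = float(mids[0]), float(mids[1])

    beta, theta = np.sort(rng.uniform(plo, phi, size=2))
    if theta == beta:  # measure-zero; nudge within range
        theta = min(phi, beta + spec.min_gap)

    params = ParameterSet(
        C11=C11, C12=C12, C21=C21, C22=C22, C31=C31, C32=C32,
        C41=C41, C42=C42,
        C43=float(rng.uniform(clo, chi)), C44=float(rng.uniform(clo, chi)),
        C45=float(rng.uniform(clo, chi)), C46=float(rng.uniform(clo, chi)),
        R11=float(rng.uniform(blo, bhi)),
        R12=float(rng.uniform(blo, bhi)), R13=float(rng.uniform(blo, bhi)),
        R21=R21, R22=R22,
        R31=R31, R32=R32, R33=R33, R34=R34,
        R41=float(rng.uniform(blo, bhi)), R42=float(rng.uniform(blo, bhi)),
        R43=float(rng.uniform(blo, bhi)),
        R44=float(rng.uniform(blo, bhi)), R45=float(rng.uniform(blo, bhi)),
        alpha=float(rng.uniform(plo, phi)),
        beta=float(beta), theta=float(theta),
        F1=float(rng.uniform(0.0, 0.5)),
        T1=float(rng.uniform(0.0, 0.5)), T2=float(rng.uniform(0.0, 0.5)),
        T3=float(rng.uniform(0.0, 0.5)),
    )
    validate_parameters(params, mode="strict")
    return params


def sample_initial_state(spec: SamplingSpec,
                         rng: np.random.Generator | None = None,
                         margin: float = 0.02) -> PopulationState:
    """A random interior state, components uniform in (margin, 1 - margin)."""
    if rng is None:
        rng = spec.rng()
    return PopulationState(*rng.uniform(margin, 1.0 - margin, size=4))
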