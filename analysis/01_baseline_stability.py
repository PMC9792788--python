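#!/usr/bin/env python
"""Stability portrait of the canonical game.

Evaluates the seven net-benefit expressions on the canonical parameter set,
classifies all 16 corner rest points by their Jacobian eigenvalues, and
records which stability conditions hold. Finding: expressions 1, 2, 4, 6
are negative while 3 and 7 are positive, so Conditions 1 and 9 hold
simultaneously and the system is bistable between E1 (0,0,0,0) — full-time
platforms, no leasing, Internet-preference patients, relying-on
institutions — and E12 (0,1,1,1) — part-time platforms, leasing,
physical-preference patients.

Writes results/baseline_stability.json.
"""

import json
from pathlib import Path

from chronicgame import (
    baseline_parameters,
    check_conditions,
    classify_equilibria,
    expression_values,
    validate_parameters,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = baseline_parameters()
    report = validate_parameters(params, mode="strict")
    print(f"assumption check: {'ok' if report.ok else report.violations}")

    exprs = expression_values(params)
    print("\nexpression values (payoff units):")
    for key, value in exprs.as_dict().items():
        print(f"  {key} = {value:+.4f} ({exprs.signs()[key]})")

    satisfied, boundary = check_conditions(params)
    print(f"\nsatisfied conditions: {sorted(satisfied)} (boundary: {sorted(boundary)})")

    equilibria = classify_equilibria(params)
    print("\ncorner classification:")
    for r in equilibria:
        eigs = ", ".join(f"{v:+.3f}" for v in r.eigenvalues)
        print(f"  {r.corner:<4} {r.coordinates}  [{eigs}]  -> {r.verdict}")
    ess = [r.corner for r in equilibria if r.verdict == "ESS"]
    print(f"\nESS set: {ess}")

    OUT.mkdir(exist_ok=True)
    payload = {
        "expressions": exprs.as_dict(),
        "expression_signs": exprs.signs(),
        "satisfied_conditions": sorted(satisfied),
        "ess": ess,
        "equilibria": [r.as_dict() for r in equilibria],
    }
    out = OUT / "baseline_stability.json"
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
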