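# chronicgame

An evolutionary-game analysis of chronic-disease diagnosis-and-treatment
systems. Four stakeholder populations interact around the "re-visits and
drug renewal" needs of chronic-disease patients:

| population | strategy share | first strategy | second strategy |
|---|---|---|---|
| physical medical institutions | `x` | self-built online platform | relying on a third-party platform |
| medical service platforms | `y` | part-time doctors | full-time doctors |
| intelligent medical device providers | `z` | device leasing | sale only |
| chronic-disease patients | `p` | physical (on-site) preference | Internet preference |

Each group's two strategies have cost/benefit parameters (C's and R's), a
benefit-share ratio `α` kept by a relying-on institution, probabilities
`β < θ` that an Internet-preference patient picks the platform under
part-time vs full-time staffing, a full-time staffing penalty `F₁` on the
institutions' online channel, and positive spillovers `T₁–T₃`. The package
is aimed at health-policy modellers who want to recompute, perturb, or
extend this class of multi-population games.

## Model

With the expected payoff advantage `ΔU_v = U₁(v) − U₂(v)` of each group's
first strategy, every share follows the two-strategy replicator equation

```
dv/dt = v (1 − v) ΔU_v ,   v ∈ {x, y, z, p}.
```

The 16 corners of the unit hypercube are rest points; at a corner the
Jacobian is diagonal, so by Lyapunov's first method a corner is an
evolutionarily stable strategy (ESS) exactly when its four eigenvalues are
strictly negative. Ten corners are stable-capable, each under a named
Condition (1–10); the other six contain an eigenvalue forced positive by
the cost orderings (`C₁₁ > C₁₂`, `C₂₁ < C₂₂`, ...) and are never stable.
The Conditions are sign requirements on seven net-benefit expressions
(e₁–e₇) — e.g. e₁ = (R₂₁ − C₂₁) − (R₂₂ − C₂₂) is the platforms' part-time
minus full-time net benefit — and their mutual sign clashes imply that at
most two Conditions hold at once (bistability), while Conditions 3, 6, 8
and 10 each force a unique ESS.

## Worked example

```python
from chronicgame import (baseline_parameters, expression_values,
                         classify_equilibria, simulate, classify_endpoint)

params = baseline_parameters()          # the canonical parameter set
print(expression_values(params).as_dict())
# {'e1': -0.6..., 'e2': -0.09..., 'e3': 0.19..., 'e4': -0.59...,
#  'e5': -0.49..., 'e6': -0.10..., 'e7': 0.10...}

print([r.corner for r in classify_equilibria(params) if r.verdict == "ESS"])
# ['E1', 'E12']

traj = simulate(params, (0.3, 0.3, 0.3, 0.3))
print(classify_endpoint(traj).corner)   # 'E1'
traj = simulate(params, (0.7, 0.7, 0.7, 0.7))
print(classify_endpoint(traj).corner)   # 'E12'
```

Read: under the canonical costs and benefits, e₁, e₂, e₄, e₆ are negative
and e₃, e₇ positive, so Conditions 1 and 9 hold together and the system is
bistable. Starting everyone below 50% first-strategy share, it settles at
E1 = (0,0,0,0) — relying-on institutions, full-time platforms, no leasing,
Internet-preference patients; starting above 50%, at E12 = (0,1,1,1) —
part-time platforms, leasing, physical-preference patients.

The same pipeline is scripted in `analysis/`:

* `01_baseline_stability.py` — expressions and the 16-corner portrait,
* `02_reproduce_scenarios.py` — all named regimes (dual- and unique-ESS),
* `03_sensitivity_speed.py` — settling-time effect of seven policy levers,
* `04_random_sweep.py` — structural property checks over random games,

each writing its table under `results/`. A `chronicgame` CLI wraps the same
functions (`validate`, `expressions`, `stability`, `simulate`, `reproduce`,
`sweep`), e.g.

```
chronicgame simulate --config configs/baseline.yaml --init 0.3,0.3,0.3,0.3 --out traj.csv
chronicgame reproduce --all --out reports/
```

(`--config` takes a flat YAML/JSON file of the parameter symbols; see
`configs/baseline.yaml`. Omitting it uses the same canonical values.)

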