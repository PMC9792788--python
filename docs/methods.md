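# Methods

## The game

Four large populations play an asymmetric game: physical medical
institutions choose between a *self-built* online platform and *relying on*
a third-party platform; medical service platforms staff with *part-time* or
*full-time* doctors; intelligent medical device providers either *lease*
devices or sell only; chronic-disease patients hold a *physical* or an
*Internet* care preference. State is the vector of first-strategy shares
(x, y, z, p) ∈ [0,1]⁴. Payoffs for all 16 pure strategy profiles are built
from the cost/benefit parameters (`payoffs.build_payoff_tensor`); expected
payoffs weight the tensor by the opposing groups' shares, and each share
follows the two-strategy replicator equation dv/dt = v(1−v)(U₁−U₂).

Structural assumptions (ten orderings, `parameters.ASSUMPTIONS`): self-built
costs more than relying-on (C₁₁ > C₁₂); full-time staffing costs more but
earns more (C₂₁ < C₂₂, R₂₁ < R₂₂) and responds faster (θ > β); leasing
costs providers more to run (C₃₁ > C₃₂) but is cheaper for patients
(C₄₁ < C₄₂); provider benefits order as R₃₃ < {R₃₁, R₃₄} < R₃₂ (leasing
beats not leasing for either patient type, Internet-preference patients are
worth more). The validator enforces these in strict or warn mode; the
`C₄₁ < C₄₂` check is skipped when both are left at their inert default 0.

### Payoff differences

The payoff advantages (`payoffs.payoff_deltas`) have closed forms:

* ΔU_x = (C₁₂−C₁₁) + (1−p)(R₁₂−αR₁₃) − (1−p)(1−y)F₁(1−α)
* ΔU_y = (1−p)(R₂₁−R₂₂) + (C₂₂−C₂₁)
* ΔU_z = (C₃₂−C₃₁) + (R₃₂−R₃₄) + (R₃₁+R₃₄−R₃₂−R₃₃)p
* ΔU_p = (R₄₁−C₄₅) − [y·((1−β)(R₄₁−C₄₆)+β(R₄₂−C₄₃)) + (1−y)·((1−θ)(R₄₁−C₄₆)+θ(R₄₃−C₄₄))]

ΔU_x was derived from the payoff tensor (the institution difference
collects the (1−p) online terms with and without the full-time penalty) and
is cross-checked two independent ways in the tests: against the weighted
tensor expectation at random states, and against the corner eigenvalues it
must reproduce (at y=0,p=0 it equals expression e₄; at y=1,p=0 expression
e₅). No delta depends on z, and ΔU_z depends only on p — leasing affects
others only through levels, never through differences — so the z dynamics
are slaved to p and trajectory endpoints of (x,y,p) are independent of the
initial z.

Eight parameters (R₁₁, R₄₄, R₄₅, C₄₁, C₄₂, T₁, T₂, T₃) appear identically
in both strategies of the affected group and cancel from every difference.
They default to 0 in configs (with a log note) and a property test perturbs
each one to confirm the dynamics are invariant.

## Stability analysis

Only the 16 corners can be evolutionarily stable (in multi-population
replicator dynamics an ESS must be a strict, pure-strategy equilibrium).
At a corner the Jacobian is diagonal; the eigenvalue of group v equals
+ΔU_v when the corner has v=0 and −ΔU_v when v=1. `corner_eigenvalues`
evaluates these closed forms (stored in a fixed reference row order per
corner), `numeric_jacobian` finite-differences the right-hand side as an
independent route, and `classify_equilibria` applies the eigenvalue sign
test: all strictly negative → ESS; any positive → unstable; any within the
boundary tolerance (1e−12) of zero and none positive → inconclusive (the
linearization is silent; such corners are never promoted).

Ten corners are stable-capable; their Conditions reduce to sign
requirements on seven expressions e₁–e₇ (`stability.CONDITION_SIGNS`), each
being one ΔU evaluated at a specific opposing-strategy regime. Six corners
are unstable under the assumptions because their eigenvalue lists contain
C₂₂−C₂₁ > 0 or C₁₁−C₁₂ > 0. A set of Conditions can co-occur only if the
union of its sign requirements is consistent; `permitted` implements
exactly that check, from which the known structure follows: dual-ESS
combinations pair Condition 1/2/4/7 with 5 or 9, while Conditions 3, 6, 8,
10 are singletons.

One convention worth making explicit: the first eigenvalue of the corner
(1,0,1,0) is α(R₁₃−F₁)−C₁₂ minus (R₁₂−F₁−C₁₁), i.e. −e₄ — the full-time
penalty enters the relying-on institution's payoff inside the shared
benefit, so it is scaled by α. This is the only reading consistent with
the (1,0,0,0) corner and with the derived ΔU_x, and all cross-checks
(numeric Jacobian, simulated endpoints) confirm it.

## Numerical integration

`simulate` integrates the interior components in logit coordinates,
u = log(v/(1−v)), where the replicator equation becomes the boundary-free
du/dt = ΔU. This preserves the exact flow's key structural fact — hypercube
faces are invariant, and an interior trajectory never reaches one in finite
time — so no component can be absorbed at 0/1 by floating-point rounding.
Absorption is not hypothetical: integrating the raw shares, a trajectory
passing exponentially close to an unstable corner (a saddle passage) has
its escaping component rounded onto the face and freezes there, producing
spurious "convergence" to unstable corners. Components that start exactly
on a face are held fixed (the face is invariant). The solver is adaptive
explicit RK45 (the right-hand side is smooth and non-stiff), rel_tol 1e−8 /
abs_tol 1e−10, sampled on a uniform grid (2001 points by default); sampled
states are clipped to [0,1] to absorb logistic round-off. Runs are
deterministic for identical inputs.

`classify_endpoint` calls an endpoint converged to its nearest corner when
(a) the max-norm distance is below ε (default 1e−3), (b) the RHS max-norm
is below ε, and (c) the payoff drift at the endpoint points *into* the
corner — positive advantage for components at 1, negative at 0, with
face-started components exempt. Check (c) is what distinguishes a sink from
a lingering saddle passage: during such a passage both the distance and the
RHS are tiny, and once the logistic saturates (|u| ≳ 37) the escaping
component is invisible below double precision, so no geometric test on the
sampled path can detect it — the drift direction can. A consequence worth
stating: the endpoint-vs-ESS agreement sweep is not a fully independent
cross-validation, since the drift check and the closed-form eigenvalues
both ultimately read the signs of the payoff differences (through different
code paths — the reference-row-ordered closed forms with per-corner sign
flips versus the raw drift at the integrated endpoint); the sweep still exercises
basin selection, the integrator, and the eigenvalue transcription. An
earlier design stopped integration early when the RHS max-norm fell below
1e−10; this was removed because it halts precisely in the middle of saddle
passages.

`convergence_time` reports the first sampled time after which a component
stays within ε of its corner limit (grid resolution horizon/4000 by
default), and an explicit `None` — never a number — when the component has
not converged by the horizon.

## Scenarios and experiments

The canonical parameter set (`baseline_parameters`) fixes all 26 live
parameters; the scenario registry (`scenarios.SCENARIOS`) resolves the
named variants explicitly, including the chained ones, so no variant is
ambiguous: fig2 = {R₃₂:2}, fig3 = {R₁₃:2}, fig4 = {R₃₂:2, R₁₃:2},
fig5 = {R₂₂:1.8, R₄₂:1.5}, fig6–8 extend fig5, and the sensitivity pairs
fig9–15 record (parameter, slow, fast, watched component). The pairs
fig9–11 use the fig5 regime as base — the only base under which their
quoted expression transitions (e.g. e₇: −0.1 → −0.26) are arithmetically
consistent — and fig12/13 use {R₂₂:1.8} (resp. plus {R₂₁:1.3}) for the same
reason. Expected outcomes (conditions, ESS sets, endpoints) are stored as
registry data, not asserted in code.

Qualitative sources state only that dual-ESS regimes split at initial
shares "below/above 0.5", so the canonical starts are (0.3,0.3,0.3,0.3)
and (0.7,0.7,0.7,0.7); the default horizon of 200 time units converges all
named regimes to within 1e−3. Settling-time comparisons start both variants
of a pair from (0.5,0.5,0.5,0.5), where all seven pairs converge within the
default horizon. The speed claim verified is the directional one — the
accelerated variant settles strictly faster — not any particular magnitude.
Note that a larger |relevant expression| is *not* a universal speed
predictor: for the R₂₁/C₂₁ pairs the expression e₁ moves from −0.3 to +0.1
(magnitude shrinks) yet the platform component still settles faster,
because the sign change moves the regime from bistable (slow basin
boundary effects) to a unique part-time outcome; from low starts the
ordering can even reverse.

## Synthetic games

`sampling.sample_parameters` generates random parameter sets in the
magnitude regime of the canonical game (costs in [0.1, 1.5], benefits in
[0.5, 3.5], probabilities in (0.05, 0.95)) satisfying all ten orderings by
construction rather than rejection: ordered pairs draw the smaller value
and add a positive gap uniform in (0.05, 0.8) — the larger value may
overshoot the range top by at most the gap — and the four provider benefits
are drawn jointly and assigned min→R₃₃, max→R₃₂, middle two randomly to
R₃₁/R₃₄. All sampling is driven by a single seeded generator, so sweeps are
reproducible. These games emulate the *structure* of the model (orderings
and magnitudes), not any empirical distribution of real costs and benefits;
property sweeps passing on them demonstrate internal consistency of the
pipeline, not calibration to real care systems. Random-game sweeps use
horizon 1000 rather than the scenario default 200, because generic draws
can have much slower transients (small payoff gaps, close saddle passages);
roughly 90% of draws converge within that horizon and the rest are reported
as unconverged rather than forced.

## Known limitations

* Payoffs are unitless; nothing is calibrated to currency or to data from
  real institutions, platforms, providers or patients.
* Only pure-strategy (corner) candidates are classified; interior or mixed
  rest points are outside scope (and none arises in the canonical regimes).
* The dynamics are deterministic infinite-population replicator equations:
  no finite-population noise, no time-varying parameters.
* Non-hyperbolic corners (a zero eigenvalue) are reported as inconclusive;
  no center-manifold analysis is attempted.
* Settling times are measured on a fixed sampling grid (resolution 0.05
  time units at the defaults) and comparisons are meaningful only for the
  same start and ε.
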