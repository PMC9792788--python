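"""Payoff tensor, expected payoffs, payoff differences, and the seven
sign-determining expressions."""

from fractions import Fraction

import numpy as np
import pytest

from chronicgame import (
    PopulationState,
    build_payoff_tensor,
    expression_values,
    group_payoffs,
    payoff_deltas,
    sample_initial_state,
    sample_parameters,
)

# strategy indices: 0 = (self-built, part-time, leasing, physical)
SELF, PART, LEASE, PHYS = 0, 0, 0, 0
RELY, FULL, NOLEASE, NET = 1, 1, 1, 1


class TestPayoffTensor:
    def test_all_sixteen_profiles_present(self, baseline):
        t = build_payoff_tensor(baseline)
        assert t.shape == (2, 2, 2, 2, 4)
        assert np.all(np.isfinite(t))

    def test_reference_profile_cells(self, baseline):
        q = baseline
        t = build_payoff_tensor(q)
        cell = t[SELF, PART, LEASE, PHYS]
        assert cell[0] == pytest.approx(q.R11 - q.C11 + q.T2)
        assert cell[1] == pytest.approx(-q.C21)
        assert cell[2] == pytest.approx(q.R31 - q.C31)
        assert cell[3] == pytest.approx(q.R41 + q.R44 - q.C41 - q.C45)
        # with the inert defaults the patient cell is 1.5 - 1.0 = 0.5
        assert cell[3] == pytest.approx(0.5)

    def test_platform_cell_part_time_leasing_internet(self, baseline):
        q = baseline
        t = build_payoff_tensor(q)
        for ix in (0, 1):
            assert t[ix, PART, LEASE, NET, 1] == pytest.approx(q.R21 - q.C21 + q.T1)

    def test_provider_payoff_ignores_institution_and_platform(self, baseline):
        t = build_payoff_tensor(baseline)
        prov = t[..., 2]
        for iz in (0, 1):
            for ip in (0, 1):
                assert len({prov[ix, iy, iz, ip] for ix in (0, 1) for iy in (0, 1)}) == 1

    def test_full_time_penalty_hits_online_institution_benefit(self, baseline):
        q = baseline
        t = build_payoff_tensor(q)
        # self-built, Internet-preference patients: full-time mode costs F1
        diff = t[SELF, PART, LEASE, NET, 0] - t[SELF, FULL, LEASE, NET, 0]
        assert diff == pytest.approx(q.F1)
        # relying-on mode: the penalty is shared, only alpha*F1 remains
        diff = t[RELY, PART, LEASE, NET, 0] - t[RELY, FULL, LEASE, NET, 0]
        assert diff == pytest.approx(q.alpha * q.F1)


class TestGroupPayoffs:
    def test_pure_state_recovers_tensor_cells(self, baseline):
        t = build_payoff_tensor(baseline)
        gp = group_payoffs(baseline, PopulationState(1, 0, 1, 0))
        # institution U1 at (x=1 -> self-built) with y=0 -> full-time,
        # z=1 -> leasing, p=0 -> Internet preference
        assert gp.u1[0] == pytest.approx(t[SELF, FULL, LEASE, NET, 0])
        assert gp.u2[0] == pytest.approx(t[RELY, FULL, LEASE, NET, 0])
        assert gp.u1[3] == pytest.approx(t[SELF, FULL, LEASE, PHYS, 3])

    def test_mean_is_share_weighted_average(self, baseline, rng):
        for _ in range(20):
            state = PopulationState(*rng.uniform(0, 1, 4))
            gp = group_payoffs(baseline, state)
            shares = (state.x, state.y, state.z, state.p)
            for g in range(4):
                expected = shares[g] * gp.u1[g] + (1 - shares[g]) * gp.u2[g]
                assert gp.mean[g] == pytest.approx(expected, abs=1e-12)

    def test_platform_advantage_at_midpoint(self, baseline):
        gp = group_payoffs(baseline, PopulationState(0.5, 0.5, 0.5, 0.5))
        # (1-p)(R21-R22) + (C22-C21) = 0.5*(-0.8) + 0.2
        assert gp.u1[1] - gp.u2[1] == pytest.approx(-0.2)


class TestPayoffDeltas:
    def test_deltas_match_tensor_expectation(self, sampling_spec):
        """Closed-form differences equal U1-U2 from the weighted tensor."""
        rng = sampling_spec.rng()
        for _ in range(300):
            params = sample_parameters(sampling_spec, rng)
            state = sample_initial_state(sampling_spec, rng)
            closed = payoff_deltas(params, state).as_array()
            from_tensor = np.array(group_payoffs(params, state).delta())
            np.testing.assert_allclose(closed, from_tensor, atol=1e-10)

    @pytest.mark.parametrize(
        "state, component, expected",
        [
            (PopulationState(0, 0, 0, 1), "dy", 0.2),    # C22 - C21
            (PopulationState(0, 0, 0, 0), "dz", -0.1),   # expression e2
            (PopulationState(0, 1, 0, 0), "dx", -0.5),   # expression e5
            (PopulationState(0, 0, 0, 0), "dp", -0.1),   # expression e6
            (PopulationState(0, 1, 0, 0), "dp", 0.1),    # expression e7
            (PopulationState(0, 0, 0, 1), "dz", 0.2),    # expression e3
        ],
    )
    def test_corner_regime_values(self, baseline, state, component, expected):
        deltas = payoff_deltas(baseline, state)
        assert getattr(deltas, component) == pytest.approx(expected)

    def test_inert_parameters_cancel(self, baseline, rng):
        """Offline benefit, device benefits/costs and the three spillovers
        appear in both strategies of the affected group and never move the
        dynamics."""
        state = PopulationState(0.37, 0.81, 0.25, 0.64)
        ref = payoff_deltas(baseline, state).as_array()
        for name in ("R11", "R44", "R45", "C41", "C42", "T1", "T2", "T3"):
            perturbed = baseline.with_overrides(**{name: float(rng.uniform(-5, 5))})
            np.testing.assert_allclose(
                payoff_deltas(perturbed, state).as_array(), ref, atol=1e-12)

    def test_decoupling_structure(self, baseline, rng):
        """No delta depends on z; the provider delta depends only on p."""
        base_state = PopulationState(0.3, 0.6, 0.2, 0.45)
        ref = payoff_deltas(baseline, base_state)
        for z in rng.uniform(0, 1, 5):
            d = payoff_deltas(baseline, PopulationState(0.3, 0.6, float(z), 0.45))
            assert (d.dx, d.dy, d.dp) == (ref.dx, ref.dy, ref.dp)
        for x, y in rng.uniform(0, 1, (5, 2)):
            d = payoff_deltas(baseline, PopulationState(float(x), float(y), 0.2, 0.45))
            assert d.dz == ref.dz


class TestExpressions:
    def test_canonical_values(self, baseline):
        e = expression_values(baseline)
        assert e.e1 == pytest.approx(-0.6)
        assert e.e2 == pytest.approx(-0.1)
        assert e.e3 == pytest.approx(0.2)
        assert e.e4 == pytest.approx(-0.59)
        assert e.e5 == pytest.approx(-0.5)
        assert e.e6 == pytest.approx(-0.1)
        assert e.e7 == pytest.approx(0.1)

    def test_signs_classification(self, baseline):
        signs = expression_values(baseline).signs()
        assert signs == {"e1": "-", "e2": "-", "e3": "+", "e4": "-",
                         "e5": "-", "e6": "-", "e7": "+"}

    def test_exact_rational_spot_check(self, baseline):
        """Re-derive the expressions with exact fractions on the canonical
        values and compare to the floating-point evaluation."""
        F = Fraction
        q = {k: F(str(v)) for k, v in baseline.as_dict().items()}
        exact = {
            "e1": (q["R21"] - q["C21"]) - (q["R22"] - q["C22"]),
            "e2": (q["R32"] - q["C31"]) - (q["R34"] - q["C32"]),
            "e3": (q["R31"] - q["C31"]) - (q["R33"] - q["C32"]),
            "e4": (q["R12"] - q["F1"] - q["C11"])
            - (q["alpha"] * (q["R13"] - q["F1"]) - q["C12"]),
            "e5": (q["R12"] - q["C11"]) - (q["alpha"] * q["R13"] - q["C12"]),
            "e6": (q["R41"] - q["C45"])
            - ((1 - q["theta"]) * (q["R41"] - q["C46"])
               + q["theta"] * (q["R43"] - q["C44"])),
            "e7": (q["R41"] - q["C45"])
            - ((1 - q["beta"]) * (q["R41"] - q["C46"])
               + q["beta"] * (q["R42"] - q["C43"])),
        }
        assert exact == {
            "e1": F("-0.6"), "e2": F("-0.1"), "e3": F("0.2"), "e4": F("-0.59"),
            "e5": F("-0.5"), "e6": F("-0.1"), "e7": F("0.1"),
        }
        computed = expression_values(baseline).as_dict()
        for key, val in exact.items():
            assert computed[key] == pytest.approx(float(val), abs=1e-12)

    def test_expressions_are_deltas_at_their_regimes(self, random_parameter_sets):
        """Each expression equals the corresponding payoff difference at its
        defining opposing-strategy regime, for random games."""
        for params in random_parameter_sets[:50]:
            e = expression_values(params)
            assert e.e1 == pytest.approx(
                payoff_deltas(params, PopulationState(0, 0, 0, 0)).dy, abs=1e-12)
            assert e.e2 == pytest.approx(
                payoff_deltas(params, PopulationState(0, 0, 0, 0)).dz, abs=1e-12)
            assert e.e3 == pytest.approx(
                payoff_deltas(params, PopulationState(0, 0, 0, 1)).dz, abs=1e-12)
            assert e.e4 == pytest.approx(
                payoff_deltas(params, PopulationState(0, 0, 0, 0)).dx, abs=1e-12)
            assert e.e5 == pytest.approx(
                payoff_deltas(params, PopulationState(0, 1, 0, 0)).dx, abs=1e-12)
            assert e.e6 == pytest.approx(
                payoff_deltas(params, PopulationState(0, 0, 0, 0)).dp, abs=1e-12)
            assert e.e7 == pytest.approx(
                payoff_deltas(params, PopulationState(0, 1, 0, 0)).dp, abs=1e-12)
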