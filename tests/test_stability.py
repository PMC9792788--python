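"""Corner equilibrium eigenvalues, ESS classification, conditions, and the
compatibility logic."""

import numpy as np
import pytest

from chronicgame import (
    CORNERS,
    check_conditions,
    classify_equilibria,
    compatibility_matrix,
    corner_eigenvalues,
    numeric_jacobian,
    permitted,
)
from chronicgame.stability import CONDITION_CORNER, NEVER_STABLE, _EIG_ORDER, _GROUP_INDEX


def ess_ids(params):
    return {r.corner for r in classify_equilibria(params) if r.verdict == "ESS"}


class TestCornerEigenvalues:
    def test_reference_corner_values(self, baseline):
        np.testing.assert_allclose(
            corner_eigenvalues(baseline, "E1"), (-0.6, -0.1, -0.59, -0.1), atol=1e-12)
        np.testing.assert_allclose(
            corner_eigenvalues(baseline, "E12"), (-0.1, -0.2, -0.2, -0.1), atol=1e-12)

    def test_shared_platform_corner_eigenvalue(self, random_parameter_sets):
        """Corners with a fixated part-time platform share the C21 - C22
        eigenvalue; corners with p=1, y=0 share C22 - C21 > 0."""
        for params in random_parameter_sets[:20]:
            lam = corner_eigenvalues(params, "E2")
            assert lam[0] == pytest.approx(params.C12 - params.C11)
            assert lam[1] == pytest.approx(params.C22 - params.C21)
            assert lam[1] > 0  # forced by the cost ordering: never an ESS

    def test_unknown_corner_rejected(self, baseline):
        with pytest.raises(KeyError):
            corner_eigenvalues(baseline, "E17")

    def test_closed_form_agrees_with_numeric_jacobian(self, random_parameter_sets):
        for params in random_parameter_sets[:40]:
            for eid, coords in CORNERS.items():
                jac = numeric_jacobian(params, tuple(map(float, coords)))
                diag = [jac[_GROUP_INDEX[g], _GROUP_INDEX[g]]
                        for g in _EIG_ORDER[eid]]
                np.testing.assert_allclose(
                    corner_eigenvalues(params, eid), diag, atol=1e-8)

    def test_jacobian_diagonal_at_corners_full_elsewhere(self, baseline):
        jac = numeric_jacobian(baseline, (0.0, 0.0, 0.0, 0.0))
        off = jac - np.diag(np.diag(jac))
        assert np.max(np.abs(off)) < 1e-8
        interior = numeric_jacobian(baseline, (0.4, 0.6, 0.5, 0.3))
        off = interior - np.diag(np.diag(interior))
        assert np.max(np.abs(off)) > 1e-3


class TestClassification:
    @pytest.mark.parametrize(
        "overrides, expected_ess",
        [
            ({}, {"E1", "E12"}),
            ({"R32": 2.0}, {"E3", "E12"}),
            ({"R13": 2.0}, {"E5", "E12"}),
            ({"R32": 2.0, "R13": 2.0}, {"E10", "E12"}),
            ({"R22": 1.8, "R42": 1.5}, {"E4"}),
            ({"R22": 1.8, "R42": 1.5, "R32": 2.0}, {"E9"}),
            ({"R22": 1.8, "R42": 1.5, "R13": 2.0}, {"E11"}),
            ({"R22": 1.8, "R42": 1.5, "R13": 2.0, "R32": 2.0}, {"E15"}),
        ],
    )
    def test_ess_sets_across_regimes(self, baseline, overrides, expected_ess):
        assert ess_ids(baseline.with_overrides(**overrides)) == expected_ess

    def test_structurally_unstable_corners(self, random_parameter_sets):
        """Six corners combine a fixated costly strategy with a payoff-
        dominated one and are unstable for every assumption-respecting
        game."""
        for params in random_parameter_sets[:50]:
            reports = {r.corner: r for r in classify_equilibria(params)}
            for eid in NEVER_STABLE:
                assert reports[eid].verdict == "unstable"

    def test_boundary_eigenvalue_is_inconclusive(self, baseline):
        # make the platform net benefits equal: e1 becomes exactly 0
        params = baseline.with_overrides(R22=1.9)
        reports = {r.corner: r for r in classify_equilibria(params)}
        assert reports["E1"].signs[0] == "boundary"
        assert reports["E1"].verdict == "inconclusive"

    def test_report_fields_consistent(self, baseline):
        for r in classify_equilibria(baseline):
            assert r.coordinates == CORNERS[r.corner]
            assert len(r.eigenvalues) == len(r.signs) == 4
            if r.verdict == "ESS":
                assert all(v < 0 for v in r.eigenvalues)
                assert r.condition is not None


class TestConditions:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({}, {1, 9}),
            ({"R32": 2.0}, {2, 9}),
            ({"R13": 2.0}, {4, 9}),
            ({"R32": 2.0, "R13": 2.0}, {7, 9}),
            ({"R22": 1.8, "R42": 1.5}, {3}),
            ({"R22": 1.8, "R42": 1.5, "R32": 2.0}, {6}),
            ({"R22": 1.8, "R42": 1.5, "R13": 2.0}, {8}),
            ({"R22": 1.8, "R42": 1.5, "R13": 2.0, "R32": 2.0}, {10}),
        ],
    )
    def test_satisfied_condition_sets(self, baseline, overrides, expected):
        satisfied, boundary = check_conditions(baseline.with_overrides(**overrides))
        assert satisfied == expected
        assert not boundary

    def test_conditions_coincide_with_ess_classification(self, random_parameter_sets):
        """The sign-based conditions and the eigenvalue-based ESS verdicts
        are two routes to the same answer."""
        for params in random_parameter_sets:
            satisfied, _ = check_conditions(params)
            assert {CONDITION_CORNER[c] for c in satisfied} == ess_ids(params)

    def test_boundary_condition_reported(self, baseline):
        params = baseline.with_overrides(R22=1.9)  # e1 exactly 0
        satisfied, boundary = check_conditions(params)
        assert 1 in boundary and 1 not in satisfied


class TestCompatibility:
    def test_rule_table_covers_all_conditions(self):
        rules = {r.condition: r for r in compatibility_matrix()}
        assert set(rules) == set(range(1, 11))
        assert rules[1].corner == "E1" and rules[9].corner == "E12"
        assert rules[5].signs == {"e3": "-", "e7": "+"}

    @pytest.mark.parametrize("conds, ok", [
        ({1, 9}, True),
        ({1, 5}, True),
        ({2, 9}, True),
        ({4, 9}, True),
        ({7, 9}, True),
        ({1, 2}, False),   # e1 required both - and +
        ({5, 9}, False),   # e3 required both - and +
        ({1}, True),
        ({9}, True),
    ])
    def test_pairwise_compatibility(self, conds, ok):
        assert permitted(conds) is ok

    @pytest.mark.parametrize("cond", [3, 6, 8, 10])
    def test_unique_ess_conditions_are_singletons(self, cond):
        assert permitted({cond})
        for other in range(1, 11):
            if other != cond:
                assert not permitted({cond, other})

    def test_unknown_condition_rejected(self):
        with pytest.raises(KeyError):
            permitted({11})

    def test_observed_condition_sets_always_permitted(self, random_parameter_sets):
        for params in random_parameter_sets:
            satisfied, _ = check_conditions(params)
            assert permitted(satisfied)
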