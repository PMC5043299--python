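import numpy as np
import pytest

from crimedyn import (
    condition_E0,
    condition_E1,
    condition_E2,
    condition_E3,
    corruption_invades,
    equilibrium_E2,
    equilibrium_E3,
    find_all_equilibria,
    hopf_excluded_core_free,
    hopf_excluded_no_criminal,
    jacobian_reduced,
    rhs_reduced,
    stability_report,
    with_overrides,
)


def fd_jacobian(state, params):
    """Central finite-difference oracle for the analytic Jacobian."""
    x = np.asarray(state, dtype=float)
    J = np.zeros((3, 3))
    for j in range(3):
        step = 1e-6 * max(1.0, abs(x[j]))
        e = np.zeros(3)
        e[j] = step
        fp = np.array(rhs_reduced(tuple(x + e), params))
        fm = np.array(rhs_reduced(tuple(x - e), params))
        J[:, j] = (fp - fm) / (2 * step)
    return J


def numeric_classification(rec, params):
    return stability_report(
        (rec.state.Sg, rec.state.Ig, rec.state.Ip), params, label=rec.label
    )


class TestJacobian:
    def test_matches_finite_differences_on_random_states(self, defaults):
        rng = np.random.default_rng(0)
        for _ in range(20):
            state = (
                rng.uniform(1.0, 3e4),
                rng.uniform(1.0, 8e3),
                rng.uniform(0.0, defaults.P - 1),
            )
            J = jacobian_reduced(state, defaults)
            assert np.max(np.abs(J - fd_jacobian(state, defaults))) < 1e-6

    def test_corruption_entry_at_extinction(self, defaults):
        """At the origin the corruption eigendirection grows at beta3 - mu2:
        corruption invades an uncorrupted force whenever beta3 > mu2."""
        J = jacobian_reduced((0.0, 0.0, 0.0), defaults)
        assert J[2, 2] == pytest.approx(defaults.beta3 - defaults.mu2)
        assert J[2, 2] == pytest.approx(0.0049)

    def test_core_growth_entry_at_core_free_state(self, defaults):
        sg2 = equilibrium_E2(defaults)[0].state.Sg
        J = jacobian_reduced((sg2, 0.0, 0.0), defaults)
        assert J[1, 1] == pytest.approx(defaults.beta1 - defaults.b, abs=1e-12)

    def test_gang_invasion_entry_at_extinction(self, defaults):
        J = jacobian_reduced((0.0, 0.0, 0.0), defaults)
        ap = defaults.a / defaults.U
        expected = defaults.b - ap * defaults.P / (1 - defaults.c * defaults.P) - defaults.mu1
        assert J[0, 0] == pytest.approx(expected)


class TestClassification:
    def test_base_case_pattern(self, defaults):
        """Only coexistence is stable at the base parameters; every
        gang-free state is unstable."""
        expected = {"E0": "unstable", "E1": "unstable", "E2": "unstable",
                    "E3": "unstable", "E4": "stable"}
        for rec in find_all_equilibria(defaults):
            assert numeric_classification(rec, defaults).classification == expected[rec.label]

    def test_non_equilibrium_rejected(self, defaults):
        with pytest.raises(ValueError, match="not an equilibrium"):
            stability_report((1000.0, 50.0, 100.0), defaults)

    def test_char_poly_consistency(self, defaults, e4):
        rep = numeric_classification(e4, defaults)
        a1, a2, a3 = rep.char_poly
        assert a1 == pytest.approx(-np.trace(rep.jacobian), rel=1e-10)
        assert a3 == pytest.approx(-np.linalg.det(rep.jacobian), rel=1e-10)
        # eigenvalues are roots of the cubic
        for lam in rep.eigenvalues:
            assert abs(lam**3 + a1 * lam**2 + a2 * lam + a3) < 1e-10

    def test_routh_hurwitz_agrees_with_eigenvalues(self, defaults, sampled_params):
        for p in [defaults] + sampled_params[:25]:
            for rec in find_all_equilibria(p):
                rep = numeric_classification(rec, p)
                if abs(rep.max_real) < 1e-7:
                    continue
                a1, a2, a3, disc = rep.routh_hurwitz
                rh_stable = a1 > 0 and a2 > 0 and a3 > 0 and disc > 0
                assert rh_stable == (rep.classification == "stable")


class TestClosedFormConditions:
    def test_gang_invasion_thresholds_at_defaults(self, defaults):
        # predation too weak to stop gang growth at the base values
        assert not condition_E0(defaults)
        assert not condition_E1(defaults)

    def test_extinction_stabilized_by_large_force(self, defaults):
        assert condition_E0(with_overrides(defaults, P=500.0))

    def test_zero_net_growth_always_controlled(self, defaults):
        assert condition_E0(with_overrides(defaults, b=defaults.mu1))

    def test_criminal_free_threshold_crossing(self, defaults):
        assert condition_E1(with_overrides(defaults, P=451.0))
        assert not condition_E1(with_overrides(defaults, P=450.0))

    def test_full_rate_corrupt_equalizes_E0_E1(self, defaults):
        p = with_overrides(defaults, r=1.0)
        for P in (200.0, 449.0, 452.0, 600.0):
            q = with_overrides(p, P=P)
            assert condition_E0(q) == condition_E1(q)

    def test_core_free_conditions_at_defaults(self, defaults):
        sg2 = equilibrium_E2(defaults)[0].state.Sg
        sg3 = equilibrium_E3(defaults)[0].state.Sg
        # beta1 > b: the recruitment clause fails for both
        assert not condition_E2(defaults, sg2)
        assert not condition_E3(defaults, sg3)

    def test_core_free_saturation_clause(self, defaults):
        p = with_overrides(defaults, beta1=0.15)
        sg2 = equilibrium_E2(p)[0].state.Sg
        assert condition_E2(p, sg2)

    def test_no_handling_always_saturation_stable(self, defaults):
        p = with_overrides(defaults, t_h=0.0, beta1=0.15)
        sg2 = equilibrium_E2(p)[0].state.Sg
        assert condition_E2(p, sg2)

    def test_higher_entry_rate_stabilizes_core_free(self, defaults):
        p = with_overrides(defaults, b=0.25)
        sg3 = equilibrium_E3(p)[0].state.Sg
        assert condition_E3(p, sg3)
        rec = equilibrium_E3(p)[0]
        assert numeric_classification(rec, p).classification == "stable"

    def test_full_rate_corrupt_equalizes_E2_E3_conditions(self, defaults):
        p = with_overrides(defaults, r=1.0, beta1=0.15)
        sg2 = equilibrium_E2(p)[0].state.Sg
        sg3 = equilibrium_E3(p)[0].state.Sg
        assert sg2 == pytest.approx(sg3, rel=1e-12)
        assert condition_E2(p, sg2) == condition_E3(p, sg3)

    def test_conditions_agree_with_eigenvalues_on_sampled_sets(self, sampled_params):
        """The closed-form threshold inequalities predict the numeric
        eigenvalue classification on every sampled set (augmented by the
        corruption-invasion threshold for the corruption-free states)."""
        for p in sampled_params:
            for rec in find_all_equilibria(p):
                rep = numeric_classification(rec, p)
                if abs(rep.max_real) < 1e-7 or rec.label == "E4":
                    continue
                numeric = rep.classification == "stable"
                if rec.label == "E0":
                    closed = condition_E0(p) and not corruption_invades(p)
                elif rec.label == "E1":
                    closed = condition_E1(p)
                elif rec.label == "E2":
                    closed = condition_E2(p, rec.state.Sg) and not corruption_invades(p)
                else:  # E3
                    closed = condition_E3(p, rec.state.Sg)
                assert closed == numeric, (rec.label, p)


class TestHopfExclusion:
    def test_no_criminal_states_at_defaults(self, defaults):
        res = hopf_excluded_no_criminal(defaults)
        assert res.excluded and res.applicable
        assert res.trace_terms["E0"] == pytest.approx(0.12 + 0.0476 + 0.03 / 0.7)
        assert res.trace_terms["E1"] > 0

    def test_core_free_states(self, defaults):
        assert not hopf_excluded_core_free(defaults).applicable  # beta1 >= b
        res = hopf_excluded_core_free(with_overrides(defaults, beta1=0.15))
        assert res.applicable and res.excluded

    def test_excluded_on_all_sampled_sets(self, sampled_params):
        for p in sampled_params:
            assert hopf_excluded_no_criminal(p).excluded
            res = hopf_excluded_core_free(p)
            if p.beta1 < p.b:
                assert res.excluded
            else:
                assert not res.applicable
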