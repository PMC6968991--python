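import numpy as np
import pytest
from scipy.optimize import fsolve

from acidinvasion import (
    DimensionlessParams,
    classify_regime,
    classify_stability,
    critical_competition,
    enumerate_steady_states,
    homogeneous_jacobian,
    reaction_terms,
)
from acidinvasion.steady_states import residuals


def states_at(p, **kw):
    return {s.label: s for s in enumerate_steady_states(p, **kw)}


class TestEnumeration:
    def test_acid_monoculture_closed_form(self, defaults):
        ss1 = states_at(defaults)["SS1"]
        assert (ss1.S, ss1.T_A, ss1.T_M, ss1.L) == (0, 1, 0, 1)
        assert ss1.m_free

    def test_symmetric_coexistence_at_half_competition(self, defaults):
        ss3 = states_at(defaults.replace(c_MA=0.5, c_AM=0.5))["SS3"]
        assert np.allclose((ss3.T_A, ss3.T_M, ss3.L), 2 / 3)
        assert (ss3.S, ss3.M) == (0, 0)

    def test_degrader_stroma_state_infeasible_for_strong_stroma(self, defaults):
        ss5 = states_at(defaults)["SS5"]
        assert ss5.T_M == pytest.approx(-0.5)
        assert not ss5.feasible and ss5.stability == "not-applicable"

    def test_acid_stroma_coexistence_values(self, defaults):
        ss4 = states_at(defaults)["SS4"]
        assert ss4.S == pytest.approx((1 - 12.5) / (1 - 18.75), rel=1e-12)
        assert ss4.T_A == pytest.approx((1 - 1.5) / (1 - 18.75), rel=1e-12)
        assert ss4.S == pytest.approx(0.64789, abs=5e-6)
        assert ss4.T_A == pytest.approx(0.02817, abs=5e-6)
        assert ss4.T_M == 0 and ss4.m_free

    def test_degenerate_coexistence_denominator_flagged(self, defaults):
        ss3 = states_at(defaults.replace(c_MA=2.0, c_AM=0.5))["SS3"]
        assert not ss3.feasible
        assert "degenerate" in ss3.note

    def test_three_way_family_exists_only_at_unit_competition(self, defaults):
        fam = states_at(defaults.replace(c_MA=1.0, c_AM=1.0), ss6_family_T_A=0.04)["SS6"]
        assert "family" in fam.note
        assert np.allclose(residuals(fam, defaults.replace(c_MA=1.0, c_AM=1.0)), 0, atol=1e-12)
        rational = states_at(defaults.replace(c_MA=0.4, c_AM=0.7))["SS6"]
        assert "family" not in rational.note
        assert np.allclose(
            residuals(rational, defaults.replace(c_MA=0.4, c_AM=0.7)), 0, atol=1e-12
        )

    def test_trivial_state_behind_flag(self, defaults):
        assert "trivial" not in states_at(defaults)
        assert "trivial" in states_at(defaults, include_trivial=True)

    def test_residuals_vanish_for_all_feasible_states(self, rng):
        for _ in range(10):
            p = DimensionlessParams(
                delta=rng.uniform(8, 16), rho_L=rng.uniform(50, 90),
                kappa=rng.uniform(5, 15), c_S=rng.uniform(1.2, 1.8),
                c_MA=rng.uniform(0, 2), c_AM=rng.uniform(0, 2),
            )
            for ss in enumerate_steady_states(p):
                if ss.feasible:
                    assert np.max(np.abs(residuals(ss, p))) < 1e-12

    def test_no_feasible_equilibrium_missed_by_enumeration(self, rng):
        """Dense multi-start root search of the kinetics finds nothing
        beyond the closed-form catalogue (plus matrix-level freedom)."""
        for _ in range(10):
            p = DimensionlessParams(
                delta=rng.uniform(8, 16), rho_L=rng.uniform(50, 90),
                kappa=rng.uniform(5, 15), c_S=rng.uniform(1.2, 1.8),
                c_MA=rng.uniform(0, 1.9), c_AM=rng.uniform(0, 1.9),
            )
            known = [s for s in enumerate_steady_states(p, include_trivial=True)]
            fun = lambda v: np.array(reaction_terms(*v, p))
            for _ in range(100):
                start = rng.uniform(0, 1.2, 5)
                root, info, ier, _ = fsolve(fun, start, full_output=True)
                if ier != 1 or np.max(np.abs(fun(root))) > 1e-9:
                    continue
                if not np.all((root > -1e-8) & (root < 1.2)):
                    continue
                matched = False
                for ss in known:
                    ref = np.array(ss.values(m_star=root[4]))
                    if ss.label == "SS6" and "family" in ss.note:
                        # compare against the family member at this T_A
                        ta = root[1]
                        ref = np.array((1 - p.delta * ta, ta,
                                        1 - p.c_S - (1 - p.c_S * p.delta) * ta, ta, 0.0))
                    if np.allclose(root, ref, atol=1e-6):
                        matched = True
                        break
                # roots with both populations absent leave M free as well
                if not matched and abs(root[2]) < 1e-8:
                    for ss in known:
                        if np.allclose(root[:4], np.array(ss.values())[:4], atol=1e-6):
                            matched = True
                            break
                assert matched, (p, root)


class TestStability:
    def test_coexistence_stable_below_unit_competition(self, defaults):
        p = defaults.replace(c_MA=0.5, c_AM=0.5)
        ss3 = classify_stability(states_at(p)["SS3"], p)
        assert ss3.stability == "stable"
        assert ss3.leading_eigenvalue_real_part < 0

    def test_acid_monoculture_marginal_with_matrix_zero_mode(self, defaults):
        p = defaults.replace(c_AM=1.2)
        ss1 = classify_stability(states_at(p)["SS1"], p)
        assert ss1.stability == "marginal"
        assert ss1.nonmatrix_stability == "stable"
        # all eigenvalues other than the matrix zero mode are negative
        eig = np.sort(ss1.eigenvalues.real)
        assert np.all(eig[:-1] < 0) and abs(eig[-1]) < 1e-12

    @pytest.mark.parametrize("c_MA,c_AM", [(0.0, 0.0), (0.5, 1.5), (2.0, 2.0), (1.0, 0.3)])
    def test_degrader_monoculture_always_unstable(self, defaults, c_MA, c_AM):
        p = defaults.replace(c_MA=c_MA, c_AM=c_AM)
        ss2 = classify_stability(states_at(p)["SS2"], p)
        assert ss2.stability == "unstable"

    def test_infeasible_state_not_classified(self, defaults):
        ss5 = classify_stability(states_at(defaults)["SS5"], defaults)
        assert ss5.stability == "not-applicable"

    def test_jacobian_alias_matches_kinetics_jacobian(self, defaults):
        from acidinvasion import reaction_jacobian

        s = (0.2, 0.3, 0.1, 0.4, 0.5)
        assert np.array_equal(homogeneous_jacobian(s, defaults), reaction_jacobian(s, defaults))


class TestRegimes:
    @pytest.mark.parametrize(
        "c_MA,c_AM,expected",
        [
            (0.2, 0.7, "stable_coexistence"),
            (1.2, 0.7, "exclusion_of_TA"),
            (0.7, 1.2, "exclusion_of_TM"),
            (1.7, 1.7, "bistable"),
            (1.0, 0.5, "boundary"),
            (0.5, 1.0 + 1e-12, "boundary"),
        ],
    )
    def test_quadrant_labels(self, c_MA, c_AM, expected):
        assert classify_regime(c_MA, c_AM, tol=1e-9) == expected

    def test_regime_matches_stability_of_candidate_states(self, defaults):
        """Inside each open quadrant the linear stability of SS1/SS2/SS3
        reflects the scenario: coexistence stable only below (1,1), the
        acid monoculture stable (non-matrix) only for c_AM > 1."""
        for c_MA, c_AM in [(0.5, 0.5), (1.5, 0.5), (0.5, 1.5), (1.7, 1.7)]:
            p = defaults.replace(c_MA=c_MA, c_AM=c_AM)
            st = {k: classify_stability(v, p) for k, v in states_at(p).items()}
            if c_MA < 1 and c_AM < 1:
                assert st["SS3"].stability == "stable"
            else:
                assert st["SS3"].stability != "stable"
            ss1_ok = st["SS1"].nonmatrix_stability or st["SS1"].stability
            if c_AM > 1:
                assert ss1_ok == "stable"
            else:
                assert st["SS1"].stability == "unstable"
            assert st["SS2"].stability == "unstable"

    def test_negative_competition_rejected(self):
        with pytest.raises(ValueError):
            classify_regime(-0.1, 0.5)


class TestCriticalCompetition:
    def test_symmetric_coexistence_threshold_at_unity(self, defaults):
        c = critical_competition(defaults, "symmetric", target_state="SS3")
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_acid_pressure_axis_threshold_at_unity(self, defaults):
        c = critical_competition(defaults, "c_AM", other_value=0.5, target_state="SS3")
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_degrader_pressure_axis_limited_by_acid_sufficiency(self, defaults):
        """Along c_MA at c_AM = 0.5 the stroma-reinvasion mode crosses
        first: 1 - delta T_A* = 0 with T_A* = (1-c)/(1-c/2) gives c = 23/24."""
        c = critical_competition(defaults, "c_MA", other_value=0.5, target_state="SS3")
        assert c == pytest.approx(23.0 / 24.0, abs=1e-6)

    def test_acid_monoculture_onset_at_unity(self, defaults):
        c = critical_competition(defaults, "c_AM", target_state="SS1")
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_no_sign_change_reports_none(self, defaults):
        # SS1's non-matrix spectrum never crosses zero along c_MA
        assert critical_competition(defaults, "c_MA", target_state="SS1") is None

    def test_unknown_axis_rejected(self, defaults):
        with pytest.raises(ValueError):
            critical_competition(defaults, "c_XX")
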