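"""Steady-state model definitions, solver and flux-balance audits."""

import numpy as np
import pytest

from notchcis.models import (
    MODEL_IDS,
    ParameterSet,
    flux_balance_residual,
    integrate_to_steady,
    rhs,
    solve_steady_state,
    state_labels,
    states_close,
    total_activation,
)
from notchcis.scan import ScanConfig, sample_parameters

CIS_MODELS = ("M0", "M1", "M2a", "M2b", "M2c", "M2d")


class TestRhs:
    def test_unknown_model_raises(self):
        with pytest.raises(ValueError, match="unknown model"):
            rhs("M3", [1, 1, 1], ParameterSet())

    def test_state_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            rhs("M0", [1.0, 1.0, 1.0, 1.0], ParameterSet())

    def test_free_balance_is_equilibrium_without_binding(self, no_binding):
        # With k_on = 0 the free species balance at alpha/gamma and the
        # complex-free point is an exact fixed point.
        state = {"N": no_binding.alpha_N / no_binding.gamma_N,
                 "D": no_binding.alpha_D / no_binding.gamma_D, "C+": 0.0}
        assert np.allclose(rhs("M0", state, no_binding), 0.0)

    def test_trans_model_reduces_to_m2c_at_zero_trans(self, all_ones):
        state = [0.7, 1.3, 0.4, 0.2]
        d_cis = rhs("M2c", state, all_ones)
        d_tr = rhs("M2c_trans", state + [0.0], all_ones)
        assert np.allclose(d_tr[:4], d_cis)
        assert d_tr[4] == 0.0

    @pytest.mark.parametrize("model", ["M2c_trans", "M2c_trans_inhib"])
    def test_trans_variants_share_dynamics(self, model, all_ones):
        p = all_ones.replace(D_trans=0.8)
        d = rhs(model, [1.0, 1.0, 1.0, 1.0, 0.5], p)
        # dT/dt = k_on*N*D_trans - k_off*T - gamma_C+*T
        assert d[-1] == pytest.approx(1.0 * 0.8 - 0.5 - 0.5)

    def test_m2b_matches_independent_transcription(self, all_ones):
        # Second, term-by-term transcription of the M2b scheme
        # (N+D <-> C+, C+ + C+ -> C- with 2 C+ returned on dissociation),
        # written without the helper groupings of the implementation.
        p = all_ones.replace(alpha_N=1.0, alpha_D=1.0)
        y = np.array([1.0, 1.0, 1.0, 1.0])
        N, D, Cp, Cm = y
        expected = np.array([
            p.alpha_N - p.gamma_N * N - p.k_Cplus_on * N * D
            + p.k_Cplus_off * Cp,
            p.alpha_D - p.gamma_D * D - p.k_Cplus_on * N * D
            + p.k_Cplus_off * Cp,
            -p.gamma_Cplus * Cp + p.k_Cplus_on * N * D
            - p.k_Cplus_off * Cp - p.k_Cminus_on * Cp ** 2
            + 2.0 * p.k_Cminus_off * Cm,
            -p.gamma_Cminus * Cm + p.k_Cminus_on * Cp ** 2
            - p.k_Cminus_off * Cm,
        ])
        assert np.allclose(rhs("M2b", y, p), expected, rtol=0, atol=1e-15)

    def test_m2d_matches_independent_transcription(self, all_ones):
        p = all_ones
        y = np.array([0.5, 2.0, 0.3, 0.7])
        N, D, Cp, Cm = y
        expected = np.array([
            p.alpha_N - p.gamma_N * N - p.k_Cplus_on * N * D
            + p.k_Cplus_off * Cp - p.k_Cminus_on * N**2 * D**2
            + 2.0 * p.k_Cminus_off * Cm,
            p.alpha_D - p.gamma_D * D - p.k_Cplus_on * N * D
            + p.k_Cplus_off * Cp - p.k_Cminus_on * N**2 * D**2
            + 2.0 * p.k_Cminus_off * Cm,
            -p.gamma_Cplus * Cp + p.k_Cplus_on * N * D
            - p.k_Cplus_off * Cp,
            -p.gamma_Cminus * Cm + p.k_Cminus_on * N**2 * D**2
            - p.k_Cminus_off * Cm,
        ])
        assert np.allclose(rhs("M2d", y, p), expected, rtol=0, atol=1e-15)


class TestParameterSet:
    def test_rejects_nonpositive_production(self):
        with pytest.raises(ValueError, match="alpha_N"):
            ParameterSet(alpha_N=0.0)

    def test_rejects_negative_binding(self):
        with pytest.raises(ValueError, match="k_Cplus_on"):
            ParameterSet(k_Cplus_on=-1.0)

    def test_fixture_round_trips_through_json(self, all_ones):
        import json
        rebuilt = ParameterSet(**json.loads(json.dumps(all_ones.as_dict())))
        assert rebuilt == all_ones


class TestSolveSteadyState:
    def test_no_binding_closed_form(self, no_binding):
        ss = solve_steady_state("M0", no_binding)
        assert ss.converged
        assert ss.concentrations["N"] == pytest.approx(4.0)
        assert ss.concentrations["D"] == pytest.approx(2.0)
        assert ss.concentrations["C+"] == pytest.approx(0.0, abs=1e-12)

    def test_m0_symmetric_parameters_give_equal_species(self):
        p = ParameterSet(alpha_N=3.0, alpha_D=3.0, gamma_N=0.7, gamma_D=0.7,
                         k_Cplus_on=2.0, k_Cplus_off=0.5)
        ss = solve_steady_state("M0", p)
        assert ss.converged
        assert ss.concentrations["N"] == pytest.approx(
            ss.concentrations["D"], rel=1e-10)

    def test_m0_symmetry_under_nd_swap(self):
        p = ParameterSet(alpha_N=2.0, alpha_D=5.0, gamma_N=0.3, gamma_D=1.1)
        q = p.replace(alpha_N=p.alpha_D, alpha_D=p.alpha_N,
                      gamma_N=p.gamma_D, gamma_D=p.gamma_N)
        a = solve_steady_state("M0", p)
        b = solve_steady_state("M0", q)
        assert a.concentrations["N"] == pytest.approx(
            b.concentrations["D"], rel=1e-9)
        assert a.concentrations["C+"] == pytest.approx(
            b.concentrations["C+"], rel=1e-9)

    def test_matches_integration_oracle_on_fixture(self, all_ones):
        ss = solve_steady_state("M2c", all_ones)
        oracle = integrate_to_steady("M2c", all_ones, tol=1e-10)
        assert ss.converged and oracle.converged
        assert states_close(ss, oracle, "M2c", rtol=1e-6)

    def test_trans_model_reduction_invariant(self, m2c_nonmono):
        p = m2c_nonmono.replace(D_trans=0.0)
        cis = solve_steady_state("M2c", p)
        tr = solve_steady_state("M2c_trans", p)
        assert tr.converged
        for s in ("N", "D", "C+", "C-"):
            assert tr.concentrations[s] == pytest.approx(
                cis.concentrations[s], rel=1e-8, abs=1e-12)
        assert tr.concentrations["T"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("model", CIS_MODELS)
    def test_random_ensemble_nonnegative_and_balanced(self, model):
        cfg = ScanConfig(n_sets=25, seed=11)
        tol = 1e-10
        n_conv = 0
        for p in sample_parameters(cfg, model):
            ss = solve_steady_state(model, p, tol=tol)
            if not ss.converged:
                continue
            n_conv += 1
            vals = np.array(list(ss.concentrations.values()))
            assert np.all(vals >= 0)
            scale = max(1.0, float(np.max(np.abs(vals))))
            assert flux_balance_residual(model, ss, p) <= 1e-6 * scale
        assert n_conv >= 20  # the ensemble is overwhelmingly solvable

    def test_nonconvergence_is_reported_not_raised(self):
        # A strongly autocatalytic M2b corner has no steady state; the
        # solver must say so rather than raise or fabricate one.
        p = ParameterSet(alpha_N=100.0, alpha_D=100.0, gamma_N=0.01,
                         gamma_D=0.01, gamma_Cplus=0.01, gamma_Cminus=0.01,
                         k_Cplus_on=100.0, k_Cplus_off=0.01,
                         k_Cminus_on=100.0, k_Cminus_off=100.0)
        ss = solve_steady_state("M2b", p)
        if not ss.converged:
            assert ss.method == "integration_fallback"
        else:  # if a root exists it must be a genuine, physical one
            assert min(ss.concentrations.values()) >= 0


class TestIntegrateToSteady:
    def test_no_binding_limit(self, no_binding):
        ss = integrate_to_steady("M0", no_binding)
        assert ss.converged
        assert ss.concentrations["N"] == pytest.approx(4.0, rel=1e-6)
        assert ss.concentrations["C+"] == pytest.approx(0.0, abs=1e-8)

    def test_zero_horizon_returns_initial_condition(self, all_ones):
        ss = integrate_to_steady("M2c", all_ones, t_max=0.0)
        assert not ss.converged
        assert ss.concentrations["N"] == pytest.approx(1.0)
        assert ss.concentrations["C+"] == pytest.approx(1.0)

    @pytest.mark.parametrize("model", ["M0", "M2c", "M2c_trans"])
    def test_oracle_agrees_with_root_solver(self, model):
        cfg = ScanConfig(n_sets=10, seed=3)
        for p in sample_parameters(cfg, model):
            if model == "M2c_trans":
                p = p.replace(D_trans=1.0)
            a = solve_steady_state(model, p)
            b = integrate_to_steady(model, p, tol=1e-9)
            if a.converged and b.converged:
                assert states_close(a, b, model, rtol=1e-4)


class TestFluxBalance:
    def test_closed_form_m0_is_exact(self, no_binding):
        ss = solve_steady_state("M0", no_binding)
        assert flux_balance_residual("M0", ss, no_binding) < 1e-12

    def test_m2d_integration_state_balances(self, all_ones):
        ss = integrate_to_steady("M2d", all_ones, tol=1e-12)
        assert ss.converged
        assert flux_balance_residual("M2d", ss, all_ones) <= 1e-6

    def test_perturbed_state_fails_the_audit(self, all_ones):
        ss = solve_steady_state("M2c", all_ones)
        broken = dict(ss.concentrations)
        broken["N"] *= 1.5
        assert flux_balance_residual("M2c", broken, all_ones) > 1e-3


def test_total_activation_counts_only_activating_species():
    from notchcis.models import SteadyState
    ss = SteadyState({"N": 1, "D": 1, "C+": 0.4, "C-": 9.0, "T-": 5.0},
                     0.0, True, "root")
    assert total_activation("M2c_trans_inhib", ss) == pytest.approx(0.4)
    ss2 = SteadyState({"N": 1, "D": 1, "C+": 0.4, "C-": 9.0, "T": 0.6},
                      0.0, True, "root")
    assert total_activation("M2c_trans", ss2) == pytest.approx(1.0)


@pytest.mark.parametrize("model", MODEL_IDS)
def test_state_labels_are_consistent(model):
    labels = state_labels(model)
    assert labels[:2] == ("N", "D")
    assert "C+" in labels
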