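"""Kinetic core: right-hand side, exact vs numeric engines, steady state."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sflt1kin import (
    ParameterSet,
    Protocol,
    closed_form_solution,
    model_rhs,
    simulate,
    steady_state,
)

from conftest import random_parameter_sets


def make_params(**kw):
    base = dict(k_prod=1000.0, tau=0.5, k_out_Si=0.5, k_deg_Si=0.5, k_deg_Sx=0.1)
    base.update(kw)
    return ParameterSet(**base)


class TestParameterSet:
    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError, match="k_out_Si"):
            make_params(k_out_Si=-0.1)

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            make_params(k_prod=float("nan"))

    def test_json_round_trip(self, tmp_path):
        p = make_params()
        path = tmp_path / "p.json"
        p.to_json(path)
        assert ParameterSet.from_json(path) == p

    def test_unknown_json_key_rejected(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text('{"k_prod": 1, "tau": 0, "k_out_Si": 1, '
                        '"k_deg_Si": 1, "k_deg_Sx": 0, "bogus": 3}')
        with pytest.raises(ValueError, match="bogus"):
            ParameterSet.from_json(path)

    def test_missing_json_key_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ParameterSet.from_dict({"k_prod": 1.0})


class TestModelRhs:
    def test_empty_system_is_stationary(self):
        d = model_rhs(make_params(), (0.0, 0.0), u=0.0)
        assert d == (0.0, 0.0)

    def test_pure_production(self):
        d_si, _ = model_rhs(make_params(k_prod=1000.0), (0.0, 0.0), u=1.0)
        assert d_si == 1000.0

    def test_turnover_algebra(self):
        p = make_params(k_prod=0.0, k_out_Si=0.5, k_deg_Si=0.5, k_deg_Sx=0.2)
        d_si, d_sx = model_rhs(p, (100.0, 30.0), u=0.0)
        assert d_si == pytest.approx(-100.0)
        assert d_sx == pytest.approx(0.5 * 100.0 - 0.2 * 30.0)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            model_rhs(make_params(), (-1.0, 0.0), u=1.0)


class TestClosedForm:
    def test_zero_length_segment_returns_initial_condition(self):
        p = make_params()
        traj = closed_form_solution(p, 0.0, np.array([0.0]), state0=(40.0, 7.0))
        assert traj.S_i[0] == 40.0
        assert traj.S_x[0] == 7.0

    def test_no_production_decay_matches_textbook_form(self):
        # k_prod=0, k_deg_Sx=0: pure partitioning of the initial pool
        p = make_params(k_prod=0.0, k_out_Si=0.3, k_deg_Si=0.2, k_deg_Sx=0.0)
        s0 = 500.0
        t = np.linspace(0.0, 20.0, 41)
        traj = closed_form_solution(p, 20.0, t, state0=(s0, 0.0), u=0.0)
        a = 0.5
        phi = 0.3 / a
        np.testing.assert_allclose(traj.S_i, s0 * np.exp(-a * t), rtol=1e-12)
        np.testing.assert_allclose(traj.S_x, s0 * phi * (1 - np.exp(-a * t)),
                                   rtol=1e-12)

    def test_resonant_double_root_is_finite_and_continuous(self):
        # k_deg_Sx exactly equal to total turnover: degenerate t*exp branch
        p_res = make_params(k_out_Si=0.5, k_deg_Si=0.5, k_deg_Sx=1.0)
        p_near = make_params(k_out_Si=0.5, k_deg_Si=0.5, k_deg_Sx=1.0 + 1e-9)
        t = np.linspace(0.0, 24.0, 25)
        a = closed_form_solution(p_res, 24.0, t, state0=(100.0, 0.0), u=1.0)
        b = closed_form_solution(p_near, 24.0, t, state0=(100.0, 0.0), u=1.0)
        assert np.all(np.isfinite(a.S_x))
        np.testing.assert_allclose(a.S_x, b.S_x, rtol=1e-6)

    def test_matches_numeric_engine_on_constant_input(self):
        p = make_params(tau=0.0)
        proto = Protocol(kind="accumulation", horizon=10.0, history="zero")
        t = np.linspace(0.1, 10.0, 30)
        cf = closed_form_solution(p, 10.0, t, state0=(0.0, 0.0), u=1.0)
        num = simulate(p, proto, t, engine="numeric")
        np.testing.assert_allclose(cf.S_i, num.S_i, rtol=1e-6)
        np.testing.assert_allclose(cf.S_x, num.S_x, rtol=1e-6)


class TestSimulate:
    def test_delayed_onset_value(self):
        # production switched on at t=0 through a 0.5 h delay: at t=2 the
        # intracellular pool has only seen 1.5 h of input
        p = make_params(k_prod=1000.0, tau=0.5, k_out_Si=0.5, k_deg_Si=0.5)
        proto = Protocol(kind="accumulation", horizon=4.0, history="zero")
        traj = simulate(p, proto, np.array([2.0]))
        assert traj.S_i[0] == pytest.approx(1000.0 * (1 - np.exp(-1.5)), rel=1e-9)

    def test_ballistic_accumulation_without_sinks(self):
        p = make_params(tau=0.0, k_out_Si=0.0, k_deg_Si=0.0, k_deg_Sx=0.0)
        proto = Protocol(kind="accumulation", horizon=10.0, history="zero")
        t = np.array([1.0, 5.0, 10.0])
        traj = simulate(p, proto, t)
        np.testing.assert_allclose(traj.S_i, p.k_prod * t, rtol=1e-12)
        np.testing.assert_allclose(traj.S_x, 0.0, atol=1e-12)

    def test_linearity_in_k_prod(self):
        p = make_params()
        proto = Protocol(kind="accumulation", horizon=24.0, history="zero")
        t = np.linspace(0.5, 24.0, 20)
        a = simulate(p, proto, t)
        b = simulate(p.scaled("k_prod", 3.0), proto, t)
        for ch in ("S_i", "S_x", "cum_produced", "cum_secreted",
                   "cum_deg_i", "cum_deg_x"):
            np.testing.assert_allclose(getattr(b, ch), 3.0 * getattr(a, ch),
                                       rtol=1e-12, atol=1e-12)

    def test_delay_shifts_trajectory(self):
        # with zero history, the delayed system is the undelayed one shifted
        tau = 0.75
        p0 = make_params(tau=0.0)
        p1 = make_params(tau=tau)
        proto0 = Protocol(kind="accumulation", horizon=24.0, history="zero")
        proto1 = Protocol(kind="accumulation", horizon=24.0 + tau, history="zero")
        t = np.linspace(0.5, 24.0, 30)
        a = simulate(p0, proto0, t)
        b = simulate(p1, proto1, t + tau)
        np.testing.assert_allclose(b.S_i, a.S_i, rtol=1e-9)
        np.testing.assert_allclose(b.S_x, a.S_x, rtol=1e-9)

    def test_media_change_resets_extracellular_only(self):
        p = make_params()
        proto = Protocol(kind="accumulation", horizon=48.0,
                         media_events=[0.0, 24.0], history="steady_state")
        t = np.array([23.9, 24.0, 24.1, 48.0])
        traj = simulate(p, proto, t)
        assert traj.S_x[1] == pytest.approx(0.0, abs=1e-9)
        assert traj.S_x[0] > 100
        assert traj.S_i[1] == pytest.approx(traj.S_i[0], rel=1e-3)
        assert traj.mass_balance_error() < 1e-9
        # removed mass is the extracellular pool discarded at 24 h, which by
        # then is essentially at its plateau value
        assert traj.cum_removed[-1] == pytest.approx(traj.S_x[0], rel=1e-2)

    def test_event_outside_horizon_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            Protocol(kind="accumulation", horizon=10.0, media_events=[12.0])

    def test_grid_outside_horizon_rejected(self, params):
        proto = Protocol(kind="accumulation", horizon=10.0)
        with pytest.raises(ValueError, match="horizon"):
            simulate(params, proto, np.array([5.0, 11.0]))

    def test_long_time_convergence_to_steady_state(self):
        for p in random_parameter_sets(10, seed=5):
            ss = steady_state(p)
            T = 10.0 / p.turnover + p.tau
            proto = Protocol(kind="accumulation", horizon=T, history="zero")
            traj = simulate(p, proto, np.array([T]))
            assert abs(traj.S_i[-1] - ss.S_i_star) / ss.S_i_star < 1e-3


class TestEngineAgreement:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        k_out=st.floats(1e-3, 10.0), k_deg_i=st.floats(1e-3, 10.0),
        k_deg_x=st.floats(1e-3, 10.0), tau=st.floats(0.0, 4.0),
    )
    def test_exact_and_numeric_engines_agree(self, k_out, k_deg_i, k_deg_x, tau):
        p = ParameterSet(k_prod=1000.0, tau=tau, k_out_Si=k_out,
                         k_deg_Si=k_deg_i, k_deg_Sx=k_deg_x)
        proto = Protocol(kind="accumulation", horizon=48.0,
                         media_events=[0.0], history="steady_state")
        t = np.linspace(0.5, 48.0, 25)
        a = simulate(p, proto, t)
        b = simulate(p, proto, t, engine="numeric")
        for ch in ("S_i", "S_x"):
            x, y = getattr(a, ch), getattr(b, ch)
            scale = np.maximum(np.maximum(np.abs(x), np.abs(y)), 1e-6)
            assert np.max(np.abs(x - y) / scale) < 1e-6
        assert a.mass_balance_error() < 1e-6
        assert b.mass_balance_error() < 1e-6


class TestSteadyState:
    def test_equal_rates_split_production_evenly(self):
        ss = steady_state(ParameterSet(k_prod=60000.0, tau=0.5, k_out_Si=1.0,
                                       k_deg_Si=1.0, k_deg_Sx=0.0))
        assert ss.S_i_star == pytest.approx(30000.0)
        assert ss.secretion_flux_star == pytest.approx(30000.0)
        assert ss.fraction_secreted == pytest.approx(0.5)

    def test_no_degradation_means_everything_secreted(self):
        ss = steady_state(make_params(k_deg_Si=0.0))
        assert ss.fraction_secreted == pytest.approx(1.0)

    def test_fraction_secreted_ratio(self):
        ss = steady_state(make_params(k_out_Si=1.0, k_deg_Si=3.0))
        assert ss.fraction_secreted == pytest.approx(0.25)

    def test_zero_turnover_has_no_steady_state(self):
        with pytest.raises(ValueError, match="steady state"):
            steady_state(make_params(k_out_Si=0.0, k_deg_Si=0.0))
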