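"""Gating integration along waveforms and current reconstruction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import apclamp as ac
from apclamp.presets import GATE_N_STANDARD


def test_initial_state_matches_steady_states(ik1, ina):
    n0 = ac.initial_state(ik1, -80.0)
    assert n0[0] == pytest.approx(0.12912670817536034, abs=1e-10)
    assert abs(n0[0] - 0.1288) < 5e-4  # printed worked-example value
    mh = ac.initial_state(ina, -80.0)
    assert mh[0] == pytest.approx(0.08691110861545038, abs=1e-10)
    assert mh[1] == pytest.approx(0.29459635345012507, abs=1e-10)


def test_worked_segment_integration(worked_segment, ik1):
    """Integrating n across the printed first AP segment reproduces the
    published n_2 within rounding of the printed inputs."""
    g = ac.integrate_gating(worked_segment, ik1)
    n2 = g.x[0, -1]
    assert n2 == pytest.approx(0.12922022986799798, abs=1e-9)  # fine-step oracle
    assert abs(n2 - 0.1289) < 5e-4  # printed value


def test_constant_voltage_stays_at_steady_state(ik1):
    w = ac.VoltageWaveform(np.linspace(0, 5, 40), np.full(40, -60.0))
    g = ac.integrate_gating(w, ik1)
    x_inf = ac.steady_state(ik1.gates[0], -60.0)
    assert np.max(np.abs(g.x[0] - x_inf)) < 1e-9


def test_adaptive_agrees_with_exponential_euler_oracle(worked_segment, ik1):
    ga = ac.integrate_gating(worked_segment, ik1)
    ge = ac.integrate_gating(
        worked_segment, ik1, solver=ac.SolverConfig(method="expeuler", dt=1e-4)
    )
    assert np.max(np.abs(ga.x - ge.x)) < 1e-6


def test_halving_tolerance_changes_result_less_than_tolerance(worked_segment, ik1):
    tol = 1e-8
    a = ac.integrate_gating(worked_segment, ik1, solver=ac.SolverConfig(rtol=tol))
    b = ac.integrate_gating(worked_segment, ik1, solver=ac.SolverConfig(rtol=tol / 2))
    assert abs(a.x[0, -1] - b.x[0, -1]) < tol


def test_temp_factor_scales_approach_rate_not_steady_state(ik1):
    """Time to reach 1 - 1/e of the gap to steady state scales as
    1/temp_factor; the steady state itself does not move."""
    w = ac.VoltageWaveform(np.linspace(0, 80, 8001), np.full(8001, -50.0))
    times = {}
    for factor in (1.0, 2.0):
        model = ik1.with_temp_factor(factor)
        g = ac.integrate_gating(w, model, x0=np.array([0.0]))
        x_inf = ac.steady_state(model.gates[0], -50.0)
        target = (1 - 1 / np.e) * x_inf
        times[factor] = w.t[np.argmax(g.x[0] >= target)]
        assert abs(g.x[0, -1] - x_inf) < 1e-6  # same steady state
    assert times[1.0] / times[2.0] == pytest.approx(2.0, rel=0.01)


def test_gates_stay_bounded_over_full_ap(param_ap, ina):
    g = ac.integrate_gating(param_ap, ina)
    assert np.all(g.x >= 0.0)
    assert np.all(g.x <= 1.0)


@given(
    st.floats(-100.0, 60.0),
    st.floats(0.0, 1.0),
)
def test_ode_forms_are_algebraically_identical(V, x):
    """-(alpha+beta) x + alpha == alpha (1-x) - beta x."""
    a = ac.eval_rate(GATE_N_STANDARD.alpha, V)
    b = ac.eval_rate(GATE_N_STANDARD.beta, V)
    lhs = -(a + b) * x + a
    rhs = a * (1 - x) - b * x
    assert lhs == pytest.approx(rhs, abs=1e-12)


def test_x0_validation(worked_segment, ik1):
    with pytest.raises(ac.DomainError):
        ac.integrate_gating(worked_segment, ik1, x0=np.array([1.5]))
    with pytest.raises(ac.DomainError):
        ac.integrate_gating(worked_segment, ik1, x0=np.array([0.1, 0.2]))


def test_compute_current_zero_at_reversal(ik1):
    w = ac.VoltageWaveform([0.0, 1.0, 2.0], [-110.0, -110.0, -110.0])
    g, c = ac.ap_clamp(w, ik1)
    assert np.allclose(c.I, 0.0, atol=1e-15)


def test_compute_current_ghk_reference_composition(ik2):
    # a * n^4 * GHK(V - E_K) at n = 0.283, V = -50 mV
    I = ik2.current_at(-50.0, np.array([0.283]))
    expected = 1.3 * 0.283**4 * ac.ghk_drive(-50.0, -110.0, 26.7)
    assert I == pytest.approx(expected, rel=1e-12)
    assert I == pytest.approx(0.1562, abs=5e-4)


def test_fully_activated_linear_relation(ik1):
    V = np.array([-120.0, -110.0, -60.0, 0.0, 40.0])
    I = ik1.current_at(V, np.ones((1, V.size)))
    # mS/cm^2 * mV -> mA/cm^2 carries a factor 1e-3
    assert np.allclose(I, 36.0e-3 * (V + 110.0), rtol=1e-12)


def test_compute_current_grid_mismatch_rejected(ik1):
    w = ac.VoltageWaveform([0.0, 1.0, 2.0], [-80.0, -70.0, -60.0])
    g = ac.integrate_gating(w, ik1)
    w2 = ac.VoltageWaveform([0.0, 1.0], [-80.0, -70.0])
    with pytest.raises(ac.GridMismatchError):
        ac.compute_current(ik1, g, w2)


def test_ap_clamp_contract_on_shared_grid(param_ap, ik1, ik2):
    g1, c1 = ac.ap_clamp(param_ap, ik1)
    g2, c2 = ac.ap_clamp(param_ap, ik2)
    assert np.array_equal(c1.t, c2.t)
    assert not np.allclose(c1.I, c2.I)  # different models, different traces


def test_ap_clamp_at_reversal_gives_zero_current(ik1):
    w = ac.VoltageWaveform(np.linspace(0, 2, 20), np.full(20, ik1.E))
    _, c = ac.ap_clamp(w, ik1)
    assert np.allclose(c.I, 0.0, atol=1e-15)


def test_dense_output_matches_samples(param_ap, ik2):
    g = ac.integrate_gating(param_ap, ik2)
    mid = 0.5 * (param_ap.t[:-1] + param_ap.t[1:])
    dense_at_nodes = g.at(param_ap.t)
    assert np.max(np.abs(dense_at_nodes - g.x)) < 1e-9
    dense_mid = g.at(mid)
    assert np.all((dense_mid >= 0) & (dense_mid <= 1))


def test_current_model_validation():
    with pytest.raises(ac.DomainError):
        ac.CurrentModel("bad", (GATE_N_STANDARD,), "ghk", E=-110.0, g_max=36.0)
    with pytest.raises(ac.DomainError):
        ac.CurrentModel("bad", (GATE_N_STANDARD,), "linear", E=-110.0, a=1.3)
    with pytest.raises(ac.DomainError):
        ac.CurrentModel("bad", (), "linear", E=-110.0, g_max=36.0)
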