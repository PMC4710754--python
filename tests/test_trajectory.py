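"""I-V trajectories, gate extrema, tangency, overlap charge."""

import numpy as np
import pytest

import apclamp as ac
from apclamp.engine import CurrentTrace
from apclamp.trajectory import (
    gate_peak,
    iv_trajectory,
    overlap_charge,
    tangency_gap,
)


def test_trajectory_pairs_samples_in_time_order(param_ap, ik2):
    g, c = ac.ap_clamp(param_ap, ik2)
    traj = iv_trajectory(param_ap, c, gating=g, model=ik2)
    assert np.array_equal(traj.V, param_ap.V)
    assert np.array_equal(traj.I, c.I)


def test_trajectory_grid_mismatch_rejected(param_ap, ik2):
    _, c = ac.ap_clamp(param_ap, ik2)
    w2 = ac.VoltageWaveform(param_ap.t[:-1], param_ap.V[:-1])
    with pytest.raises(ac.GridMismatchError):
        iv_trajectory(w2, c)


def test_linear_model_with_constant_gates_lies_on_a_line(ik1):
    V = np.linspace(-100.0, 20.0, 60)
    w = ac.VoltageWaveform(np.arange(60) * 0.1, V)
    x = np.full((1, 60), 0.4)
    c = CurrentTrace(w.t, np.asarray(ik1.current_at(V, x)))
    traj = iv_trajectory(w, c)
    expected = 36.0e-3 * 0.4**4 * (V + 110.0)
    assert np.allclose(traj.I, expected, rtol=1e-12)


def test_ghk_model_with_constant_gates_lies_on_fixed_gate_curve(ik2):
    V = np.linspace(-100.0, 20.0, 60)
    w = ac.VoltageWaveform(np.arange(60) * 0.1, V)
    c = CurrentTrace(w.t, np.asarray(ik2.current_at(V, np.full((1, 60), 0.3))))
    _, fixed = ac.fixed_gate_iv(ik2, 0.3, V)
    assert np.allclose(c.I, fixed, rtol=1e-12)


def test_gate_peak_monotone_trace_returns_last_sample():
    t = np.linspace(0, 1, 11)
    g = ac.GatingTrace(t, np.linspace(0.1, 0.9, 11)[None, :], ("n",))
    t_pk, x_pk = gate_peak(g, "n")
    assert t_pk == 1.0 and x_pk == 0.9


def test_gate_peak_constructed_peak_and_tie_breaking():
    t = np.arange(7.0)
    x = np.array([0.1, 0.4, 0.8, 0.5, 0.8, 0.2, 0.1])
    g = ac.GatingTrace(t, x[None, :], ("n",))
    t_pk, x_pk = gate_peak(g, "n")
    assert t_pk == 2.0  # earliest of the tied maxima
    assert x_pk == 0.8


def test_gate_peak_refinement_polishes_the_discrete_maximum(mech_ap, ik2, mech_clamp_ik2):
    g, _ = mech_clamp_ik2
    t0, x0 = gate_peak(g, "n")
    t1, x1 = gate_peak(g, "n", refine=True, waveform=mech_ap, model=ik2)
    assert abs(t1 - t0) <= float(np.max(np.diff(mech_ap.t)))
    assert x1 >= x0 - 1e-12  # the true extremum cannot be below a sample


def test_fixed_gate_iv_zero_cases(ik2):
    _, I = ac.fixed_gate_iv(ik2, 0.0, np.linspace(-100, 40, 20))
    assert np.allclose(I, 0.0)
    _, I = ac.fixed_gate_iv(ik2, 0.5, [ik2.E])
    assert I[0] == pytest.approx(0.0, abs=1e-12)


def test_fixed_gate_iv_reference_value(ik2):
    _, I = ac.fixed_gate_iv(ik2, 0.283, [-50.0])
    assert I[0] == pytest.approx(0.1562, abs=5e-4)


def test_tangency_gap_small_at_gate_extremum(mech_ap, ik2, mech_clamp_ik2):
    g, c = mech_clamp_ik2
    traj = iv_trajectory(mech_ap, c, gating=g, model=ik2)
    t_pk, _ = gate_peak(g, "n", refine=True, waveform=mech_ap, model=ik2)
    gap, fixed = tangency_gap(traj, ik2, t_pk, gate="n")
    assert gap < 1e-3 * abs(fixed)


def test_tangency_gap_zero_for_constant_gates(ik2):
    V = np.linspace(-90.0, 0.0, 80)
    t = np.arange(80) * 0.05
    w = ac.VoltageWaveform(t, V)
    x = np.full((1, 80), 0.3)
    c = CurrentTrace(t, np.asarray(ik2.current_at(V, x)))
    traj = ac.IVTrajectory(t, V, c.I, gating=ac.GatingTrace(t, x, ("n",)))
    gap, fixed = tangency_gap(traj, ik2, t_star=2.0, gate="n")
    assert gap < 1e-9 * abs(fixed)


def test_tangency_gap_large_when_gate_changes_fast(mech_ap, ik2, mech_clamp_ik2):
    g, c = mech_clamp_ik2
    traj = iv_trajectory(mech_ap, c, gating=g, model=ik2)
    # during the upstroke n grows quickly: trajectory and fixed-gate
    # slopes must disagree
    i_up = int(np.argmax(mech_ap.V))
    t_fast = float(mech_ap.t[i_up] )
    gap, fixed = tangency_gap(traj, ik2, t_fast, gate="n")
    assert gap > 0.05 * abs(fixed)


def test_tangency_gap_undefined_where_voltage_is_flat(ik2):
    t = np.arange(10.0)
    V = np.full(10, -60.0)
    x = np.linspace(0.1, 0.5, 10)[None, :]
    traj = ac.IVTrajectory(t, V, np.linspace(0, 1, 10),
                           gating=ac.GatingTrace(t, x, ("n",)))
    with pytest.raises(ac.DomainError):
        tangency_gap(traj, ik2, t_star=5.0, gate="n")


def _pulse(t, start, width, amp):
    return np.where((t >= start) & (t < start + width), amp, 0.0)


def test_overlap_disjoint_pulses_is_zero():
    t = np.linspace(0, 10, 1001)
    na = CurrentTrace(t, -_pulse(t, 1.0, 2.0, 1.0))
    k = CurrentTrace(t, _pulse(t, 6.0, 2.0, 1.0))
    res = overlap_charge(na, k)
    assert res.overlap_charge == 0.0
    assert res.fraction == 0.0


def test_overlap_identical_traces_equals_full_charge():
    t = np.linspace(0, 10, 1001)
    na = CurrentTrace(t, -_pulse(t, 1.0, 2.0, 1.0))
    k = CurrentTrace(t, _pulse(t, 1.0, 2.0, 1.0))
    res = overlap_charge(na, k, floor_fraction=0.0)
    assert res.overlap_charge == pytest.approx(res.na_charge, rel=1e-12)
    assert res.fraction == pytest.approx(1.0, rel=1e-12)


def test_overlap_half_overlapping_equal_pulses():
    """An Na pulse whose second half coincides with a K pulse overlaps by
    half the pulse charge (trapezoid on the constructed rectangles)."""
    dt = 0.01
    t = np.arange(0, 10 + dt / 2, dt)
    na = CurrentTrace(t, -_pulse(t, 1.0, 2.0, 1.0))
    k = CurrentTrace(t, _pulse(t, 2.0, 2.0, 1.0))
    res = overlap_charge(na, k, floor_fraction=0.0)
    q_na = np.trapezoid(np.abs(na.I), t)
    q_ov = np.trapezoid(np.minimum(np.abs(na.I), np.maximum(k.I, 0)), t)
    assert res.overlap_charge == pytest.approx(q_ov, rel=1e-12)
    assert res.overlap_charge == pytest.approx(q_na / 2, rel=2 * dt)


def test_overlap_bounded_by_smaller_total_charge(mech_ap, ina, ik2, mech_clamp_ik2):
    _, c_k = mech_clamp_ik2
    _, c_na = ac.ap_clamp(mech_ap, ina)
    res = overlap_charge(c_na, c_k)
    assert 0.0 <= res.overlap_charge <= min(res.na_charge, res.k_charge)
    assert 0.0 <= res.fraction <= 1.0


def test_overlap_grid_mismatch_rejected():
    t = np.linspace(0, 10, 101)
    na = CurrentTrace(t, -np.ones(101))
    k = CurrentTrace(t + 0.5, np.ones(101))
    with pytest.raises(ac.GridMismatchError):
        overlap_charge(na, k)
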