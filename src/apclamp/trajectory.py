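"""Current-voltage trajectories, gate extrema, tangency, charge overlap.

During an AP the state (V(t), I(t)) traces a loop in the I-V plane.  At
any instant where a single activation gate passes through an extremum
(dx/dt = 0) while the voltage is still moving, the chain rule gives

    dI/dV |_trajectory = amplitude * x^p * dG/dV,

i.e. the trajectory is tangent to the fixed-gate (instantaneous) I-V
curve drawn at the extremal gate value.  For a GHK-driven K+ current
this places the model's open-channel rectification directly on top of
the trajectory around the tangency point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .engine import CurrentModel, CurrentTrace, GatingTrace
from .errors import DegenerateInputError, DomainError, GridMismatchError
from .rates import eval_rate
from .waveform import VoltageWaveform

__all__ = [
    "IVTrajectory",
    "iv_trajectory",
    "gate_peak",
    "fixed_gate_iv",
    "tangency_gap",
    "overlap_charge",
    "OverlapResult",
]


@dataclass(frozen=True)
class IVTrajectory:
    """Time-ordered (V, I) pairs of an AP-clamp run.

    Optionally carries the source waveform and gating trace, which lets
    slope computations evaluate the underlying continuous solution
    instead of only the samples.
    """

    t: np.ndarray
    V: np.ndarray
    I: np.ndarray
    waveform: VoltageWaveform | None = None
    gating: GatingTrace | None = None
    model: CurrentModel | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        V = np.asarray(self.V, dtype=float)
        I = np.asarray(self.I, dtype=float)
        for name, arr in (("t", t), ("V", V), ("I", I)):
            object.__setattr__(self, name, arr)
        if not (t.shape == V.shape == I.shape) or t.ndim != 1:
            raise GridMismatchError("trajectory arrays must share one grid")
        if not np.all(np.isfinite(I)):
            raise DomainError("trajectory currents must be finite")


def iv_trajectory(
    w: VoltageWaveform,
    c: CurrentTrace,
    gating: GatingTrace | None = None,
    model: CurrentModel | None = None,
) -> IVTrajectory:
    """Pair the waveform with a current trace into an I-V trajectory."""
    if c.t.shape != w.t.shape or not np.allclose(c.t, w.t, rtol=0, atol=1e-12):
        raise GridMismatchError("current trace and waveform grids differ")
    return IVTrajectory(w.t, w.V, c.I, waveform=w, gating=gating, model=model)


def _gate_rhs(model: CurrentModel, gate_index: int, w: VoltageWaveform,
              g: GatingTrace):
    """dx/dt of one gate as a function of t, using the dense solution."""
    scheme = model.gates[gate_index]
    k = model.temp_factor

    def xdot(t: float) -> float:
        V = w.voltage_at(t)
        a = eval_rate(scheme.alpha, V)
        b = eval_rate(scheme.beta, V)
        x = float(g.at(t)[gate_index])
        return k * (a - (a + b) * x)

    return xdot


def gate_peak(
    g: GatingTrace,
    gate: str,
    refine: bool = False,
    waveform: VoltageWaveform | None = None,
    model: CurrentModel | None = None,
) -> tuple[float, float]:
    """Time and value of a gate's maximum, ties broken by earliest time.

    With ``refine=True`` (requires the dense solution plus the source
    waveform and model) the discrete maximum is polished by solving
    dx/dt = 0 in its bracketing interval, giving the true extremum of
    the continuous solution rather than the nearest sample.
    """
    x = g[gate]
    i = int(np.argmax(x))  # argmax returns the first (earliest) maximum
    t_star, x_star = float(g.t[i]), float(x[i])
    if not refine:
        return t_star, x_star
    if g.dense is None or waveform is None or model is None:
        raise DomainError("refine=True needs a dense gating trace, the "
                          "waveform, and the model")
    if i == 0 or i == len(g.t) - 1:
        return t_star, x_star  # boundary maximum: nothing to polish
    gi = g.gate_names.index(gate)
    xdot = _gate_rhs(model, gi, waveform, g)
    lo, hi = float(g.t[i - 1]), float(g.t[i + 1])
    f_lo, f_hi = xdot(lo), xdot(hi)
    if f_lo > 0 >= f_hi:
        t_ref = float(brentq(xdot, lo, hi, xtol=1e-12))
        return t_ref, float(g.at(t_ref)[gi])
    return t_star, x_star


def fixed_gate_iv(model: CurrentModel, x_star: float, V_grid) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous I-V curve with every gate frozen at ``x_star``:
    I(V) = amplitude * x*^sum(p) * drive(V)."""
    if not (0.0 <= x_star <= 1.0):
        raise DomainError("gate value must lie in [0, 1]")
    V = np.atleast_1d(np.asarray(V_grid, dtype=float))
    frozen = np.full((len(model.gates), V.size), x_star)
    return V, np.asarray(model.current_at(V, frozen), dtype=float)


def _fixed_gate_slope(model: CurrentModel, x_star: float, V: float, dV: float) -> float:
    _, I = fixed_gate_iv(model, x_star, [V - dV, V + dV])
    return float((I[1] - I[0]) / (2 * dV))


def tangency_gap(
    traj: IVTrajectory,
    model: CurrentModel | None = None,
    t_star: float | None = None,
    gate: str | None = None,
    h: float | None = None,
) -> tuple[float, float]:
    """Difference between the trajectory slope and the fixed-gate I-V slope
    at time ``t_star``, both by centred finite differences.

    Returns ``(gap, fixed_slope)`` in (mA/cm^2)/mV.  At a gate extremum
    the exact slopes coincide, so the gap measures only the
    finite-difference residual, which shrinks at second order in ``h``
    (default: the median sample spacing).

    When the trajectory carries its waveform and a dense gating trace,
    I and V are evaluated from the continuous solution at t* +/- h;
    otherwise centred differences on the nearest interior sample are
    used.
    """
    model = model or traj.model
    if model is None:
        raise DomainError("tangency_gap needs the current model")
    if t_star is None:
        raise DomainError("tangency_gap needs the evaluation time t_star")
    if not (traj.t[0] < t_star < traj.t[-1]):
        raise DomainError("t_star must lie strictly inside the trace")
    if h is None:
        h = float(np.median(np.diff(traj.t)))
    gate_names = model.gate_names
    gi = gate_names.index(gate) if gate else 0

    dense_ok = traj.waveform is not None and traj.gating is not None \
        and traj.gating.dense is not None
    if dense_ok:
        w, g = traj.waveform, traj.gating
        hh = min(h, t_star - float(w.t[0]), float(w.t[-1]) - t_star)
        tm, tp = t_star - hh, t_star + hh
        Vm, Vp = w.voltage_at(tm), w.voltage_at(tp)
        if abs(Vp - Vm) < 1e-12:
            raise DomainError("dV/dt vanishes at t_star: trajectory slope undefined")
        Im = model.current_at(Vm, g.at(tm))
        Ip = model.current_at(Vp, g.at(tp))
        traj_slope = float((Ip - Im) / (Vp - Vm))
        x_star = float(g.at(t_star)[gi])
        V_star = float(w.voltage_at(t_star))
        dV = Vp - Vm
    else:
        i = int(np.argmin(np.abs(traj.t - t_star)))
        i = min(max(i, 1), traj.t.size - 2)
        dV = traj.V[i + 1] - traj.V[i - 1]
        if abs(dV) < 1e-12:
            raise DomainError("dV/dt vanishes at t_star: trajectory slope undefined")
        traj_slope = float((traj.I[i + 1] - traj.I[i - 1]) / dV)
        if traj.gating is None:
            raise DomainError("tangency_gap needs the gating trace")
        x_star = float(traj.gating.x[gi, i])
        V_star = float(traj.V[i])

    # matching the FD step of the fixed-gate slope to the trajectory's
    # voltage step keeps both truncation errors at the same order in h
    fixed = _fixed_gate_slope(model, x_star, V_star, dV=abs(dV) / 2.0)
    return abs(traj_slope - fixed), fixed


@dataclass(frozen=True)
class OverlapResult:
    """Charge overlap of an inward and an outward current."""

    overlap_charge: float  # uC/cm^2
    na_charge: float  # uC/cm^2, total |inward| charge
    k_charge: float  # uC/cm^2, total outward charge
    fraction: float  # overlap / na_charge


def overlap_charge(
    ina: CurrentTrace,
    ik: CurrentTrace,
    floor_fraction: float = 0.01,
) -> OverlapResult:
    """Temporal overlap charge of a (negative, inward) Na+ trace and a
    (positive, outward) K+ trace on a shared grid.

    Integrates ``min(|I_Na|, I_K+)`` by the trapezoid rule over samples
    where both magnitudes exceed ``floor_fraction`` of their respective
    peaks (numerical tails are excluded); reports the overlap charge in
    uC/cm^2 (mA/cm^2 x ms) and its fraction of the total Na+ charge.
    """
    if ina.t.shape != ik.t.shape or not np.allclose(ina.t, ik.t, rtol=0, atol=1e-12):
        raise GridMismatchError("current traces do not share a grid")
    if not (0 <= floor_fraction < 1):
        raise DomainError("floor_fraction must lie in [0, 1)")
    a = np.abs(np.minimum(ina.I, 0.0))  # inward magnitude
    b = np.maximum(ik.I, 0.0)  # outward part
    if a.max() == 0 or b.max() == 0:
        both = np.zeros_like(a)
    else:
        mask = (a >= floor_fraction * a.max()) & (b >= floor_fraction * b.max())
        both = np.where(mask, np.minimum(a, b), 0.0)
    t = ina.t
    q_overlap = float(np.trapezoid(both, t))
    q_na = float(np.trapezoid(a, t))
    q_k = float(np.trapezoid(b, t))
    if q_na == 0:
        raise DegenerateInputError("Na trace carries no inward charge")
    return OverlapResult(q_overlap, q_na, q_k, q_overlap / q_na)
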