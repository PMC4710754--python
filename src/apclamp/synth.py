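"""Synthetic data: MFB-like action potentials and noisy activation points.

Two AP sources are provided on purpose:

* :func:`parametric_ap` — a shape-controlled double-exponential spike
  (fast, analytic, no channel model involved);
* :func:`simulate_membrane_ap` — a mechanistic fixture solving the
  current-balance equation C dV/dt = -(I_ion + I_leak) + I_stim with
  the package's own Na+/K+ models, which yields a self-consistent
  regenerative spike.

Both emulate the salient features of a mossy-fiber-bouton AP (rest near
-80 mV, overshoot above 0 mV, ~1 ms width) so that every pipeline can
be exercised without any recorded data.  Neither is a quantitative fit
to a recorded waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import CurrentModel, initial_state
from .errors import DomainError, SolverError
from .rates import GateScheme, RateLaw, eval_rate, steady_state
from .renorm import ActivationPoints
from .permeation import ghk_drive
from .waveform import VoltageWaveform

__all__ = [
    "APShapeParams",
    "parametric_ap",
    "simulate_membrane_ap",
    "default_leak",
    "synth_activation_points",
]


@dataclass(frozen=True)
class APShapeParams:
    """Shape parameters of the parametric AP (mV, ms)."""

    V_rest: float = -80.0
    V_peak: float = 32.0
    t_foot: float = 0.3  # latency before the upstroke
    tau_rise: float = 0.15
    tau_decay: float = 0.45
    ahp_depth: float = 4.0  # afterhyperpolarization below rest; 0 disables
    tau_ahp: float = 0.8
    duration: float = 6.0
    dt: float = 0.039

    def __post_init__(self) -> None:
        if self.V_peak <= self.V_rest:
            raise DomainError("V_peak must exceed V_rest")
        for name in ("tau_rise", "tau_decay", "tau_ahp", "duration", "dt"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.t_foot < 0 or self.ahp_depth < 0:
            raise DomainError("t_foot and ahp_depth must be non-negative")


def parametric_ap(p: APShapeParams = APShapeParams()) -> VoltageWaveform:
    """Deterministic double-exponential spike waveform.

    The depolarizing transient is exp(-t/tau_decay) - exp(-t/tau_rise),
    rescaled so the maximum equals ``V_peak`` exactly; the optional AHP
    is a delayed alpha-function dip below rest.  The first sample is
    exactly ``V_rest`` and the waveform must be back within 0.5 mV of
    rest by ``duration``.
    """
    n = int(np.floor(p.duration / p.dt)) + 1
    t = p.dt * np.arange(n)
    s = np.clip(t - p.t_foot, 0.0, None)
    if p.tau_rise >= p.tau_decay:
        raise DomainError("tau_rise must be smaller than tau_decay")
    spike = np.where(s > 0, np.exp(-s / p.tau_decay) - np.exp(-s / p.tau_rise), 0.0)
    t_pk = np.log(p.tau_decay / p.tau_rise) * p.tau_rise * p.tau_decay / (
        p.tau_decay - p.tau_rise
    )
    spike_pk = np.exp(-t_pk / p.tau_decay) - np.exp(-t_pk / p.tau_rise)
    shape = spike / spike_pk
    if p.ahp_depth > 0:
        u = np.clip(s - t_pk, 0.0, None) / p.tau_ahp
        shape = shape - (p.ahp_depth / (p.V_peak - p.V_rest)) * u * np.exp(1.0 - u)
    V = p.V_rest + (p.V_peak - p.V_rest) * shape / shape.max()
    if abs(V[-1] - p.V_rest) > 0.5:
        raise DomainError(
            f"duration {p.duration:g} ms too short: V(end) = {V[-1]:.2f} mV "
            f"has not returned to within 0.5 mV of rest"
        )
    return VoltageWaveform(t, V, label="parametric MFB-like AP (synthetic)")


def _total_steady_current(models, V: float) -> float:
    return float(sum(m.current_at(V, initial_state(m, V)) for m in models))


def default_leak(models, V_rest: float = -80.0, E_leak: float = -90.0):
    """Leak conductance (mS/cm^2) that balances the models' steady
    currents at ``V_rest``: g_L (V_rest - E_leak) = -sum I_ion(V_rest)."""
    if V_rest == E_leak:
        raise DomainError("V_rest must differ from E_leak")
    # steady current is mA/cm^2 -> x1e3 to uA/cm^2 so g comes out in mS/cm^2
    g = -_total_steady_current(models, V_rest) * 1e3 / (V_rest - E_leak)
    if g <= 0:
        raise DomainError(
            "steady ionic current at V_rest has the wrong sign for a "
            "passive leak; choose a different E_leak"
        )
    return float(g)


def simulate_membrane_ap(
    models,
    leak_g: float | None = None,
    leak_E: float = -90.0,
    C: float = 1.0,
    stim_amp: float = 30.0,
    stim_dur: float = 0.5,
    stim_start: float = 0.3,
    duration: float = 6.0,
    dt: float = 1e-3,
    dt_out: float = 0.039,
    V0: float | None = None,
    seed: int = 0,
) -> VoltageWaveform:
    """Mechanistic synthetic AP from the current-balance equation.

    Fixed-step RK4 at ``dt`` (ms) on C dV/dt = -(sum I_ion + g_L (V -
    E_L)) + I_stim(t), gates integrated alongside; the returned
    waveform is downsampled to ``dt_out``.  ``leak_g`` defaults to
    :func:`default_leak` at the initial potential.  Entirely
    deterministic; ``seed`` is accepted for interface uniformity with
    the other generators.

    Units: C in uF/cm^2, currents mA/cm^2, stimulus uA/cm^2 (positive =
    depolarizing), so dV/dt = (uA/cm^2) / (uF/cm^2) = mV/ms.
    """
    del seed  # deterministic generator
    models = list(models)
    if C <= 0 or dt <= 0 or dt_out <= 0:
        raise DomainError("C, dt and dt_out must be positive")
    if V0 is None:
        V0 = -80.0
    if leak_g is None:
        leak_g = default_leak(models, V_rest=V0, E_leak=leak_E)

    gate_schemes: list[tuple[int, GateScheme, float]] = []
    offsets = []
    off = 0
    for mi, m in enumerate(models):
        offsets.append(off)
        for g in m.gates:
            gate_schemes.append((mi, g, m.temp_factor))
            off += 1
    n_gates = off

    def deriv(t: float, y: np.ndarray) -> np.ndarray:
        V = y[0]
        x = y[1:]
        dy = np.empty_like(y)
        I_ion = 0.0
        for mi, m in enumerate(models):
            o = offsets[mi]
            I_ion += m.current_at(V, x[o : o + len(m.gates)])
        # I_ion is mA/cm^2 -> x1e3 to uA/cm^2; leak mS/cm^2 * mV = uA/cm^2
        I_stim = stim_amp if stim_start <= t < stim_start + stim_dur else 0.0
        dy[0] = (-(I_ion * 1e3 + leak_g * (V - leak_E)) + I_stim) / C
        for j, (mi, g, k) in enumerate(gate_schemes):
            a = eval_rate(g.alpha, V)
            b = eval_rate(g.beta, V)
            dy[1 + j] = k * (a - (a + b) * x[j])
        return dy

    y = np.empty(1 + n_gates)
    y[0] = V0
    for mi, m in enumerate(models):
        y[1 + offsets[mi] : 1 + offsets[mi] + len(m.gates)] = initial_state(m, V0)

    n_steps = int(round(duration / dt))
    stride = max(1, int(round(dt_out / dt)))
    ts = [0.0]
    Vs = [float(y[0])]
    t = 0.0
    for i in range(n_steps):
        k1 = deriv(t, y)
        k2 = deriv(t + dt / 2, y + dt / 2 * k1)
        k3 = deriv(t + dt / 2, y + dt / 2 * k2)
        k4 = deriv(t + dt, y + dt * k3)
        y = y + (dt / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (i + 1) * dt
        if not np.isfinite(y[0]) or abs(y[0]) > 500:
            raise SolverError(
                f"membrane simulation blew up at t={t:g} ms "
                f"(V={y[0]:g} mV, max |dV/dt| so far exceeded)"
            )
        y[1:] = np.clip(y[1:], 0.0, 1.0)
        if (i + 1) % stride == 0 or i == n_steps - 1:
            if t > ts[-1]:
                ts.append(t)
                Vs.append(float(y[0]))
    return VoltageWaveform(
        np.asarray(ts), np.asarray(Vs), label="mechanistic MFB-like AP (synthetic)"
    )


def synth_activation_points(
    scheme: GateScheme,
    B_true: float,
    V_grid,
    noise_sd: float,
    seed: int,
    generator: str = "ghk_norm",
    E_lin: float = -85.0,
    E_ghk: float = -104.0,
    Vt: float = 26.5,
) -> ActivationPoints:
    """Generate an activation-point set from a known slope voltage B_true.

    ``generator='ghk_norm'`` emits the open probabilities themselves,
    po = x_inf(V; B_true)^p, tagged as GHK-normalized; ``'linear_norm'``
    emits what a linear (V - E_lin) normalization of GHK-rectifying
    currents would have produced, po = x^p * GHK(V, E_ghk, Vt) /
    (V - E_lin), rescaled to a maximum of one and tagged accordingly.
    Gaussian noise of sd ``noise_sd`` is added and truncated at zero.
    Deterministic for a fixed ``seed``.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if generator not in ("ghk_norm", "linear_norm"):
        raise DomainError(f"unknown generator {generator!r}")
    V = np.atleast_1d(np.asarray(V_grid, dtype=float))
    beta = RateLaw(scheme.beta.form, scheme.beta.A, scheme.beta.V0, B_true)
    s = GateScheme(scheme.name, scheme.alpha, beta, scheme.exponent)
    po = np.asarray(steady_state(s, V), dtype=float) ** s.exponent
    if generator == "linear_norm":
        drive = np.asarray(ghk_drive(V, E_ghk, Vt), dtype=float)
        po = po * drive / (V - E_lin)
        po = po / po.max()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        po = np.clip(po + rng.normal(0.0, noise_sd, size=po.shape), 0.0, None)
    if generator == "linear_norm":
        return ActivationPoints(V, po, "linear", E_ref=E_lin)
    return ActivationPoints(V, po, "ghk", E_ref=E_ghk, Vt_ref=Vt)
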