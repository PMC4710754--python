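"""Hodgkin-Huxley rate laws, steady states, time constants, Q10 scaling.

Units are fixed package-wide: membrane potential in mV, time in ms, rates
in ms^-1 (linoid amplitudes in ms^-1 mV^-1), current density in mA/cm^2,
conductance density in mS/cm^2.

A gating variable ``x`` obeys ``dx/dt = alpha(V) (1 - x) - beta(V) x``,
equivalently ``dx/dt = -(alpha + beta) x + alpha``.  Each of ``alpha`` and
``beta`` is one of three closed forms commonly used for voltage-gated
channels: the linoid (linear-over-expm1), the exponential, and the
logistic (Boltzmann) form.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DegenerateInputError, DomainError

__all__ = [
    "RateForm",
    "RateLaw",
    "GateScheme",
    "eval_rate",
    "steady_state",
    "time_constant",
    "q10_factor",
    "activation_curve",
]

#: half-width (mV) of the guard band around a linoid's removable
#: singularity inside which the analytic limit -A*B is returned
SINGULARITY_BAND = 1e-6


class RateForm(str, Enum):
    """Closed forms of voltage-dependent transition rates."""

    LINOID = "linoid"  # A (V - V0) / (exp(-(V - V0)/B) - 1)
    EXPONENTIAL = "exponential"  # A exp(-(V - V0)/B)
    LOGISTIC = "logistic"  # A / (exp(-(V - V0)/B) + 1)


@dataclass(frozen=True)
class RateLaw:
    """One voltage-dependent transition rate.

    Parameters
    ----------
    form : RateForm
        Functional form (see :class:`RateForm`).
    A : float
        Amplitude, ms^-1 (exponential/logistic) or ms^-1 mV^-1 (linoid).
    V0 : float
        Offset voltage, mV.
    B : float
        Slope voltage, mV.  Must be nonzero.
    """

    form: RateForm
    A: float
    V0: float
    B: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", RateForm(self.form))
        if self.B == 0:
            raise DomainError("rate-law slope voltage B must be nonzero")
        for name in ("A", "V0", "B"):
            if not np.isfinite(getattr(self, name)):
                raise DomainError(f"rate-law parameter {name} must be finite")

    def __call__(self, V):
        return eval_rate(self, V)


@dataclass(frozen=True)
class GateScheme:
    """One gating variable: its alpha/beta rate laws and the power to
    which it enters the current expression (n^4, m^3, h^1, ...)."""

    name: str
    alpha: RateLaw
    beta: RateLaw
    exponent: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.exponent, (int, np.integer)) and self.exponent >= 1):
            raise DomainError("gate exponent must be a positive integer")


def _check_V(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise DomainError("membrane potential must be finite")
    return V


def eval_rate(law: RateLaw, V):
    """Evaluate a rate law at membrane potential ``V`` (mV), in ms^-1.

    Accepts scalars or arrays.  The linoid form has a removable
    singularity at ``V = V0``; within ``SINGULARITY_BAND`` of it the
    analytic limit ``-A*B`` is returned, which keeps the evaluation
    continuous and free of catastrophic cancellation.
    """
    V = _check_V(V)
    u = (V - law.V0) / law.B
    if law.form is RateForm.LINOID:
        with np.errstate(over="ignore", invalid="ignore"):
            denom = np.expm1(-u)
            out = np.where(
                np.abs(V - law.V0) < SINGULARITY_BAND,
                -law.A * law.B,
                law.A * (V - law.V0) / np.where(denom == 0.0, 1.0, denom),
            )
    elif law.form is RateForm.EXPONENTIAL:
        out = law.A * np.exp(-u)
    else:  # logistic
        out = law.A / (np.exp(-u) + 1.0)
    return out if out.ndim else float(out)


def steady_state(scheme: GateScheme, V):
    """Steady-state gate value x_inf(V) = alpha / (alpha + beta), in [0, 1].

    Independent of any common scaling of alpha and beta (hence of
    temperature factors).
    """
    a = np.asarray(eval_rate(scheme.alpha, V), dtype=float)
    b = np.asarray(eval_rate(scheme.beta, V), dtype=float)
    s = a + b
    if np.any(s <= 0):
        raise DegenerateInputError(
            f"alpha + beta must be positive for gate {scheme.name!r}"
        )
    out = a / s
    return out if out.ndim else float(out)


def time_constant(scheme: GateScheme, V, temp_factor: float = 1.0):
    """Gate relaxation time constant tau = 1 / [temp_factor (alpha + beta)], ms.

    ``temp_factor`` multiplies both rates uniformly, so it scales tau
    without moving the steady state.
    """
    if not (np.isfinite(temp_factor) and temp_factor > 0):
        raise DomainError("temp_factor must be positive and finite")
    a = np.asarray(eval_rate(scheme.alpha, V), dtype=float)
    b = np.asarray(eval_rate(scheme.beta, V), dtype=float)
    s = a + b
    if np.any(s <= 0):
        raise DegenerateInputError(
            f"alpha + beta must be positive for gate {scheme.name!r}"
        )
    out = 1.0 / (temp_factor * s)
    return out if out.ndim else float(out)


def q10_factor(Q10: float, T_ref: float, T_target: float) -> float:
    """Rate scale factor Q10^((T_target - T_ref)/10) for temperatures in deg C.

    Multiplying every alpha and beta of a model by this factor
    extrapolates its kinetics from ``T_ref`` to ``T_target``.
    """
    if not (np.isfinite(Q10) and Q10 > 0):
        raise DomainError("Q10 must be positive and finite")
    if not (np.isfinite(T_ref) and np.isfinite(T_target)):
        raise DomainError("temperatures must be finite")
    return float(Q10 ** ((T_target - T_ref) / 10.0))


def activation_curve(scheme: GateScheme, V_grid):
    """Steady-state open probability x_inf(V)^exponent on a voltage grid.

    Returns ``(V, p_o)`` as two aligned arrays.
    """
    V = np.atleast_1d(np.asarray(V_grid, dtype=float))
    if V.size == 0:
        raise DegenerateInputError("voltage grid must be non-empty")
    x = np.asarray(steady_state(scheme, V), dtype=float)
    return V, x**scheme.exponent
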