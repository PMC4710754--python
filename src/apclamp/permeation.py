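"""Thermal voltage, Nernst potentials, and driving-force functions.

Two driving-force conventions are supported for the open-channel
(fully activated) current-voltage relation of a perfectly selective
channel:

* linear:  I proportional to (V - E), the classical ohmic assumption;
* GHK:     I proportional to the constant-field (Goldman-Hodgkin-Katz)
  factor ``(V/Vt) (exp((V-E)/Vt) - 1) / (exp(V/Vt) - 1)``, which
  rectifies outward whenever the internal concentration exceeds the
  external one (E < 0 for a monovalent cation).

The GHK factor is kept dimensionless; the mA/cm^2 amplitude lives on
the current model.  Valence is fixed at +1 (K+, Na+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ELEMENTARY_CHARGE_C",
    "ZERO_CELSIUS_K",
    "IonConditions",
    "thermal_voltage",
    "nernst",
    "ghk_drive",
    "linear_drive",
]

# CODATA 2018 exact values
BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19
ZERO_CELSIUS_K = 273.15

#: |V| guard band (mV) inside which the GHK factor uses its V -> 0 limit
_GHK_BAND = 1e-6


def thermal_voltage(T_celsius: float) -> float:
    """Thermal voltage kT/q in mV at temperature ``T_celsius`` (deg C).

    ~26.7 mV at 37 deg C, ~26.5 mV at 34 deg C.
    """
    if not np.isfinite(T_celsius) or T_celsius <= -ZERO_CELSIUS_K:
        raise DomainError("temperature must be finite and above absolute zero")
    T_K = T_celsius + ZERO_CELSIUS_K
    return BOLTZMANN_J_PER_K * T_K / ELEMENTARY_CHARGE_C * 1e3


def nernst(C_out: float, C_in: float, Vt: float) -> float:
    """Reversal potential E = Vt ln(C_out/C_in) in mV for a monovalent cation.

    Concentrations in mM (any common unit: only the ratio matters).
    """
    if not (C_out > 0 and C_in > 0):
        raise DomainError("concentrations must be positive")
    if not (np.isfinite(Vt) and Vt > 0):
        raise DomainError("thermal voltage must be positive")
    return float(Vt * np.log(C_out / C_in))


def ghk_drive(V, E: float, Vt: float):
    """Dimensionless GHK driving factor.

    ``(V/Vt) (exp((V-E)/Vt) - 1) / (exp(V/Vt) - 1)``; at V = 0 the
    removable singularity is filled with the analytic limit
    ``exp(-E/Vt) - 1``.  Sign equals sign(V - E); strictly increasing
    in V.  Accepts scalar or array V.
    """
    if not (np.isfinite(Vt) and Vt > 0):
        raise DomainError("thermal voltage must be positive")
    if not np.isfinite(E):
        raise DomainError("reversal potential must be finite")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise DomainError("membrane potential must be finite")
    with np.errstate(over="ignore", invalid="ignore"):
        num = np.expm1((V - E) / Vt)
        den = np.expm1(V / Vt)
        out = np.where(
            np.abs(V) < _GHK_BAND,
            np.expm1(-E / Vt),
            (V / Vt) * num / np.where(den == 0.0, 1.0, den),
        )
    return out if out.ndim else float(out)


def linear_drive(V, E: float):
    """Ohmic driving force V - E in mV."""
    V = np.asarray(V, dtype=float)
    out = V - E
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class IonConditions:
    """Ionic conditions of one monovalent species and the quantities
    derived from them (thermal voltage and Nernst reversal potential)."""

    species: str
    C_out: float  # mM
    C_in: float  # mM
    T: float  # deg C
    Vt: float = field(init=False)  # mV
    E: float = field(init=False)  # mV

    def __post_init__(self) -> None:
        vt = thermal_voltage(self.T)
        object.__setattr__(self, "Vt", vt)
        object.__setattr__(self, "E", nernst(self.C_out, self.C_in, vt))
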