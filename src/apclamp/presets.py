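"""Built-in rate-law catalogue, model presets, and YAML config I/O.

The shipped preset family ``engel_jonas_mfb`` carries the published
Hodgkin-Huxley-type description of the delayed-rectifier K+ current and
the fast Na+ current of hippocampal mossy-fiber boutons (MFBs):

* ``ik_model1`` — I_K = g_K n^4 (V - E_K), g_K = 36 mS/cm^2,
  E_K = -110 mV, the original ohmic driving force; kinetics
  extrapolated from 34 to 37 deg C (Q10 = 2.2, factor 1.27).
* ``ik_model2`` — I_K = a n^4 GHK(V - E_K), a = 1.3 mA/cm^2, with the
  revised (four-fold steeper) beta_n slope voltage of 20 mV.
* ``ina`` — I_Na = g_Na m^3 h (V - E_Na), g_Na = 110 mS/cm^2,
  E_Na = 62 mV; kinetics extrapolated from 23 to 37 deg C (factor 2.8).

Rate laws are data, not code: any other cell's model can be declared in
a YAML file with the same schema.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .engine import CurrentModel
from .errors import ConfigError
from .permeation import IonConditions
from .rates import GateScheme, RateLaw

__all__ = [
    "ALPHA_N",
    "BETA_N_STANDARD",
    "BETA_N_REVISED",
    "ALPHA_M",
    "BETA_M",
    "ALPHA_H",
    "BETA_H",
    "GATE_N_STANDARD",
    "GATE_N_REVISED",
    "GATE_M",
    "GATE_H",
    "MFB_K_CONDITIONS",
    "FIG2_RENORM_PRESET",
    "get_model",
    "model_presets",
    "load_model",
    "dump_model",
]

# ---------------------------------------------------------------- rate laws

ALPHA_N = RateLaw("linoid", A=-0.01, V0=-55.0, B=10.0)
BETA_N_STANDARD = RateLaw("exponential", A=0.125, V0=-65.0, B=80.0)
BETA_N_REVISED = RateLaw("exponential", A=0.125, V0=-65.0, B=20.0)
ALPHA_M = RateLaw("linoid", A=-93.8, V0=105.0, B=17.7)
BETA_M = RateLaw("exponential", A=0.17, V0=0.0, B=23.3)
ALPHA_H = RateLaw("exponential", A=0.00035, V0=0.0, B=18.7)
BETA_H = RateLaw("logistic", A=6.6, V0=-17.7, B=13.3)

GATE_N_STANDARD = GateScheme("n", ALPHA_N, BETA_N_STANDARD, exponent=4)
GATE_N_REVISED = GateScheme("n", ALPHA_N, BETA_N_REVISED, exponent=4)
GATE_M = GateScheme("m", ALPHA_M, BETA_M, exponent=3)
GATE_H = GateScheme("h", ALPHA_H, BETA_H, exponent=1)

# ------------------------------------------------------------- ionic setup

#: MFB K+ conditions at 37 deg C: K_o = 2.5 mM, K_i = 155 mM -> E_K ~ -110 mV
MFB_K_CONDITIONS = IonConditions("K", C_out=2.5, C_in=155.0, T=37.0)

#: Activation-curve renormalization constants for the MFB K+ data
#: recorded at 34 deg C: the original linear normalization used
#: E_K = -85 mV; the GHK renormalization uses E_K = -104 mV
#: (K_o = 2.5 mM, K_i = 125 mM) and kT/q = 26.5 mV.
FIG2_RENORM_PRESET = {"E_lin": -85.0, "E_ghk": -104.0, "Vt": 26.5}

RENORM_PRESETS = {"geiger_jonas_fig2": FIG2_RENORM_PRESET}

# ----------------------------------------------------------- model presets

_MODELS = {
    "ik_model1": CurrentModel(
        name="ik_model1",
        gates=(GATE_N_STANDARD,),
        driving="linear",
        g_max=36.0,
        E=-110.0,
        temp_factor=1.27,
    ),
    "ik_model2": CurrentModel(
        name="ik_model2",
        gates=(GATE_N_REVISED,),
        driving="ghk",
        a=1.3,
        E=-110.0,
        Vt=26.7,
        temp_factor=1.27,
    ),
    "ina": CurrentModel(
        name="ina",
        gates=(GATE_M, GATE_H),
        driving="linear",
        g_max=110.0,
        E=62.0,
        temp_factor=2.8,
    ),
}

PRESET_FAMILY = "engel_jonas_mfb"


def model_presets() -> tuple[str, ...]:
    """Names of the built-in model presets."""
    return tuple(_MODELS)


def get_model(name: str) -> CurrentModel:
    """Look up a built-in model preset (``ik_model1``, ``ik_model2``,
    ``ina``; the ``engel_jonas_mfb/`` family prefix is accepted)."""
    key = name.split("/")[-1]
    if key not in _MODELS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(_MODELS)}"
        )
    return _MODELS[key]


# ------------------------------------------------------------- YAML schema

_RATE_KEYS = {"form", "A", "V0", "B"}
_GATE_KEYS = {"name", "exponent", "alpha", "beta"}
_MODEL_KEYS = {"name", "driving", "gates", "E", "g_max", "a", "Vt", "temp_factor"}


def _require_keys(d: dict, allowed: set, required: set, what: str) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"{what} must be a mapping")
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {what}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"missing key(s) {sorted(missing)} in {what}")


def _rate_from_dict(d: dict, what: str) -> RateLaw:
    _require_keys(d, _RATE_KEYS, _RATE_KEYS, what)
    try:
        return RateLaw(d["form"], float(d["A"]), float(d["V0"]), float(d["B"]))
    except ValueError as exc:
        raise ConfigError(f"invalid rate law in {what}: {exc}") from exc


def _gate_from_dict(d: dict) -> GateScheme:
    _require_keys(d, _GATE_KEYS, _GATE_KEYS, "gate")
    name = str(d["name"])
    return GateScheme(
        name,
        _rate_from_dict(d["alpha"], f"gate {name} alpha"),
        _rate_from_dict(d["beta"], f"gate {name} beta"),
        exponent=int(d["exponent"]),
    )


def load_model(source) -> CurrentModel:
    """Load a :class:`CurrentModel` from a YAML file path or a preset name."""
    if isinstance(source, str) and not source.endswith((".yaml", ".yml")):
        if not Path(source).exists():
            return get_model(source)
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"model file not found: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "model" not in doc:
        raise ConfigError(f"{path}: expected a top-level 'model' mapping")
    m = doc["model"]
    _require_keys(m, _MODEL_KEYS, {"name", "driving", "gates", "E"}, "model")
    gates = tuple(_gate_from_dict(g) for g in m["gates"])
    try:
        return CurrentModel(
            name=str(m["name"]),
            gates=gates,
            driving=str(m["driving"]),
            E=float(m["E"]),
            g_max=None if m.get("g_max") is None else float(m["g_max"]),
            a=None if m.get("a") is None else float(m["a"]),
            Vt=None if m.get("Vt") is None else float(m["Vt"]),
            temp_factor=float(m.get("temp_factor", 1.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_model(model: CurrentModel, path) -> None:
    """Write a model as a YAML file loadable by :func:`load_model`."""
    doc = {
        "model": {
            "name": model.name,
            "driving": model.driving,
            "E": model.E,
            "temp_factor": model.temp_factor,
            "gates": [
                {
                    "name": g.name,
                    "exponent": g.exponent,
                    "alpha": {"form": g.alpha.form.value, "A": g.alpha.A,
                              "V0": g.alpha.V0, "B": g.alpha.B},
                    "beta": {"form": g.beta.form.value, "A": g.beta.A,
                             "V0": g.beta.V0, "B": g.beta.B},
                }
                for g in model.gates
            ],
        }
    }
    if model.driving == "linear":
        doc["model"]["g_max"] = model.g_max
    else:
        doc["model"]["a"] = model.a
        doc["model"]["Vt"] = model.Vt
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
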