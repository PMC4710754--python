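"""Activation-curve renormalization under the GHK driving force.

Activation curves of voltage-gated K+ channels have traditionally been
obtained by dividing a family of current records by the ohmic driving
force (V - E_K).  If the open channel actually follows the constant-field
(GHK) current-voltage relation, that linear normalization flattens the
curve.  The pipeline here undoes it:

1. ``exclude_voltages`` — drop strongly depolarized points (default
   V >= +50 mV) where voltage-dependent block by internal Na+ cannot be
   ruled out;
2. ``strip_linear_norm`` — multiply by (V - E_lin) to recover values
   proportional to the raw currents;
3. ``ghk_renormalize`` — divide by the GHK driving factor and rescale
   (default: maximum to one).

The result is a markedly steeper open-probability curve.  Within the
n^4 description, the steepening is captured by refitting the slope
voltage B of beta_n = A exp(-(V - V0)/B); ``fit_beta_slope`` provides a
least-squares estimate of B (the published revision chose B by
inspection — the fit is this package's principled surrogate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateInputError, DomainError, SolverError
from .permeation import ghk_drive
from .rates import GateScheme, RateLaw, steady_state

__all__ = [
    "ActivationPoints",
    "exclude_voltages",
    "strip_linear_norm",
    "ghk_renormalize",
    "fit_beta_slope",
    "BetaSlopeFit",
    "read_points",
    "write_points",
]

logger = logging.getLogger(__name__)

_ZERO_DRIVE_TOL = 1e-9


@dataclass(frozen=True)
class ActivationPoints:
    """A set of (V, p_o) activation points with normalization provenance.

    ``norm`` records how the values were produced: ``linear`` (divided
    by V - E_ref), ``ghk`` (divided by GHK(V - E_ref) with thermal
    voltage Vt_ref), or ``raw`` (proportional to current).
    """

    V: np.ndarray  # mV
    po: np.ndarray  # dimensionless, >= 0
    norm: str  # 'linear' | 'ghk' | 'raw'
    E_ref: float | None = None  # mV
    Vt_ref: float | None = None  # mV, ghk only

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        po = np.asarray(self.po, dtype=float)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "po", po)
        if V.ndim != 1 or V.shape != po.shape or V.size == 0:
            raise DomainError("V and po must be equal-length non-empty 1-D arrays")
        if not (np.all(np.isfinite(V)) and np.all(np.isfinite(po))):
            raise DomainError("activation points must be finite")
        if np.any(po < 0):
            raise DomainError("open probabilities must be non-negative")
        if self.norm not in ("linear", "ghk", "raw"):
            raise DomainError(f"unknown normalization {self.norm!r}")
        if self.norm in ("linear", "ghk") and self.E_ref is None:
            raise DomainError(f"{self.norm} normalization requires E_ref")
        if self.norm == "ghk" and self.Vt_ref is None:
            raise DomainError("ghk normalization requires Vt_ref")

    def __len__(self) -> int:
        return int(self.V.size)


def exclude_voltages(points: ActivationPoints, V_max: float = 50.0) -> ActivationPoints:
    """Retain points with V < ``V_max`` (mV).

    The default +50 mV cut removes potentials where a voltage-dependent
    partial block of I_K by internal Na+ cannot be excluded.
    """
    keep = points.V < V_max
    if not np.any(keep):
        raise DegenerateInputError("no activation points left below V_max")
    removed = int(len(points) - keep.sum())
    if removed:
        logger.info("exclude_voltages: removed %d point(s) at V >= %g mV",
                    removed, V_max)
    return replace(points, V=points.V[keep], po=points.po[keep])


def strip_linear_norm(points: ActivationPoints, E_lin: float) -> ActivationPoints:
    """Undo a linear (V - E_lin) normalization: po_raw = po * (V - E_lin).

    Fails on any point at V = E_lin, where the linear driving force is
    zero and the normalization cannot be inverted.
    """
    if points.norm != "linear":
        raise DomainError(f"expected linear-normalized points, got {points.norm!r}")
    drive = points.V - E_lin
    if np.any(np.abs(drive) < _ZERO_DRIVE_TOL):
        raise DegenerateInputError(
            f"point at V = E_lin = {E_lin:g} mV cannot be unnormalized"
        )
    return ActivationPoints(points.V, points.po * drive, "raw")


def ghk_renormalize(
    points: ActivationPoints,
    E_ghk: float,
    Vt: float,
    rescale: str = "max_to_one",
) -> ActivationPoints:
    """Normalize raw-current points by the GHK driving factor.

    po_ghk = po_raw / GHK(V, E_ghk, Vt); with ``rescale='max_to_one'``
    (default) the result is then divided by its maximum so the
    most-activated point is 1; ``rescale='none'`` leaves the scale.
    """
    if points.norm != "raw":
        raise DomainError(f"expected raw points, got {points.norm!r}")
    if rescale not in ("max_to_one", "none"):
        raise DomainError(f"unknown rescale mode {rescale!r}")
    drive = np.asarray(ghk_drive(points.V, E_ghk, Vt), dtype=float)
    if np.any(np.abs(drive) < _ZERO_DRIVE_TOL):
        raise DegenerateInputError(
            f"point at V = E_ghk = {E_ghk:g} mV has zero GHK driving force"
        )
    po = points.po / drive
    if np.any(po < 0):
        raise DomainError("negative open probability after GHK renormalization")
    if rescale == "max_to_one":
        top = po.max()
        if top <= 0:
            raise DegenerateInputError("cannot rescale an all-zero point set")
        po = po / top
    return ActivationPoints(points.V, po, "ghk", E_ref=E_ghk, Vt_ref=Vt)


@dataclass(frozen=True)
class BetaSlopeFit:
    """Result of :func:`fit_beta_slope`."""

    B: float  # fitted slope voltage, mV
    scale: float  # fitted amplitude multiplier
    rss: float  # residual sum of squares
    n_points: int


def fit_beta_slope(
    points: ActivationPoints,
    template: GateScheme,
    B0: float = 40.0,
) -> BetaSlopeFit:
    """Least-squares estimate of the beta slope voltage B from GHK-normalized
    activation points.

    Fits ``po ~ c * x_inf(V; B)^p`` where x_inf uses the template's
    alpha law and a beta law equal to the template's with slope voltage
    B free; all other parameters stay at the template's values.  The
    free amplitude ``c`` makes the estimate invariant to any overall
    rescaling of the input (max-to-one included).
    """
    if points.norm != "ghk":
        raise DomainError("fit_beta_slope expects ghk-normalized points")
    if len(points) < 4:
        raise DegenerateInputError("need at least 4 points to fit the slope")
    V = points.V
    po = points.po

    def curve(B: float) -> np.ndarray:
        beta = RateLaw(template.beta.form, template.beta.A, template.beta.V0, B)
        scheme = GateScheme(template.name, template.alpha, beta, template.exponent)
        return np.asarray(steady_state(scheme, V)) ** template.exponent

    def residuals(p: np.ndarray) -> np.ndarray:
        logB, c = p
        return c * curve(float(np.exp(logB))) - po

    res = least_squares(
        residuals,
        x0=np.array([np.log(B0), 1.0]),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
    )
    if not res.success:
        raise SolverError(f"beta-slope fit did not converge: {res.message}")
    B_hat = float(np.exp(res.x[0]))
    return BetaSlopeFit(
        B=B_hat,
        scale=float(res.x[1]),
        rss=float(np.sum(res.fun**2)),
        n_points=len(points),
    )


# ----------------------------------------------------------------- text I/O

def read_points(path, norm: str = "linear", E_ref=None, Vt_ref=None) -> ActivationPoints:
    """Read (voltage_mV, po) points from delimited text (CSV/whitespace).

    Normalization provenance is supplied by the caller (the file format
    carries data, not semantics).
    """
    path = Path(path)
    V, po = [], []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip().replace("−", "-")
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) < 2:
            continue
        try:
            v, p = float(parts[0]), float(parts[1])
        except ValueError:
            continue  # header line
        V.append(v)
        po.append(p)
    if not V:
        raise DegenerateInputError(f"{path}: no numeric rows found")
    return ActivationPoints(np.asarray(V), np.asarray(po), norm,
                            E_ref=E_ref, Vt_ref=Vt_ref)


def write_points(points: ActivationPoints, path, header=None) -> None:
    """Write activation points as CSV with a provenance comment."""
    lines = [f"# apclamp activation points; norm={points.norm}"
             f" E_ref={points.E_ref} Vt_ref={points.Vt_ref}"]
    if header:
        lines += [f"# {h}" for h in np.atleast_1d(header)]
    lines.append("voltage_mV,po")
    for v, p in zip(points.V, points.po):
        lines.append(f"{float(v)!r},{float(p)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
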