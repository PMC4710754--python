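"""Digitized voltage waveforms: I/O, validation, interpolation, resampling.

An AP-clamp command waveform is an ordered polyline of (t_i, V_i)
samples.  The method is defined on the raw polyline — adjacent samples
are connected by straight lines and no smoothing is applied — so
interpolation here is strictly piecewise linear and exact at the nodes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError, WaveformValidationError

__all__ = ["VoltageWaveform", "read_waveform", "write_waveform"]

_DIALECT_SEP = {"csv": ",", "tsv": "\t", "whitespace": None}
# Unicode minus (U+2212) and en-dash sometimes survive digitization
_MINUS_RE = re.compile("[−–]")


@dataclass(frozen=True)
class VoltageWaveform:
    """Ordered (t, V) samples of a membrane-potential waveform.

    ``t`` in ms, strictly increasing; ``V`` in mV; both finite;
    at least two samples.
    """

    t: np.ndarray
    V: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        V = np.asarray(self.V, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "V", V)
        if t.ndim != 1 or V.ndim != 1 or t.shape != V.shape:
            raise WaveformValidationError("t and V must be 1-D arrays of equal length")
        if t.size < 2:
            raise WaveformValidationError("a waveform needs at least two samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(V))):
            raise WaveformValidationError("waveform samples must be finite")
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            i = int(bad[0])
            raise WaveformValidationError(
                f"sample times must be strictly increasing; violation at row "
                f"{i + 2} (t[{i}]={t[i]:g} -> t[{i + 1}]={t[i + 1]:g} ms)"
            )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def span(self) -> float:
        """Total duration t_last - t_first in ms."""
        return float(self.t[-1] - self.t[0])

    def voltage_at(self, t):
        """Piecewise-linear interpolation V(t); exact at sample points.

        ``t`` (scalar or array) must lie within [t_first, t_last]; no
        extrapolation is performed.
        """
        tq = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(tq)):
            raise DomainError("query time must be finite")
        if np.any(tq < self.t[0]) or np.any(tq > self.t[-1]):
            raise DomainError(
                f"query time outside waveform range "
                f"[{self.t[0]:g}, {self.t[-1]:g}] ms"
            )
        out = np.interp(tq, self.t, self.V)
        return out if out.ndim else float(out)

    def slope_at(self, t: float) -> float:
        """dV/dt (mV/ms) of the segment containing ``t`` (right-continuous)."""
        if not (self.t[0] <= t <= self.t[-1]):
            raise DomainError("query time outside waveform range")
        i = min(int(np.searchsorted(self.t, t, side="right")) - 1, len(self) - 2)
        i = max(i, 0)
        return float((self.V[i + 1] - self.V[i]) / (self.t[i + 1] - self.t[i]))

    def resample(self, dt: float) -> "VoltageWaveform":
        """Resample on a uniform grid of spacing ``dt`` over the full span.

        Both endpoints are preserved exactly (the last grid interval may
        be shorter than ``dt``).
        """
        if not (np.isfinite(dt) and dt > 0):
            raise DomainError("dt must be positive")
        if dt >= self.span:
            raise DomainError("dt must be smaller than the waveform span")
        n = int(np.floor(self.span / dt + 1e-12))
        grid = self.t[0] + dt * np.arange(n + 1)
        if grid[-1] < self.t[-1] - 1e-12 * max(1.0, abs(self.t[-1])):
            grid = np.append(grid, self.t[-1])
        else:
            grid[-1] = self.t[-1]
        return VoltageWaveform(grid, self.voltage_at(grid), label=self.label)

    def shifted_to_zero(self) -> "VoltageWaveform":
        """Copy with times shifted so the first sample is at t = 0."""
        return VoltageWaveform(self.t - self.t[0], self.V.copy(), label=self.label)


def _parse_cell(token: str, row: int, col: int) -> float:
    token = _MINUS_RE.sub("-", token.strip())
    try:
        return float(token)
    except ValueError:
        raise WaveformValidationError(
            f"non-numeric cell {token!r} at row {row}, column {col + 1}"
        ) from None


def read_waveform(
    path,
    dialect: str = "whitespace",
    rezero: bool = False,
    label: str | None = None,
) -> VoltageWaveform:
    """Read a two-column (time ms, voltage mV) delimited text file.

    ``dialect`` is one of ``csv``, ``tsv``, ``whitespace``.  Lines
    starting with ``#`` are comments; one optional non-numeric header
    line is allowed.  Unicode minus signs are accepted.  With
    ``rezero=True`` times are shifted so the first sample is t = 0.
    """
    if dialect not in _DIALECT_SEP:
        raise DomainError(f"unknown dialect {dialect!r}")
    sep = _DIALECT_SEP[dialect]
    path = Path(path)
    t_vals: list[float] = []
    v_vals: list[float] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [s for s in line.split(sep) if s.strip() != ""]
            if len(tokens) != 2:
                raise WaveformValidationError(
                    f"expected 2 columns at row {lineno}, found {len(tokens)}"
                )
            if not t_vals and not header_seen:
                try:
                    pair = [_parse_cell(tok, lineno, c) for c, tok in enumerate(tokens)]
                except WaveformValidationError:
                    header_seen = True  # single header line tolerated
                    continue
                t_vals.append(pair[0])
                v_vals.append(pair[1])
                continue
            t_vals.append(_parse_cell(tokens[0], lineno, 0))
            v_vals.append(_parse_cell(tokens[1], lineno, 1))
    if len(t_vals) < 2:
        raise WaveformValidationError(f"{path}: fewer than two data rows")
    w = VoltageWaveform(
        np.asarray(t_vals), np.asarray(v_vals), label=label if label else path.stem
    )
    return w.shifted_to_zero() if rezero else w


def write_waveform(w: VoltageWaveform, path, dialect: str = "csv", header=None) -> None:
    """Write a waveform as delimited text (columns time_ms, voltage_mV).

    A ``#`` comment line records provenance; ASCII hyphen-minus is used
    for negative numbers.  Round-trips through :func:`read_waveform` at
    full double precision.
    """
    if dialect not in _DIALECT_SEP:
        raise DomainError(f"unknown dialect {dialect!r}")
    sep = _DIALECT_SEP[dialect] or " "
    path = Path(path)
    lines = [f"# apclamp waveform: {w.label or 'unlabelled'}"]
    if header:
        lines += [f"# {h}" for h in np.atleast_1d(header)]
    lines.append(sep.join(["time_ms", "voltage_mV"]))
    for ti, vi in zip(w.t, w.V):
        lines.append(f"{float(ti)!r}{sep}{float(vi)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
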