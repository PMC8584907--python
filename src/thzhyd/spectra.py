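"""Core domain types, unit conventions, and plain-text I/O.

Unit conventions (external, matching how this field reports numbers):
wavenumber in cm^-1, time in ps, thickness in um, conductivity in S/m,
temperature in K.  Internal computations convert wavenumber to SI angular
frequency once, at module boundaries, via :func:`wavenumber_to_angular`.

Sign convention: complex permittivity is written eps* = eps' + i*eps'',
with eps'' >= 0 for a passive (absorbing) medium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

#: speed of light in cm/s (exact, SI definition)
C_CM_PER_S = 2.99792458e10

SpectrumKind = Literal["permittivity", "transmission", "refractive_index"]

_VALUE_COLUMNS: dict[str, tuple[str, ...]] = {
    "permittivity": ("eps_real", "eps_imag"),
    "transmission": ("transmission",),
    "refractive_index": ("n",),
}


def wavenumber_to_angular(nu_cm: float | np.ndarray) -> float | np.ndarray:
    """Convert wavenumber (cm^-1) to angular frequency (rad/s): w = 2*pi*c*nu."""
    nu = np.asarray(nu_cm, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumber must be positive")
    out = 2.0 * np.pi * C_CM_PER_S * nu
    return out if out.ndim else float(out)


def angular_to_wavenumber(omega: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`wavenumber_to_angular`."""
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise ValueError("angular frequency must be positive")
    out = w / (2.0 * np.pi * C_CM_PER_S)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing wavenumber grid (cm^-1), all points > 0.

    The default analysis grid spans 10-110 cm^-1 on 250 points, the band
    where the collective dynamics of liquid water (fast relaxation and the
    intermolecular stretching band) dominate the dielectric response.
    """

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        if nu.ndim != 1 or nu.size < 2:
            raise ValueError("grid must be a 1-D array with at least 2 points")
        if np.any(nu <= 0):
            raise ValueError("all wavenumbers must be positive")
        if np.any(np.diff(nu) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", nu)

    @classmethod
    def default(cls, lo: float = 10.0, hi: float = 110.0, n: int = 250) -> "FrequencyGrid":
        return cls(np.linspace(lo, hi, n))

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def angular(self) -> np.ndarray:
        """Angular frequencies (rad/s) for every grid point."""
        return np.asarray(wavenumber_to_angular(self.wavenumbers))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return self.wavenumbers.shape == other.wavenumbers.shape and bool(
            np.allclose(self.wavenumbers, other.wavenumbers, rtol=0, atol=1e-9)
        )


@dataclass
class ComplexSpectrum:
    """Complex-valued spectrum on a :class:`FrequencyGrid`.

    ``kind`` tags the physical quantity: ``permittivity`` (eps' + i*eps''),
    ``transmission`` (power transmittance, real in (0, 1]), or
    ``refractive_index`` (real part of the complex index).  ``meta`` carries
    provenance (sample label, thickness_um, temperature_K, sigma0_S_per_m...).
    """

    grid: FrequencyGrid
    values: np.ndarray
    kind: SpectrumKind = "permittivity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.grid),):
            raise ValueError("values must match grid length")
        if self.kind not in _VALUE_COLUMNS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "permittivity":
            v = v.astype(complex)
            if np.any(v.imag < -1e-9):
                warnings.warn(
                    "permittivity with negative imaginary part: not a passive "
                    "medium under the eps' + i*eps'' convention",
                    stacklevel=2,
                )
        else:
            v = np.real(v).astype(float)
            if self.kind == "transmission":
                if np.any(v <= 0):
                    raise ValueError("transmission must be positive")
                if np.any(v > 1.0 + 1e-12):
                    warnings.warn("transmission exceeds 1 at some points", stacklevel=2)
        self.values = v

    @property
    def real(self) -> np.ndarray:
        return np.real(self.values)

    @property
    def imag(self) -> np.ndarray:
        return np.imag(self.values)


@dataclass
class TimeTrace:
    """Sampled electric-field pulse E(t): time axis in ps, uniform spacing."""

    times: np.ndarray
    field: np.ndarray
    meta: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.field, dtype=float)
        if t.ndim != 1 or t.size < 64:
            raise ValueError("trace must have at least 64 samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
            raise ValueError("time axis must be uniform and increasing")
        if e.shape != t.shape:
            raise ValueError("field must match time axis length")
        self.times, self.field = t, e
        if self.meta is None:
            self.meta = {}

    @property
    def dt(self) -> float:
        """Sampling interval in ps."""
        return float(self.times[1] - self.times[0])


# ---------------------------------------------------------------------------
# plain-text I/O: '#'-commented metadata header, then a CSV table
# ---------------------------------------------------------------------------

def _format_meta(meta: dict) -> list[str]:
    return [f"# {k} = {meta[k]}" for k in meta]


def _parse_header(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                val = val.strip()
                try:
                    parsed: object = int(val)
                except ValueError:
                    try:
                        parsed = float(val)
                    except ValueError:
                        parsed = val
                meta[key.strip()] = parsed
    return meta, n_skip


def write_spectrum(spectrum: ComplexSpectrum, path: str | Path) -> None:
    """Write a spectrum as commented-header CSV, deterministically.

    Columns are ``wavenumber_cm-1`` followed by the value columns of the
    spectrum kind; floats use repr precision so write -> read is lossless.
    """
    path = Path(path)
    cols = _VALUE_COLUMNS[spectrum.kind]
    lines = _format_meta(spectrum.meta)
    lines.append(f"# kind = {spectrum.kind}")
    lines.append("wavenumber_cm-1," + ",".join(cols))
    if spectrum.kind == "permittivity":
        data = zip(spectrum.grid.wavenumbers, spectrum.real, spectrum.imag)
    else:
        data = zip(spectrum.grid.wavenumbers, spectrum.values)
    for row in data:
        lines.append(",".join(f"{x:.17g}" for x in row))
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path, kind: SpectrumKind | None = None) -> ComplexSpectrum:
    """Read a spectrum written by :func:`write_spectrum` (or hand-made CSV).

    ``kind`` may be omitted when the header records it.
    """
    path = Path(path)
    meta, n_skip = _parse_header(path)
    file_kind = meta.pop("kind", None)
    kind = kind or file_kind
    if kind is None:
        raise ValueError(f"{path}: spectrum kind neither given nor in header")
    raw = np.genfromtxt(path, delimiter=",", skip_header=n_skip, names=True)
    names = raw.dtype.names
    if names is None or "wavenumber_cm1" not in names:
        raise ValueError(f"{path}: missing wavenumber column")
    nu = np.atleast_1d(raw["wavenumber_cm1"])
    if np.any(np.diff(nu) <= 0):
        raise ValueError(f"{path}: wavenumber column is not strictly increasing")
    grid = FrequencyGrid(nu)
    if kind == "permittivity":
        for col in ("eps_real", "eps_imag"):
            if col not in names:
                raise ValueError(f"{path}: missing column {col}")
        values = np.atleast_1d(raw["eps_real"]) + 1j * np.atleast_1d(raw["eps_imag"])
    else:
        col = _VALUE_COLUMNS[kind][0]
        if col not in names:
            raise ValueError(f"{path}: missing column {col}")
        values = np.atleast_1d(raw[col])
    return ComplexSpectrum(grid, values, kind=kind, meta=meta)


def write_trace(trace: TimeTrace, path: str | Path) -> None:
    """Write a time trace as commented-header CSV (`time_ps, field_au`)."""
    path = Path(path)
    lines = _format_meta(trace.meta)
    lines.append("time_ps,field_au")
    for t, e in zip(trace.times, trace.field):
        lines.append(f"{t:.17g},{e:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> TimeTrace:
    path = Path(path)
    meta, n_skip = _parse_header(path)
    raw = np.genfromtxt(path, delimiter=",", skip_header=n_skip, names=True)
    names = raw.dtype.names
    if names is None or "time_ps" not in names or "field_au" not in names:
        raise ValueError(f"{path}: expected columns time_ps, field_au")
    return TimeTrace(np.atleast_1d(raw["time_ps"]), np.atleast_1d(raw["field_au"]), meta=meta)
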