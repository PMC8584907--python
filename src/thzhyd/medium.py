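"""Complex effective-medium mixing and its inversion.

A dilute solution is treated as a biphasic dielectric: a water phase with
permittivity eps_w* carrying inclusions of the solute with permittivity
eps_c* at volume fraction f.  Two mixing rules are provided:

* Maxwell Garnett — small spherical or chaotically oriented inclusions
  (monosaccharides):  (eps_s - eps_w)/(eps_s + 2 eps_w)
                        = f (eps_c - eps_w)/(eps_c + 2 eps_w).
* fiber model — the low-concentration limit for fiber-like inclusions
  (polysaccharides):  eps_s = eps_w + f (eps_c - eps_w)(5 eps_w + eps_c)
                                        / (3 (eps_w + eps_c)).

Both relations are quadratic in eps_w once eps_s is measured, so removing
the solute contribution amounts to picking the physical root (non-negative
loss, positive real part, continuous along the frequency grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from thzhyd.spectra import ComplexSpectrum

Geometry = str  # "spherical" | "fiber"

_GEOMETRIES = ("spherical", "fiber")


def volume_fraction(mass_concentration: float, specific_volume: float) -> float:
    """Volume fraction f = mass concentration (g/cm^3) x specific volume (cm^3/g).

    Typical specific volumes: 0.62 cm^3/g for glucose/galactose, 0.60 for
    dextran/amylopectin, 0.55 for (poly)galacturonic acid.
    """
    if mass_concentration < 0 or specific_volume < 0:
        raise ValueError("mass concentration and specific volume must be >= 0")
    return mass_concentration * specific_volume


@dataclass
class MixtureSpec:
    """Inclusion geometry, volume fraction, solute spectrum and conductivity."""

    geometry: Geometry
    f: float
    solute_eps: ComplexSpectrum
    sigma0: float = 0.0

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}")
        if not 0 <= self.f < 0.3:
            raise ValueError("volume fraction must lie in [0, 0.3): the fiber "
                             "model is a low-concentration limit")
        if self.sigma0 < 0:
            raise ValueError("conductivity must be >= 0")


def mg_forward(eps_w, eps_c, f: float):
    """Maxwell Garnett mixture permittivity for inclusions eps_c in host eps_w."""
    eps_w = np.asarray(eps_w, dtype=complex)
    eps_c = np.asarray(eps_c, dtype=complex)
    if not 0 <= f < 1:
        raise ValueError("volume fraction must lie in [0, 1)")
    denom = eps_c + 2 * eps_w
    if np.any(denom == 0):
        raise ZeroDivisionError("degenerate mixture: eps_c + 2 eps_w = 0")
    q = f * (eps_c - eps_w) / denom
    out = eps_w * (1 + 2 * q) / (1 - q)
    return out if out.ndim else complex(out)


def fiber_forward(eps_w, eps_c, f: float):
    """Fiber-inclusion mixture permittivity (low-concentration limit)."""
    eps_w = np.asarray(eps_w, dtype=complex)
    eps_c = np.asarray(eps_c, dtype=complex)
    if f < 0:
        raise ValueError("volume fraction must be >= 0")
    if f > 0.3:
        warnings.warn("fiber model used beyond its low-concentration range (f > 0.3)",
                      stacklevel=2)
    denom = eps_w + eps_c
    if np.any(denom == 0):
        raise ZeroDivisionError("degenerate mixture: eps_w + eps_c = 0")
    out = eps_w + f * (eps_c - eps_w) * (5 * eps_w + eps_c) / (3 * denom)
    return out if out.ndim else complex(out)


def _select_physical(roots: np.ndarray, eps_s: np.ndarray):
    """Pick the physical root per point: eps'' >= -1e-9 and eps' > 0.

    If both roots qualify, the one closer to the mixture value eps_s wins.
    A continuity sweep along the grid then removes isolated branch jumps.
    """
    r1, r2 = roots
    ok1 = (r1.imag >= -1e-9) & (r1.real > 0)
    ok2 = (r2.imag >= -1e-9) & (r2.real > 0)
    if np.any(~ok1 & ~ok2):
        bad = np.nonzero(~ok1 & ~ok2)[0][0]
        raise ValueError(
            "no physical root when inverting the mixture relation: "
            f"candidates {r1.flat[bad]:.6g} and {r2.flat[bad]:.6g}"
        )
    closer1 = np.abs(r1 - eps_s) <= np.abs(r2 - eps_s)
    pick1 = ok1 & (~ok2 | closer1)
    out = np.where(pick1, r1, r2)
    # continuity along the grid: undo isolated jumps far beyond the local scale
    if out.size > 2:
        step = np.median(np.abs(np.diff(out))) + 1e-30
        for i in range(1, out.size):
            alt = r2.flat[i] if pick1.flat[i] else r1.flat[i]
            alt_ok = (ok2 if pick1.flat[i] else ok1).flat[i]
            if alt_ok and abs(out.flat[i] - out.flat[i - 1]) > 10 * step and \
                    abs(alt - out.flat[i - 1]) < abs(out.flat[i] - out.flat[i - 1]):
                out.flat[i] = alt
    return out


def _invert_quadratic(a, b, c, eps_s):
    """Roots of a*x^2 + b*x + c = 0 per point, physical branch selected."""
    disc = np.sqrt(b * b - 4 * a * c + 0j)
    r1 = (-b + disc) / (2 * a)
    r2 = (-b - disc) / (2 * a)
    return _select_physical(np.stack([np.atleast_1d(r1), np.atleast_1d(r2)]),
                            np.atleast_1d(eps_s))


def mg_invert(eps_s, eps_c, f: float):
    """Water-phase permittivity from the Maxwell Garnett relation.

    Clearing denominators in the mixing rule gives a complex quadratic in
    eps_w; the physical root is returned (see :func:`_select_physical`).
    """
    eps_s = np.asarray(eps_s, dtype=complex)
    eps_c = np.asarray(eps_c, dtype=complex)
    if not 0 <= f < 1:
        raise ValueError("volume fraction must lie in [0, 1)")
    if f == 0:
        return eps_s if eps_s.ndim else complex(eps_s)
    a = 2.0 * (f - 1.0)
    b = (2.0 + f) * eps_s - (1.0 + 2.0 * f) * eps_c
    c = (1.0 - f) * eps_s * eps_c
    out = _invert_quadratic(a, b, c, eps_s)
    return out if np.asarray(eps_s).ndim else complex(out[0])


def fiber_invert(eps_s, eps_c, f: float):
    """Water-phase permittivity from the fiber mixing rule (quadratic root).

    The closed-form expression :func:`fiber_invert_closed_form` is the
    printed solution of the same quadratic; this routine solves it directly
    and applies the physical-branch rules, and the two agree to 1e-10.
    """
    eps_s = np.asarray(eps_s, dtype=complex)
    eps_c = np.asarray(eps_c, dtype=complex)
    if f < 0:
        raise ValueError("volume fraction must be >= 0")
    a = 5.0 * f - 3.0
    b = 3.0 * eps_s - (3.0 + 4.0 * f) * eps_c
    c = eps_c * (3.0 * eps_s - f * eps_c)
    out = _invert_quadratic(a, b, c, eps_s)
    return out if np.asarray(eps_s).ndim else complex(out[0])


def fiber_invert_closed_form(eps_s, eps_c, f: float):
    """Closed-form inversion of the fiber mixing rule.

    Writes the quadratic's solution through the real intermediates
    a, b, c, d, e with e = 2(5f - 3); equivalent to taking the root
    (a + i b - sqrt(3) * principal_sqrt(c + i d)) / e.
    """
    eps_s = np.asarray(eps_s, dtype=complex)
    eps_c = np.asarray(eps_c, dtype=complex)
    es_r, es_i = eps_s.real, eps_s.imag
    ec_r, ec_i = eps_c.real, eps_c.imag
    a = (3 + 4 * f) * ec_r - 3 * es_r
    b = (3 + 4 * f) * ec_i - 3 * es_i
    c = (3 * (es_r**2 - es_i**2)
         + (6 - 28 * f) * ec_r * es_r
         - 2 * (3 - 14 * f) * ec_i * es_i
         + (3 + 4 * f + 12 * f**2) * (ec_r**2 - ec_i**2))
    d = ((6 - 28 * f) * ec_i * es_r
         + 6 * es_r * es_i
         + ec_r * ((6 - 28 * f) * es_i + (6 + 8 * f + 24 * f**2) * ec_i))
    e = 2 * (5 * f - 3)
    hyp = np.hypot(c, d)
    root_re = np.sqrt(1.5 * (hyp + c))
    root_im = np.sign(d) * np.sqrt(np.maximum(1.5 * (hyp - c), 0.0))
    out = ((a - root_re) + 1j * (b - root_im)) / e
    return out if out.ndim else complex(out)


def apply_mixture(water: ComplexSpectrum, mix: MixtureSpec) -> ComplexSpectrum:
    """Forward-mix a water-phase spectrum into a solution spectrum."""
    _check_grids(water, mix)
    fwd = mg_forward if mix.geometry == "spherical" else fiber_forward
    values = fwd(water.values, mix.solute_eps.values, mix.f)
    meta = dict(water.meta, geometry=mix.geometry, volume_fraction=mix.f)
    return ComplexSpectrum(water.grid, values, kind="permittivity", meta=meta)


def remove_mixture(solution: ComplexSpectrum, mix: MixtureSpec) -> ComplexSpectrum:
    """Subtract the solute phase: solution spectrum -> water-phase spectrum."""
    _check_grids(solution, mix)
    inv = mg_invert if mix.geometry == "spherical" else fiber_invert
    values = inv(solution.values, mix.solute_eps.values, mix.f)
    meta = dict(solution.meta, geometry=mix.geometry, volume_fraction=mix.f)
    return ComplexSpectrum(solution.grid, values, kind="permittivity", meta=meta)


def _check_grids(spectrum: ComplexSpectrum, mix: MixtureSpec) -> None:
    if spectrum.kind != "permittivity" or mix.solute_eps.kind != "permittivity":
        raise ValueError("mixing operates on permittivity spectra")
    if not (spectrum.grid == mix.solute_eps.grid):
        raise ValueError("solute spectrum must share the solution grid")
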