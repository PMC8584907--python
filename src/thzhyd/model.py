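"""Model dielectric permittivity of the water phase, fitting, and the
free-water-fraction statistic.

The water-phase permittivity in the 10-110 cm^-1 band is decomposed as

    eps*(w) = d_eps1 / (1 - i w tau1)          (slow Debye relaxation)
            + d_eps2 / (1 - i w tau2)          (free / weakly bound molecules)
            + A / (w0^2 - w^2 - i w gamma)     (intermolecular stretch band)
            + eps_inf + i sigma0 / (eps0 w)    (high-frequency + dc ionic)

with w = 2*pi*c*nu the angular frequency.  Fitting fixes tau1 = 8.28 ps
(pure water, 25 C), eps_inf = 2.5 and the measured sigma0, leaving six free
parameters: d_eps1, d_eps2, tau2, A, w0, gamma.

The share of free water molecules follows from the strength d_eps2 of the
fast relaxation via the orientational-polarizability ratio

    n = 3 d_eps2 / ((d_eps2 + E) E) * 9 k T eps0 / (N p^2) * 100%,
    E = eps_inf + A/w0^2 + 2,

with p the water dipole moment and N the number density of water molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from thzhyd.spectra import ComplexSpectrum, FrequencyGrid, wavenumber_to_angular

#: SI vacuum permittivity, F/m
EPS0 = 8.8541878128e-12


@dataclass(frozen=True)
class PhysicalConstants:
    """Printed 3-digit constants used for the free-water fraction.

    Kept at printed precision (not CODATA) so the statistic is reproduced on
    the same terms as the reported tables.
    """

    k: float = 1.38e-23           # Boltzmann constant, J/K
    eps0: float = EPS0            # electric constant, F/m
    p: float = 6.17e-30           # dipole moment of a water molecule, C*m
    n_avogadro: float = 6.02e23   # 1/mol
    water_molarity: float = 55.56e3  # mol/m^3
    T: float = 298.15             # K

    @property
    def n_water(self) -> float:
        """Number density of water molecules, molecules/m^3."""
        return self.n_avogadro * self.water_molarity


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class DielectricParams:
    """The nine parameters of the model permittivity.

    ``amplitude`` is the oscillator amplitude A in (rad/s)^2; reporting uses
    the dimensionless ratio A/w0^2 (``a_over_w0sq``), the static contribution
    of the intermolecular band.
    """

    d_eps1: float                 # slow Debye strength
    d_eps2: float                 # fast (free-molecule) strength
    tau2_ps: float                # fast relaxation time, ps
    amplitude: float              # oscillator amplitude A, (rad/s)^2
    w0_cm: float                  # oscillator resonance, cm^-1
    gamma_cm: float               # oscillator bandwidth, cm^-1
    tau1_ps: float = 8.28         # slow Debye time, ps (pure water, 25 C)
    eps_inf: float = 2.5          # high-frequency permittivity
    sigma0: float = 0.0           # dc conductivity, S/m

    def __post_init__(self) -> None:
        for name in ("d_eps1", "d_eps2", "tau2_ps", "amplitude", "w0_cm",
                     "gamma_cm", "tau1_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.eps_inf < 1:
            raise ValueError("eps_inf must be >= 1")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be >= 0")

    @property
    def a_over_w0sq(self) -> float:
        """Dimensionless oscillator contribution A/w0^2 (w0 in rad/s)."""
        return self.amplitude / float(wavenumber_to_angular(self.w0_cm)) ** 2

    @classmethod
    def from_oscillator_strength(
        cls, d_eps1: float, d_eps2: float, tau2_ps: float, a_over_w0sq: float,
        w0_cm: float, gamma_cm: float, tau1_ps: float = 8.28,
        eps_inf: float = 2.5, sigma0: float = 0.0,
    ) -> "DielectricParams":
        """Build from the dimensionless A/w0^2 instead of A itself."""
        amplitude = a_over_w0sq * float(wavenumber_to_angular(w0_cm)) ** 2
        return cls(d_eps1, d_eps2, tau2_ps, amplitude, w0_cm, gamma_cm,
                   tau1_ps, eps_inf, sigma0)


#: fitted parameters of pure water at 25 C (replicate means)
PURE_WATER = DielectricParams.from_oscillator_strength(
    d_eps1=68.86, d_eps2=2.691, tau2_ps=0.316, a_over_w0sq=1.702,
    w0_cm=207.2, gamma_cm=196.5,
)


def eval_model(params: DielectricParams, grid: FrequencyGrid) -> ComplexSpectrum:
    """Evaluate the model permittivity on a wavenumber grid."""
    w = grid.angular
    tau1 = params.tau1_ps * 1e-12
    tau2 = params.tau2_ps * 1e-12
    w0 = float(wavenumber_to_angular(params.w0_cm))
    g = float(wavenumber_to_angular(params.gamma_cm))
    eps = (params.d_eps1 / (1 - 1j * w * tau1)
           + params.d_eps2 / (1 - 1j * w * tau2)
           + params.amplitude / (w0**2 - w**2 - 1j * w * g)
           + params.eps_inf)
    if params.sigma0:
        eps = eps + 1j * params.sigma0 / (EPS0 * w)
    return ComplexSpectrum(grid, eps, kind="permittivity")


def objective_s(model: ComplexSpectrum, experiment: ComplexSpectrum) -> float:
    """Mean squared relative deviation between model and experiment.

    s = 1/N sum_i [ ((e'_mod - e'_exp)/e'_mod)^2 + ((e''_mod - e''_exp)/e''_mod)^2 ]

    Note the normalization by the *model* value.
    """
    if not (model.grid == experiment.grid):
        raise ValueError("model and experiment must share one grid")
    mr, mi = model.real, model.imag
    if np.any(mr == 0) or np.any(mi == 0):
        raise ZeroDivisionError("model permittivity has a zero part on the grid")
    rr = (mr - experiment.real) / mr
    ri = (mi - experiment.imag) / mi
    return float(np.mean(rr**2 + ri**2))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_FREE = ("d_eps1", "d_eps2", "tau2_ps", "w0_cm", "gamma_cm", "a_over_w0sq")

#: generous envelopes around reported water-phase values; they prevent the
#: two Debye terms from swapping roles during the search
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "d_eps1": (20.0, 120.0),
    "d_eps2": (0.1, 10.0),
    "tau2_ps": (0.05, 2.0),
    "w0_cm": (120.0, 350.0),
    "gamma_cm": (50.0, 500.0),
    "a_over_w0sq": (0.3, 5.0),
}


@dataclass
class FitConfig:
    """Configuration of the six-parameter fit.

    tau1, eps_inf and sigma0 are fixed (never free); the optimizer restarts
    ``multistart`` times from the initial point jittered by +-``jitter``
    (relative), keeping the best objective.
    """

    tau1_ps: float = 8.28
    eps_inf: float = 2.5
    sigma0: float = 0.0
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    initial: DielectricParams = PURE_WATER
    multistart: int = 8
    jitter: float = 0.3
    seed: int = 0


@dataclass
class FitResult:
    """Outcome of one fit: parameters, objective s, free-water fraction n."""

    params: DielectricParams
    s: float
    n_free: float
    n_starts: int
    nfev: int
    at_bounds: list

    def as_dict(self) -> dict:
        p = self.params
        return {
            "d_eps1": p.d_eps1, "d_eps2": p.d_eps2, "tau2_ps": p.tau2_ps,
            "w0_cm": p.w0_cm, "gamma_cm": p.gamma_cm,
            "a_over_w0sq": p.a_over_w0sq, "tau1_ps": p.tau1_ps,
            "eps_inf": p.eps_inf, "sigma0": p.sigma0,
            "s": self.s, "n_free_pct": self.n_free,
        }


def _params_from_x(x: np.ndarray, config: FitConfig) -> DielectricParams:
    return DielectricParams.from_oscillator_strength(
        d_eps1=x[0], d_eps2=x[1], tau2_ps=x[2], w0_cm=x[3], gamma_cm=x[4],
        a_over_w0sq=x[5], tau1_ps=config.tau1_ps, eps_inf=config.eps_inf,
        sigma0=config.sigma0,
    )


def fit_model(experiment: ComplexSpectrum, config: FitConfig | None = None) -> FitResult:
    """Fit the six free parameters to an experimental water-phase spectrum.

    Bounded trust-region least squares on the stacked relative residuals
    (whose mean of squares is exactly the objective s), restarted from
    jittered initial points; the best run is returned.
    """
    config = config or FitConfig()
    grid = experiment.grid
    w = grid.angular
    n_pts = len(grid)
    tau1 = config.tau1_ps * 1e-12
    er, ei = experiment.real, experiment.imag
    cond = config.sigma0 / (EPS0 * w) if config.sigma0 else 0.0

    def residuals(x: np.ndarray) -> np.ndarray:
        d1, d2, t2, w0c, gc, aw = x
        t2s = t2 * 1e-12
        w0 = 2 * np.pi * 2.99792458e10 * w0c
        g = 2 * np.pi * 2.99792458e10 * gc
        eps = (d1 / (1 - 1j * w * tau1) + d2 / (1 - 1j * w * t2s)
               + aw * w0**2 / (w0**2 - w**2 - 1j * w * g) + config.eps_inf)
        mr = eps.real
        mi = eps.imag + cond
        return np.concatenate([(mr - er) / mr, (mi - ei) / mi])

    p0 = config.initial
    x0 = np.array([p0.d_eps1, p0.d_eps2, p0.tau2_ps, p0.w0_cm, p0.gamma_cm,
                   p0.a_over_w0sq])
    lo = np.array([config.bounds[k][0] for k in _FREE])
    hi = np.array([config.bounds[k][1] for k in _FREE])
    rng = np.random.default_rng(config.seed)

    best = None
    nfev = 0
    for start in range(max(1, config.multistart)):
        if start == 0:
            xs = x0
        else:
            xs = x0 * (1 + config.jitter * rng.uniform(-1, 1, size=x0.size))
        xs = np.clip(xs, lo, hi)
        try:
            sol = optimize.least_squares(
                residuals, xs, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:
            continue
        nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed to converge")

    s = float(2 * best.cost / n_pts)  # cost = 1/2 sum r^2; s = sum r^2 / N
    params = _params_from_x(best.x, config)
    at_bounds = [name for name, v, a, b in zip(_FREE, best.x, lo, hi)
                 if math.isclose(v, a, rel_tol=1e-9) or math.isclose(v, b, rel_tol=1e-9)]
    if at_bounds:
        import warnings
        warnings.warn(f"fitted parameters pinned at bounds: {at_bounds}", stacklevel=2)
    n = free_water_fraction(params)
    return FitResult(params=params, s=s, n_free=n,
                     n_starts=max(1, config.multistart), nfev=nfev,
                     at_bounds=at_bounds)


def free_water_fraction(
    params: DielectricParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Percentage of free (fast-relaxing) water molecules.

    n = 3 d_eps2 / ((d_eps2 + E) E) * 9 k T eps0 / (N p^2) * 100, with
    E = eps_inf + A/w0^2 + 2 the non-orientational static background.
    """
    E = params.eps_inf + params.a_over_w0sq + 2.0
    ratio = 3.0 * params.d_eps2 / ((params.d_eps2 + E) * E)
    lang = 9.0 * constants.k * constants.T * constants.eps0 / (
        constants.n_water * constants.p**2)
    return ratio * lang * 100.0


_TABLE_COLUMNS = ("d_eps1", "d_eps2", "tau2_ps", "w0_cm", "gamma_cm",
                  "a_over_w0sq", "n_free_pct")


def aggregate_replicates(results: list[FitResult]) -> pd.DataFrame:
    """Replicate means and 95% confidence intervals of the mean.

    Returns a DataFrame with one row per reported parameter (in the
    conventional order d_eps1, d_eps2, tau2, w0, gamma, A/w0^2, n) and
    columns mean / ci95 (t-distribution half-width).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    rows = pd.DataFrame([r.as_dict() for r in results])
    n = len(rows)
    tcrit = stats.t.ppf(0.975, n - 1)
    mean = rows[list(_TABLE_COLUMNS)].mean()
    half = tcrit * rows[list(_TABLE_COLUMNS)].std(ddof=1) / math.sqrt(n)
    return pd.DataFrame({"mean": mean, "ci95": half})


def refit_sigma0(config: FitConfig, sigma0: float) -> FitConfig:
    """Copy of a fit configuration with a different fixed conductivity."""
    return replace(config, sigma0=sigma0)
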