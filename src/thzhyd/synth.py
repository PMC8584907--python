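"""Synthetic data: every input of the pipeline without an instrument.

Generates model water-phase spectra with replicate noise, smooth solute
spectra, effective-medium-mixed solution spectra, and virtual picosecond
pulse pairs propagated through the solution layer, so the full chain
(traces -> permittivity -> solute removal -> fit -> free-water fraction)
can be exercised and validated end to end.

All randomness is seeded; replicate r of a generator seeded s draws from
an independent stream keyed (s, r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from thzhyd.medium import MixtureSpec, apply_mixture, volume_fraction
from thzhyd.model import DielectricParams, PURE_WATER, eval_model
from thzhyd.spectra import C_CM_PER_S, ComplexSpectrum, FrequencyGrid, TimeTrace


#: per-parameter relative replicate jitter, calibrated so that 20-replicate
#: aggregated confidence intervals reproduce the dispersion observed in
#: repeated pure-water measurements (sigma_rel = ci * sqrt(20) / t_0.975,19
#: divided by the mean value)
DEFAULT_PARAM_JITTER: dict[str, float] = {
    "d_eps1": 0.025,
    "d_eps2": 0.033,
    "tau2_ps": 0.041,
    "w0_cm": 0.044,
    "gamma_cm": 0.121,
    "a_over_w0sq": 0.024,
}


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise: run-to-run parameter jitter plus point noise.

    Replicate-to-replicate variation of repeated THz measurements is
    dominated by slow drifts (alignment, humidity, temperature), which move
    whole spectra coherently; white per-point noise is comparatively small.
    The generator therefore jitters the generating parameters per replicate
    (relative normal jitter, per-parameter amplitudes in ``param_jitter``)
    and adds multiplicative point noise of relative amplitude ``sigma_rel``
    on both permittivity parts.
    """

    sigma_rel: float = 0.005
    param_jitter: dict = field(
        default_factory=lambda: dict(DEFAULT_PARAM_JITTER))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or any(v < 0 for v in self.param_jitter.values()):
            raise ValueError("noise amplitudes must be >= 0")

    def rng(self, replicate: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, replicate])


@dataclass(frozen=True)
class SoluteModel:
    """Smooth (resonance-free) permittivity of the dry carbohydrate.

    Low-order polynomials in wavenumber for eps' and eps''; dissolved
    carbohydrates show no phonon bands in this range, so a featureless
    spectrum is the right stand-in.  Defaults are flat, plausible-magnitude
    placeholders, overridable per sample.
    """

    real_coef: tuple = (3.0,)
    imag_coef: tuple = (0.2,)

    def evaluate(self, grid: FrequencyGrid) -> ComplexSpectrum:
        nu = grid.wavenumbers
        re = npoly.polyval(nu, np.asarray(self.real_coef, dtype=float))
        im = npoly.polyval(nu, np.asarray(self.imag_coef, dtype=float))
        if np.any(im < 0):
            raise ValueError("solute eps'' must be >= 0 across the band")
        return ComplexSpectrum(grid, re + 1j * im, kind="permittivity",
                               meta={"sample": "synthetic solute"})

    @classmethod
    def monosaccharide(cls) -> "SoluteModel":
        return cls(real_coef=(3.0,), imag_coef=(0.2,))

    @classmethod
    def polysaccharide(cls) -> "SoluteModel":
        return cls(real_coef=(2.6,), imag_coef=(0.15,))


def _jittered(params: DielectricParams, jitter: dict,
              rng: np.random.Generator) -> DielectricParams:
    if not jitter or all(v == 0 for v in jitter.values()):
        return params

    def draw(name: str, value: float) -> float:
        return value * (1 + jitter.get(name, 0.0) * rng.standard_normal())

    return DielectricParams.from_oscillator_strength(
        d_eps1=draw("d_eps1", params.d_eps1),
        d_eps2=draw("d_eps2", params.d_eps2),
        tau2_ps=draw("tau2_ps", params.tau2_ps),
        a_over_w0sq=draw("a_over_w0sq", params.a_over_w0sq),
        w0_cm=draw("w0_cm", params.w0_cm),
        gamma_cm=draw("gamma_cm", params.gamma_cm),
        tau1_ps=params.tau1_ps, eps_inf=params.eps_inf, sigma0=params.sigma0,
    )


def make_water_phase(params: DielectricParams, grid: FrequencyGrid,
                     noise: NoiseModel | None = None,
                     replicate: int = 0) -> ComplexSpectrum:
    """Model water-phase permittivity with multiplicative replicate noise."""
    noise = noise or NoiseModel(sigma_rel=0.0, param_jitter={})
    rng = noise.rng(replicate)
    params = _jittered(params, noise.param_jitter, rng)
    spec = eval_model(params, grid)
    if noise.sigma_rel > 0:
        re = spec.real * (1 + noise.sigma_rel * rng.standard_normal(len(grid)))
        im = spec.imag * (1 + noise.sigma_rel * rng.standard_normal(len(grid)))
        spec = ComplexSpectrum(grid, re + 1j * im, kind="permittivity",
                               meta=dict(spec.meta))
    spec.meta.update(replicate=replicate, sigma_rel=noise.sigma_rel)
    return spec


def make_solution(water: ComplexSpectrum, solute: SoluteModel | ComplexSpectrum,
                  f: float, geometry: str) -> ComplexSpectrum:
    """Mix a water-phase spectrum with solute inclusions at fraction f."""
    if isinstance(solute, SoluteModel):
        solute = solute.evaluate(water.grid)
    mix = MixtureSpec(geometry=geometry, f=f, solute_eps=solute)
    return apply_mixture(water, mix)


@dataclass(frozen=True)
class PulseConfig:
    """Band-limited reference pulse: a Gaussian derivative.

    Defaults cover 10-110 cm^-1 with margin: 0.05 ps sampling over 40 ps,
    width 0.06 ps (spectral peak near 1.3 THz, usable amplitude past
    3.5 THz).
    """

    dt_ps: float = 0.05
    duration_ps: float = 40.0
    center_ps: float = 5.0
    width_ps: float = 0.06

    def reference_trace(self) -> TimeTrace:
        t = np.arange(0.0, self.duration_ps, self.dt_ps)
        x = t - self.center_ps
        e = -x / self.width_ps**2 * np.exp(-x**2 / (2 * self.width_ps**2))
        return TimeTrace(t, e / np.abs(e).max(), meta={"pulse": "gaussian_derivative"})


def make_pulse_pair(eps_solution: ComplexSpectrum, l_thin_um: float = 50.06,
                    l_thick_um: float = 100.26,
                    pulse: PulseConfig | None = None,
                    noise: NoiseModel | None = None,
                    replicate: int = 0) -> tuple[TimeTrace, TimeTrace]:
    """Virtual two-cuvette measurement of a solution.

    The reference pulse is propagated (in the frequency domain) through the
    solution layer of each cuvette: the field picks up exp(-2 pi nu kappa l)
    in amplitude and a delay phase 2 pi nu (n - 1) l relative to the same
    geometric path in air, with n + i kappa = sqrt(eps).  Returns
    (sample, background) = (thick-cuvette, thin-cuvette) traces.
    """
    if not l_thick_um > l_thin_um > 0:
        raise ValueError("need l_thick > l_thin > 0")
    pulse = pulse or PulseConfig()
    noise = noise or NoiseModel(sigma_rel=0.0, param_jitter={})
    ref = pulse.reference_trace()
    n_fft = int(2 ** np.ceil(np.log2(ref.field.size * 4)))
    spec0 = np.fft.rfft(ref.field, n_fft)
    nu = np.fft.rfftfreq(n_fft, pulse.dt_ps) * 1e12 / C_CM_PER_S

    band_max = eps_solution.grid.wavenumbers[-1]
    peak = np.abs(spec0).max()
    at_edge = np.interp(band_max, nu, np.abs(spec0))
    if at_edge < 1e-4 * peak:
        raise ValueError(
            f"pulse bandwidth insufficient: relative amplitude at "
            f"{band_max:g} cm^-1 is {at_edge / peak:.2e}")

    # hold-extrapolate the permittivity outside the analysis band; the
    # differential referencing only ever uses in-band values
    gw = eps_solution.grid.wavenumbers
    eps_r = np.interp(nu, gw, eps_solution.real)
    eps_i = np.interp(nu, gw, eps_solution.imag)
    n_idx = np.sqrt(eps_r + 1j * eps_i)  # principal root: Re, Im >= 0

    rng = noise.rng(replicate)
    traces = []
    for l_um in (l_thick_um, l_thin_um):
        l_cm = l_um * 1e-4
        # analysis convention exp(-i w t): a delay lowers the phase and the
        # extinction enters as n - i kappa
        prop = np.exp(-1j * 2 * np.pi * nu * (np.conj(n_idx) - 1.0) * l_cm)
        spec = spec0 * prop
        if noise.sigma_rel > 0:
            spec = spec * (1 + noise.sigma_rel * rng.standard_normal(spec.size))
        e = np.fft.irfft(spec, n_fft)[: ref.field.size]
        traces.append(TimeTrace(ref.times, e, meta={
            "thickness_um": l_um, "replicate": replicate}))
    sample, background = traces
    return sample, background


# ---------------------------------------------------------------------------
# sample presets: generating water-phase parameters, geometry and fraction
# ---------------------------------------------------------------------------

def _params(d1, d2, t2, aw, w0, g, sigma0=0.0) -> DielectricParams:
    return DielectricParams.from_oscillator_strength(
        d_eps1=d1, d_eps2=d2, tau2_ps=t2, a_over_w0sq=aw, w0_cm=w0,
        gamma_cm=g, sigma0=sigma0)


@dataclass(frozen=True)
class SamplePreset:
    """Ground truth for one simulated solution."""

    name: str
    water_params: DielectricParams
    solute: SoluteModel
    f: float
    geometry: str
    sigma0: float = 0.0


_MONO = SoluteModel.monosaccharide()
_POLY = SoluteModel.polysaccharide()

#: generating parameters per sample: replicate-mean water-phase values of
#: the studied solutions, volume fractions from mass concentration x
#: specific volume, conductivities as measured (zero when < 0.008 S/m)
PRESETS: dict[str, SamplePreset] = {
    "water": SamplePreset("water", PURE_WATER, _MONO, 0.0, "spherical"),
    "glucose": SamplePreset(
        "glucose", _params(62.45, 2.939, 0.326, 1.807, 215.9, 202.6),
        _MONO, volume_fraction(0.050, 0.62), "spherical"),
    "galactose": SamplePreset(
        "galactose", _params(62.23, 2.931, 0.327, 1.844, 221.3, 217.3),
        _MONO, volume_fraction(0.050, 0.62), "spherical"),
    "galacturonic": SamplePreset(
        "galacturonic", _params(63.20, 3.006, 0.334, 1.867, 221.7, 223.1, sigma0=1.3),
        _MONO, volume_fraction(0.05387, 0.55), "spherical", sigma0=1.3),
    "dextran": SamplePreset(
        "dextran", _params(63.81, 2.728, 0.321, 1.719, 210.6, 200.0),
        _POLY, volume_fraction(0.045, 0.60), "fiber"),
    "amylopectin": SamplePreset(
        "amylopectin", _params(65.97, 2.688, 0.319, 1.737, 209.7, 197.4),
        _POLY, volume_fraction(0.045, 0.60), "fiber"),
    "polygalacturonic": SamplePreset(
        "polygalacturonic", _params(63.75, 2.729, 0.312, 1.801, 219.1, 208.2, sigma0=1.86),
        _POLY, volume_fraction(0.04887, 0.55), "fiber", sigma0=1.86),
}


def simulate_replicates(preset: SamplePreset, grid: FrequencyGrid,
                        n_replicates: int, noise: NoiseModel) -> list[ComplexSpectrum]:
    """Noisy solution spectra for one sample (mixed, conductivity included)."""
    out = []
    for r in range(n_replicates):
        water = make_water_phase(preset.water_params, grid, noise, replicate=r)
        if preset.f > 0:
            spec = make_solution(water, preset.solute, preset.f, preset.geometry)
        else:
            spec = water
        spec.meta.update(sample=preset.name, replicate=r,
                         sigma0_S_per_m=preset.sigma0,
                         geometry=preset.geometry, volume_fraction=preset.f)
        out.append(spec)
    return out
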