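"""Time-domain to frequency-domain processing of THz pulse pairs.

A solution is measured in two cuvettes that differ only in their
inter-window distance; the thick-cuvette trace plays "sample" and the
thin-cuvette trace plays "background", so that their ratio isolates a
solution layer of thickness dl = l_thick - l_thin and the cuvette windows
cancel.  From the power transmittance Tr(nu) and refractive index n(nu) of
that layer the complex permittivity follows as

    eps'(nu)  = n^2 - [ln Tr / (4 pi nu l)]^2,
    eps''(nu) = -n ln Tr / (2 pi nu l),

which is exactly (n + i kappa)^2 with kappa = -ln Tr / (4 pi nu l).

FFT phase convention: numpy's forward transform analyses with exp(-i w t),
so a medium that *delays* the pulse (n > 1) lowers the spectral phase; the
index is therefore n = 1 - dphi / (2 pi nu dl) with dphi the unwrapped
sample-minus-background phase difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from thzhyd.spectra import (C_CM_PER_S, ComplexSpectrum, FrequencyGrid,
                            TimeTrace)

#: water-like band-average refractive index used to resolve a residual
#: 2*pi phase ambiguity (solutions under study are >= 95% water)
N_WATER_GUESS = 2.3


@dataclass
class OpticalPair:
    """Power transmittance and refractive index sharing one grid."""

    transmission: ComplexSpectrum
    index: ComplexSpectrum
    effective_thickness: float  # um

    def __post_init__(self) -> None:
        if self.transmission.kind != "transmission":
            raise ValueError("transmission member must have kind=transmission")
        if self.index.kind != "refractive_index":
            raise ValueError("index member must have kind=refractive_index")
        if not (self.transmission.grid == self.index.grid):
            raise ValueError("both members must share one grid")
        if self.effective_thickness <= 0:
            raise ValueError("effective thickness must be > 0")


def _dense_fft(trace: TimeTrace, window: str, pad_factor: int = 8):
    """Zero-padded rfft of a trace; returns (wavenumber_cm, complex spectrum)."""
    e = trace.field.astype(float)
    if window == "hann":
        # taper only the trailing half: keeps the pulse, kills wrap-around
        w = np.ones_like(e)
        half = e.size // 2
        w[half:] = np.hanning(2 * (e.size - half))[e.size - half:]
        e = e * w
    elif window != "none":
        raise ValueError("window must be 'none' or 'hann'")
    n_fft = int(2 ** np.ceil(np.log2(e.size * pad_factor)))
    spec = np.fft.rfft(e, n_fft)
    freq_thz = np.fft.rfftfreq(n_fft, trace.dt)  # 1/ps = THz
    nu_cm = freq_thz * 1e12 / C_CM_PER_S
    return nu_cm, spec


def fourier_spectrum(trace: TimeTrace, grid: FrequencyGrid,
                     window: str = "none") -> np.ndarray:
    """Complex Fourier amplitude of a pulse at the grid wavenumbers.

    The discrete transform is zero-padded and amplitude/unwrapped phase are
    interpolated separately, so the returned phase is continuous in
    frequency.
    """
    nu_cm, spec = _dense_fft(trace, window)
    nyquist = nu_cm[-1]
    if grid.wavenumbers[-1] > nyquist:
        raise ValueError(
            f"grid extends to {grid.wavenumbers[-1]:g} cm^-1, beyond the "
            f"trace Nyquist limit {nyquist:g} cm^-1")
    amp = np.interp(grid.wavenumbers, nu_cm, np.abs(spec))
    phase = np.interp(grid.wavenumbers, nu_cm, np.unwrap(np.angle(spec)))
    return amp * np.exp(1j * phase)


def optics_from_pair(sample: TimeTrace, background: TimeTrace, dl_um: float,
                     grid: FrequencyGrid, window: str = "none") -> OpticalPair:
    """Transmittance and index of the differential solution layer.

    ``sample`` is the thick-cuvette trace, ``background`` the thin-cuvette
    trace; ``dl_um`` their inter-window distance difference.
    """
    if dl_um <= 0:
        raise ValueError("thickness difference must be > 0")
    nu_s, spec_s = _dense_fft(sample, window)
    nu_b, spec_b = _dense_fft(background, window)
    if nu_s.size != nu_b.size or not np.allclose(nu_s, nu_b):
        raise ValueError("sample and background traces must share time sampling")
    if grid.wavenumbers[-1] > nu_s[-1]:
        raise ValueError("grid exceeds the trace Nyquist limit")

    band = (nu_s >= 0.5 * grid.wavenumbers[0]) & (nu_s <= 1.1 * grid.wavenumbers[-1])
    mag_b = np.abs(spec_b)
    floor = 1e-8 * mag_b.max()
    dead = band & (mag_b <= floor)
    if np.any(dead):
        raise ValueError(
            "background amplitude vanishes near "
            f"{nu_s[dead][0]:.2f} cm^-1; cannot reference the sample there")

    ratio = spec_s[band] / spec_b[band]
    nu_band = nu_s[band]
    amp = np.interp(grid.wavenumbers, nu_band, np.abs(ratio))
    tr = amp**2  # power transmittance

    dl_cm = dl_um * 1e-4
    phase = np.unwrap(np.angle(ratio))
    # anchor: the phase of the ratio extrapolates to a multiple of 2*pi at
    # nu -> 0; remove that whole-cycle offset
    k_fit = min(20, nu_band.size)
    slope, intercept = np.polyfit(nu_band[:k_fit], phase[:k_fit], 1)
    cycles = np.round(intercept / (2 * np.pi))
    phase = phase - 2 * np.pi * cycles
    dphi = np.interp(grid.wavenumbers, nu_band, phase)
    n = 1.0 - dphi / (2 * np.pi * grid.wavenumbers * dl_cm)
    # residual ambiguity: if the anchored intercept was far from a whole
    # cycle, pick the neighbouring branch closest to a water-like index
    residual = abs(intercept - 2 * np.pi * cycles)
    if residual > 0.3 * 2 * np.pi:
        candidates = [n + k / (grid.wavenumbers * dl_cm) for k in (-1, 0, 1)]
        scores = [abs(np.mean(c) - N_WATER_GUESS) for c in candidates]
        n = candidates[int(np.argmin(scores))]

    meta = {"dl_um": dl_um}
    return OpticalPair(
        transmission=ComplexSpectrum(grid, tr, kind="transmission", meta=dict(meta)),
        index=ComplexSpectrum(grid, n, kind="refractive_index", meta=dict(meta)),
        effective_thickness=dl_um,
    )


def permittivity_from_optics(pair: OpticalPair) -> ComplexSpectrum:
    """Complex permittivity from transmittance and index of a known layer."""
    tr = pair.transmission.values
    if np.any(tr <= 0):
        raise ValueError("transmission must be positive everywhere")
    n = pair.index.values
    nu = pair.transmission.grid.wavenumbers
    l_cm = pair.effective_thickness * 1e-4
    log_tr = np.log(tr)
    eps_r = n**2 - (log_tr / (4 * np.pi * nu * l_cm))**2
    eps_i = -n * log_tr / (2 * np.pi * nu * l_cm)
    meta = dict(pair.transmission.meta, thickness_um=pair.effective_thickness)
    return ComplexSpectrum(pair.transmission.grid, eps_r + 1j * eps_i,
                           kind="permittivity", meta=meta)


@dataclass
class EtalonResult:
    """Gap thickness recovered from interference fringes."""

    thickness_um: float
    se_um: float
    n_extrema: int


def etalon_thickness(empty_cuvette: ComplexSpectrum) -> EtalonResult:
    """Air-gap thickness of an empty cuvette from its fringe spacing.

    Multiple reflections between parallel windows modulate the transmission
    with period dnu = 1/(2 d) (n_gap = 1); the extrema of the smoothed
    spectrum are located, their positions regressed on their index (the
    slope is dnu/2), and d = 1/(2 dnu) returned with the standard error
    propagated from the regression.
    """
    if empty_cuvette.kind != "transmission":
        raise ValueError("etalon analysis expects a transmission spectrum")
    nu = empty_cuvette.grid.wavenumbers
    y = np.asarray(empty_cuvette.values, dtype=float)
    win = max(5, y.size // 25) | 1
    smooth = signal.savgol_filter(y, win, 2) if y.size > win else y
    prom = 0.1 * (smooth.max() - smooth.min())
    peaks, _ = signal.find_peaks(smooth, prominence=prom)
    troughs, _ = signal.find_peaks(-smooth, prominence=prom)
    extrema = np.sort(np.concatenate([nu[peaks], nu[troughs]]))
    # >= 3 full fringes = >= 6 alternating extrema
    if extrema.size < 6:
        raise ValueError(
            f"only {extrema.size} extrema detected; need at least 3 fringes")
    idx = np.arange(extrema.size)
    coef, cov = np.polyfit(idx, extrema, 1, cov=True)
    half_spacing = coef[0]
    se_half = float(np.sqrt(cov[0, 0]))
    dnu = 2 * half_spacing
    d_cm = 1.0 / (2.0 * dnu)
    se_cm = d_cm * (2 * se_half) / dnu  # relative errors propagate linearly
    return EtalonResult(thickness_um=d_cm * 1e4, se_um=se_cm * 1e4,
                        n_extrema=int(extrema.size))
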