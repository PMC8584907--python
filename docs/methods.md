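# Methods

## Conventions and units

All user-facing quantities use the units this field reports: wavenumber ν
in cm⁻¹, times in ps, thicknesses in µm, conductivity in S/m, temperature
in K. Internally each module converts once to SI angular frequency,
ω = 2πcν. The permittivity sign convention is ε\* = ε′ + iε″ with ε″ ≥ 0
for passive media; it is asserted in tests and fixed consistently through
the FFT conventions below.

The default analysis grid is 250 equally spaced points over 10–110 cm⁻¹.
That band is wide enough to constrain the fast Debye term and the low-
frequency wing of the intermolecular stretch band, and narrow enough that
carbohydrate intramolecular relaxations (times > 10 ps) contribute nothing.

## TDS processing

The differential two-cuvette scheme treats the thick-cuvette trace as
"sample" and the thin-cuvette trace as "background"; their ratio in the
frequency domain isolates the extra 50.2 µm of solution and cancels the
cuvette windows, so no window transfer function is modelled. Internal
Fabry–Pérot reflections inside the thin water layer are likewise not
deconvolved: water is strongly absorbing in this band and the differential
referencing suppresses the residual to below the other error terms (the
synthetic generator also omits them by default, so the closure test is
consistent).

Numerically: traces are zero-padded (8× next power of two) before the real
FFT; amplitude and unwrapped phase are interpolated separately onto the
analysis grid, keeping the phase continuous. With numpy's `exp(−iωt)`
analysis convention a delaying medium *lowers* the spectral phase, so
n(ν) = 1 − Δφ/(2πνΔl) with Δφ the unwrapped sample-minus-background phase.
The unwrapped phase is anchored by extrapolating its low-frequency end to
ν → 0, where it must be a whole number of cycles; if the intercept is
ambiguous (off by more than 0.3 of a cycle) the branch is chosen that
brings the band-averaged index closest to the water-like value 2.3. The
conditional form matters: unconditional "closest to water" scoring would
corrupt legitimate non-water media such as pure-delay calibration layers.

**Transmittance convention.** Tr(ν) is the *power* transmittance. This is
what makes the extraction formulae the exact complex square of n + iκ with
κ = −ln Tr/(4πνl); the field-amplitude ratio |S/B| is squared before use.
The identity ε\* = (n + iκ)² is asserted elementwise in tests, and the
round trip generator → traces → ε\* closes to < 2 % on both parts.

Etalon thickness: an empty cuvette shows interference fringes with spacing
Δν = 1/(2d) (air gap, n = 1). Extrema of the Savitzky–Golay-smoothed
transmission are located by prominence-based peak detection, their
positions regressed on their index (slope = Δν/2), giving d = 1/(2Δν) with
a standard error propagated from the regression. At least three full
fringes (six alternating extrema) are required.

## Effective-medium stage

Both mixing rules relate the solution permittivity ε_s\* to the host
(water) ε_w\* and inclusion (solute) ε_c\* permittivities at volume
fraction f:

* Maxwell Garnett, for small spherical or chaotically oriented inclusions;
* a fiber-inclusion model in its low-concentration form,
  ε_s = ε_w + f(ε_c − ε_w)(5ε_w + ε_c)/(3(ε_w + ε_c)), for polymers.

Cleared of denominators each is a complex quadratic in ε_w, solved per grid
point. Root selection: keep roots with ε″ ≥ −10⁻⁹ and ε′ > 0; if both
qualify take the root closer to ε_s; a continuity sweep then removes
isolated branch jumps larger than 10× the local inter-point variation. The
forward relation is the arbiter throughout — forward∘inverse is the
identity to ≤ 10⁻¹⁰ on physical inputs, which the tests enforce on 1000
random draws for both geometries.

The printed closed-form solution of the fiber quadratic (real intermediates
a, b, c, d and e = 2(5f − 3)) is implemented separately
(`fiber_invert_closed_form`) and cross-checked against the generic
quadratic solve; the contract is defined by exact satisfaction of the
forward relation, since radical expressions of this kind are typographically
fragile. The closed form equals the root (a + ib − √3·√(c + id))/e with the
principal complex square root.

Volume fractions are caller-supplied or computed as mass concentration ×
specific volume (defaults quoted per solute class: 0.62 cm³/g for
glucose/galactose, 0.60 for dextran/amylopectin, 0.55 for the uronic
acids); geometry is always explicit, never inferred.

## Dielectric model and fit

The model permittivity is two Debye terms, one damped harmonic oscillator,
a high-frequency constant and a dc-conductivity term (see README for the
formula). Fixed during fitting: τ₁ = 8.28 ps (pure water at 25 °C — Δε₁
and τ₁ move oppositely upon binding, so only the strength is left free),
ε∞ = 2.5, and σ₀ at its measured value (0 when below 0.008 S/m). The six
free parameters are Δε₁, Δε₂, τ₂, A, ω₀, γ, with A parametrised internally
as the dimensionless ratio A/ω₀² that is also the reported quantity.

The objective is s = (1/N)Σ[((ε′_mod − ε′_exp)/ε′_mod)² + (ε″ analogue)²].
Normalisation by the *model* value is kept as the method defines it, even
though experiment-normalised residuals would be more conventional. The
optimizer is bounded trust-region least squares (`scipy.optimize
.least_squares`, method `trf`) on the stacked relative residuals, whose
mean of squares is exactly s; tolerances 10⁻¹⁴ so noiseless self-fits reach
s ≲ 10⁻³⁰. Multistart (default 8) jitters the initial point ±30 % around
the pure-water values; the first start is un-jittered; seed 0 by default.
Bounds (Δε₁ ∈ [20, 120], Δε₂ ∈ [0.1, 10], τ₂ ∈ [0.05, 2] ps,
ω₀ ∈ [120, 350] cm⁻¹, γ ∈ [50, 500] cm⁻¹, A/ω₀² ∈ [0.3, 5]) are generous
envelopes whose main job is preventing the two Debye terms from swapping
roles. Parameters landing on a bound raise a warning; a fit whose s exceeds
0.0021 — the worst value seen in careful repeated water-phase analyses —
is flagged by the pipeline.

## Free-water statistic

n = 3Δε₂/[(Δε₂ + E)·E] × 9kTε₀/(Np²) × 100 %, with E = ε∞ + A/ω₀² + 2.
The constants are deliberately the printed 3-digit values
(k = 1.38×10⁻²³ J/K, p = 6.17×10⁻³⁰ C·m, N = 6.02×10²³ × 55.56×10³ m⁻³,
T = 298.15 K) rather than CODATA, so the statistic reproduces reported
tables on their own terms. Recomputing n from the reported rounded
replicate-mean Δε₂ and A/ω₀² of all seven studied samples lands within
0.02 points of each reported percentage (the residual offset is consistent
with n having been computed per replicate before averaging, which the
pipeline also does; both routes are exposed). The statistic is strictly
increasing in Δε₂ and strictly decreasing in A/ω₀², asserted numerically.

## Synthetic-data generator

The generator emulates the study conditions: 250-point 10–110 cm⁻¹
spectra; water phases from the dielectric model with the replicate-mean
parameter sets of the seven studied samples as presets (volume fractions
from their mass concentrations and specific volumes; conductivities 1.3
and 1.86 S/m for the two dissociating acids, zero otherwise); smooth,
resonance-free solute spectra (flat placeholders ε\* = 3.0 + 0.2i for the
monosaccharide preset and 2.6 + 0.15i for the polysaccharide preset —
plausible magnitudes, overridable, and nothing downstream depends on them);
effective-medium mixing at f ≈ 0.03; and virtual pulse pairs (Gaussian-
derivative reference pulse, width 0.06 ps, sampled at 0.05 ps over 40 ps,
covering the band with margin) propagated through the default 50.06/100.26
µm cuvette pair.

**Replicate noise.** Run-to-run variation of repeated THz measurements is
dominated by slow drifts that move whole spectra coherently, not by white
point noise. Pure per-point noise is also statistically awkward here: with
the model-normalised objective it biases the fitted parameters by ~σ²
terms, which at the dispersion magnitudes seen in replicate tables would
exceed the confidence intervals themselves. The default `NoiseModel`
therefore combines small multiplicative point noise (σ_rel = 0.005) with
per-replicate *parameter* jitter, whose per-parameter relative amplitudes
(2.5 % on Δε₁ … 12 % on γ) are calibrated so that 20-replicate aggregated
95 % CIs reproduce the dispersions observed for pure water. The
calibration property (all six CIs within a factor 3 of those magnitudes)
and unbiased parameter recovery within the aggregated CIs are both tested.
All randomness is seeded, with independent streams per replicate index.

What the generator does **not** emulate: detector dark noise and delay-line
jitter, cuvette-window dispersion, internal Fabry–Pérot reflections
(excluded by default to match the differential scheme's assumption), or
any concentration dependence of the hydration shell. Passing tests
therefore demonstrate the correctness and statistical calibration of the
analysis chain, not instrument-level robustness.

## Problem sizes

The test suite and acceptance script run the study-scale problems
directly: 250-point spectra, 20 replicates, 8-start fits — each full
20-replicate pipeline completes in a few seconds, so no scaling down was
needed anywhere.

## Known limitations

* The fiber mixing rule is the low-concentration limit only; `MixtureSpec`
  rejects f ≥ 0.3 and the forward model warns above that range.
* Interpolation of measured spectra onto the 250-point grid is linear.
* The phase-branch heuristic assumes water-like solutions when the ν → 0
  anchor is ambiguous; exotic media should supply well-anchored traces.
* τ₁ is a fixed input; no temperature model is provided.
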