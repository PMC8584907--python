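# thzhyd

Terahertz time-domain spectroscopy (THz-TDS) analysis of the **dynamic
hydration shells** of dissolved biomolecules — carbohydrates in particular.

Water around a solute relaxes and vibrates differently from bulk water, and
the 10–110 cm⁻¹ band is where those collective dynamics live. THz-TDS
measures the electric-field time profile *E(t)* of picosecond pulses, which
yields both amplitude and phase and hence the full complex dielectric
permittivity ε\*(ν) = ε′ + iε″ of a liquid sample. `thzhyd` implements the
complete analysis chain from pulse pairs to a physical summary of the water
phase:

1. **TDS processing** — a solution is measured in two cuvettes that differ
   only in inter-window distance (50.06 and 100.26 µm); referencing the
   thick-cuvette pulse against the thin-cuvette pulse isolates a 50.2 µm
   solution layer and cancels window effects. From the power transmittance
   Tr(ν) and refractive index n(ν) of that layer,

       ε′ = n² − [ln Tr / (4πνl)]²,   ε″ = −n ln Tr / (2πνl),

   i.e. ε\* = (n + iκ)² with κ = −ln Tr/(4πνl).
2. **Effective-medium inversion** — the solution is a biphasic dielectric:
   water host plus solute inclusions at volume fraction *f* ≈ 0.03
   (mass concentration × specific volume). The solute contribution is
   removed with the Maxwell Garnett relation (compact/chaotic inclusions,
   monosaccharides) or a fiber-inclusion model (polysaccharides), each a
   complex quadratic in the water-phase permittivity ε_w\*.
3. **Dielectric decomposition** — ε_w\*(ω) is fit with

       ε\*(ω) = Δε₁/(1 − iωτ₁) + Δε₂/(1 − iωτ₂)
               + A/(ω₀² − ω² − iωγ) + ε∞ + iσ₀/(ε₀ω),

   two Debye relaxations (bulk-like water, τ₁ = 8.28 ps fixed; free or
   weakly bound molecules, τ₂ ≈ 0.3 ps) plus a damped oscillator for the
   intermolecular hydrogen-bond stretch, with ε∞ = 2.5 and the measured dc
   conductivity σ₀ held fixed — six free parameters. The fit minimises the
   mean squared relative deviation *s* over 250 spectral points.
4. **Free-water fraction** — the share of water molecules with unoccupied
   hydrogen-bond vacancies follows from the fast-relaxation strength:

       n = 3Δε₂ / [(Δε₂ + E)·E] × 9kTε₀/(Np²) × 100 %,   E = ε∞ + A/ω₀² + 2.

A seeded synthetic-data generator replaces the spectrometer: it produces
model water-phase spectra with replicate noise, smooth solute spectra,
mixed solution spectra, and virtual pulse pairs, so the whole pipeline is
testable end to end without instrument data.

## Worked example

Simulate 20 replicates of a glucose solution (f = 0.031, spherical
inclusions), remove the solute phase, fit each replicate and aggregate:

```python
from thzhyd import (FrequencyGrid, NoiseModel, FitConfig, fit_model,
                    free_water_fraction, make_water_phase, make_solution)
from thzhyd.model import PURE_WATER, aggregate_replicates
from thzhyd.medium import MixtureSpec, remove_mixture
from thzhyd.synth import PRESETS

grid = FrequencyGrid.default()          # 250 points, 10-110 cm^-1
preset = PRESETS["glucose"]
noise = NoiseModel(seed=0)

results = []
for r in range(20):
    water_true = make_water_phase(preset.water_params, grid, noise, replicate=r)
    solution = make_solution(water_true, preset.solute, preset.f, "spherical")
    mix = MixtureSpec("spherical", preset.f, preset.solute.evaluate(grid))
    results.append(fit_model(remove_mixture(solution, mix), FitConfig(seed=0)))

summary = aggregate_replicates(results)
print(summary.round(4))
```

```
                 mean     ci95
d_eps1        62.0265   0.6416
d_eps2         2.9543   0.0383
tau2_ps        0.3283   0.0066
w0_cm        214.3794   4.7155
gamma_cm     195.2206  11.0341
a_over_w0sq    1.7962   0.0174
n_free_pct     3.9179   0.0322
```

Every generating parameter is recovered within its 95 % confidence
interval. The last row is the free-water percentage: 3.92 ± 0.03 % in the
glucose solution against 3.77 % for pure water
(`free_water_fraction(PURE_WATER)`) — the hydration shell holds *more*
fast-relaxing molecules than bulk water, while the lowered Δε₁ (62.0 vs
68.9) shows an increased overall binding degree.

The same analysis is available from the shell:

```sh
thzh simulate --preset glucose --replicates 20 --seed 0 --out-dir sim
thzh tds --sample s.csv --background b.csv --dl-um 50.2 --out eps_s.csv
thzh invert-medium --solution eps_s.csv --solute solute.csv \
     --f 0.031 --geometry spherical --out eps_w.csv
thzh fit --eps eps_w.csv --out fit.json
thzh pipeline --config run.yaml
```

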