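# memlipid

Quantitative analysis of membrane lipid homeostasis for cell biologists and
lipidomicists: how mammalian cells remodel their lipidome when dietary
polyunsaturated fatty acids (PUFAs such as DHA, 22:6, or arachidonic acid,
20:4) flood into membrane phospholipids, and what that remodeling does to
membrane physical properties. The package covers the four measurement
modalities such a study rests on:

1. **Lipidome composition statistics** from shotgun-lipidomics species
   tables (pmol abundances, Lipotype-style nomenclature):
   mol% normalization with storage-lipid (TAG/SE) exclusion, the
   concentration-weighted unsaturation index
   `UI = Σᵢ wᵢ·dᵢ / Σᵢ wᵢ` (wᵢ mol%, dᵢ total double bonds),
   fatty-acid-set fractions (ω-3 = {22:6, 20:5, 24:6},
   ω-6 = {20:4, 22:4, 24:4}, including metabolic derivatives),
   "remaining-lipid" analyses that exclude the supplemented FA before
   recomputing statistics, saturation profiles, class composition, and
   fold changes with delta-method errors.
2. **First-order kinetics** of FA incorporation and wash-out:
   `y(t) = y∞ + (y₀ − y∞)·e^(−kt)`, half-time `t½ = ln 2 / k`.
3. **C-Laurdan generalized polarization (GP)** from emission spectra
   (`GP = (Σ₄₂₀⁴⁶⁰I − Σ₄₇₀⁵¹⁰I)/(Σ₄₂₀⁴⁶⁰I + Σ₄₇₀⁵¹⁰I)`) and from
   two-channel spectral images (433–463 / 473–503 nm bands): 2×2 binning,
   background subtraction, dual-channel 3-SD thresholding, per-pixel GP
   maps, and three independent internal-membrane quantification methods
   (mask histogram, line scan, perinuclear ROI) plus ΔGP between
   treatment groups.
4. **Fick's-law membrane permeability** from fluorescein diacetate (FDA)
   influx traces: `Q = P·A·(C_out − C_in)` with `C_in = 0` (intracellular
   hydrolysis), giving the permeability coefficient `P = Q/(A·C_out)` in
   cm/s from a fluorescein-calibrated fluorescence slope.

A seed-deterministic synthetic-data generator produces every input the
analysis consumes — species tables with configurable supplementation
effects, noisy kinetic courses, two-channel cell images with prescribed GP
fields, emission spectra, FDA traces — and retains ground truth so every
estimator can be scored. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

```python
import dataclasses
import numpy as np
import memlipid as m

# DHA-supplementation experiment: 4 replicates, 10% lognormal CV
samples, truth = m.simulate_lipidome(dataclasses.replace(m.DHA_SUPPLEMENTATION, seed=1))
gpl = [m.normalize(s, "GPL") for s in samples]
fracs = [m.fraction_containing(l, m.OMEGA3_SET) for l in gpl]
ui = [m.unsaturation_index(l).value for l in gpl]
rem = [m.unsaturation_index(m.exclude_set(l, m.OMEGA3_SET)).value for l in gpl]
print(f"omega-3 GPL fraction: {np.mean(fracs):.1f} +/- {np.std(fracs, ddof=1):.1f} mol%")
print(f"unsaturation index:   {np.mean(ui):.2f} (remaining lipids: {np.mean(rem):.2f})")

# incorporation kinetics at a 4 h half-time with 10% noise
tc, _ = m.simulate_time_course("incorporation", half_time_h=4.0, amplitude=15.0,
                               noise_sd=1.5, seed=1)
fit = m.fit_first_order(tc)
print(f"incorporation half-time: {fit.half_time:.2f} h (k = {fit.k:.3f} /h)")

# FDA permeability from the printed reference inputs
we = m.worked_example()
print(f"FDA permeability, strict Fick arithmetic:   {we['P_strict_cm_per_s']:.2e} cm/s")
print(f"FDA permeability, effective 2000 um^2/cell: {we['P_effective_cm_per_s']:.2e} cm/s")
```

prints

```
omega-3 GPL fraction: 15.4 +/- 0.4 mol%
unsaturation index:   2.12 (remaining lipids: 1.43)
incorporation half-time: 4.21 h (k = 0.165 /h)
FDA permeability, strict Fick arithmetic:   1.47e-06 cm/s
FDA permeability, effective 2000 um^2/cell: 2.20e-06 cm/s
```

DHA supplementation lifts ω-3-containing glycerophospholipids to ~15 mol%
(from <1 mol% at baseline) and raises the overall unsaturation index
(untreated ≈ 1.70 here), while the lipids *not* containing the supplemented
FA become more saturated — the remaining-lipid index drops to 1.43. The
fitted incorporation half-time recovers the configured 4 h within the noise.
The permeability block reports both readings of the Fick's-law reference
calculation: strict arithmetic on the stated inputs (flux 6.6×10⁻⁵ nmol/s,
250,000 cells × 3000 μm², 2.5 μg/mL FDA) and the variant with a smaller
effective transport area that matches the commonly quoted ~2.2×10⁻⁶ cm/s.

A command-line interface mirrors the library
(`memlipid simulate …`, `memlipid lipidome-stats`, `memlipid fit-kinetics`,
`memlipid gp-spectrum`, `memlipid gp-map`, `memlipid permeability`,
`memlipid run --config study.yaml`).

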