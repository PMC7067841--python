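# Methods

This note documents the models, conventions and numerical choices behind
`memlipid`, and what the synthetic-data generators do and do not emulate.

## Lipid nomenclature

Species are annotated `[class]-[C]:[D];[H]` (total acyl carbons : double
bonds ; hydroxyls), e.g. `SM-32:2;1`, optionally chain-resolved with one
block per chain (`PC-18:1;0-24:2;0`). The class vocabulary is the standard
shotgun-lipidomics set (PC, PE, PS, PI, PG, PA, their lyso `L…` and ether
`… O-` variants, CL, SM, Cer, HexCer, DiHexCer, DAG, Chol, TAG, SE).
Conventions:

- Both hyphen- and space-separated dialects parse; canonical output uses
  hyphens. The `;H` field defaults to 0 when omitted.
- The `O-` marker is part of the class token, not the composition.
- Isotope-labelled cholesterol standards (`Chol D6`) collapse onto `Chol`
  with a warning; no other isotope handling exists.
- Chain-resolved totals are validated against the chain sums at
  construction. A one-block composition always parses as a sum
  composition; for single-chain classes (lyso species, SE) the one chain
  is implied by the totals and is exposed by `chains_of`.

## Composition statistics

Abundances (pmol) are converted to mol% of a *scope*: `all` lipids,
`membrane` (TAG and SE dropped, then renormalized — storage lipids are not
part of membranes), or `GPL` (glycerophospholipids only). CL is excluded
from GPL scope: its four acyl chains make per-chain statistics
incommensurate with the diacyl classes that dominate the scope.

- **Unsaturation index**: mol%-weighted mean of total double bonds per
  lipid. Cholesterol (no acyl chains) is excluded with a logged note.
  Hydroxyls are ignored by all unsaturation statistics.
- **Fatty-acid-set containment** is a chain-level judgment. The shipped
  sets include the supplemented FA *and* its metabolic derivatives:
  ω-3 = {22:6, 20:5, 24:6} (DHA retro-converts to EPA, which elongates to
  24:6), ω-6 = {20:4, 22:4, 24:4}. A species without chain resolution is
  judged only when its class forces a single chain; otherwise it counts as
  not containing the member, and the mol% of unresolved abundance is
  reported by `saturation_profile` so users can bound the error —
  guessing chain splits would fabricate data.
- **Remaining-lipid analysis** (`exclude_set`) removes every containing
  species and renormalizes to 100 mol%, so compensatory remodeling is not
  masked by the over-abundant supplemented species.
- **Saturation profile**: species-level double-bond distribution (top bin
  pools ≥7), the fully saturated (0 db) species mol%, and chain-level
  percentages (0-db chains; 5–6-db chains) abundance-weighted over
  chain-resolved species only. "Di-/tri-unsaturated" is species-level
  (total double bonds 2–3); a chain-level reading is available through the
  distribution but is not the default, since species totals are defined
  for every lipid while chain assignments are not.
- **Fold changes** are ratios of group means with a delta-method SD
  (independent groups, first-order propagation). Replicate aggregation is
  always compute-per-sample, then mean ± SD across replicates.

Normalization closure (sum = 100 ± 1e-9), scale invariance, and agreement
with brute-force loop implementations to 1e-10 relative are enforced by
the test suite.

## First-order kinetics

Incorporation and wash-out courses are fit with the three-parameter
mono-exponential `y(t) = y∞ + (y₀ − y∞)e^(−kt)` (sign of `y₀ − y∞`
selects rise vs decay; no separate wash-out form). Unweighted nonlinear
least squares (`scipy.optimize.least_squares`, TRF) with
`k ∈ [1e-6, 1e3] /h`; initialization `y₀ = first value`,
`y∞ = last value`, `k = ln2 / (time of closest approach to the midpoint)`,
which is robust for monotone courses. Optimizer failure is reported via a
`converged` flag rather than an exception; `half_time = ln2/k` requires a
converged fit. Courses need ≥4 points and non-constant values (the rate is
otherwise unidentifiable). Replicate readings at duplicate times are
averaged before fitting; with balanced replication this equals the pooled
fit.

A practical information limit worth knowing: with 7 time points and noise
at 10% of the amplitude, single-course half-time estimates scatter with
~20% SD (an independent optimizer reproduces the same scatter), so only
the *median* across many courses is tightly constrained at that noise
level; per-course 20%-accuracy rates above 90% require noise around a few
percent.

## Generalized polarization

`GP = (I_blue − I_red)/(I_blue + I_red) ∈ [−1, 1]`; higher GP = more
tightly packed, less polar membrane environment. Two band conventions are
supported and never mixed: spectroscopy integrates 420–460 and 470–510 nm
(inclusive) from a spectrum covering at least that range; imaging uses
detector bands 433–463 and 473–503 nm, which arrive already integrated as
the two channels.

Image pipeline, in order:

1. **2×2 binning** by summation (photon-count preserving; GP is
   ratio-based, so sum vs mean is immaterial — summation is stated for
   bit-exactness).
2. **Background subtraction** per channel (clipped at 0). Background
   statistics come from a user-supplied ROI when given. The automatic
   fallback seeds on pixels in the lowest 10% of the robust intensity
   range (0.5–99.5 percentile) in both channels and grows the selection by
   upward 3-sigma clipping until fixed point. A rank-based percentile
   cutoff was rejected: it samples only the lower tail of the background
   distribution, biasing the mean and SD low and letting noisy background
   pixels through the threshold.
3. **Thresholding**: valid pixels must exceed 3 × SD(background) after
   subtraction in *both* channels. Valid pixels with a zero channel sum
   are invalidated and counted.

Internal-membrane quantification, three ways (they cross-validate each
other; agreement within ±0.03 is asserted on synthetic cells):

- `mask_histogram`: mean + 100-bin histogram over an internal mask
  (supplied, or auto-derived by eroding the valid mask 4 px to strip the
  peripheral PM band; the stripped band then yields an approximate PM
  mean). Histograms are reported as raw counts and area-normalized
  density.
- `line_scan`: per image row, GP peaks with prominence ≥25% of the row's
  GP range; the two outermost peaks are the PM, the mean of values between
  them (excluding 2 px around each peak) is internal. Segments are padded
  so boundary maxima register; rows shorter than half the longest chord
  are skipped (near-tangent rows run along the ring and contain no
  internal stretch), as are rows without two peaks (counted and warned).
- `perinuclear_roi`: mean over a user ROI drawn around the dark nucleus.

ΔGP is mean(treated) − mean(untreated) for one region kind and one method;
mixing methods raises.

## Permeability

`P = Q / (A·(C_out − C_in))` with `C_in = 0` hard-wired for FDA (instant
intracellular hydrolysis) but the general form implemented for reuse.
`Q` comes from the linear-regression slope of fluorescence vs time scaled
by a fluorescein calibration (OLS through the origin by default; ≥3
standards spanning ≥10× concentration). The slope uses the full trace by
default — influx is linear over the assay window — with the longest prefix
at R² ≥ 0.99 reported as a diagnostic. `A = n_cells × area per cell`;
defaults 250,000 cells and 3000 μm². Molar masses: FDA 416.4 g/mol,
fluorescein (sodium salt) 376.3 g/mol; both configurable. Mass and molar
concentration inputs are interconverted exactly (1 mL = 1 cm³).

The reference calculation from the stated inputs (Q = 6.6×10⁻⁵ nmol/s,
A = 7.5 cm², C_out = 2.5 μg/mL ≈ 6.0×10⁻⁹ mol/cm³) gives
P ≈ 1.47×10⁻⁶ cm/s by strict arithmetic; the commonly quoted
~2.2×10⁻⁶ cm/s corresponds to a smaller effective per-cell transport area
(~2000 μm², plausible once membrane folding and cell-size assumptions are
relaxed). `worked_example()` reports both rather than guessing intent.

## Synthetic data: what it emulates, and what it does not

All generators take a seed and are bit-deterministic; every generator
returns a truth record sufficient to score the downstream estimator.

- **Lipidomes.** A hand-constructed baseline of 75 species (chain-resolved
  glycerophospholipids, SM/Cer/HexCer, DAG, Chol ~27 mol%, TAG/SE) with
  class proportions loosely guided by published mammalian whole-cell
  ranges; ω-3-containing species sit below 1 mol% of GPLs, ω-6 at
  ~5.9 mol%, fully saturated species at ~7% and di-/tri-unsaturated at
  ~42% of GPLs. The supplementation transform is a joint constraint on
  the final GPL composition — containing fraction = target, saturated
  fraction = fold × baseline, di/tri fraction = depletion × baseline,
  remainder rescaled, non-GPL species untouched — so configured effect
  sizes are *exactly* recoverable at zero noise (sequential
  multiplications would shift each other's fractions). Study-condition
  defaults: DHA target 15 mol%, AA target 20 mol% (the supplemented 20:4
  species plus converted 22:4/24:4 chains, which alone reach 13–15 mol%),
  saturated fold 2.0, di/tri depletion 0.6, 4 replicates, 10% CV.
  Noise is multiplicative lognormal with unit mean (compositional data);
  abundances are scaled to 10⁵ pmol total, immaterial to all statistics.
  Not emulated: the ~600-species richness of real lipidomes, class-
  dependent noise, inter-replicate correlations, or any cell biology
  (transcription, viability). Passing recovery tests therefore shows the
  estimators are correct and unbiased under realistic noise — not that
  real-data preprocessing upstream of the species table is handled.
- **Time courses**: exact first-order curves plus i.i.d. Gaussian noise
  (defaults: half-times 4 h incorporation / 25 h wash-out, amplitude
  15 mol%, 7–8 points over 0–48/0–96 h). No replicate structure, no
  drift.
- **Images**: an elliptical cell on a 256×256 grid with a ≥2-px (binned)
  PM ring at GP 0.45, interior at GP 0.10, a dark nucleus, and uniform
  background haze (GP 0, 20 counts) *under* the cell signal (500 counts),
  split into channels as I(1±g)/2 with optional Poisson noise. Geometry
  is laid out on the post-binning grid and upsampled 2×, so truth masks
  are exact in binned coordinates. Not emulated: organelle texture,
  out-of-focus light, detector offsets/flat-field, multiple cells.
- **Spectra**: two Gaussian bands (440/490 nm, SD 15 nm, 1-nm sampling
  400–550 nm) with weights solved so the band sums realize the target GP
  exactly; additive Gaussian noise clipped at 0.
- **Traces**: exactly linear fluorescence from a prescribed P (default
  2.2×10⁻⁶ cm/s, 250,000 cells × 3000 μm², C_out 6×10⁻⁹ mol/cm³, 5 min at
  1 Hz) plus Gaussian noise; no hydrolysis saturation or quenching.

## Problem sizes and tolerances

The bundled checks use 200 seeded courses for kinetic medians (within 15%
of truth), 4 replicates at 10% CV for lipidome effect sizes (within
2 SEM), single 256×256 images for the GP pipeline (fields within ±0.03,
valid mask within 2% of truth pixel count, three methods within ±0.03 of
each other), and 3% for permeability round trips at 1% trace noise. Mol%
closure is enforced at 1e-9 absolute, oracle agreement at 1e-10 relative,
GP construction identities at 1e-9 or tighter.

## Known limitations

- Sum-only multi-chain species cannot be assigned to fatty-acid sets;
  heavily unresolved tables bias set fractions downward (the unresolved
  mol% is reported so the bias can be bounded).
- The kinetic model is phenomenological; it does not separate synthesis,
  uptake and dilution-by-growth, which the wash-out half-time conflates.
- Line-scan PM values are peak statistics and carry a small upward noise
  bias relative to the ring mean (~0.02 at the default photon budget).
- Hypothesis tests (t-tests, ANOVA) are deliberately out of scope; use
  `scipy.stats`/`statsmodels` on the tidy statistics table.
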