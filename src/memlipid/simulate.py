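"""Synthetic inputs with retained ground truth for every analysis stage.

Generators emulate: whole-cell shotgun-lipidomics species tables with
configurable PUFA-supplementation effects; first-order incorporation and
wash-out time courses; two-channel C-Laurdan images of a cell with a
tightly packed plasma-membrane ring, looser internal membranes and a dark
nucleus; band-structured emission spectra; and linear FDA influx traces
built from a prescribed permeability coefficient.  Every generator is
deterministic for a fixed seed and returns a machine-readable truth
record sufficient to score the downstream estimators.

The bundled baseline species profile is synthetic: hand-constructed, with
class proportions loosely guided by published mammalian whole-cell ranges
(PC-dominant glycerophospholipids, ~27 mol% cholesterol, mono- and
di-unsaturated species most abundant, omega-3-containing lipids below
1 mol% of glycerophospholipids).  It is a fixture for testing, not data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .gp import EmissionSpectrum, SpectralImagePair
from .kinetics import TimeCourse
from .lipidome import (
    OMEGA3_SET,
    OMEGA6_SET,
    FattyAcidSet,
    LipidomeSample,
    species_contains,
)
from .nomenclature import LipidSpecies, parse_species
from .permeability import Calibration, FluorescenceTrace

__all__ = [
    "BASELINE_SPECIES",
    "LipidomeSimConfig",
    "ImageSimConfig",
    "TraceSimConfig",
    "DHA_SUPPLEMENTATION",
    "AA_SUPPLEMENTATION",
    "UNTREATED",
    "simulate_lipidome",
    "simulate_time_course",
    "simulate_spectral_image",
    "simulate_fda_trace",
    "simulate_emission_spectrum",
]

# ---------------------------------------------------------------------------
# Baseline lipidome profile (synthetic; weights renormalized to 100 mol%)
# ---------------------------------------------------------------------------

BASELINE_SPECIES: tuple[tuple[str, float], ...] = (
    # PC
    ("PC-16:0;0-18:1;0", 7.0),
    ("PC-16:0;0-16:0;0", 1.6),
    ("PC-14:0;0-16:0;0", 0.5),
    ("PC-16:0;0-18:2;0", 3.5),
    ("PC-18:1;0-18:1;0", 2.8),
    ("PC-18:0;0-18:1;0", 2.5),
    ("PC-16:0;0-20:4;0", 0.9),
    ("PC-18:0;0-20:4;0", 0.5),
    ("PC-16:0;0-22:4;0", 0.1),
    ("PC-18:1;0-18:2;0", 1.7),
    ("PC-16:1;0-18:1;0", 1.4),
    ("PC-16:0;0-16:1;0", 1.3),
    ("PC-18:0;0-18:2;0", 1.2),
    ("PC-16:0;0-22:6;0", 0.10),
    ("PC-18:0;0-22:6;0", 0.05),
    ("PC-16:0;0-20:5;0", 0.03),
    ("PC-16:0;0-20:3;0", 0.8),
    ("PC-18:0;0-20:3;0", 0.5),
    ("PC-14:0;0-18:1;0", 0.6),
    ("PC-18:1;0-20:3;0", 0.5),
    # PE
    ("PE-16:0;0-18:1;0", 2.2),
    ("PE-18:0;0-18:1;0", 1.6),
    ("PE-18:0;0-20:4;0", 0.4),
    ("PE-16:0;0-20:4;0", 0.2),
    ("PE-18:0;0-22:4;0", 0.1),
    ("PE-18:1;0-18:1;0", 1.3),
    ("PE-16:0;0-18:2;0", 1.2),
    ("PE-18:0;0-18:2;0", 0.9),
    ("PE-18:0;0-22:6;0", 0.10),
    ("PE-16:0;0-22:6;0", 0.06),
    ("PE-18:0;0-18:0;0", 0.35),
    ("PE-16:0;0-16:0;0", 0.30),
    ("PE-18:1;0-20:3;0", 0.5),
    ("PE-16:0;0-20:3;0", 0.45),
    ("PE-18:1;0-18:2;0", 0.8),
    # PS
    ("PS-18:0;0-18:1;0", 2.0),
    ("PS-18:0;0-20:4;0", 0.1),
    ("PS-18:0;0-18:2;0", 0.5),
    ("PS-18:1;0-18:1;0", 0.5),
    ("PS-18:0;0-22:6;0", 0.05),
    ("PS-18:0;0-18:0;0", 0.35),
    ("PS-16:0;0-18:1;0", 0.6),
    # PI
    ("PI-18:0;0-20:4;0", 0.35),
    ("PI-16:0;0-20:4;0", 0.10),
    ("PI-16:0;0-18:1;0", 0.9),
    ("PI-18:0;0-18:1;0", 0.8),
    ("PI-18:0;0-18:2;0", 0.6),
    ("PI-18:0;0-18:0;0", 0.20),
    ("PI-18:1;0-18:1;0", 0.4),
    # PG / PA
    ("PG-16:0;0-18:1;0", 0.5),
    ("PG-18:1;0-18:1;0", 0.4),
    ("PA-16:0;0-18:1;0", 0.5),
    ("PA-18:0;0-18:2;0", 0.4),
    # ether and lyso glycerophospholipids
    ("PC O-16:0;0-18:1;0", 0.8),
    ("PC O-18:1;0-18:1;0", 0.4),
    ("PE O-18:1;0-18:1;0", 0.7),
    ("PE O-16:0;0-18:2;0", 0.6),
    ("LPC-16:0;0", 0.3),
    ("LPC-18:1;0", 0.15),
    ("LPE-18:1;0", 0.10),
    ("CL-72:8;0", 0.8),
    # sphingolipids and other membrane lipids
    ("SM-34:1;2", 3.0),
    ("SM-34:2;2", 1.0),
    ("SM-42:2;2", 1.2),
    ("SM-42:1;2", 0.8),
    ("SM-32:1;2", 0.5),
    ("Cer-34:1;2", 0.4),
    ("Cer-42:1;2", 0.3),
    ("HexCer-34:1;2", 0.25),
    ("DiHexCer-34:1;2", 0.10),
    ("DAG-16:0;0-18:1;0", 0.6),
    ("Chol", 27.0),
    # storage lipids (removed at membrane scope)
    ("TAG-52:2;0", 1.8),
    ("TAG-54:3;0", 1.0),
    ("SE-18:1;0", 0.5),
)

#: Species injected when the baseline lacks the supplemented fatty acid
#: entirely (mass split 60/40).
_INJECTION_SPECIES = ("PC-16:0;0-22:6;0", "PE-18:0;0-22:6;0")


@dataclass
class LipidomeSimConfig:
    """Configuration of a simulated supplementation experiment.

    ``target_fraction_pct`` is the desired mol% (within glycerophospholipid
    scope) of species containing the supplemented fatty acid or its
    derivatives; ``saturated_fold`` and ``di_tri_depletion`` multiply the
    baseline GPL fractions of fully saturated (0 double bonds) and di-/
    tri-unsaturated (2-3 total double bonds) species.  Replicate noise is
    multiplicative lognormal with the given CV.
    """

    condition: str = "untreated"
    supplement_set: Optional[FattyAcidSet] = None
    target_fraction_pct: Optional[float] = None
    saturated_fold: float = 1.0
    di_tri_depletion: float = 1.0
    n_replicates: int = 4
    cv: float = 0.10
    total_pmol: float = 100_000.0
    seed: int = 0
    baseline: Sequence[tuple[str, float]] = BASELINE_SPECIES

    def __post_init__(self) -> None:
        if self.saturated_fold <= 0 or self.di_tri_depletion <= 0:
            raise ValueError("fold factors must be > 0")
        if self.cv < 0:
            raise ValueError("CV must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


#: Study conditions: DHA supplementation raises omega-3-containing GPLs
#: from <1 to ~15 mol% with a ~2-fold saturated-lipid increase and
#: depletion of di-/tri-unsaturated species; AA supplementation raises
#: omega-6-containing GPLs to ~20 mol% (a >3-fold rise over the ~6 mol%
#: baseline: converted chains alone reach 13-15 mol% on top of the
#: supplemented 20:4 species) with the same compensatory folds.
DHA_SUPPLEMENTATION = LipidomeSimConfig(
    condition="DHA",
    supplement_set=OMEGA3_SET,
    target_fraction_pct=15.0,
    saturated_fold=2.0,
    di_tri_depletion=0.6,
)
AA_SUPPLEMENTATION = LipidomeSimConfig(
    condition="AA",
    supplement_set=OMEGA6_SET,
    target_fraction_pct=20.0,
    saturated_fold=2.0,
    di_tri_depletion=0.6,
)
UNTREATED = LipidomeSimConfig(condition="untreated")


def _is_gpl(species: LipidSpecies) -> bool:
    return species.lipid_class.is_glycerophospholipid and species.lipid_class.name != "CL"


def _transform_profile(
    config: LipidomeSimConfig,
) -> tuple[dict[LipidSpecies, float], dict]:
    """Noiseless supplemented mol% profile plus the truth record."""
    profile = {parse_species(n): float(w) for n, w in config.baseline}
    total = sum(profile.values())
    profile = {s: 100.0 * w / total for s, w in profile.items()}

    fa = config.supplement_set
    gpl = {s: w for s, w in profile.items() if _is_gpl(s)}
    G = sum(gpl.values())

    def frac(pred) -> float:
        return sum(w for s, w in gpl.items() if pred(s)) / G

    contains = (lambda s: species_contains(s, fa)) if fa else (lambda s: False)
    sat = lambda s: s.total_double_bonds == 0 and not contains(s)
    ditri = lambda s: s.total_double_bonds in (2, 3) and not contains(s)
    other = lambda s: not (contains(s) or sat(s) or ditri(s))

    c0, s0, d0 = frac(contains), frac(sat), frac(ditri)
    c_t = c0 if config.target_fraction_pct is None else config.target_fraction_pct / 100.0
    s_t = config.saturated_fold * s0
    d_t = config.di_tri_depletion * d0
    o_t = 1.0 - c_t - s_t - d_t
    if c_t >= 1.0 or o_t <= 0:
        raise ValueError(
            f"infeasible transform: containing {c_t:.3f}, saturated {s_t:.3f}, "
            f"di/tri {d_t:.3f} leave no room for the remaining species"
        )

    out = dict(profile)
    for pred, f_old, f_new in ((sat, s0, s_t), (ditri, d0, d_t), (other, 1 - c0 - s0 - d0, o_t)):
        members = [s for s in gpl if pred(s)]
        if not members:
            if f_new > 0 and f_old == 0:
                raise ValueError("cannot scale an empty species group")
            continue
        scale = (f_new / f_old) if f_old > 0 else 0.0
        for s in members:
            out[s] = profile[s] * scale
    members = [s for s in gpl if contains(s)]
    if fa is not None:
        if members:
            scale = (c_t / c0) if c0 > 0 else 0.0
            for s in members:
                out[s] = profile[s] * scale
        elif c_t > 0:
            inject = [parse_species(n) for n in _INJECTION_SPECIES]
            out[inject[0]] = 0.6 * c_t * G
            out[inject[1]] = out.get(inject[1], 0.0) + 0.4 * c_t * G

    truth = {
        "condition": config.condition,
        "seed": config.seed,
        "gpl_fraction_containing_pct": c_t * 100.0 if fa else c0 * 100.0,
        "baseline_fraction_containing_pct": c0 * 100.0,
        "gpl_fully_saturated_pct": s_t * 100.0,
        "baseline_fully_saturated_pct": s0 * 100.0,
        "gpl_di_tri_pct": d_t * 100.0,
        "baseline_di_tri_pct": d0 * 100.0,
        "saturated_fold": s_t / s0 if s0 > 0 else None,
        "supplement_set": fa.label if fa else None,
    }
    return out, truth


def simulate_lipidome(
    config: LipidomeSimConfig = UNTREATED,
) -> tuple[list[LipidomeSample], dict]:
    """Simulate replicate lipidome samples under a supplementation regime.

    The baseline profile is reshaped so that, within GPL scope, the mol%
    of supplemented-FA-containing species hits the configured target and
    the fully saturated / di-tri-unsaturated fractions change by the
    configured folds (non-GPL species are untouched).  Each replicate then
    receives i.i.d. multiplicative lognormal noise (unit mean, given CV)
    per species and is scaled to picomoles.
    """
    profile, truth = _transform_profile(config)
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.cv**2)) if config.cv > 0 else 0.0
    samples = []
    species = list(profile)
    weights = np.array([profile[s] for s in species])
    for r in range(config.n_replicates):
        if sigma > 0:
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(species))
        else:
            noise = np.ones(len(species))
        pmol = config.total_pmol * (weights * noise) / 100.0
        samples.append(
            LipidomeSample(
                sample_id=f"{config.condition}_r{r + 1}",
                abundances={
                    s: float(v) for s, v in zip(species, pmol) if v > 0
                },
                condition=config.condition,
                replicate=r + 1,
            )
        )
    truth["n_replicates"] = config.n_replicates
    truth["cv"] = config.cv
    return samples, truth


# ---------------------------------------------------------------------------
# Kinetic time courses
# ---------------------------------------------------------------------------

def simulate_time_course(
    kind: str = "incorporation",
    half_time_h: float = 4.0,
    amplitude: float = 15.0,
    noise_sd: float = 0.0,
    times: Optional[Sequence[float]] = None,
    seed: int = 0,
    baseline: float = 0.0,
) -> tuple[TimeCourse, dict]:
    """First-order time course with additive Gaussian noise.

    ``incorporation`` rises from ``baseline`` toward baseline+amplitude;
    ``washout`` decays from baseline+amplitude toward ``baseline``.  The
    defaults mirror DHA incorporation into glycerophospholipids: a ~4 h
    incorporation half-time (use 25 h for wash-out) and a ~15 mol%
    amplitude.
    """
    if half_time_h <= 0:
        raise ValueError("half_time_h must be > 0")
    if times is None:
        times = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0)
    t = np.asarray(times, dtype=float)
    k = math.log(2.0) / half_time_h
    if kind == "incorporation":
        y = baseline + amplitude * (1.0 - np.exp(-k * t))
    elif kind == "washout":
        y = baseline + amplitude * np.exp(-k * t)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    truth = {
        "kind": kind,
        "half_time_h": half_time_h,
        "k_per_h": k,
        "amplitude": amplitude,
        "baseline": baseline,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return TimeCourse(t, y, condition=kind), truth


# ---------------------------------------------------------------------------
# Two-channel spectral images
# ---------------------------------------------------------------------------

@dataclass
class ImageSimConfig:
    """Geometry and intensities of a synthetic C-Laurdan cell image.

    Geometry is laid out on the post-binning grid (half the stated image
    size) and upsampled 2x, so the ground-truth masks are exact in binned
    coordinates.  GP defaults: tightly packed PM ring at 0.45, looser
    internal membranes at 0.10, dark nucleus, background at GP 0.
    """

    shape: tuple[int, int] = (256, 256)
    cell_center: Optional[tuple[float, float]] = None  # binned coords
    cell_radii: tuple[float, float] = (45.0, 55.0)  # binned px
    ring_width: float = 3.0  # binned px (>= 2 after binning)
    nucleus_radii: tuple[float, float] = (14.0, 17.0)
    nucleus_offset: tuple[float, float] = (5.0, 0.0)
    pm_gp: float = 0.45
    interior_gp: float = 0.10
    background_gp: float = 0.0
    cell_intensity: float = 500.0  # expected counts per full-res pixel
    background_intensity: float = 20.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] % 2 or self.shape[1] % 2:
            raise ValueError("image shape must be even (2x2 binning)")
        for g in (self.pm_gp, self.interior_gp, self.background_gp):
            if not -1.0 < g < 1.0:
                raise ValueError("GP values must lie in (-1, 1)")
        if self.ring_width < 2:
            raise ValueError("PM ring must be >= 2 px wide after binning")
        hb, wb = self.shape[0] // 2, self.shape[1] // 2
        cr, cc = self.cell_center or (hb / 2.0, wb / 2.0)
        if cr + self.cell_radii[0] > hb or cc + self.cell_radii[1] > wb or \
           cr - self.cell_radii[0] < 0 or cc - self.cell_radii[1] < 0:
            raise ValueError("cell geometry exceeds image bounds")


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def simulate_spectral_image(
    config: ImageSimConfig = ImageSimConfig(),
) -> tuple[SpectralImagePair, dict]:
    """Two-channel image of a synthetic cell with a known GP field.

    Each pixel with total intensity I and GP g emits I(1+g)/2 in the blue
    channel and I(1-g)/2 in the red channel, optionally Poisson-sampled.
    The truth record carries binned-coordinate masks (cell body, PM ring,
    interior, nucleus) and the binned GP field.
    """
    hb, wb = config.shape[0] // 2, config.shape[1] // 2
    center = config.cell_center or (hb / 2.0, wb / 2.0)
    cell = _ellipse_mask((hb, wb), center, config.cell_radii)
    inner = _ellipse_mask(
        (hb, wb),
        center,
        (config.cell_radii[0] - config.ring_width, config.cell_radii[1] - config.ring_width),
    )
    ring = cell & ~inner
    nuc_center = (center[0] + config.nucleus_offset[0], center[1] + config.nucleus_offset[1])
    nucleus = _ellipse_mask((hb, wb), nuc_center, config.nucleus_radii) & inner
    interior = inner & ~nucleus

    gp_field = np.full((hb, wb), config.background_gp)
    gp_field[interior] = config.interior_gp
    gp_field[ring] = config.pm_gp

    # dye signal sits on top of a uniform background haze (GP 0 by default);
    # the nucleus carries no signal and appears as a dark fiducial
    signal = np.zeros((hb, wb))
    signal[interior | ring] = config.cell_intensity
    bg = config.background_intensity

    up = lambda a: np.kron(a, np.ones((2, 2)))
    blue = up(signal * (1.0 + gp_field) / 2.0 + bg * (1.0 + config.background_gp) / 2.0)
    red = up(signal * (1.0 - gp_field) / 2.0 + bg * (1.0 - config.background_gp) / 2.0)
    if config.poisson_noise:
        rng = np.random.default_rng(config.seed)
        blue = rng.poisson(blue).astype(float)
        red = rng.poisson(red).astype(float)
    truth = {
        "seed": config.seed,
        "pm_gp": config.pm_gp,
        "interior_gp": config.interior_gp,
        "cell_mask_binned": (ring | interior),
        "pm_mask_binned": ring,
        "interior_mask_binned": interior,
        "nucleus_mask_binned": nucleus,
        "gp_field_binned": gp_field,
    }
    return SpectralImagePair(blue, red), truth


# ---------------------------------------------------------------------------
# Emission spectra
# ---------------------------------------------------------------------------

_BAND_CENTERS = (440.0, 490.0)
_BAND_SD = 15.0
_WAVELENGTHS = np.arange(400.0, 551.0, 1.0)


def simulate_emission_spectrum(
    gp_target: float,
    total_intensity: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[EmissionSpectrum, dict]:
    """Two-Gaussian emission spectrum realizing a prescribed GP.

    Bands centered at 440 and 490 nm (SD 15 nm), sampled at 1-nm steps
    over 400-550 nm; the band weights are solved so that the 420-460 /
    470-510 nm sums yield ``gp_target`` exactly in the noiseless case,
    then scaled so the summed intensity equals ``total_intensity``.
    """
    if not -1.0 < gp_target < 1.0:
        raise ValueError("gp_target must lie in (-1, 1)")
    wl = _WAVELENGTHS
    a = np.exp(-0.5 * ((wl - _BAND_CENTERS[0]) / _BAND_SD) ** 2)
    b = np.exp(-0.5 * ((wl - _BAND_CENTERS[1]) / _BAND_SD) ** 2)
    band1 = (wl >= 420) & (wl <= 460)
    band2 = (wl >= 470) & (wl <= 510)
    g = gp_target
    alpha = (a[band1].sum() - a[band2].sum()) - g * (a[band1].sum() + a[band2].sum())
    beta = (b[band1].sum() - b[band2].sum()) - g * (b[band1].sum() + b[band2].sum())
    # alpha > 0, beta < 0 for g in (-1, 1) with these bands
    w_a, w_b = -beta, alpha
    spec = w_a * a + w_b * b
    spec *= total_intensity / spec.sum()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        spec = np.clip(spec + rng.normal(0.0, noise_sd, size=spec.shape), 0.0, None)
    truth = {"gp": gp_target, "noise_sd": noise_sd, "seed": seed}
    return EmissionSpectrum(wl, spec), truth


# ---------------------------------------------------------------------------
# FDA influx traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSimConfig:
    """Linear FDA influx trace from a prescribed permeability coefficient."""

    true_p_cm_per_s: float = 2.2e-6
    n_cells: float = 250_000.0
    area_per_cell_um2: float = 3000.0
    c_out_mol_per_cm3: float = 6.0e-9  # ~2.5 ug/mL FDA
    cal_factor_mol_per_au: float = 1e-15
    baseline_au: float = 10.0
    noise_sd_au: float = 0.0
    duration_s: float = 300.0
    rate_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (
            self.true_p_cm_per_s,
            self.n_cells,
            self.area_per_cell_um2,
            self.c_out_mol_per_cm3,
            self.cal_factor_mol_per_au,
            self.duration_s,
            self.rate_hz,
        ):
            if v <= 0:
                raise ValueError("all trace parameters must be positive")


def simulate_fda_trace(
    config: TraceSimConfig = TraceSimConfig(),
) -> tuple[FluorescenceTrace, Calibration, dict]:
    """Fluorescence trace F(t) = baseline + (Q / cal_factor) t + noise.

    The ground-truth flux is Q = P A C_out with A the total membrane area;
    a matching :class:`~memlipid.permeability.Calibration` is returned so
    the round trip trace -> flux -> P can be scored.
    """
    area_cm2 = config.n_cells * config.area_per_cell_um2 / 1e8
    q_true = config.true_p_cm_per_s * area_cm2 * config.c_out_mol_per_cm3
    t = np.arange(0.0, config.duration_s + 1e-9, 1.0 / config.rate_hz)
    f = config.baseline_au + (q_true / config.cal_factor_mol_per_au) * t
    if config.noise_sd_au > 0:
        rng = np.random.default_rng(config.seed)
        f = f + rng.normal(0.0, config.noise_sd_au, size=t.shape)
    trace = FluorescenceTrace(
        t,
        f,
        n_cells=config.n_cells,
        volume_ml=2.0,
        area_per_cell_um2=config.area_per_cell_um2,
        c_out_mol_per_cm3=config.c_out_mol_per_cm3,
    )
    cal = Calibration(
        factor=config.cal_factor_mol_per_au,
        slope=1.0 / config.cal_factor_mol_per_au,
        volume_ml=1.0,
        r_squared=1.0,
    )
    truth = {
        "P_cm_per_s": config.true_p_cm_per_s,
        "Q_mol_per_s": q_true,
        "area_cm2": area_cm2,
        "c_out_mol_per_cm3": config.c_out_mol_per_cm3,
        "seed": config.seed,
    }
    return trace, cal, truth
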