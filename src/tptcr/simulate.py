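"""Synthetic native-MS data with known ground truth.

The generator emulates the data types of a targeted native ambient MS
experiment on liver tissue: full-scan and SIM nano-electrospray spectra of
a small protein mixture, proton-transfer charge reduction (PTCR) product
scans, HCD dissociation of a protein-ligand complex, and a rasterised
tissue phantom with a blood-vessel region whose drug-complex abundance
decays with time post-dose.

Default species are the liver panel the method was developed on: liver
fatty acid binding protein (FABP1, ~14.3 kDa apo), its 1:1 bezafibrate
complex (+361.1 Da), the heme-bound alpha-globin monomer (~15.8 kDa,
vascular) and acyl-CoA binding protein (ACBP, ~10 kDa).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import poisson

from .errors import InvalidInputError
from .masses import IonSpecies, MolecularFormula, molecular_mass, mz_from_mass, predict_reduced_ladder
from .spectra import Peak, Spectrum

log = logging.getLogger(__name__)

#: Neutral masses (Da) of the default liver panel.
BEZAFIBRATE_FORMULA = "C19H20ClNO4"
BEZAFIBRATE_MASS = 361.108086  # monoisotopic, from the formula
COMPLEX_MASS = 14675.40        # [FABP1+bezafibrate], consistent with its 7+/6+ PTCR products
APO_FABP1_MASS = COMPLEX_MASS - 361.108086
ALPHA_GLOBIN_HEME_MASS = 15812.2
ACBP_MASS = 9913.0             # nominal ~10 kDa

GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = this * sigma


@dataclass(frozen=True)
class SpeciesDefinition:
    """A neutral species plus its native ESI charge envelope.

    Native (folded) proteins take few protons, so the envelope is a narrow
    Gaussian over integer charge centred at ``z0`` with width ``sigma_z``
    (charge units) and total abundance ``abundance`` (arbitrary units).
    """

    name: str
    mass: float
    z0: float
    sigma_z: float = 0.7
    abundance: float = 1.0

    def __post_init__(self):
        if self.mass <= 0:
            raise InvalidInputError("mass must be positive")
        if self.z0 < 1:
            raise InvalidInputError("z0 must be >= 1")
        if self.sigma_z <= 0:
            raise InvalidInputError("sigma_z must be > 0")
        if self.abundance < 0:
            raise InvalidInputError("abundance must be >= 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Mass-analyser model: m/z range, resolving power, noise and SIM gain.

    ``resolving_power`` R sets peak FWHM = m/R. ``noise_sigma`` is the
    per-bin additive Gaussian noise; ``shot_noise`` scales a relative
    sqrt-intensity jitter on each peak. ``sim_gain`` g >= 1 is the ion
    accumulation gain of SIM acquisition: peak intensities are multiplied
    by g while the noise floor is unchanged, so SNR improves by g.
    """

    mz_range: tuple[float, float] = (1500.0, 3000.0)
    resolving_power: float = 1000.0
    baseline: float = 0.0
    noise_sigma: float = 0.0
    shot_noise: float = 0.0
    sim_gain: float = 20.0
    grid_step: float | None = None

    def __post_init__(self):
        lo, hi = self.mz_range
        if not lo < hi:
            raise InvalidInputError("mz_range must satisfy lo < hi")
        if self.resolving_power <= 0:
            raise InvalidInputError("resolving power must be > 0")
        if self.sim_gain < 1:
            raise InvalidInputError("SIM gain must be >= 1")

    def step(self) -> float:
        """Grid spacing: ~1/8 of the narrowest FWHM in range unless overridden."""
        if self.grid_step is not None:
            return self.grid_step
        return self.mz_range[0] / self.resolving_power / 8.0


@dataclass(frozen=True)
class HCDConfig:
    """Beam-type collisional activation of a protein-ligand complex.

    ``nce`` is the normalized collision energy (%); the dissociation
    probability follows a logistic curve in NCE (monotone non-decreasing,
    0..1) unless a custom curve is supplied. The ligand departs as a
    neutral by default (the observed pathway for FABP1+bezafibrate); set
    ``charged_ligand`` to model the more common charged-ligand loss.
    """

    nce: float = 7.0
    curve: Callable[[float], float] | None = None
    charged_ligand: bool = False
    nce50: float = 5.0
    nce_width: float = 1.5

    def dissociation_probability(self) -> float:
        if self.curve is not None:
            p = float(self.curve(self.nce))
        else:
            p = 1.0 / (1.0 + math.exp(-(self.nce - self.nce50) / self.nce_width))
        if not 0.0 <= p <= 1.0:
            raise InvalidInputError("dissociation probability must lie in [0, 1]")
        return p


def simulate_envelope(species: SpeciesDefinition) -> list[Peak]:
    """Centroid peaks of one species' native charge envelope.

    One peak per integer charge z, weighted by a Gaussian in (z − z0) and
    normalised so the weights sum to the species abundance.
    """
    if species.abundance == 0:
        return []
    z_lo = max(1, math.floor(species.z0 - 4 * species.sigma_z))
    z_hi = math.ceil(species.z0 + 4 * species.sigma_z)
    zs = np.arange(z_lo, z_hi + 1)
    w = np.exp(-((zs - species.z0) ** 2) / (2.0 * species.sigma_z**2))
    w *= species.abundance / w.sum()
    return [
        Peak(mz_from_mass(species.mass, int(z)), float(wi), z=int(z), label=species.name)
        for z, wi in zip(zs, w)
    ]


def render_profile(
    peaks: Sequence[Peak],
    cfg: AcquisitionConfig,
    seed: int | np.random.Generator | None = None,
) -> Spectrum:
    """Render centroid peaks as a profile trace with Gaussian peak shapes.

    Each peak becomes a Gaussian of FWHM m/R whose *integral* equals the
    centroid intensity; baseline and seeded noise are added on top.
    Out-of-range peaks are clipped (and logged), not an error.
    """
    rng = _as_rng(seed)
    lo, hi = cfg.mz_range
    step = cfg.step()
    grid = np.arange(lo, hi + step / 2, step)
    trace = np.full(grid.size, float(cfg.baseline))
    clipped = []
    for p in peaks:
        if not (lo <= p.mz <= hi):
            clipped.append(p.mz)
            continue
        sigma = (p.mz / cfg.resolving_power) / GAUSS_FWHM
        inten = p.intensity
        if cfg.shot_noise > 0 and inten > 0:
            inten = max(0.0, inten * (1.0 + cfg.shot_noise * rng.normal() / math.sqrt(inten)))
        amp = inten / (sigma * math.sqrt(2.0 * math.pi))
        i0 = np.searchsorted(grid, p.mz - 5 * sigma)
        i1 = np.searchsorted(grid, p.mz + 5 * sigma)
        window = grid[i0:i1]
        trace[i0:i1] += amp * np.exp(-((window - p.mz) ** 2) / (2.0 * sigma**2))
    if clipped:
        log.info("render_profile: clipped %d out-of-range peaks: %s", len(clipped), clipped)
    if cfg.noise_sigma > 0:
        # additive noise is left unclipped (baseline-subtracted convention),
        # so robust noise estimators downstream see a symmetric distribution
        trace = trace + rng.normal(0.0, cfg.noise_sigma, trace.size)
    return Spectrum(grid, trace, mode="profile", metadata={"cfg": cfg, "clipped": clipped})


def simulate_full_scan(
    mixture: Sequence[SpeciesDefinition],
    cfg: AcquisitionConfig,
    seed: int | None = None,
) -> Spectrum:
    """Full-scan spectrum of a mixture: superposed envelopes plus noise.

    Low-abundance species (e.g. a drug complex at <1% of the free protein)
    can fall below the noise floor here — the failure mode SIM acquisition
    is designed to rescue.
    """
    peaks = [p for sp in mixture for p in simulate_envelope(sp)]
    spec = render_profile(peaks, cfg, seed)
    spec.metadata.update(scan_type="full", seed=seed)
    return spec


def simulate_sim_scan(
    mixture: Sequence[SpeciesDefinition],
    window: tuple[float, float],
    cfg: AcquisitionConfig,
    seed: int | None = None,
) -> Spectrum:
    """Selected-ion-monitoring scan over a narrow window.

    Only peaks inside the window are retained; their intensities gain the
    accumulation factor ``cfg.sim_gain`` while the noise level is
    unchanged, improving SNR linearly in the gain.
    """
    lo, hi = window
    if not lo < hi:
        raise InvalidInputError("SIM window must satisfy lo < hi")
    if lo < cfg.mz_range[0] or hi > cfg.mz_range[1]:
        raise InvalidInputError("SIM window must lie inside the acquisition range")
    peaks = [
        replace_peak(p, intensity=p.intensity * cfg.sim_gain)
        for sp in mixture
        for p in simulate_envelope(sp)
        if lo <= p.mz <= hi
    ]
    wcfg = replace(cfg, mz_range=(lo, hi), grid_step=cfg.step())
    spec = render_profile(peaks, wcfg, seed)
    spec.metadata.update(scan_type="sim", window=window, gain=cfg.sim_gain, seed=seed)
    return spec


def replace_peak(p: Peak, **kw) -> Peak:
    d = dict(mz=p.mz, intensity=p.intensity, z=p.z, snr=p.snr, label=p.label, merged=p.merged)
    d.update(kw)
    return Peak(**d)


def _truncated_poisson_weights(mu: float, z: int) -> tuple[float, np.ndarray]:
    """(survivor fraction, weights over k=1..z-1 transfers), summing to 1."""
    survivor = float(poisson.pmf(0, mu))
    if z == 1:
        return 1.0, np.array([])
    ks = np.arange(1, z)
    w = poisson.pmf(ks, mu)
    total = w.sum()
    if total <= 0:
        return 1.0, np.zeros(z - 1)
    return survivor, w / total


def simulate_ptcr(
    precursors: Sequence[tuple[IonSpecies, float]],
    mu: float = 1.5,
    *,
    seed: int | np.random.Generator | None = None,
    mz_jitter: float = 0.0,
    intensity_cv: float = 0.0,
) -> Spectrum:
    """Proton-transfer charge-reduction product scan (centroid).

    Each (precursor ion, intensity) pair loses k protons to the reagent
    anion, with k following a Poisson(mu) count conditioned on
    1 <= k < z; the Poisson zero class survives at the precursor m/z.
    Intensity is redistributed, never created: the noiseless total ion
    current is conserved exactly. Optional seeded jitter models m/z and
    intensity measurement noise.
    """
    if mu <= 0:
        raise InvalidInputError("mean transfer count mu must be > 0")
    rng = _as_rng(seed)
    peaks: list[Peak] = []
    for ion, inten in precursors:
        if inten < 0:
            raise InvalidInputError("precursor intensity must be >= 0")
        if inten == 0:
            continue
        survivor, w = _truncated_poisson_weights(mu, ion.z)
        peaks.append(Peak(ion.mz, inten * survivor, z=ion.z, label=f"{ion.name} {ion.z}+"))
        if ion.z > 1:
            ladder = predict_reduced_ladder(ion.mz, ion.z, ion.z - 1, ion.adduct)
            reduced = inten * (1.0 - survivor)
            for (mz_k, z_k), w_k in zip(ladder, w):
                peaks.append(
                    Peak(mz_k, reduced * w_k, z=z_k, label=f"{ion.name} {z_k}+")
                )
    if mz_jitter > 0 or intensity_cv > 0:
        peaks = [
            replace_peak(
                p,
                mz=p.mz + (rng.normal(0.0, mz_jitter) if mz_jitter > 0 else 0.0),
                intensity=max(
                    0.0,
                    p.intensity * (1.0 + (rng.normal(0.0, intensity_cv) if intensity_cv > 0 else 0.0)),
                ),
            )
            for p in peaks
        ]
    spec = Spectrum.from_peaks(peaks, metadata={"scan_type": "ptcr", "mu": mu})
    return spec


def simulate_hcd(
    complex_species: IonSpecies,
    ligand_formula: MolecularFormula | str,
    hcd: HCDConfig,
    intensity: float = 1.0,
    seed: int | None = None,
) -> Spectrum:
    """HCD MS/MS of a protein-ligand complex precursor (centroid).

    A fraction p_d(NCE) of the precursor dissociates to the free protein at
    the *same* charge, i.e. the ligand leaves as a neutral: the product
    sits ΔM = m_ligand below the precursor in neutral mass and no ion
    appears at the free ligand's own m/z. With ``charged_ligand`` set the
    ligand instead departs protonated ([L+H]+ plus protein at z−1).
    """
    ligand_mass = molecular_mass(ligand_formula, "monoisotopic")
    if ligand_mass >= complex_species.mass:
        raise InvalidInputError("ligand mass must be below the complex mass")
    p_d = hcd.dissociation_probability()
    peaks = [
        Peak(
            complex_species.mz,
            intensity * (1.0 - p_d),
            z=complex_species.z,
            label=f"{complex_species.name} {complex_species.z}+",
        )
    ]
    free_mass = complex_species.mass - ligand_mass
    if p_d > 0:
        if hcd.charged_ligand:
            if complex_species.z < 2:
                raise InvalidInputError("charged-ligand loss needs precursor z >= 2")
            z_prot = complex_species.z - 1
            peaks.append(
                Peak(mz_from_mass(free_mass, z_prot), intensity * p_d, z=z_prot,
                     label=f"free protein {z_prot}+")
            )
            peaks.append(
                Peak(mz_from_mass(ligand_mass, 1), intensity * p_d, z=1, label="ligand [L+H]+")
            )
        else:
            peaks.append(
                Peak(mz_from_mass(free_mass, complex_species.z), intensity * p_d,
                     z=complex_species.z, label=f"free protein {complex_species.z}+")
            )
    peaks = [p for p in peaks if p.intensity > 0]
    return Spectrum.from_peaks(
        peaks, metadata={"scan_type": "ms2", "nce": hcd.nce, "neutral_loss": not hcd.charged_ligand}
    )


# ---------------------------------------------------------------------------
# Tissue phantom


@dataclass
class PhantomSpecies:
    """One member of the phantom panel: targeted precursor plus localisation."""

    name: str
    mass: float
    precursor_z: int
    compartment: str  # 'bulk' | 'vessel'
    base_abundance: float
    is_complex: bool = False  # subject to dose-time decay


def default_liver_panel() -> list[PhantomSpecies]:
    """The four-protein targeted panel used throughout the examples."""
    return [
        PhantomSpecies("apo-FABP1", APO_FABP1_MASS, 8, "bulk", 1000.0),
        PhantomSpecies("FABP1+bezafibrate", COMPLEX_MASS, 8, "bulk", 60.0, is_complex=True),
        PhantomSpecies("heme-alpha-globin", ALPHA_GLOBIN_HEME_MASS, 8, "vessel", 800.0),
        PhantomSpecies("ACBP", ACBP_MASS, 6, "bulk", 300.0),
    ]


@dataclass
class TissuePhantom:
    """Ground truth of a simulated tissue section.

    Disjoint, covering masks (vessel / bulk / background) on a pixel grid
    plus the realised per-species abundance map actually used to generate
    each pixel's spectrum. The drug-complex abundance carries the
    first-order clearance factor 2^(−t / t_half).
    """

    shape: tuple[int, int]
    pixel_size_um: float
    masks: dict[str, np.ndarray]
    abundance_maps: dict[str, np.ndarray]
    species: list[PhantomSpecies]
    t_hours: float
    t_half_hours: float

    def __post_init__(self):
        total = sum(m.astype(int) for m in self.masks.values())
        if not np.all(total == 1):
            raise InvalidInputError("phantom masks must be disjoint and covering")
        for name, amap in self.abundance_maps.items():
            if amap.shape != self.shape:
                raise InvalidInputError(f"abundance map {name!r} shape mismatch")
            if np.any(amap < 0):
                raise InvalidInputError(f"abundance map {name!r} has negative values")


@dataclass
class ImagingDataset:
    """A rasterised imaging acquisition: one spectrum per pixel, row-major.

    ``spectra[r * n_cols + c]`` is the scan at 0-based (row r, col c);
    ``qc_mask`` flags pixels with a missing scan (rendered as 0 in images).
    ``truth`` is present for simulated data only.
    """

    shape: tuple[int, int]
    pixel_size_um: float
    spectra: list[Spectrum | None]
    qc_mask: np.ndarray
    truth: TissuePhantom | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.shape[0] * self.shape[1]
        if len(self.spectra) != n:
            raise InvalidInputError("spectra list does not match grid size")
        if self.qc_mask.shape != self.shape:
            raise InvalidInputError("qc mask shape mismatch")

    def pixel(self, row: int, col: int) -> Spectrum | None:
        return self.spectra[row * self.shape[1] + col]


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def clearance_factor(t_hours: float, t_half_hours: float) -> float:
    """Fraction of the dosed complex remaining t hours post-dose: 2^(−t/t_half)."""
    if t_hours < 0:
        raise InvalidInputError("time post-dose must be >= 0")
    if t_half_hours <= 0:
        raise InvalidInputError("half-life must be > 0")
    return 2.0 ** (-t_hours / t_half_hours)


def generate_phantom(
    shape: tuple[int, int] = (64, 64),
    *,
    species: Sequence[PhantomSpecies] | None = None,
    vessel_center: tuple[float, float] | None = None,
    vessel_radius: float = 6.0,
    tissue_margin: int = 2,
    t_hours: float = 2.0,
    t_half_hours: float = 4.5,
    mu: float = 1.5,
    heterogeneity: float = 0.15,
    mz_jitter: float = 0.05,
    intensity_cv: float = 0.05,
    dosed: bool = True,
    interferents: Sequence[tuple[str, float, float]] = (),
    pixel_size_um: float = 100.0,
    seed: int = 0,
) -> ImagingDataset:
    """Simulate a targeted-PTCR imaging run over a liver-like phantom.

    The section is an ellipse of tissue with a circular blood vessel;
    alpha-globin localises to the vessel while FABP1, the drug complex and
    ACBP localise to bulk tissue. The complex abundance is scaled by
    2^(−t/t_half) (plasma clearance of the drug). Each pixel's spectrum is
    the PTCR product scan of the targeted precursors weighted by the local
    abundances, with seeded log-normal spatial heterogeneity and m/z /
    intensity jitter. ``interferents`` are untargeted background ions
    (name, m/z, abundance) added to bulk pixels as-is — they are never
    charge-reduced, which is what product-ion-only imaging exploits.

    Returns the dataset together with its ground truth. Fixed seed gives a
    bit-identical dataset; independent RNG streams are used for abundance,
    spectral jitter and interferents so that adding an interferent leaves
    every other draw unchanged.
    """
    if t_hours < 0:
        raise InvalidInputError("t_hours must be >= 0")
    species = list(species) if species is not None else default_liver_panel()
    n_rows, n_cols = shape
    center = (n_rows / 2.0, n_cols / 2.0)
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    a = n_rows / 2.0 - tissue_margin
    b = n_cols / 2.0 - tissue_margin
    tissue = ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0
    if vessel_center is None:
        vessel_center = (n_rows * 0.38, n_cols * 0.6)
    vessel = _disk_mask(shape, vessel_center, vessel_radius) & tissue
    bulk = tissue & ~vessel
    background = ~tissue
    if not vessel.any():
        raise InvalidInputError("vessel mask is empty")
    if vessel.sum() >= bulk.sum():
        raise InvalidInputError("vessel must be smaller than bulk tissue")

    ss = np.random.SeedSequence(seed)
    rng_abund, rng_spec, rng_interf = (np.random.default_rng(s) for s in ss.spawn(3))

    decay = clearance_factor(t_hours, t_half_hours)
    abundance_maps: dict[str, np.ndarray] = {}
    for sp in species:
        comp = vessel if sp.compartment == "vessel" else bulk
        base = sp.base_abundance * (decay if sp.is_complex else 1.0)
        if not dosed and sp.is_complex:
            base = 0.0
        field_ = np.zeros(shape)
        if base > 0 and heterogeneity > 0:
            noise = rng_abund.lognormal(0.0, heterogeneity, size=shape)
            field_[comp] = base * noise[comp]
        elif base > 0:
            field_[comp] = base
        else:
            # keep the abundance RNG stream aligned across dosed/undosed runs
            if heterogeneity > 0:
                rng_abund.lognormal(0.0, heterogeneity, size=shape)
        abundance_maps[sp.name] = field_

    phantom = TissuePhantom(
        shape=shape,
        pixel_size_um=pixel_size_um,
        masks={"vessel": vessel, "bulk": bulk, "background": background},
        abundance_maps=abundance_maps,
        species=species,
        t_hours=t_hours,
        t_half_hours=t_half_hours,
    )

    spectra: list[Spectrum | None] = []
    for r in range(n_rows):
        for c in range(n_cols):
            precursors = [
                (IonSpecies(sp.name, sp.mass, sp.precursor_z), abundance_maps[sp.name][r, c])
                for sp in species
            ]
            spec = simulate_ptcr(
                precursors, mu, seed=rng_spec, mz_jitter=mz_jitter, intensity_cv=intensity_cv
            )
            if interferents and bulk[r, c]:
                extra = [
                    Peak(mz, ab * float(rng_interf.lognormal(0.0, heterogeneity)), label=name)
                    for name, mz, ab in interferents
                ]
                spec = Spectrum.from_peaks(list_peaks(spec) + extra, dict(spec.metadata))
            spec.metadata.update(row=r, col=c)
            spectra.append(spec)

    return ImagingDataset(
        shape=shape,
        pixel_size_um=pixel_size_um,
        spectra=spectra,
        qc_mask=np.zeros(shape, dtype=bool),
        truth=phantom,
        metadata={
            "seed": seed,
            "mu": mu,
            "t_hours": t_hours,
            "t_half_hours": t_half_hours,
            "dosed": dosed,
            "heterogeneity": heterogeneity,
            "mz_jitter": mz_jitter,
            "intensity_cv": intensity_cv,
        },
    )


def list_peaks(spec: Spectrum) -> list[Peak]:
    """Centroid spectrum back to a Peak list (annotations dropped)."""
    return [Peak(float(m), float(i)) for m, i in zip(spec.mz, spec.intensity)]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
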