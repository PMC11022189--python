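"""Synthetic NIR/MIR study generator.

Emulates a two-component powder adulteration study with Beer-Lambert
mixing: an adulterant (atenolol) blended into a herbal matrix (Panax
notoginseng powder) at 21 mass fractions spanning 0.5-20%, three replicate
mixtures per level, sieved at three mesh sizes.  NIR spectra (860-2500 nm,
2 nm grid) are generated for every mesh with a particle-size-dependent
multiplicative gain, additive baseline lift and extra noise (coarser powder
scatters more); MIR spectra (4000-400 cm^-1, 4 cm^-1 grid) are generated at
120-mesh only, mirroring the KBr-pellet protocol.

Component absorptivity curves are sums of Gaussian peaks — broad
overtone-like bands in NIR, narrow fundamental-like bands in MIR — scaled
so that the NIR mixture absorbance falls and the MIR absorbance rises with
the adulterant fraction, the correlation signs seen in real spectra of this
system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SampleMeta, SpectralAxis, SpectraSet

NIR_GRID = np.arange(860.0, 2501.0, 2.0)        # 821 points, nm
MIR_GRID = np.arange(4000.0, 399.0, -4.0)       # 901 points, cm^-1 (acq. order)

# mean absorptivity levels enforcing the correlation signs:
# NIR: adulterant darker than matrix -> absorbance falls with fraction
_NIR_MEANS = {"atenolol": 0.35, "matrix": 1.0}
# MIR: adulterant brighter than matrix -> absorbance rises with fraction
_MIR_MEANS = {"atenolol": 1.2, "matrix": 0.5}


@dataclass(frozen=True)
class ComponentSpectrum:
    """Pure-component absorptivity curve on one modality grid."""

    component: str  # atenolol | matrix
    modality: str
    curve: np.ndarray

    def __post_init__(self):
        curve = np.asarray(self.curve, dtype=float)
        object.__setattr__(self, "curve", curve)
        if np.any(curve < 0):
            raise ValueError("absorptivity curves must be nonnegative")


@dataclass(frozen=True)
class MeshDistortion:
    """Particle-size distortion of NIR spectra for one sieve mesh.

    The 120-mesh (finest) is the identity reference; coarser meshes get a
    wavelength-dependent multiplicative scatter gain >= 1 (scatter grows
    toward long wavelengths and with particle size, which is why a simple
    per-spectrum scatter correction cannot undo it), a slowly varying
    additive baseline lift, and a noise amplification factor — all monotone
    in particle size.
    """

    mesh: int
    gain: float           # multiplicative lift at the short-wavelength end
    gain_slope: float     # extra lift accrued toward the long-wavelength end
    region_amp: float     # extra lift on the scatter-sensitive long-NIR band
    baseline_amp: float
    noise_factor: float
    exponent: float = 1.0  # scatter compression: absorbance -> absorbance**exponent

    def __post_init__(self):
        if (self.gain < 1.0 or self.gain_slope < 0 or self.region_amp < 0
                or self.baseline_amp < 0 or self.noise_factor < 1.0
                or not 0.0 < self.exponent <= 1.0):
            raise ValueError("distortion parameters must not shrink the spectrum")

    def gain_curve(self, grid: np.ndarray) -> np.ndarray:
        # smooth but structured: a global scatter lift with slow ripples that
        # a per-spectrum scale correction (SNV) cannot absorb, plus the extra
        # lift on the scatter-sensitive band beyond 2000 nm
        x = (grid - grid.min()) / (grid.max() - grid.min())
        band = 1.0 / (1.0 + np.exp(-(grid - 2000.0) / 80.0))  # >= 2000 nm
        ripple = 1.0 + 0.3 * np.sin(3 * np.pi * x) + 0.2 * np.sin(8 * np.pi * x + 1.0)
        return (self.gain + self.gain_slope * (0.5 + x) * ripple
                + self.region_amp * band)

    def baseline(self, grid: np.ndarray) -> np.ndarray:
        # smooth, strictly positive shape; larger lift toward long wavelengths
        x = (grid - grid.min()) / (grid.max() - grid.min())
        return self.baseline_amp * (0.7 + 0.3 * x + 0.1 * np.sin(2 * np.pi * x))


DEFAULT_DISTORTIONS = {
    120: MeshDistortion(120, 1.00, 0.00, 0.00, 0.00, 1.0, exponent=1.00),
    100: MeshDistortion(100, 1.05, 0.05, 0.07, 0.06, 1.3, exponent=0.96),
    80: MeshDistortion(80, 1.11, 0.11, 0.16, 0.14, 1.6, exponent=0.92),
}


@dataclass(frozen=True)
class DesignConfig:
    """Study design: concentrations, replicates, meshes, noise, seed.

    Noise model per sample (all seeded):

    * white channel noise, SD = ``noise_sd_frac`` of the ideal signal range,
      tripled on the scatter-sensitive long-wavelength NIR band and
      amplified by the mesh noise factor;
    * per-sample scatter variability — a random multiplicative gain with a
      smooth random wavelength dependence (SD ``scatter_sd``) plus a random
      additive offset (SD ``baseline_jitter_frac`` of the range) — the
      sample-to-sample packing/path-length effects that SNV and MSC exist
      to correct, likewise amplified for coarser meshes;
    * aliquot sampling error — the material actually probed by each
      instrument is a small subsample of the blend, so the locally effective
      adulterant fraction deviates from the nominal one by a relative error
      of SD ``aliquot_rel_sd``, drawn independently per modality.  This is
      the irreducible single-modality error that motivates fusing two
      instruments, and no pre-treatment can remove it;
    * interference bands — a few fixed spectral regions per modality
      (minor-constituent / moisture-like absorptions) whose amplitudes vary
      randomly from blend to blend (SD ``interference_sd`` of the signal
      range; like the co-component, a blend property shared by its mesh
      fractions).  These contaminate full-spectrum models and are what
      reliability-based wavelength selection learns to avoid;
    * blend-level matrix variability — each blend's natural co-component
      loading deviates by N(0, ``matrix_covariate_sd``) (mass-fraction
      units).  The loading is a property of the blend, so it is shared by
      every mesh fraction and both modalities of that blend; its signature
      nearly mimics the adulterant contrast within NIR and anti-mimics it
      within MIR, so a single modality confounds it with the adulterant
      while the fused modalities resolve it.

    Setting all noise knobs to zero gives exactly affine spectra
    (see :meth:`noiseless`).
    """

    seed: int
    concentrations: np.ndarray = field(
        default_factory=lambda: np.linspace(0.5, 20.0, 21)
    )
    replicates: int = 3
    meshes: tuple[int, ...] = (80, 100, 120)
    noise_sd_frac: float = 0.005   # fraction of the ideal signal range
    scatter_sd: float = 0.005      # per-sample relative gain variability
    baseline_jitter_frac: float = 0.003  # per-sample offset, fraction of range
    aliquot_rel_sd: float = 0.01   # relative subsampling error per modality
    interference_sd: float = 0.1   # band amplitude SD, fraction of signal range
    matrix_covariate_sd: float = 0.02  # blend-level co-component loading SD

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if conc.size < 1 or np.any(conc < 0) or np.any(conc > 100):
            raise ValueError("concentrations must lie in [0, 100] %")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if min(self.noise_sd_frac, self.scatter_sd, self.baseline_jitter_frac,
               self.aliquot_rel_sd, self.interference_sd,
               self.matrix_covariate_sd) < 0:
            raise ValueError("noise levels must be nonnegative")

    @property
    def n_samples(self) -> int:
        """Total NIR sample count: meshes x concentrations x replicates."""
        return len(self.meshes) * self.concentrations.size * self.replicates

    @classmethod
    def noiseless(cls, seed: int, **kwargs) -> "DesignConfig":
        """Ideal-spectra design: zero noise, zero scatter variability."""
        return cls(seed=seed, noise_sd_frac=0.0, scatter_sd=0.0,
                   baseline_jitter_frac=0.0, aliquot_rel_sd=0.0,
                   interference_sd=0.0, matrix_covariate_sd=0.0, **kwargs)


def _gaussian_curve(rng: np.random.Generator, grid: np.ndarray, n_peaks: int,
                    width_range: tuple[float, float]) -> np.ndarray:
    lo, hi = float(grid.min()), float(grid.max())
    centers = rng.uniform(lo, hi, n_peaks)
    widths = rng.uniform(*width_range, n_peaks)
    heights = rng.uniform(0.3, 1.0, n_peaks)
    curve = np.zeros_like(grid)
    for c, w, h in zip(centers, widths, heights):
        curve += h * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return curve + 0.05 * curve.mean()  # small floor keeps curves well positive


def make_component_library(seed: int) -> dict:
    """Reproducible pure-component curves per modality.

    Returns ``{"NIR": {"atenolol": ..., "matrix": ...}, "MIR": {...}}`` with
    mean absorptivities scaled to enforce the correlation-sign invariants
    (NIR falls, MIR rises with adulterant fraction).
    """
    if seed is None:
        raise ValueError("a seed is mandatory")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    lib: dict[str, dict[str, ComponentSpectrum]] = {}
    # the crystalline adulterant has few, sharp bands; the herbal matrix has
    # many broad ones — so the adulterant-matrix contrast is localized and
    # most of the axis carries matrix background rather than analyte signal
    specs = {
        "NIR": (NIR_GRID, {"atenolol": (6, (15.0, 40.0)),
                           "matrix": (8, (80.0, 200.0))}, _NIR_MEANS),
        "MIR": (MIR_GRID, {"atenolol": (10, (8.0, 25.0)),
                           "matrix": (8, (40.0, 90.0))}, _MIR_MEANS),
    }
    for modality, (grid, comp_specs, means) in specs.items():
        lib[modality] = {}
        for component, (n_peaks, widths) in comp_specs.items():
            raw = _gaussian_curve(rng, grid, n_peaks, widths)
            curve = raw * (means[component] / raw.mean())
            lib[modality][component] = ComponentSpectrum(component, modality, curve)
        # fixed interference-prone regions (minor-constituent / moisture-like
        # bands): band positions are a property of the chemical system, the
        # per-sample band amplitudes are drawn at generation time
        lo, hi = float(grid.min()), float(grid.max())
        band_widths = comp_specs["matrix"][1]
        bands = []
        for _ in range(8):
            center = rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo))
            width = rng.uniform(*band_widths)
            band = np.exp(-0.5 * ((grid - center) / width) ** 2)
            bands.append(band / band.max())
        lib[modality]["interference_bands"] = bands
        # variable matrix co-component: its signature duplicates the
        # adulterant-vs-matrix contrast among the overtones (NIR) but its
        # negative among the fundamentals (MIR).  Within one modality the
        # loading is spectrally indistinguishable from adulterant content
        # (apparent concentration c+u in NIR, c-u in MIR); only the two
        # modalities jointly can resolve it — the complementarity that makes
        # fusion outperform any single-modality model.
        sign = 1.0 if modality == "NIR" else -1.0
        contrast = sign * (lib[modality]["atenolol"].curve
                           - lib[modality]["matrix"].curve)
        lib[modality]["covariate"] = ComponentSpectrum(
            "covariate", modality, contrast - contrast.min() + 0.02)
    return lib


@dataclass
class SimulatedStudy:
    """Generated datasets: NIR per mesh, MIR at the reference mesh."""

    nir: dict[int, SpectraSet]
    mir: SpectraSet
    config: DesignConfig


def _ideal_mixture(lib_mod: dict, fraction: float) -> np.ndarray:
    """Beer-Lambert two-component mixture at mass fraction (0..1)."""
    return (
        fraction * lib_mod["atenolol"].curve
        + (1.0 - fraction) * lib_mod["matrix"].curve
    )


def generate_dataset(cfg: DesignConfig, lib: dict | None = None,
                     distortions: dict | None = None) -> SimulatedStudy:
    """Generate the full synthetic study for one seed.

    NIR: for each mesh and each (concentration, replicate) cell, the ideal
    mixture spectrum is scaled/lifted by the mesh distortion and perturbed
    with Gaussian noise whose SD is ``noise_sd_frac`` of the ideal signal
    range, tripled on the long-wavelength region (>= 2000 nm, the NIR
    counterpart of 4000-5000 cm^-1) and amplified by the mesh noise factor.
    MIR: generated at the reference 120-mesh only, with independent noise.
    """
    lib = lib or make_component_library(cfg.seed)
    distortions = distortions or DEFAULT_DISTORTIONS
    ss = np.random.SeedSequence([int(cfg.seed), 202])
    rng = np.random.default_rng(ss)

    fractions = cfg.concentrations / 100.0
    ideal_nir = np.vstack([_ideal_mixture(lib["NIR"], f) for f in fractions])
    ideal_mir = np.vstack([_ideal_mixture(lib["MIR"], f) for f in fractions])
    nir_range = float(ideal_nir.max() - ideal_nir.min())
    mir_range = float(ideal_mir.max() - ideal_mir.min())
    nir_sd = cfg.noise_sd_frac * nir_range
    mir_sd = cfg.noise_sd_frac * mir_range
    region = np.where(NIR_GRID >= 2000.0, 3.0, 1.0)  # scatter-sensitive band

    nir_axis = SpectralAxis("NIR", "nm", NIR_GRID)
    mir_axis = SpectralAxis("MIR", "cm-1", MIR_GRID)

    def _scatter_gain(grid: np.ndarray, sd: float) -> np.ndarray:
        """Per-sample multiplicative scatter: random level with a smooth,
        random wavelength dependence (scatter is wavelength-dependent, so
        SNV/MSC remove it only approximately)."""
        if sd == 0:
            rng.normal(size=3)  # keep the stream aligned across noise levels
            return np.ones_like(grid)
        x = (grid - grid.min()) / (grid.max() - grid.min())
        level, slope, curve = rng.normal(0.0, sd, 3)
        return 1.0 + level + 0.5 * slope * (x - 0.5) + 0.25 * curve * np.sin(
            np.pi * x
        )

    def _effective_fraction(nominal: float) -> float:
        """Aliquot subsampling: the probed fraction deviates from nominal."""
        delta = rng.normal(0.0, cfg.aliquot_rel_sd)
        return max(nominal * (1.0 + delta), 0.0)

    # blend-level latent loadings: one draw per design point, shared by every
    # mesh fraction (and, for the co-component, both modalities) of that
    # blend — they are properties of the blend's composition, not of a
    # single measurement
    n_points = (cfg.concentrations.size, cfg.replicates)
    u = rng.normal(0.0, cfg.matrix_covariate_sd, n_points)
    cov_nir = lib["NIR"]["covariate"].curve
    cov_mir = lib["MIR"]["covariate"].curve
    band_amps = {
        mod: rng.normal(0.0, cfg.interference_sd * rng_range, n_points
                        + (len(lib[mod]["interference_bands"]),))
        for mod, rng_range in (("NIR", nir_range), ("MIR", mir_range))
    }

    def _interference(modality: str, ci: int, rep: int) -> np.ndarray:
        """The blend's contribution from the fixed interference bands."""
        bands = lib[modality]["interference_bands"]
        amps = band_amps[modality][ci, rep - 1]
        out = np.zeros_like(bands[0])
        for a, band in zip(amps, bands):
            out += a * band
        return out

    nir_sets: dict[int, SpectraSet] = {}
    for mesh in sorted(cfg.meshes):
        dist = distortions[mesh]
        mesh_gain = dist.gain_curve(NIR_GRID)
        mesh_base = dist.baseline(NIR_GRID)
        rows, meta = [], []
        for ci, conc in enumerate(cfg.concentrations):
            for rep in range(1, cfg.replicates + 1):
                ideal = (_ideal_mixture(lib["NIR"], _effective_fraction(fractions[ci]))
                         + u[ci, rep - 1] * cov_nir
                         + _interference("NIR", ci, rep))
                # scatter compression (stronger for coarser powder) is the
                # nonlinear part of the particle-size effect: no per-spectrum
                # scale correction can undo it, a windowed local regression can
                base = mesh_gain * np.abs(ideal) ** dist.exponent + mesh_base
                gain = _scatter_gain(NIR_GRID, cfg.scatter_sd * dist.noise_factor)
                offset = rng.normal(
                    0.0, cfg.baseline_jitter_frac * dist.noise_factor
                ) * nir_range
                noise = rng.normal(0.0, 1.0, NIR_GRID.size)
                rows.append(
                    gain * base + offset
                    + nir_sd * dist.noise_factor * region * noise
                )
                meta.append(SampleMeta(
                    sample_id=f"m{mesh:03d}_c{ci:02d}_r{rep}",
                    concentration=float(conc), mesh=mesh, replicate=rep,
                ))
        nir_sets[mesh] = SpectraSet(nir_axis, np.vstack(rows), meta)

    rows, meta = [], []
    for ci, conc in enumerate(cfg.concentrations):
        for rep in range(1, cfg.replicates + 1):
            ideal = (_ideal_mixture(lib["MIR"], _effective_fraction(fractions[ci]))
                     + u[ci, rep - 1] * cov_mir + _interference("MIR", ci, rep))
            gain = _scatter_gain(MIR_GRID, cfg.scatter_sd)
            offset = rng.normal(0.0, cfg.baseline_jitter_frac) * mir_range
            noise = rng.normal(0.0, 1.0, MIR_GRID.size)
            rows.append(gain * ideal + offset + mir_sd * noise)
            meta.append(SampleMeta(
                sample_id=f"mir120_c{ci:02d}_r{rep}",
                concentration=float(conc), mesh=120, replicate=rep,
            ))
    mir_set = SpectraSet(mir_axis, np.vstack(rows), meta)
    return SimulatedStudy(nir=nir_sets, mir=mir_set, config=cfg)
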