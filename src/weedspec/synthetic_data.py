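"""Synthetic VNIR plant hypercubes and labelled ROIs for the nine weed species.

The generator emulates the spectral structure of the laboratory survey so
every downstream stage is testable without imagery: nine species, 25 plants
each, 400-1000 nm reflectance with species-specific VIS (5-14 %) and NIR
(16-26 %) levels, part-dependent curve shapes, pixel-level sensor noise and
plant-level biological variability.

Spectral model
--------------
Chlorophyll-bearing parts (leaves, stems) follow an additive composition:

    R(lambda) = baseline + green bump + red-edge rise

a flat VIS baseline (strong chlorophyll absorption in the blue and red), a
Gaussian bump at 550 nm (the green reflectance peak), and a logistic rise
across the red edge (690-740 nm) from the VIS level to the NIR plateau.
The baseline is offset by the analytic average of the green bump over the
500-700 nm window so that the *mean* VIS reflectance of the clean curve
equals the species' nominal VIS level — this is what makes cohort-level
parameter recovery unbiased.

Chlorophyll-free parts (roots, root collars, basal zones) replace the rise
with a bright 550-750 nm plateau that drops into the NIR; white flowers are
a flat bright curve gently declining past the red edge.  Both families keep
VIS reflectance at or above NIR, as amyloplast/lignin-dominated tissue does.

Variability model
-----------------
Per plant: one multiplicative gain, one additive offset, and a small shift
of the red-edge centre (biological variation in chlorophyll content).  Per
pixel: a multiplicative illumination gain and additive per-band sensor
noise.  A single global seed feeds a per-(species, plant) seed sequence, so
any plant is regenerable in isolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .hypercube_io import SpectralCube
from .roi_sampling import MIN_PIXELS, ROI, ROIDataset
from .reference_ranges import REFERENCE_PART_RANGES, SPECIES

__all__ = [
    "SPECIES",
    "SpeciesProfile",
    "PartProfile",
    "NoiseModel",
    "generate_species_profile",
    "render_spectrum",
    "generate_cohort",
    "generate_plant_cube",
    "default_wavelength_grid",
    "measure_vis_nir",
]

GREEN_PEAK_NM = 550.0
GREEN_PEAK_SD_NM = 25.0
VIS_WINDOW = (500.0, 700.0)
NIR_WINDOW = (700.0, 780.0)
NIR_PLATEAU_WINDOW = (760.0, 780.0)

# (VIS %, NIR %) species levels of the generalised leaf/stem signatures.
_SPECIES_LEVELS: dict[str, tuple[float, float]] = {
    "Convolvulus arvensis": (5.0, 17.0),
    "Erigeron canadensis": (8.0, 23.0),
    "Erysimum cheiranthoides": (6.0, 16.0),
    "Sonchus arvensis": (11.0, 25.0),
    "Capsella bursa-pastoris": (14.0, 21.0),
    "Artemisia vulgaris": (8.0, 19.0),
    "Ambrosia artemisiifolia": (6.0, 21.0),
    "Amaranthus retroflexus": (9.0, 26.0),
    "Chenopodium album": (14.0, 25.0),
}

# Species-level red-edge geometry and green-peak amplitude.  Centres stay in
# the 690-740 nm red-edge region; the spread across species mimics the
# chlorophyll-driven interspecific shifts in red-edge position that make the
# signatures classifiable.
_SPECIES_SHAPES: dict[str, tuple[float, float, float]] = {
    # species: (red_edge_center nm, red_edge_width nm, green_peak_amplitude %)
    # centres stay >= ~708 nm so the sigmoid tail contributes negligibly to
    # the 500-700 nm VIS mean (cohort parameter recovery stays unbiased) and
    # are spread ~3.5 nm apart, comfortably above the per-plant jitter
    "Convolvulus arvensis": (722.0, 5.0, 1.0),
    "Erigeron canadensis": (715.0, 5.5, 1.6),
    "Erysimum cheiranthoides": (729.0, 4.5, 0.8),
    "Sonchus arvensis": (711.5, 6.0, 1.8),
    "Capsella bursa-pastoris": (725.5, 5.0, 2.0),
    "Artemisia vulgaris": (718.5, 5.5, 1.2),
    "Ambrosia artemisiifolia": (732.5, 4.5, 0.9),
    "Amaranthus retroflexus": (708.0, 6.5, 1.4),
    "Chenopodium album": (736.0, 5.0, 2.2),
}

# Part kinds whose curves carry chlorophyll (red-edge rise).
_CHLOROPHYLL_MODES = {"red_edge_rise"}


@dataclass(frozen=True)
class PartProfile:
    """Shape and level of one morphological part relative to its species.

    ``vis_offset``/``nir_offset`` are added to the species VIS/NIR levels.
    For the bright modes (``vis_plateau_nir_drop``, ``flat_bright``) the
    "VIS" level is the plateau height and the "NIR" level the tail beyond
    the drop, so VIS >= NIR as chlorophyll-free tissue requires.

    ``center_offset`` (nm) and ``width_scale`` displace and stretch the
    part's transition geometry relative to the species red edge: stems rise
    slightly later than leaves, carotenoid-bearing yellow flowers earlier
    and more gradually.  Part curves inherit the species' red-edge geometry,
    so tissue shape stays species-specific — which is what makes roots of
    different species distinguishable after scatter correction.
    """

    part_kind: str
    vis_offset: float
    nir_offset: float
    shape_mode: str  # red_edge_rise | vis_plateau_nir_drop | flat_bright
    center_offset: float = 0.0
    width_scale: float = 1.0


@dataclass(frozen=True)
class SpeciesProfile:
    species_name: str
    vis_level: float
    nir_level: float
    red_edge_center: float
    red_edge_width: float
    green_peak_amplitude: float
    part_profiles: dict[str, PartProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.vis_level <= 100.0 and 0.0 <= self.nir_level <= 100.0):
            raise ValueError("vis_level and nir_level must be in [0, 100]")
        if not (690.0 <= self.red_edge_center <= 740.0):
            raise ValueError("red_edge_center must lie in the 690-740 nm red-edge region")
        for pp in self.part_profiles.values():
            vis = self.vis_level + pp.vis_offset
            nir = self.nir_level + pp.nir_offset
            if pp.shape_mode in _CHLOROPHYLL_MODES:
                if nir <= vis:
                    raise ValueError(
                        f"{self.species_name}/{pp.part_kind}: chlorophyll parts need NIR > VIS"
                    )
            else:
                if vis < nir:
                    raise ValueError(
                        f"{self.species_name}/{pp.part_kind}: bright parts need VIS >= NIR"
                    )


@dataclass(frozen=True)
class NoiseModel:
    """Pixel- and plant-level variability; identical seeds are bit-identical.

    sds: ``pixel_gain_sd`` multiplicative per-pixel illumination;
    ``band_noise_sd`` additive per-band sensor noise (%);
    ``plant_offset_sd`` / ``plant_gain_sd`` additive/multiplicative per-plant
    effects; ``red_edge_jitter_sd`` per-plant shift of the red-edge centre
    (nm), the biological component that survives SNV normalisation.
    """

    pixel_gain_sd: float = 0.05
    band_noise_sd: float = 0.5
    plant_offset_sd: float = 1.0
    plant_gain_sd: float = 0.05
    red_edge_jitter_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_gain_sd", "band_noise_sd", "plant_offset_sd",
                     "plant_gain_sd", "red_edge_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_wavelength_grid(n_bands: int = 1200) -> np.ndarray:
    """The camera's 400-1000 nm grid (1200 channels ~ 0.5 nm step by default).

    A coarser grid (e.g. 61 bands, 10 nm step) is the recommended setting for
    tests and desk-scale pipeline runs.
    """
    return np.linspace(400.0, 1000.0, n_bands)


def _part_kind_of(table_part: str, species_name: str) -> tuple[str, PartProfile] | None:
    """Map a reference-table part label to a PartProfile for the generator."""
    vis, nir = _SPECIES_LEVELS[species_name]
    r_min, r_max, _, _ = REFERENCE_PART_RANGES[species_name][table_part]
    if table_part == "Leaf":
        return "leaf", PartProfile("leaf", 0.0, 0.0, "red_edge_rise")
    if table_part == "Stem":
        # stems sit higher in the VIS than leaves and rise slightly later
        return "stem", PartProfile("stem", r_min - vis, r_max - nir, "red_edge_rise",
                                   center_offset=4.0, width_scale=1.15)
    if table_part in ("Root", "Root collar"):
        kind = "root" if table_part == "Root" else "root_collar"
        # plateau at the part max, NIR tail at the part min
        return kind, PartProfile(kind, r_max - vis, r_min - nir, "vis_plateau_nir_drop",
                                 center_offset=0.0 if kind == "root" else 3.0)
    if table_part == "Flower":
        if species_name == "Capsella bursa-pastoris":  # white, pigment-free
            return "flower_white", PartProfile("flower_white", r_max - vis, r_min - nir,
                                               "flat_bright")
        # carotenoid absorption releases earlier and more gradually
        return "flower_yellow", PartProfile("flower_yellow", r_min - vis, r_max - nir,
                                            "red_edge_rise", center_offset=-6.0,
                                            width_scale=1.4)
    return None  # "General"/"Body" are whole-plant rows, not parts


def generate_species_profile(species_name: str) -> SpeciesProfile:
    """Default spectral profile for one of the nine study species."""
    if species_name not in _SPECIES_LEVELS:
        raise ValueError(
            f"unknown species {species_name!r}; valid names: {', '.join(SPECIES)}"
        )
    vis, nir = _SPECIES_LEVELS[species_name]
    center, width, green_amp = _SPECIES_SHAPES[species_name]
    parts: dict[str, PartProfile] = {}
    for table_part in REFERENCE_PART_RANGES[species_name]:
        mapped = _part_kind_of(table_part, species_name)
        if mapped is not None:
            kind, pp = mapped
            parts[kind] = pp
    return SpeciesProfile(species_name, vis, nir, center, width, green_amp, parts)


def _gaussian_bump(wavelengths: np.ndarray, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(
        -((wavelengths - GREEN_PEAK_NM) ** 2) / (2.0 * GREEN_PEAK_SD_NM**2)
    )


def _bump_mean_vis(amplitude: float) -> float:
    """Analytic average of the green bump over the 500-700 nm VIS window."""
    lo, hi = VIS_WINDOW
    s = GREEN_PEAK_SD_NM * math.sqrt(2.0)
    integral = (
        amplitude * GREEN_PEAK_SD_NM * math.sqrt(2.0 * math.pi) / 2.0
        * (math.erf((hi - GREEN_PEAK_NM) / s) - math.erf((lo - GREEN_PEAK_NM) / s))
    )
    return integral / (hi - lo)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def render_spectrum(
    profile: SpeciesProfile,
    part_kind: str,
    wavelengths: np.ndarray,
    noise: NoiseModel | None = None,
    red_edge_shift: float = 0.0,
) -> np.ndarray:
    """Clean (or pixel-noisy) reflectance spectrum of one part, in percent.

    With ``noise=None`` the output is deterministic.  ``red_edge_shift``
    displaces the red-edge centre (nm) and is used for plant-level biology.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength vector")
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if wavelengths[0] < 400.0 or wavelengths[-1] > 1000.0:
        raise ValueError("wavelengths must lie within [400, 1000] nm")

    if part_kind in profile.part_profiles:
        pp = profile.part_profiles[part_kind]
    elif part_kind == "leaf":
        pp = PartProfile("leaf", 0.0, 0.0, "red_edge_rise")
    else:
        raise ValueError(
            f"species {profile.species_name!r} has no part {part_kind!r}; "
            f"available: {sorted(profile.part_profiles)}"
        )
    vis = profile.vis_level + pp.vis_offset
    nir = profile.nir_level + pp.nir_offset
    center = profile.red_edge_center + red_edge_shift + pp.center_offset
    width = profile.red_edge_width * pp.width_scale

    if pp.shape_mode == "red_edge_rise":
        bump = _gaussian_bump(wavelengths, profile.green_peak_amplitude)
        base = vis - _bump_mean_vis(profile.green_peak_amplitude)
        clean = base + bump + (nir - base) * _sigmoid((wavelengths - center) / width)
    elif pp.shape_mode == "vis_plateau_nir_drop":
        # plateau geometry inherits the species red edge: the 550 nm rise and
        # the ~740 nm drop shift with the species' transition position
        rise_c = 550.0 + 1.5 * (center - 710.0)
        drop_c = 738.0 + 2.5 * (center - 710.0)
        low = 0.3 * vis  # dim blue edge of chlorophyll-free tissue
        rise = _sigmoid((wavelengths - rise_c) / (18.0 + width))
        drop = _sigmoid((wavelengths - drop_c) / (6.0 + width))
        clean = low + (vis - low) * rise - (vis - nir) * drop
    elif pp.shape_mode == "flat_bright":
        decline_c = 690.0 + (center - 710.0)
        clean = vis - (vis - nir) * _sigmoid((wavelengths - decline_c) / 40.0)
    else:  # pragma: no cover - profiles are validated at construction
        raise ValueError(f"unknown shape mode {pp.shape_mode!r}")

    if noise is None:
        return clean
    rng = np.random.default_rng(noise.seed)
    gain = 1.0 + rng.normal(0.0, noise.pixel_gain_sd)
    return clean * gain + rng.normal(0.0, noise.band_noise_sd, size=clean.shape)


def measure_vis_nir(spectrum: np.ndarray, wavelengths: np.ndarray) -> tuple[float, float]:
    """(VIS, NIR) summary of a spectrum: mean over 500-700 nm and over the
    760-780 nm NIR plateau, matching how the survey's species levels read."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    vis_sel = (wavelengths >= VIS_WINDOW[0]) & (wavelengths <= VIS_WINDOW[1])
    nir_sel = (wavelengths >= NIR_PLATEAU_WINDOW[0]) & (wavelengths <= NIR_PLATEAU_WINDOW[1])
    return float(np.mean(spectrum[..., vis_sel])), float(np.mean(spectrum[..., nir_sel]))


def _plant_rng(seed: int, species_idx: int, plant_idx: int) -> np.random.Generator:
    """Per-plant generator from a global seed; any plant regenerates alone."""
    return np.random.default_rng(np.random.SeedSequence((seed, species_idx, plant_idx)))


def _roi_counts_per_plant(
    total: int | None, n_plants: int, rois_per_plant: tuple[int, ...],
    rng: np.random.Generator,
) -> list[int]:
    if total is not None:
        base, extra = divmod(total, n_plants) if n_plants else (0, 0)
        counts = [base + (1 if i < extra else 0) for i in range(n_plants)]
        return counts
    return [int(rng.choice(rois_per_plant)) for _ in range(n_plants)]


def generate_cohort(
    species: tuple[str, ...] = SPECIES,
    n_plants_per_species: int = 25,
    rois_per_plant: tuple[int, ...] = (2, 3),
    pixels_per_roi: int = 60,
    wavelengths: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    roi_counts: dict[str, int] | None = None,
    seed: int = 0,
) -> ROIDataset:
    """Simulate the full labelled cohort of ROIs.

    Defaults mirror the study design: 9 species x 25 plants, 2-3 ROIs per
    plant with >= 50 pure pixels each.  ``roi_counts`` optionally fixes the
    per-species ROI totals (e.g. the survey's imbalanced 132...45 counts),
    distributed as evenly as possible across plants.  Each ROI is labelled
    with species, plant id and part kind; plant-level random effects are
    shared by all ROIs of a plant.
    """
    if n_plants_per_species < 0 or pixels_per_roi <= 0:
        raise ValueError("counts must be positive")
    if pixels_per_roi < MIN_PIXELS:
        warnings.warn(
            f"pixels_per_roi={pixels_per_roi} violates the >= {MIN_PIXELS} "
            "pure-pixel rule",
            stacklevel=2,
        )
    wavelengths = default_wavelength_grid() if wavelengths is None else np.asarray(
        wavelengths, dtype=float
    )
    noise = NoiseModel() if noise is None else noise

    rois: list[ROI] = []
    for s_idx, species_name in enumerate(species):
        profile = generate_species_profile(species_name)
        parts = sorted(profile.part_profiles)
        count_rng = np.random.default_rng(np.random.SeedSequence((seed, s_idx, 10_000)))
        per_plant = _roi_counts_per_plant(
            roi_counts.get(species_name) if roi_counts else None,
            n_plants_per_species, rois_per_plant, count_rng,
        )
        for p_idx in range(n_plants_per_species):
            rng = _plant_rng(seed, s_idx, p_idx)
            gain = 1.0 + rng.normal(0.0, noise.plant_gain_sd)
            offset = rng.normal(0.0, noise.plant_offset_sd)
            re_shift = rng.normal(0.0, noise.red_edge_jitter_sd)
            plant_id = f"{species_name.split()[0]}-{p_idx:02d}"
            for r_idx in range(per_plant[p_idx]):
                part = parts[int(rng.integers(len(parts)))]
                clean = render_spectrum(profile, part, wavelengths,
                                        red_edge_shift=re_shift)
                px_gain = 1.0 + rng.normal(0.0, noise.pixel_gain_sd,
                                           size=(pixels_per_roi, 1))
                band_noise = rng.normal(0.0, noise.band_noise_sd,
                                        size=(pixels_per_roi, len(wavelengths)))
                spectra = clean[None, :] * gain * px_gain + offset + band_noise
                rois.append(ROI(species_name, plant_id, part, spectra))
    return ROIDataset(wavelengths, rois)


def generate_plant_cube(
    species_name: str,
    wavelengths: np.ndarray | None = None,
    lines: int = 32,
    samples: int = 32,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[SpectralCube, np.ndarray, dict[int, tuple[str, str, str]]]:
    """Render one plant as a small hypercube plus an ROI label mask.

    The spatial layout is schematic (horizontal stripes, one per part, on a
    dark background); it carries the right spectra, not the right anatomy.
    Returns (cube, mask, labels) ready for :func:`~weedspec.roi_sampling.extract_rois`.
    """
    wavelengths = (default_wavelength_grid(61) if wavelengths is None
                   else np.asarray(wavelengths, dtype=float))
    noise = NoiseModel() if noise is None else noise
    profile = generate_species_profile(species_name)
    parts = sorted(profile.part_profiles)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 999)))

    data = np.full((lines, samples, len(wavelengths)), 2.0, dtype=np.float32)
    data += rng.normal(0.0, noise.band_noise_sd, size=data.shape).astype(np.float32)
    mask = np.zeros((lines, samples), dtype=int)
    labels: dict[int, tuple[str, str, str]] = {}
    stripe = max(1, lines // (len(parts) + 1))
    plant_id = f"{species_name.split()[0]}-00"
    for i, part in enumerate(parts):
        r0, r1 = i * stripe, (i + 1) * stripe
        clean = render_spectrum(profile, part, wavelengths)
        block_gain = 1.0 + rng.normal(0.0, noise.pixel_gain_sd,
                                      size=(r1 - r0, samples, 1))
        block_noise = rng.normal(0.0, noise.band_noise_sd,
                                 size=(r1 - r0, samples, len(wavelengths)))
        data[r0:r1, :, :] = clean[None, None, :] * block_gain + block_noise
        mask[r0:r1, :] = i + 1
        labels[i + 1] = (species_name, plant_id, part)
    cube = SpectralCube(data, wavelengths, kind="reflectance")
    return cube, mask, labels
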