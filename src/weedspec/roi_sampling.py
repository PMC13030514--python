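"""Labelled regions of interest and the plant-wise validation split.

An ROI is the unit of classification: a set of pixel spectra from one
morphological part of one plant.  The validation design is hierarchical —
plants (not ROIs) are split 70/30 per species, so no spectra from a test
plant ever leak into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hypercube_io import REFLECTANCE_CLIP, SpectralCube

log = logging.getLogger(__name__)

MIN_PIXELS = 50


@dataclass
class ROI:
    """Pixel spectra from one morphological part of one plant.

    ``pixel_count`` overrides the stored spectra row count when an ROI was
    re-read from a table that keeps only the mean spectrum.
    """

    species: str
    plant_id: str
    part: str
    spectra: np.ndarray  # (pixels, bands)
    pixel_indices: list[tuple[int, int]] | None = None
    pixel_count: int | None = None

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))

    @property
    def n_pixels(self) -> int:
        return self.pixel_count if self.pixel_count is not None else self.spectra.shape[0]

    @property
    def mean_spectrum(self) -> np.ndarray:
        return self.spectra.mean(axis=0)


@dataclass
class ROIDataset:
    """A collection of ROIs sharing one wavelength grid."""

    wavelengths: np.ndarray
    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.rois})

    @property
    def plant_ids(self) -> list[str]:
        return sorted({r.plant_id for r in self.rois})

    def to_frame(self) -> pd.DataFrame:
        """ROI table: species, plant_id, part, pixel_count, one column per band."""
        cols = [f"{w:g}" for w in self.wavelengths]
        rows = []
        for r in self.rois:
            rows.append(
                {"species": r.species, "plant_id": r.plant_id, "part": r.part,
                 "pixel_count": r.n_pixels,
                 **dict(zip(cols, r.mean_spectrum))}
            )
        return pd.DataFrame(rows)

    def write_table(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_table(cls, path: str | Path) -> "ROIDataset":
        """Read an ROI table; each row becomes a single-pixel ROI carrying the
        stored mean spectrum (pixel-level detail is not serialised)."""
        df = pd.read_csv(path, sep="\t")
        meta = {"species", "plant_id", "part", "pixel_count"}
        band_cols = [c for c in df.columns if c not in meta]
        wavelengths = np.array([float(c) for c in band_cols])
        rois = [
            ROI(row["species"], row["plant_id"], row["part"],
                row[band_cols].to_numpy(dtype=float)[None, :],
                pixel_count=int(row["pixel_count"]))
            for _, row in df.iterrows()
        ]
        return cls(wavelengths, rois)


def extract_rois(
    cube: SpectralCube,
    mask: np.ndarray,
    labels: dict[int, tuple[str, str, str]],
    min_pixels: int = MIN_PIXELS,
    specular_ceiling: float | None = REFLECTANCE_CLIP[1],
) -> list[ROI]:
    """Extract labelled ROIs from a cube using an integer label mask.

    ``mask`` has the cube's spatial shape; nonzero values index into
    ``labels`` which maps label -> (species, plant_id, part).  Pixels with
    any band at or above ``specular_ceiling`` are treated as specular
    artefacts and excluded.  Regions below ``min_pixels`` after filtering
    are dropped (and logged) to honour the pixel-purity rule.
    """
    mask = np.asarray(mask)
    if mask.shape != cube.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} != cube spatial shape {cube.shape[:2]}")
    rois: list[ROI] = []
    for value in sorted(labels):
        species, plant_id, part = labels[value]
        lines, samples = np.nonzero(mask == value)
        spectra = cube.data[lines, samples, :].astype(float)
        keep = np.ones(len(lines), dtype=bool)
        if specular_ceiling is not None and len(lines):
            keep = ~np.any(spectra >= specular_ceiling, axis=1)
            n_spec = int((~keep).sum())
            if n_spec:
                log.info("label %d: removed %d specular pixel(s)", value, n_spec)
        spectra = spectra[keep]
        if spectra.shape[0] < min_pixels:
            log.warning(
                "label %d (%s/%s/%s): %d pixel(s) < min_pixels=%d, region dropped",
                value, species, plant_id, part, spectra.shape[0], min_pixels,
            )
            continue
        indices = list(zip(lines[keep].tolist(), samples[keep].tolist()))
        rois.append(ROI(species, plant_id, part, spectra, pixel_indices=indices))
    return rois


@dataclass
class SplitPlan:
    """Per-species train/test plant assignment."""

    train_plants: dict[str, set[str]]
    test_plants: dict[str, set[str]]
    seed: int

    def role_of(self, species: str, plant_id: str) -> str:
        if plant_id in self.train_plants.get(species, set()):
            return "train"
        if plant_id in self.test_plants.get(species, set()):
            return "test"
        raise KeyError(f"plant {plant_id!r} of {species!r} not in split plan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "plant_id": p, "role": role}
            for role, mapping in (("train", self.train_plants), ("test", self.test_plants))
            for sp, plants in mapping.items()
            for p in sorted(plants)
        ]
        return pd.DataFrame(rows).sort_values(["species", "plant_id"]).reset_index(drop=True)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def plant_wise_split(
    dataset: ROIDataset, train_fraction: float = 0.7, seed: int = 0
) -> SplitPlan:
    """Randomly assign plants (per species) to train/test sets.

    The per-species train count is floor(train_fraction * n_plants), so 25
    plants at 0.7 give a 17/8 split.  A plant's ROIs are never divided
    between the two sets.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    plants_by_species: dict[str, list[str]] = {}
    for roi in dataset.rois:
        plants_by_species.setdefault(roi.species, [])
        if roi.plant_id not in plants_by_species[roi.species]:
            plants_by_species[roi.species].append(roi.plant_id)
    rng = np.random.default_rng(seed)
    train: dict[str, set[str]] = {}
    test: dict[str, set[str]] = {}
    for species in sorted(plants_by_species):
        plants = sorted(plants_by_species[species])
        if len(plants) < 2:
            raise ValueError(f"species {species!r} has fewer than 2 plants")
        n_train = int(np.floor(train_fraction * len(plants)))
        order = rng.permutation(len(plants))
        train[species] = {plants[i] for i in order[:n_train]}
        test[species] = {plants[i] for i in order[n_train:]}
    return SplitPlan(train, test, seed)


def split_rois(dataset: ROIDataset, plan: SplitPlan) -> tuple[list[ROI], list[ROI]]:
    """Partition the dataset's ROIs according to a split plan."""
    train: list[ROI] = []
    test: list[ROI] = []
    for roi in dataset.rois:
        role = plan.role_of(roi.species, roi.plant_id)  # raises on orphan plants
        (train if role == "train" else test).append(roi)
    return train, test
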