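"""Descriptive and variation metrics of spectral signatures.

Per morphological part the primitive is a :class:`PartReflectanceRange` —
reflectance extrema (percent) inside the 500-780 nm operational window,
plus the wavelength range of spectral activity.  Species-level statistics
are the unweighted arithmetic mean over all listed parts (the whole-plant
"General" row included, when present):

* mu        — mean of part midpoints (r_min + r_max) / 2
* DeltaR    — mean of part ranges r_max - r_min
* SB        — mean spectral bandwidth, lambda_max - lambda_min (nm)
* C         — mean contrast ratio lambda_max / lambda_min
* B_rel     — mean relative bandwidth (l_max - l_min) / (l_max + l_min)
* C_norm    — mean normalised contrast (l_max - l_min) / l_max

sigma, CV, the median and the rate of change R are computed from the same
part set by their textbook definitions but carry a ``non_reconciled`` flag:
they genuinely require raw spectra, which part ranges cannot recover, so
they are reported for completeness and excluded from golden comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi_sampling import ROIDataset

log = logging.getLogger(__name__)

METRIC_WINDOW = (500.0, 780.0)

# metrics whose printed species-level values cannot be reproduced from the
# per-part ranges alone (they were evidently computed from raw spectra)
NON_RECONCILED = ("sigma", "cv", "median", "rate_of_change")


@dataclass(frozen=True)
class PartReflectanceRange:
    part: str
    r_min: float
    r_max: float
    lambda_min: float
    lambda_max: float

    def __post_init__(self) -> None:
        if self.r_min > self.r_max:
            raise ValueError("r_min must be <= r_max")
        if not (0.0 < self.lambda_min < self.lambda_max):
            raise ValueError("need 0 < lambda_min < lambda_max")


@dataclass
class SpeciesSpectralStats:
    species: str
    mu: float
    delta_r: float
    sb: float
    contrast: float
    b_rel: float
    c_norm: float
    sigma: float
    cv: float
    median: float
    rate_of_change: float
    n_parts: int
    flags: dict[str, str] = field(default_factory=dict)


def part_range(
    mean_spectrum: np.ndarray,
    wavelengths: np.ndarray,
    part: str = "",
    window: tuple[float, float] = METRIC_WINDOW,
    activity_fraction: float | None = None,
) -> PartReflectanceRange:
    """Reflectance extrema of a mean spectrum inside the analysis window.

    With ``activity_fraction`` set (e.g. 0.05), the wavelength range narrows
    to where the spectrum rises that fraction of its dynamic range above its
    window minimum — the "spectral activity" range; otherwise the window
    itself is reported.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    mean_spectrum = np.asarray(mean_spectrum, dtype=float)
    lo, hi = window
    if wavelengths[0] > lo or wavelengths[-1] < hi:
        raise ValueError(
            f"window {window} not covered by wavelengths "
            f"[{wavelengths[0]}, {wavelengths[-1]}]"
        )
    sel = (wavelengths >= lo) & (wavelengths <= hi)
    seg, wl = mean_spectrum[sel], wavelengths[sel]
    r_min, r_max = float(seg.min()), float(seg.max())
    l_min, l_max = float(wl[0]), float(wl[-1])
    if activity_fraction is not None and r_max > r_min:
        thr = r_min + activity_fraction * (r_max - r_min)
        active = np.nonzero(seg >= thr)[0]
        if active.size >= 2:
            l_min, l_max = float(wl[active[0]]), float(wl[active[-1]])
    return PartReflectanceRange(part, r_min, r_max, l_min, l_max)


def wavelength_stats(lambda_min: float, lambda_max: float) -> tuple[float, float, float, float]:
    """(SB, C, B_rel, C_norm) of a single wavelength range.

    SB = l_max - l_min; C = l_max / l_min; B_rel = SB / (l_max + l_min);
    C_norm = SB / l_max.  Degenerate equal bounds give (0, 1, 0, 0);
    lambda_min = 0 leaves the contrast ratio undefined and is rejected.
    """
    if lambda_min <= 0:
        raise ValueError("contrast ratio undefined for lambda_min <= 0")
    if lambda_min > lambda_max:
        raise ValueError("lambda_min must be <= lambda_max")
    sb = lambda_max - lambda_min
    return (
        sb,
        lambda_max / lambda_min,
        sb / (lambda_max + lambda_min),
        sb / lambda_max,
    )


def species_aggregate(
    part_ranges: list[PartReflectanceRange],
    species: str = "",
    include_general: bool = True,
) -> SpeciesSpectralStats:
    """Aggregate part-level ranges into species-level statistics.

    The rule is an unweighted mean over parts, so duplicating every part
    leaves all values unchanged.  ``include_general=False`` drops parts
    labelled "General" before aggregating.
    """
    parts = [p for p in part_ranges if include_general or p.part != "General"]
    if not parts:
        raise ValueError("species_aggregate needs at least one part")

    mids = np.array([(p.r_min + p.r_max) / 2.0 for p in parts])
    ranges = np.array([p.r_max - p.r_min for p in parts])
    wl = np.array([wavelength_stats(p.lambda_min, p.lambda_max) for p in parts])

    mu = float(mids.mean())
    sigma = float(mids.std())  # population sd of the part midpoints
    rate = float(np.mean(100.0 * ranges / wl[:, 0]))  # % per 100 nm, per part

    return SpeciesSpectralStats(
        species=species,
        mu=mu,
        delta_r=float(ranges.mean()),
        sb=float(wl[:, 0].mean()),
        contrast=float(wl[:, 1].mean()),
        b_rel=float(wl[:, 2].mean()),
        c_norm=float(wl[:, 3].mean()),
        sigma=sigma,
        cv=float(100.0 * sigma / mu) if mu else float("nan"),
        median=float(np.median(mids)),
        rate_of_change=rate,
        n_parts=len(parts),
        flags={name: "non-reconciled with printed column" for name in NON_RECONCILED},
    )


def stats_table(
    dataset: ROIDataset,
    window: tuple[float, float] = METRIC_WINDOW,
    activity_fraction: float | None = 0.05,
) -> pd.DataFrame:
    """Per-species statistics table computed from measured ROI spectra.

    For every (species, part) the per-band mean spectrum over its ROIs gives
    one :class:`PartReflectanceRange`; species rows aggregate those parts.
    Species with no usable parts are omitted with a log entry.  The result
    is deterministic given the dataset and invariant to part order.
    """
    rows = []
    frame = dataset.to_frame()
    band_cols = [c for c in frame.columns
                 if c not in ("species", "plant_id", "part", "pixel_count")]
    for species_name in sorted(frame["species"].unique()):
        sub = frame[frame["species"] == species_name]
        ranges = []
        for part_name in sorted(sub["part"].unique()):
            mean_spec = (
                sub.loc[sub["part"] == part_name, band_cols].mean(axis=0).to_numpy()
            )
            ranges.append(
                part_range(mean_spec, dataset.wavelengths, part=part_name,
                           window=window, activity_fraction=activity_fraction)
            )
        if not ranges:
            log.warning("species %s has no parts; omitted from stats table", species_name)
            continue
        stats = species_aggregate(ranges, species=species_name)
        rows.append(
            {"species": stats.species, "n_parts": stats.n_parts, "mu": stats.mu,
             "delta_r": stats.delta_r, "sb": stats.sb, "contrast": stats.contrast,
             "b_rel": stats.b_rel, "c_norm": stats.c_norm, "sigma": stats.sigma,
             "cv": stats.cv, "median": stats.median,
             "rate_of_change": stats.rate_of_change}
        )
    return pd.DataFrame(rows)


def reference_stats_table(include_general: bool = True) -> pd.DataFrame:
    """Species statistics recomputed from the tabulated reference part ranges.

    This is the no-imaging path: it feeds the published per-part ranges into
    :func:`species_aggregate` and returns one row per species.
    """
    from .reference_ranges import REFERENCE_PART_RANGES

    rows = []
    for species_name, parts in REFERENCE_PART_RANGES.items():
        ranges = [
            PartReflectanceRange(part, r_min, r_max, l_min, l_max)
            for part, (r_min, r_max, l_min, l_max) in parts.items()
        ]
        s = species_aggregate(ranges, species=species_name, include_general=include_general)
        rows.append(
            {"species": s.species, "n_parts": s.n_parts, "mu": s.mu,
             "delta_r": s.delta_r, "sb": s.sb, "contrast": s.contrast,
             "b_rel": s.b_rel, "c_norm": s.c_norm}
        )
    return pd.DataFrame(rows)
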