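"""Tabulated per-part reflectance and wavelength ranges for the nine species.

These are the published laboratory survey's per-part minima/maxima: for each
morphological part, the reflectance range (percent, within the 500-780 nm
operational window) and the wavelength range of spectral activity.  They are
*inputs* to the species-level aggregation in :mod:`weedspec.spectral_metrics`
— the species-level statistics are always recomputed, never stored — and
double as anchors for the synthetic generator's part profiles.

Chlorophyll-bearing parts (leaves, most stems) respond across the full
500-780 nm window; roots, root collars and some stems only from ~550 nm.
"""

from __future__ import annotations

SPECIES = (
    "Convolvulus arvensis",
    "Erigeron canadensis",
    "Erysimum cheiranthoides",
    "Sonchus arvensis",
    "Capsella bursa-pastoris",
    "Artemisia vulgaris",
    "Ambrosia artemisiifolia",
    "Amaranthus retroflexus",
    "Chenopodium album",
)

# part -> (r_min %, r_max %, lambda_min nm, lambda_max nm)
REFERENCE_PART_RANGES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "Convolvulus arvensis": {
        "General": (5, 15, 500, 780),
        "Body": (5, 45, 500, 780),
        "Root": (20, 35, 550, 780),
        "Root collar": (25, 30, 550, 780),
        "Leaf": (10, 31, 550, 780),
        "Stem": (20, 30, 550, 780),
    },
    "Erigeron canadensis": {
        "General": (8, 23, 500, 780),
        "Body": (5, 45, 500, 780),
        "Root": (19, 30, 550, 780),
        "Leaf": (7, 30, 550, 780),
    },
    "Erysimum cheiranthoides": {
        "General": (6, 16, 500, 780),
        "Body": (5, 40, 500, 780),
        "Flower": (20, 35, 500, 780),
        "Stem": (18, 30, 500, 780),
        "Leaf": (10, 25, 500, 780),
    },
    "Sonchus arvensis": {
        "General": (11, 25, 500, 780),
        "Body": (3, 35, 500, 780),
        "Root": (19, 30, 500, 780),
        "Stem": (15, 30, 500, 780),
        "Leaf": (15, 28, 500, 780),
    },
    "Capsella bursa-pastoris": {
        "General": (14, 21, 500, 780),
        "Body": (10, 50, 500, 780),
        "Leaf": (15, 45, 500, 780),
        "Flower": (22.5, 30, 500, 780),
        "Stem": (15, 22.5, 500, 780),
    },
    "Artemisia vulgaris": {
        "General": (8, 19, 500, 780),
        "Body": (10, 55, 500, 780),
        "Leaf": (10, 28, 500, 780),
        "Root collar": (15, 40, 550, 780),
        "Root": (15, 30, 550, 780),
        "Stem": (15, 25, 550, 780),
    },
    "Ambrosia artemisiifolia": {
        "General": (6, 21, 500, 780),
        "Body": (3, 35, 500, 780),
        "Leaf": (15, 29, 500, 780),
        "Stem": (10, 25, 500, 780),
    },
    "Amaranthus retroflexus": {
        "General": (9, 26, 500, 780),
        "Body": (7.5, 43, 500, 780),
        "Root": (20, 40, 550, 780),
        "Stem": (20, 25, 550, 780),
        "Leaf": (10, 25, 550, 780),
    },
    "Chenopodium album": {
        "General": (14, 25, 500, 780),
        "Body": (7, 55, 500, 780),
        "Leaf": (22.5, 45, 500, 780),
        "Root": (10, 22.5, 500, 780),
        "Stem": (22, 25, 550, 780),
    },
}

# Published per-species ROI counts of the laboratory survey (sum = 601);
# used as the imbalanced-cohort study condition for the synthetic generator.
REFERENCE_ROI_COUNTS: dict[str, int] = {
    "Erysimum cheiranthoides": 132,
    "Erigeron canadensis": 81,
    "Capsella bursa-pastoris": 67,
    "Ambrosia artemisiifolia": 66,
    "Sonchus arvensis": 62,
    "Chenopodium album": 54,
    "Artemisia vulgaris": 48,
    "Convolvulus arvensis": 45,
    "Amaranthus retroflexus": 46,
}
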