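import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from weedspec.reference_ranges import REFERENCE_ROI_COUNTS
from weedspec.synthetic_data import SPECIES, default_wavelength_grid, generate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def coarse_grid() -> np.ndarray:
    """61-band 400-1000 nm grid used for desk-scale runs."""
    return default_wavelength_grid(61)


@pytest.fixture(scope="session")
def cohort(coarse_grid):
    """The full default cohort: 9 species x 25 plants, the survey's
    imbalanced per-species ROI counts (601 total), fixed seed."""
    return generate_cohort(
        wavelengths=coarse_grid, roi_counts=REFERENCE_ROI_COUNTS, seed=1
    )


@pytest.fixture(scope="session")
def mini_cohort():
    """Three species, six plants each — for fast structural tests."""
    return generate_cohort(
        species=SPECIES[:3], n_plants_per_species=6, pixels_per_roi=50,
        wavelengths=default_wavelength_grid(31), seed=7,
    )
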