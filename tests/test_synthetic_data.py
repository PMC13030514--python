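import numpy as np
import pytest

from weedspec.reference_ranges import REFERENCE_ROI_COUNTS
from weedspec.synthetic_data import (
    SPECIES,
    NoiseModel,
    default_wavelength_grid,
    generate_cohort,
    generate_plant_cube,
    generate_species_profile,
    measure_vis_nir,
    render_spectrum,
)

# published VIS/NIR species levels (%), the generator's anchors
LEVELS = {
    "Convolvulus arvensis": (5, 17),
    "Erigeron canadensis": (8, 23),
    "Erysimum cheiranthoides": (6, 16),
    "Sonchus arvensis": (11, 25),
    "Capsella bursa-pastoris": (14, 21),
    "Artemisia vulgaris": (8, 19),
    "Ambrosia artemisiifolia": (6, 21),
    "Amaranthus retroflexus": (9, 26),
    "Chenopodium album": (14, 25),
}


class TestSpeciesProfiles:
    @pytest.mark.parametrize("species,levels", LEVELS.items())
    def test_default_levels_match_survey(self, species, levels):
        p = generate_species_profile(species)
        assert (p.vis_level, p.nir_level) == levels

    def test_unknown_species_rejected_with_valid_names(self):
        with pytest.raises(ValueError, match="Convolvulus arvensis"):
            generate_species_profile("Triticum aestivum")

    @pytest.mark.parametrize("species", SPECIES)
    def test_leaf_nir_above_vis(self, species):
        p = generate_species_profile(species)
        assert p.nir_level > p.vis_level
        assert 690 <= p.red_edge_center <= 740

    @pytest.mark.parametrize("species", SPECIES)
    def test_bright_parts_vis_at_least_nir(self, species):
        """Roots/collars/white flowers reflect at least as much in VIS."""
        p = generate_species_profile(species)
        for pp in p.part_profiles.values():
            if pp.shape_mode != "red_edge_rise":
                assert p.vis_level + pp.vis_offset >= p.nir_level + pp.nir_offset


class TestRenderSpectrum:
    def test_convolvulus_leaf_anchors(self, coarse_grid):
        p = generate_species_profile("Convolvulus arvensis")
        leaf = render_spectrum(p, "leaf", coarse_grid)
        vis_band = leaf[(coarse_grid >= 500) & (coarse_grid <= 700)]
        assert np.all(np.abs(vis_band - 5.0) <= 1.0)
        at_780 = np.interp(780.0, coarse_grid, leaf)
        assert at_780 == pytest.approx(17.0, abs=0.5)

    @pytest.mark.parametrize("species", SPECIES)
    def test_leaf_red_edge_monotone(self, species, coarse_grid):
        p = generate_species_profile(species)
        leaf = render_spectrum(p, "leaf", coarse_grid)
        sel = (coarse_grid >= 690) & (coarse_grid <= 740)
        assert np.all(np.diff(leaf[sel]) >= 0)

    @pytest.mark.parametrize("species", SPECIES)
    def test_leaf_nir_mean_exceeds_vis_mean(self, species, coarse_grid):
        p = generate_species_profile(species)
        leaf = render_spectrum(p, "leaf", coarse_grid)
        vis = leaf[(coarse_grid >= 500) & (coarse_grid <= 700)].mean()
        nir = leaf[(coarse_grid >= 700) & (coarse_grid <= 780)].mean()
        assert nir > vis

    def test_noiseless_render_deterministic(self, coarse_grid):
        p = generate_species_profile("Sonchus arvensis")
        a = render_spectrum(p, "stem", coarse_grid)
        b = render_spectrum(p, "stem", coarse_grid)
        np.testing.assert_array_equal(a, b)

    def test_same_noise_seed_identical(self, coarse_grid):
        p = generate_species_profile("Sonchus arvensis")
        nm = NoiseModel(seed=42)
        a = render_spectrum(p, "leaf", coarse_grid, noise=nm)
        b = render_spectrum(p, "leaf", coarse_grid, noise=nm)
        np.testing.assert_array_equal(a, b)
        c = render_spectrum(p, "leaf", coarse_grid, noise=NoiseModel(seed=43))
        assert not np.array_equal(a, c)

    def test_empty_wavelengths_rejected(self):
        p = generate_species_profile("Convolvulus arvensis")
        with pytest.raises(ValueError, match="empty"):
            render_spectrum(p, "leaf", np.array([]))

    def test_unknown_part_rejected(self, coarse_grid):
        p = generate_species_profile("Ambrosia artemisiifolia")  # no root part
        with pytest.raises(ValueError, match="no part"):
            render_spectrum(p, "root", coarse_grid)

    def test_out_of_range_grid_rejected(self):
        p = generate_species_profile("Convolvulus arvensis")
        with pytest.raises(ValueError, match="400"):
            render_spectrum(p, "leaf", np.array([380.0, 500.0]))


class TestGenerateCohort:
    def test_default_cohort_bookkeeping(self, cohort):
        assert len(cohort.plant_ids) == 225
        assert len(cohort) == 601
        per_species = {sp: 0 for sp in SPECIES}
        for r in cohort.rois:
            per_species[r.species] += 1
        assert per_species == REFERENCE_ROI_COUNTS

    def test_roi_labels_complete(self, mini_cohort):
        for r in mini_cohort.rois:
            assert r.species in SPECIES
            assert r.part
            assert r.plant_id.startswith(r.species.split()[0])
            assert r.n_pixels >= 50

    def test_zero_plants_gives_empty_dataset(self, coarse_grid):
        ds = generate_cohort(n_plants_per_species=0, wavelengths=coarse_grid, seed=0)
        assert len(ds) == 0

    def test_fixed_seed_reproducible(self):
        wl = default_wavelength_grid(31)
        a = generate_cohort(species=SPECIES[:2], n_plants_per_species=3,
                            wavelengths=wl, seed=5)
        b = generate_cohort(species=SPECIES[:2], n_plants_per_species=3,
                            wavelengths=wl, seed=5)
        assert len(a) == len(b)
        for ra, rb in zip(a.rois, b.rois):
            assert (ra.species, ra.plant_id, ra.part) == (rb.species, rb.plant_id, rb.part)
            np.testing.assert_array_equal(ra.spectra, rb.spectra)

    def test_small_roi_warns_not_fatal(self, coarse_grid):
        with pytest.warns(UserWarning, match="pure-pixel"):
            ds = generate_cohort(species=SPECIES[:1], n_plants_per_species=2,
                                 pixels_per_roi=10, wavelengths=coarse_grid, seed=0)
        assert len(ds) > 0

    def test_zero_noise_pixels_equal_clean_render(self, coarse_grid):
        """With all noise sds zero every pixel is exactly the part's curve."""
        silent = NoiseModel(pixel_gain_sd=0, band_noise_sd=0, plant_offset_sd=0,
                            plant_gain_sd=0, red_edge_jitter_sd=0)
        ds = generate_cohort(species=("Convolvulus arvensis",),
                             n_plants_per_species=2, pixels_per_roi=50,
                             wavelengths=coarse_grid, noise=silent, seed=3)
        p = generate_species_profile("Convolvulus arvensis")
        for r in ds.rois:
            clean = render_spectrum(p, r.part, coarse_grid)
            np.testing.assert_allclose(
                r.spectra, np.tile(clean, (r.n_pixels, 1)), rtol=1e-12
            )

    def test_table_round_trip(self, tmp_path, mini_cohort):
        path = tmp_path / "rois.tsv"
        mini_cohort.write_table(path)
        back = type(mini_cohort).read_table(path)
        np.testing.assert_array_equal(back.wavelengths, mini_cohort.wavelengths)
        assert len(back) == len(mini_cohort)
        for ra, rb in zip(mini_cohort.rois, back.rois):
            assert (ra.species, ra.plant_id, ra.part, ra.n_pixels) == (
                rb.species, rb.plant_id, rb.part, rb.n_pixels)
            np.testing.assert_allclose(rb.mean_spectrum, ra.mean_spectrum, rtol=1e-15)


def test_plant_cube_round_trips_to_rois(coarse_grid):
    """A rendered plant cube and its mask feed extract_rois losslessly."""
    from weedspec.roi_sampling import extract_rois

    cube, mask, labels = generate_plant_cube("Artemisia vulgaris",
                                             wavelengths=coarse_grid, seed=2)
    rois = extract_rois(cube, mask, labels, min_pixels=30)
    assert {r.part for r in rois} == {
        lab[2] for lab in labels.values()
    }
    p = generate_species_profile("Artemisia vulgaris")
    for r in rois:
        clean = render_spectrum(p, r.part, coarse_grid)
        assert np.abs(r.mean_spectrum - clean).mean() < 1.0


def test_vis_nir_measurement_reads_plateau(coarse_grid):
    p = generate_species_profile("Amaranthus retroflexus")
    vis, nir = measure_vis_nir(render_spectrum(p, "leaf", coarse_grid), coarse_grid)
    assert vis == pytest.approx(p.vis_level, abs=0.5)
    assert nir == pytest.approx(p.nir_level, abs=0.5)
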