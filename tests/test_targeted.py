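"""Target-table construction and product-ion-only imaging on the phantom."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from tptcr.errors import InvalidInputError, IsolationLimitError
from tptcr.simulate import (
    AcquisitionConfig,
    generate_phantom,
    render_profile,
)
from tptcr.spectra import Peak, Spectrum
from tptcr.targeted import (
    IonImage,
    build_target_table,
    composite_image,
    extract_window,
    product_ion_image,
    region_contrast,
)


class TestTargetTable:
    def test_complex_row_products_match_printed_values(self, liver_target_table):
        row = liver_target_table.row("FABP1+bezafibrate")
        assert row.precursor_mz == pytest.approx(1835.43, abs=0.01)
        assert row.product_mzs[0] == pytest.approx(2097.5, abs=0.1)
        assert row.product_mzs[1] == pytest.approx(2446.9, abs=0.1)

    def test_globin_row_products(self, liver_target_table):
        row = liver_target_table.row("heme-alpha-globin")
        assert row.product_mzs[0] == pytest.approx(2259.9, abs=0.1)
        assert row.product_mzs[1] == pytest.approx(2636.4, abs=0.1)

    def test_all_precursors_below_isolation_limit(self, liver_target_table):
        assert all(r.precursor_mz < 2000.0 for r in liver_target_table)

    def test_heavy_species_rejected_with_named_offender(self):
        with pytest.raises(IsolationLimitError) as err:
            build_target_table([("big", 20000.0, 8)], n_reduced=2)
        assert "big" in str(err.value)

    def test_raised_limit_admits_heavy_species(self):
        table = build_target_table([("big", 20000.0, 8)], n_reduced=2, isolation_limit=8000.0)
        assert table.row("big").precursor_mz == pytest.approx(2501.0, abs=0.1)


class TestExtractWindow:
    def test_profile_window_recovers_peak_area(self):
        cfg = AcquisitionConfig(mz_range=(2080.0, 2120.0), resolving_power=1000.0)
        spec = render_profile([Peak(2097.5, 55.0)], cfg)
        assert extract_window(spec, 2097.5, 5.0) == pytest.approx(55.0, rel=0.02)

    def test_empty_spectrum_gives_zero(self):
        assert extract_window(Spectrum([], []), 2097.5, 0.5) == 0.0

    def test_window_outside_scan_range_gives_zero(self):
        spec = Spectrum([100.0, 101.0], [1.0, 1.0], mode="centroid")
        assert extract_window(spec, 2097.5, 0.5) == 0.0

    def test_overlapping_windows_double_count_independently(self):
        spec = Spectrum([2000.0], [10.0], mode="centroid")
        assert extract_window(spec, 1999.9, 0.5) == 10.0
        assert extract_window(spec, 2000.1, 0.5) == 10.0


class TestProductIonImage:
    def test_complex_image_tracks_ground_truth(self, default_phantom, liver_target_table):
        img = product_ion_image(default_phantom, liver_target_table.row("FABP1+bezafibrate"))
        truth = default_phantom.truth.abundance_maps["FABP1+bezafibrate"]
        r, _ = pearsonr(img.data.ravel(), truth.ravel())
        assert r >= 0.9

    def test_globin_confined_to_vessel(self, default_phantom, liver_target_table):
        img = product_ion_image(default_phantom, liver_target_table.row("heme-alpha-globin"))
        masks = default_phantom.truth.masks
        assert region_contrast(img, masks["vessel"], masks["bulk"]) > 5

    def test_complex_absent_from_vessel(self, default_phantom, liver_target_table):
        img = product_ion_image(default_phantom, liver_target_table.row("FABP1+bezafibrate"))
        masks = default_phantom.truth.masks
        assert region_contrast(img, masks["vessel"], masks["bulk"]) < 0.2

    def test_precursor_overlapping_interferent_changes_nothing(self, liver_target_table):
        """The tPTCR specificity claim: background at the precursor m/z
        leaves the product-ion image untouched."""
        row = liver_target_table.row("FABP1+bezafibrate")
        clean = generate_phantom((24, 24), vessel_radius=4.0, seed=21)
        dirty = generate_phantom(
            (24, 24), vessel_radius=4.0, seed=21,
            interferents=[("background", row.precursor_mz, 5000.0)],
        )
        img_clean = product_ion_image(clean, row)
        img_dirty = product_ion_image(dirty, row)
        scale = img_clean.data.max()
        assert np.all(np.abs(img_dirty.data - img_clean.data) < 0.01 * scale)

    def test_image_linearity_in_abundance(self, liver_target_table):
        row = liver_target_table.row("FABP1+bezafibrate")
        from tptcr.simulate import default_liver_panel

        panel = default_liver_panel()
        doubled = default_liver_panel()
        for sp in doubled:
            if sp.name == "FABP1+bezafibrate":
                sp.base_abundance *= 2
        a = product_ion_image(
            generate_phantom((24, 24), vessel_radius=4.0, species=panel, seed=4), row
        )
        b = product_ion_image(
            generate_phantom((24, 24), vessel_radius=4.0, species=doubled, seed=4), row
        )
        nz = a.data > 0
        assert np.allclose(b.data[nz] / a.data[nz], 2.0, rtol=1e-6)

    def test_dose_time_ordering(self, liver_target_table):
        row = liver_target_table.row("FABP1+bezafibrate")
        d2 = generate_phantom((24, 24), vessel_radius=4.0, t_hours=2.0, seed=6)
        d6 = generate_phantom((24, 24), vessel_radius=4.0, t_hours=6.0, seed=6)
        bulk = d2.truth.masks["bulk"]
        m2 = product_ion_image(d2, row).data[bulk].mean()
        m6 = product_ion_image(d6, row).data[bulk].mean()
        assert m2 > m6


class TestCompositeAndContrast:
    def test_composite_localises_channels(self, default_phantom, liver_target_table):
        red = product_ion_image(default_phantom, liver_target_table.row("heme-alpha-globin"))
        blue = product_ion_image(default_phantom, liver_target_table.row("FABP1+bezafibrate"))
        rgb = composite_image(red, blue)
        masks = default_phantom.truth.masks
        # red channel majority inside the vessel, blue majority in bulk
        assert rgb[..., 0][masks["vessel"]].mean() > rgb[..., 0][masks["bulk"]].mean()
        assert rgb[..., 2][masks["bulk"]].mean() > rgb[..., 2][masks["vessel"]].mean()

    def test_identical_channels_give_magenta(self):
        img = IonImage(np.random.default_rng(0).random((4, 4)), "x")
        rgb = composite_image(img, img)
        assert np.array_equal(rgb[..., 0], rgb[..., 2])
        assert not rgb[..., 1].any()

    def test_zero_channel_renders_single_colour(self):
        a = IonImage(np.ones((3, 3)), "a")
        b = IonImage(np.zeros((3, 3)), "b")
        rgb = composite_image(a, b)
        assert not rgb[..., 2].any()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            composite_image(IonImage(np.ones((3, 3)), "a"), IonImage(np.ones((4, 4)), "b"))

    def test_uniform_image_contrast_is_one(self):
        img = IonImage(np.ones((6, 6)), "u")
        mask_a = np.zeros((6, 6), bool)
        mask_a[:3] = True
        assert region_contrast(img, mask_a, ~mask_a) == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        img = IonImage(np.ones((4, 4)), "u")
        with pytest.raises(InvalidInputError):
            region_contrast(img, np.zeros((4, 4), bool), np.ones((4, 4), bool))
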