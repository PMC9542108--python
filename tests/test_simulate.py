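"""Generator contracts: envelopes, rendering, PTCR/HCD redistribution,
SIM gain, and the tissue phantom's ground truth."""

import numpy as np
import pytest

from tptcr.deconvolve import centroid
from tptcr.errors import InvalidInputError
from tptcr.masses import IonSpecies
from tptcr.simulate import (
    APO_FABP1_MASS,
    BEZAFIBRATE_FORMULA,
    COMPLEX_MASS,
    AcquisitionConfig,
    HCDConfig,
    SpeciesDefinition,
    clearance_factor,
    generate_phantom,
    render_profile,
    simulate_envelope,
    simulate_full_scan,
    simulate_hcd,
    simulate_ptcr,
    simulate_sim_scan,
)
from tptcr.spectra import Peak


class TestEnvelope:
    def test_dominant_charge_is_center(self):
        sp = SpeciesDefinition("complex", COMPLEX_MASS, z0=8, sigma_z=0.7, abundance=1.0)
        peaks = simulate_envelope(sp)
        top = max(peaks, key=lambda p: p.intensity)
        assert top.z == 8
        assert top.mz == pytest.approx(1835.43, abs=0.01)
        assert sum(p.intensity for p in peaks) == pytest.approx(1.0)

    def test_narrow_envelope_collapses_to_single_charge(self):
        sp = SpeciesDefinition("x", 10000.0, z0=6, sigma_z=1e-6)
        peaks = simulate_envelope(sp)
        weights = sorted((p.intensity for p in peaks), reverse=True)
        assert weights[0] == pytest.approx(1.0)

    def test_zero_abundance_gives_no_peaks(self):
        assert simulate_envelope(SpeciesDefinition("x", 1e4, 8, abundance=0.0)) == []


class TestRenderProfile:
    def test_fwhm_matches_resolving_power(self):
        cfg = AcquisitionConfig(mz_range=(1990.0, 2010.0), resolving_power=1000.0, grid_step=0.01)
        spec = render_profile([Peak(2000.0, 100.0)], cfg)
        half = spec.intensity.max() / 2
        above = spec.mz[spec.intensity > half]
        assert above[-1] - above[0] == pytest.approx(2.0, rel=0.02)

    def test_peak_area_equals_centroid_intensity(self):
        cfg = AcquisitionConfig(mz_range=(1990.0, 2010.0), resolving_power=1000.0)
        spec = render_profile([Peak(2000.0, 123.0)], cfg)
        area = spec.intensity.sum() * (spec.mz[1] - spec.mz[0])
        assert area == pytest.approx(123.0, rel=0.01)

    def test_empty_peaks_zero_baseline_is_all_zero(self):
        cfg = AcquisitionConfig(mz_range=(1000.0, 1100.0))
        assert not render_profile([], cfg).intensity.any()

    def test_seed_determinism(self):
        cfg = AcquisitionConfig(noise_sigma=1.5)
        a = render_profile([Peak(2000.0, 50.0)], cfg, seed=42)
        b = render_profile([Peak(2000.0, 50.0)], cfg, seed=42)
        assert np.array_equal(a.intensity, b.intensity)


class TestPtcr:
    def test_top_products_are_seven_and_six_plus(self, complex_ion):
        spec = simulate_ptcr([(complex_ion, 1000.0)], mu=1.5)
        reduced = [
            (m, i) for m, i in zip(spec.mz, spec.intensity) if m > complex_ion.mz + 1
        ]
        reduced.sort(key=lambda t: -t[1])
        assert reduced[0][0] == pytest.approx(2097.5, abs=0.1)
        assert reduced[1][0] == pytest.approx(2446.9, abs=0.1)

    def test_intensity_conserved(self, complex_ion):
        spec = simulate_ptcr([(complex_ion, 777.0)], mu=1.5)
        assert spec.tic == pytest.approx(777.0, rel=1e-9)

    def test_tiny_mu_leaves_mostly_survivor(self, complex_ion):
        spec = simulate_ptcr([(complex_ion, 1.0)], mu=1e-6)
        at_precursor = spec.intensity[np.isclose(spec.mz, complex_ion.mz)]
        assert at_precursor.sum() == pytest.approx(1.0, abs=1e-5)

    def test_singly_charged_precursor_only_survives(self):
        ion = IonSpecies("small", 1000.0, 1)
        spec = simulate_ptcr([(ion, 5.0)], mu=1.5)
        assert len(spec) == 1 and spec.tic == pytest.approx(5.0)

    def test_multiplexed_ladders_interleave(self, liver_species):
        precursors = [(IonSpecies(n, m, z), 100.0) for n, m, z in liver_species]
        spec = simulate_ptcr(precursors, mu=1.5)
        assert spec.tic == pytest.approx(400.0, rel=1e-9)
        # all four precursors contribute product peaks above their own m/z
        for n, m, z in liver_species:
            ion = IonSpecies(n, m, z)
            assert (spec.mz > ion.mz + 1).any()


class TestSimScan:
    def _mixture(self):
        return [
            SpeciesDefinition("apo-FABP1", APO_FABP1_MASS, 8, abundance=1000.0),
            SpeciesDefinition("complex", COMPLEX_MASS, 8, abundance=5.0),
        ]

    def _cfg(self):
        return AcquisitionConfig(
            mz_range=(1500.0, 3000.0), resolving_power=1000.0, noise_sigma=0.6, sim_gain=20.0
        )

    def test_complex_lost_in_full_scan_but_rescued_by_sim(self):
        """The 0.5%-abundance complex falls below SNR 3 in the full scan
        and is recovered in the gained SIM window."""
        mix, cfg = self._mixture(), self._cfg()
        full = centroid(simulate_full_scan(mix, cfg, seed=5), 3.0)
        assert not [p for p in full if abs(p.mz - 1835.43) < 0.5]
        sim = centroid(simulate_sim_scan(mix, (1820.0, 1850.0), cfg, seed=5), 3.0)
        hits = [p for p in sim if abs(p.mz - 1835.43) < 0.5]
        assert hits and hits[0].snr > 3

    def test_undosed_control_shows_nothing_in_window(self):
        mix = [SpeciesDefinition("apo-FABP1", APO_FABP1_MASS, 8, abundance=1000.0)]
        sim = centroid(simulate_sim_scan(mix, (1820.0, 1850.0), self._cfg(), seed=5), 3.0)
        assert not [p for p in sim if abs(p.mz - 1835.43) < 0.5]

    def test_snr_gain_matches_configured_gain(self):
        """SIM SNR / full-scan SNR ~ g across 50 replicates."""
        mix = [
            SpeciesDefinition("apo-FABP1", APO_FABP1_MASS, 8, abundance=1000.0),
            SpeciesDefinition("complex", COMPLEX_MASS, 8, abundance=80.0),
        ]
        cfg = self._cfg()

        def snr_at(peaks, mz0):
            hits = [p for p in peaks if abs(p.mz - mz0) < 0.5]
            return hits[0].snr if hits else None

        ratios = []
        for s in range(50):
            full = centroid(simulate_full_scan(mix, cfg, seed=100 + s), 3.0)
            sim = centroid(simulate_sim_scan(mix, (1820.0, 1850.0), cfg, seed=200 + s), 3.0)
            a, b = snr_at(full, 1835.43), snr_at(sim, 1835.43)
            if a and b:
                ratios.append(b / a)
        assert len(ratios) >= 45
        assert np.mean(ratios) == pytest.approx(cfg.sim_gain, rel=0.2)

    def test_window_outside_range_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_sim_scan(self._mixture(), (100.0, 200.0), self._cfg())


class TestHcd:
    def test_neutral_loss_product_positions(self, complex_ion):
        spec = simulate_hcd(complex_ion, BEZAFIBRATE_FORMULA, HCDConfig(nce=7.0))
        assert spec.mz[0] == pytest.approx(1790.29, abs=0.01)   # free protein 8+
        assert spec.mz[-1] == pytest.approx(1835.43, abs=0.01)  # surviving precursor
        # no ion anywhere near the free ligand m/z: the drug leaves neutral
        assert not ((spec.mz > 300) & (spec.mz < 500)).any()

    def test_intensity_conserved(self, complex_ion):
        spec = simulate_hcd(complex_ion, BEZAFIBRATE_FORMULA, HCDConfig(nce=7.0), intensity=42.0)
        assert spec.tic == pytest.approx(42.0, rel=1e-9)

    @pytest.mark.parametrize("p_d, n_peaks", [(0.0, 1), (1.0, 1)])
    def test_probability_extremes(self, complex_ion, p_d, n_peaks):
        cfg = HCDConfig(nce=7.0, curve=lambda nce: p_d)
        spec = simulate_hcd(complex_ion, BEZAFIBRATE_FORMULA, cfg)
        assert len(spec) == n_peaks

    def test_charged_ligand_pathway_emits_ligand_ion(self, complex_ion):
        cfg = HCDConfig(nce=7.0, charged_ligand=True)
        spec = simulate_hcd(complex_ion, BEZAFIBRATE_FORMULA, cfg)
        assert spec.mz[0] == pytest.approx(362.12, abs=0.01)

    def test_ligand_heavier_than_complex_rejected(self):
        ion = IonSpecies("tiny", 300.0, 2)
        with pytest.raises(InvalidInputError):
            simulate_hcd(ion, BEZAFIBRATE_FORMULA, HCDConfig())


class TestPhantom:
    def test_clearance_factor(self):
        assert clearance_factor(2.0, 4.5) / clearance_factor(6.0, 4.5) == pytest.approx(
            2 ** (4.0 / 4.5), rel=1e-12
        )

    def test_masks_disjoint_and_covering(self, default_phantom):
        masks = default_phantom.truth.masks
        total = sum(m.astype(int) for m in masks.values())
        assert (total == 1).all()

    def test_localisation(self, default_phantom):
        truth = default_phantom.truth
        globin = truth.abundance_maps["heme-alpha-globin"]
        cplx = truth.abundance_maps["FABP1+bezafibrate"]
        assert globin[truth.masks["vessel"]].mean() > 0
        assert globin[truth.masks["bulk"]].sum() == 0
        assert cplx[truth.masks["bulk"]].mean() > 0
        assert cplx[truth.masks["vessel"]].sum() == 0

    def test_fixed_seed_is_bit_identical(self):
        a = generate_phantom((16, 16), vessel_radius=3.0, seed=7)
        b = generate_phantom((16, 16), vessel_radius=3.0, seed=7)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.mz, sb.mz)
            assert np.array_equal(sa.intensity, sb.intensity)

    def test_complex_abundance_strictly_decreasing_in_time(self):
        means = []
        for t in (0.0, 2.0, 4.0, 6.0, 8.0):
            ds = generate_phantom((16, 16), vessel_radius=3.0, t_hours=t, seed=9)
            truth = ds.truth
            means.append(truth.abundance_maps["FABP1+bezafibrate"][truth.masks["bulk"]].mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_control_phantom_has_no_complex(self):
        ds = generate_phantom((16, 16), vessel_radius=3.0, dosed=False, seed=9)
        assert ds.truth.abundance_maps["FABP1+bezafibrate"].sum() == 0

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_phantom((16, 16), t_hours=-1.0)
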