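"""Generator correctness: area calibration, determinism, label conservation."""

import numpy as np
import pytest

from osmoquant.enzyme_kinetics import michaelis_menten
from osmoquant.nmr_quant import integrate_peak
from osmoquant.synthetic_data import (
    GrowthSimConfig,
    ImageSimConfig,
    KineticsSimConfig,
    SpectrumSimConfig,
    simulate_growth,
    simulate_ion_image,
    simulate_labeled_spectrum,
    simulate_rate_data,
    simulate_spectrum,
)

WIDE = 0.05  # ppm half-window capturing >97% of a 1.5 Hz Lorentzian at 400 MHz


class TestSimulateSpectrum:
    def test_equal_molar_equal_proton_peaks_have_equal_area(self, library, clean_cfg):
        spec = simulate_spectrum({"GB": 0.05}, 0.05, library, clean_cfg)
        a_gb = integrate_peak(spec, 3.27, WIDE)
        a_std = integrate_peak(spec, 0.0, WIDE)
        assert a_gb / a_std == pytest.approx(1.0, rel=1e-4)

    def test_area_ratio_tracks_concentration_ratio(self, library, clean_cfg):
        spec = simulate_spectrum({"GB": 0.10}, 0.05, library, clean_cfg)
        ratio = integrate_peak(spec, 3.27, WIDE) / integrate_peak(spec, 0.0, WIDE)
        assert ratio == pytest.approx(2.0, abs=1e-4)

    def test_zero_mixture_is_flat(self, library):
        cfg = SpectrumSimConfig(noise_sd=0.0)
        spec = simulate_spectrum({}, 0.0, library, cfg)
        assert np.all(spec.intensity == 0.0)

    def test_area_linear_in_concentration_and_protons(self, library, clean_cfg):
        # slope test over 3 concentrations; area = conc * n_protons * capture
        areas = []
        concs = [0.02, 0.04, 0.08]
        for c in concs:
            spec = simulate_spectrum({"GB": c}, 0.0, library, clean_cfg)
            areas.append(integrate_peak(spec, 3.27, WIDE))
        areas = np.array(areas)
        assert np.allclose(areas / areas[0], [1.0, 2.0, 4.0], rtol=1e-4)
        # GB trimethyl (9H) vs methylene (2H) at one concentration
        spec = simulate_spectrum({"GB": 0.04}, 0.0, library, clean_cfg)
        r = integrate_peak(spec, 3.27, WIDE) / integrate_peak(spec, 3.91, WIDE)
        assert r == pytest.approx(9 / 2, rel=1e-3)

    def test_unknown_solute_rejected(self, library, clean_cfg):
        with pytest.raises(KeyError, match="unknown solute"):
            simulate_spectrum({"glycerol": 0.01}, 0.05, library, clean_cfg)

    def test_seeded_noise_is_deterministic(self, library):
        cfg = SpectrumSimConfig(noise_sd=0.5, seed=42)
        a = simulate_spectrum({"GB": 0.05}, 0.05, library, cfg)
        b = simulate_spectrum({"GB": 0.05}, 0.05, library, cfg)
        assert np.array_equal(a.intensity, b.intensity)

    def test_multiplet_total_area_preserved(self, clean_cfg):
        from osmoquant.references import SolutePeak, SoluteReference

        lib = {
            "X": SoluteReference("X", (
                SolutePeak(2.0, "triplet", 3, is_quantification_peak=True,
                           j_hz=7.0),
            ))
        }
        spec = simulate_spectrum({"X": 0.05}, 0.0, lib, clean_cfg)
        # integrate across the whole multiplet (J = 7 Hz -> 0.0175 ppm spacing)
        area = integrate_peak(spec, 2.0, 0.1)
        ref = simulate_spectrum({"X": 0.05}, 0.0, {
            "X": SoluteReference("X", (
                SolutePeak(2.0, "singlet", 3, is_quantification_peak=True),
            ))
        }, clean_cfg)
        assert area == pytest.approx(integrate_peak(ref, 2.0, 0.1), rel=1e-3)


class TestLabeledSpectrum:
    def test_no_label_degenerates_to_plain_spectrum(self, library, clean_cfg):
        a = simulate_labeled_spectrum(0.05, 0.0, {"Ect": 0.02}, clean_cfg,
                                      standard_conc=0.05, library=library)
        b = simulate_spectrum({"GB": 0.05, "Ect": 0.02}, 0.05, library, clean_cfg)
        assert np.array_equal(a.intensity, b.intensity)

    def test_equal_pools_give_equal_central_and_satellite_area(self, library, clean_cfg):
        spec = simulate_labeled_spectrum(0.03, 0.03, None, clean_cfg,
                                         standard_conc=0.0, library=library)
        half = 144.0 / (2 * 400.0)
        central = integrate_peak(spec, 3.27, 0.015)
        sats = (integrate_peak(spec, 3.27 - half, 0.015)
                + integrate_peak(spec, 3.27 + half, 0.015))
        assert central == pytest.approx(sats, rel=1e-3)

    def test_label_conservation(self, library, clean_cfg):
        """central + satellites == unlabelled peak at the summed concentration."""
        mixed = simulate_labeled_spectrum(0.02, 0.04, None, clean_cfg,
                                          standard_conc=0.0, library=library)
        pooled = simulate_spectrum({"GB": 0.06}, 0.0, library, clean_cfg)
        half = 144.0 / (2 * 400.0)
        total_mixed = sum(
            integrate_peak(mixed, 3.27 + off, 0.015)
            for off in (-half, 0.0, half)
        )
        assert total_mixed == pytest.approx(
            integrate_peak(pooled, 3.27, 0.015), rel=2e-3)


class TestSimulateIonImage:
    def test_noise_free_strata_exact(self, clean_image):
        img, truth, cfg = clean_image
        assert np.all(img[truth.cytoplasm] == cfg.cytoplasm_level)
        assert np.all(img[truth.background] == cfg.background_level)
        assert np.all(img[truth.vacuole] == cfg.vacuole_level)

    def test_same_seed_same_image(self):
        cfg = ImageSimConfig(noise_sd=3.0, seed=7)
        a, _ = simulate_ion_image(cfg)
        b, _ = simulate_ion_image(cfg)
        assert np.array_equal(a, b)

    def test_vacuole_outside_cell_rejected(self):
        with pytest.raises(ValueError, match="inside the cell"):
            simulate_ion_image(ImageSimConfig(vacuole_center=(10.0, 10.0)))

    def test_level_ordering_enforced(self):
        with pytest.raises(ValueError, match="levels"):
            ImageSimConfig(background_level=60.0, cytoplasm_level=50.0)


class TestSimulateRates:
    def test_half_saturation_identity(self):
        cfg = KineticsSimConfig(true_Km=0.022, true_Vmax=1486.0,
                                substrate_concs=(0.011, 0.022, 0.044),
                                noise_cv=0.0)
        rs = simulate_rate_data(cfg)
        assert rs.rate[1] == pytest.approx(743.0)

    def test_saturating_substrate_approaches_vmax(self):
        cfg = KineticsSimConfig(true_Km=0.5, true_Vmax=100.0,
                                substrate_concs=(0.5, 50.0, 5000.0),
                                noise_cv=0.0)
        assert simulate_rate_data(cfg).rate[-1] == pytest.approx(100.0, rel=1e-3)

    def test_noise_free_matches_curve_and_replicates_expand(self):
        s = (0.01, 0.05, 0.2)
        cfg = KineticsSimConfig(true_Km=0.05, true_Vmax=10.0, substrate_concs=s,
                                noise_cv=0.0, replicates=3)
        rs = simulate_rate_data(cfg)
        assert rs.substrate.size == 9
        assert np.allclose(rs.rate, michaelis_menten(rs.substrate, 10.0, 0.05))

    def test_seeded_determinism(self):
        cfg = KineticsSimConfig(true_Km=0.05, true_Vmax=10.0,
                                substrate_concs=(0.01, 0.05, 0.2),
                                noise_cv=0.1, replicates=2, seed=11)
        assert np.array_equal(simulate_rate_data(cfg).rate,
                              simulate_rate_data(cfg).rate)


class TestSimulateGrowth:
    def test_zero_scatter_reproduces_means(self):
        cfg = GrowthSimConfig(sd_fraction=0.0, n_replicates=3, seed=0)
        df = simulate_growth(cfg)
        ctrl = df[df.treatment == "control"].cells_per_ml
        assert (ctrl == cfg.control_mean).all()
        ch = df[df.treatment == "Ch"].cells_per_ml
        assert ch.mean() / ctrl.mean() == pytest.approx(3247.0 / 280.0)

    def test_row_counts_and_truncation(self):
        cfg = GrowthSimConfig(control_mean=1.0, treatment_means={"X": 1.0},
                              sd_fraction=5.0, n_replicates=4, seed=2)
        df = simulate_growth(cfg)
        assert (df.groupby("treatment").size() == 4).all()
        assert (df.cells_per_ml >= 0).all()
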