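"""Peak detection, assignment, integration, quantification, label analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osmoquant.nmr_quant import (
    assign_solutes,
    detect_peaks,
    identified_solutes,
    integrate_peak,
    intracellular_concentration,
    label_ratio,
    quantify,
)
from osmoquant.references import InternalStandardSpec, default_library
from osmoquant.spectra import Spectrum1D
from osmoquant.synthetic_data import (
    SpectrumSimConfig,
    simulate_labeled_spectrum,
    simulate_spectrum,
)


class TestDetectPeaks:
    def test_gb_spectrum_yields_both_gb_peaks(self, library, clean_cfg):
        spec = simulate_spectrum({"GB": 0.05}, 0.0, library, clean_cfg)
        shifts = [s for s, _ in detect_peaks(spec)]
        assert len(shifts) == 2
        assert shifts[0] == pytest.approx(3.91, abs=2e-3)
        assert shifts[1] == pytest.approx(3.27, abs=2e-3)

    def test_flat_spectrum_yields_nothing(self):
        spec = Spectrum1D(np.linspace(10, 0, 4096), np.zeros(4096))
        assert detect_peaks(spec) == []

    def test_standard_peak_found_at_zero_ppm(self, mixture_spectrum):
        spec, _ = mixture_spectrum
        shifts = np.array([s for s, _ in detect_peaks(spec)])
        assert np.min(np.abs(shifts - 0.0)) < 2e-3

    def test_exclusion_window_drops_peaks(self, library, clean_cfg):
        spec = simulate_spectrum({"GB": 0.05}, 0.0, library, clean_cfg)
        shifts = [s for s, _ in
                  detect_peaks(spec, exclusion_windows=((3.2, 3.4),))]
        assert all(not 3.2 <= s <= 3.4 for s in shifts)

    def test_sorted_descending(self, mixture_spectrum):
        shifts = [s for s, _ in detect_peaks(mixture_spectrum[0])]
        assert shifts == sorted(shifts, reverse=True)


class TestAssignSolutes:
    def test_mixture_identifies_both_solutes(self, mixture_spectrum, library):
        spec, _ = mixture_spectrum
        found = identified_solutes(assign_solutes(detect_peaks(spec), library))
        assert {"GB", "Ect", "TMSP"} <= found

    def test_ect_only_spectrum_has_no_gb(self, library, clean_cfg):
        spec = simulate_spectrum({"Ect": 0.05}, 0.0, library, clean_cfg)
        found = identified_solutes(assign_solutes(detect_peaks(spec), library))
        assert "GB" not in found
        assert "Ect" in found

    def test_displacement_beyond_tolerance_kills_identification(self, library):
        tol = 0.03
        peaks = [(p.shift, 1.0) for p in library["GB"].peaks]
        peaks[0] = (peaks[0][0] + 2 * tol, 1.0)  # displace one reference match
        found = identified_solutes(assign_solutes(peaks, {"GB": library["GB"]}, tol))
        assert found == set()

    def test_permutation_invariance(self, mixture_spectrum, library):
        peaks = detect_peaks(mixture_spectrum[0])
        a = assign_solutes(peaks, library)
        b = assign_solutes(list(reversed(peaks)), library)
        assert a == b

    def test_shift_error_within_tolerance(self, mixture_spectrum, library):
        for a in assign_solutes(detect_peaks(mixture_spectrum[0]), library):
            assert abs(a.shift_error) <= 0.03


class TestIntegratePeak:
    def _unit_lorentzian(self, fwhm=0.00375, n=2**16):
        ppm = np.linspace(10, -1, n)
        hwhm = fwhm / 2
        y = hwhm / (np.pi * ((ppm - 2.0) ** 2 + hwhm**2))
        return Spectrum1D(ppm, y)

    def test_unit_area_lorentzian_captured_in_wide_window(self):
        # closed form: captured mass (2/pi) atan(2k) at k = 20 linewidths,
        # less the baseline trapezoid 2w L(w) sitting on the peak's own tail
        fwhm = 0.00375
        w = 20 * fwhm
        hwhm = fwhm / 2
        expected = (2 / np.pi) * np.arctan(2 * 20) - \
            2 * w * hwhm / (np.pi * (w**2 + hwhm**2))
        spec = self._unit_lorentzian(fwhm)
        area = integrate_peak(spec, 2.0, w)
        assert area == pytest.approx(expected, abs=2e-3)
        assert 0.95 <= area <= 1.00

    def test_zero_spectrum_integrates_to_zero(self):
        spec = Spectrum1D(np.linspace(10, 0, 4096), np.zeros(4096))
        assert integrate_peak(spec, 5.0, 0.1) == 0.0

    def test_linearity_in_intensity(self):
        spec = self._unit_lorentzian()
        a1 = integrate_peak(spec, 2.0, 0.05)
        a2 = integrate_peak(spec.scaled(2.0), 2.0, 0.05)
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_window_outside_axis_rejected(self):
        spec = self._unit_lorentzian()
        with pytest.raises(ValueError, match="outside axis"):
            integrate_peak(spec, 10.0, 0.5)

    def test_baseline_offset_removed(self):
        spec = self._unit_lorentzian()
        shifted = Spectrum1D(spec.ppm, spec.intensity + 7.5)
        assert integrate_peak(shifted, 2.0, 0.05) == pytest.approx(
            integrate_peak(spec, 2.0, 0.05), rel=1e-9)


class TestQuantify:
    def test_area_ratio_arithmetic(self):
        # c_s = (A_s/A_std) * (n_std/n_s) * c_std; 0.1 ratio, 9H/9H, 500 mM
        assert 0.1 * (9 / 9) * 0.5 == pytest.approx(0.05)

    def test_round_trip_noise_free(self, library, standard, clean_cfg):
        true = {"GB": 0.05, "Ect": 0.02, "Ch": 0.035}
        spec = simulate_spectrum(true, standard.concentration, library,
                                 clean_cfg, standard)
        tube = quantify(spec, library, standard, window=0.008)
        for name, c in true.items():
            assert tube[name] == pytest.approx(c, rel=0.02)

    def test_absent_solute_reports_zero(self, library, standard, clean_cfg):
        spec = simulate_spectrum({"Ect": 0.02}, standard.concentration,
                                 library, clean_cfg, standard)
        tube = quantify(spec, library, standard, window=0.008)
        assert tube["GB"] == 0.0
        assert tube["Ch"] == 0.0

    def test_missing_standard_is_fatal(self, library, clean_cfg):
        spec = simulate_spectrum({"GB": 0.05}, 0.0, library, clean_cfg)
        with pytest.raises(ValueError, match="standard"):
            quantify(spec, library, InternalStandardSpec(concentration=0.05))

    def test_scale_invariance(self, mixture_spectrum, library, standard):
        spec, _ = mixture_spectrum
        a = quantify(spec, library, standard, window=0.008)
        b = quantify(spec.scaled(37.0), library, standard, window=0.008)
        for k in a:
            assert b[k] == pytest.approx(a[k], rel=1e-9)


class TestIntracellularConcentration:
    def test_worked_example(self):
        # 1 umol total in the tube from 1e5 cells -> 10 pmol per cell;
        # over an 8.01 pl cell volume that is 10e-12/8.01e-12 = 1.248 mol/l
        assert intracellular_concentration(1e-6, 1.0, 1e5, 8.01) == pytest.approx(
            1.2484, abs=5e-4)

    def test_zero_tube_concentration(self):
        assert intracellular_concentration(0.0, 6e-4, 1e4, 8.01) == 0.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            intracellular_concentration(0.01, 6e-4, 0, 8.01)

    @given(
        tube=st.floats(1e-6, 1.0),
        vol=st.floats(1e-5, 1e-2),
        cells=st.floats(1.0, 1e7),
        cv=st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_bilinear_scaling(self, tube, vol, cells, cv):
        base = intracellular_concentration(tube, vol, cells, cv)
        assert intracellular_concentration(2 * tube, vol, cells, cv) == pytest.approx(2 * base, rel=1e-12)
        assert intracellular_concentration(tube, 2 * vol, cells, cv) == pytest.approx(2 * base, rel=1e-12)
        assert intracellular_concentration(tube, vol, 2 * cells, cv) == pytest.approx(base / 2, rel=1e-12)
        assert intracellular_concentration(tube, vol, cells, 2 * cv) == pytest.approx(base / 2, rel=1e-12)


class TestLabelRatio:
    def test_three_eight_one_mixture_recovered(self, library, clean_cfg):
        spec = simulate_labeled_spectrum(0.003, 0.008, {"Ect": 0.001},
                                         clean_cfg, standard_conc=0.05,
                                         library=library)
        u, l, e = label_ratio(spec, library)
        assert u == pytest.approx(3.0, rel=0.05)
        assert l == pytest.approx(8.0, rel=0.05)
        assert e == pytest.approx(1.0, rel=0.05)

    def test_no_labeled_pool_gives_zero_satellites(self, library, clean_cfg):
        spec = simulate_labeled_spectrum(0.006, 0.0, {"Ect": 0.002},
                                         clean_cfg, standard_conc=0.05,
                                         library=library)
        u, l, e = label_ratio(spec, library)
        assert l == pytest.approx(0.0, abs=0.05)
        assert u > 0 and e > 0

    def test_fully_labeled_pool_gives_zero_central(self, library, clean_cfg):
        spec = simulate_labeled_spectrum(0.0, 0.006, {"Ect": 0.002},
                                         clean_cfg, standard_conc=0.05,
                                         library=library)
        u, l, e = label_ratio(spec, library)
        assert u == pytest.approx(0.0, abs=0.05)
        assert l > 0

    def test_satellite_overlap_diagnosed(self, library, clean_cfg):
        spec = simulate_labeled_spectrum(0.003, 0.008, None, clean_cfg,
                                         standard_conc=0.05, library=library)
        with pytest.raises(ValueError, match="overlap"):
            label_ratio(spec, library, j_ch_hz=10.0)  # 0.0125 ppm < 2*window
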