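"""Raman pipeline: resampling, baseline, subtraction, factor calibration, R."""

import numpy as np
import pytest

from brisma.exceptions import ConfigurationError, GridError, RangeError
from brisma.io import Spectrum
from brisma.raman import (
    BandWindows,
    ch_oh_ratio,
    integrate_band,
    optimize_factors,
    remove_baseline,
    resample_to,
    subtract_scaled,
)
from brisma.synthetic import (
    PRESETS,
    make_raman,
    make_reference_set,
    raman_truth_areas,
)


def _flat(axis, value=1.0):
    return Spectrum("raman", axis, np.full(len(axis), float(value)))


class TestResample:
    def test_identity_axis(self):
        x = np.linspace(2400, 4000, 200)
        s = Spectrum("raman", x, np.sin(x / 100) ** 2)
        out = resample_to(s, x)
        np.testing.assert_allclose(out.intensity, s.intensity)

    def test_linear_ramp_midpoints_exact(self):
        x = np.arange(0.0, 10.0)
        s = Spectrum("raman", x, 3.0 * x + 1.0)
        mid = x[:-1] + 0.5
        out = resample_to(s, mid)
        np.testing.assert_allclose(out.intensity, 3.0 * mid + 1.0)

    def test_gaussian_area_preserved_at_2x_density(self):
        x = np.linspace(2600, 3600, 500)
        y = np.exp(-0.5 * ((x - 3100) / 50) ** 2)
        s = Spectrum("raman", x, y)
        dense = resample_to(s, np.linspace(2600, 3600, 1000))
        a0 = integrate_band(s, (2600, 3600))
        a1 = integrate_band(dense, (2600, 3600))
        assert a1 == pytest.approx(a0, rel=1e-3)

    def test_extrapolation_is_range_error(self):
        s = _flat(np.linspace(2500, 3500, 100))
        with pytest.raises(RangeError):
            resample_to(s, np.linspace(2400, 3500, 100))


class TestRemoveBaseline:
    def test_baseline_free_bands_almost_untouched(self, control_preset):
        spec, truth = make_raman(
            control_preset, 0, with_pdms=False, with_medium=False,
            with_baseline=False, noise_snr=None,
        )
        corrected, _ = remove_baseline(spec)
        w = BandWindows()
        a_ch = integrate_band(corrected, w.ch_window)
        assert a_ch == pytest.approx(integrate_band(spec, w.ch_window), rel=0.01)

    def test_polynomial_fluorescence_removed(self, control_preset):
        """Band areas after correction within 2% of the generator truth."""
        spec, truth = make_raman(
            control_preset, 0, with_pdms=False, with_medium=False, noise_snr=None
        )
        corrected, baseline = remove_baseline(spec)
        w = BandWindows()
        # generator truth areas are whole-line Gaussian areas; integrate the
        # clean bands over the same windows for a like-for-like comparison
        clean, _ = make_raman(
            control_preset, 0, with_pdms=False, with_medium=False,
            with_baseline=False, noise_snr=None,
        )
        for window in (w.ch_window, w.oh_window):
            assert integrate_band(corrected, window) == pytest.approx(
                integrate_band(clean, window), rel=0.02
            )

    def test_anchor_overlap_with_bands_is_config_error(self, control_preset):
        spec, _ = make_raman(control_preset, 0, noise_snr=None)
        with pytest.raises(ConfigurationError):
            remove_baseline(
                spec, anchor_regions=((2900, 3000),), band_windows=BandWindows()
            )

    def test_too_few_anchor_points_is_config_error(self):
        x = np.linspace(2400, 4000, 801)
        s = _flat(x)
        with pytest.raises(ConfigurationError):
            remove_baseline(s, anchor_regions=((2600.0, 2604.0),))


class TestSubtractScaled:
    def test_alpha_zero_is_identity(self):
        x = np.linspace(2400, 4000, 100)
        s = _flat(x, 5.0)
        out = subtract_scaled(s, _flat(x, 3.0), 0.0)
        np.testing.assert_allclose(out.intensity, s.intensity)

    def test_exact_cancellation(self):
        x = np.linspace(2400, 4000, 100)
        ref = Spectrum("raman", x, np.exp(-((x - 3000) / 80) ** 2))
        s = ref.copy(intensity=0.7 * ref.intensity)
        out = subtract_scaled(s, ref, 0.7)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_component_recovered_from_composite(self, control_preset):
        cell, _ = make_raman(
            control_preset, 0, with_pdms=False, with_medium=False,
            with_baseline=False, noise_snr=None,
        )
        pdms = make_reference_set(0, preset=control_preset, noise_snr=None).pdms
        composite = cell.copy(intensity=cell.intensity + 0.3 * pdms.intensity)
        out = subtract_scaled(composite, pdms, 0.3)
        np.testing.assert_allclose(out.intensity, cell.intensity, atol=1e-9)

    def test_axis_mismatch_is_grid_error(self):
        a = _flat(np.linspace(2400, 4000, 100))
        b = _flat(np.linspace(2400, 4000, 101))
        with pytest.raises(GridError):
            subtract_scaled(a, b, 1.0)


class TestIntegrateBand:
    def test_unit_rectangle(self):
        x = np.linspace(2900, 3100, 2001)
        y = np.where((x >= 2950) & (x <= 3050), 1.0, 0.0)
        s = Spectrum("raman", x, y)
        assert integrate_band(s, (2950, 3050)) == pytest.approx(100.0, abs=0.2)

    def test_gaussian_closed_form(self):
        """Unit-amplitude Gaussian, sigma 30: area = sigma*sqrt(2*pi) = 75.2."""
        x = np.linspace(2600, 3400, 4001)
        s = Spectrum("raman", x, np.exp(-0.5 * ((x - 3000) / 30.0) ** 2))
        assert integrate_band(s, (2700, 3300)) == pytest.approx(75.2, abs=0.5)

    def test_all_zero_spectrum(self):
        s = _flat(np.linspace(2400, 4000, 100), 0.0)
        assert integrate_band(s, (2800, 3020)) == 0.0

    def test_window_outside_axis_is_range_error(self):
        s = _flat(np.linspace(2800, 3000, 100))
        with pytest.raises(RangeError):
            integrate_band(s, (3100, 3200))


class TestOptimizeFactors:
    def _prep(self, spec):
        return remove_baseline(spec)[0]

    def test_known_contamination_recovered(self, control_preset, control_refs_clean):
        """Composite with pdms_level 0.20 and medium_level 0.50; the clean
        spheroid component is the off-chip reference: factors recovered to
        well within 0.01."""
        preset = control_preset.replace(pdms_level=0.20, medium_level=0.50)
        sample, _ = make_raman(preset, 1, with_baseline=False, noise_snr=None)
        a_p, a_m, obj = optimize_factors(sample, control_refs_clean)
        assert a_p == pytest.approx(0.20, abs=0.01)
        assert a_m == pytest.approx(0.50, abs=0.01)

    def test_no_pdms_gives_near_zero_factor(self, control_preset, control_refs_clean):
        sample, _ = make_raman(
            control_preset, 1, with_pdms=False, with_baseline=False, noise_snr=None
        )
        a_p, _, _ = optimize_factors(sample, control_refs_clean)
        assert a_p <= 0.02

    def test_sample_identical_to_offchip(self, control_refs_clean):
        a_p, a_m, obj = optimize_factors(control_refs_clean.offchip, control_refs_clean)
        assert a_p == pytest.approx(0.0, abs=1e-6)
        assert a_m == pytest.approx(0.0, abs=1e-6)


class TestChOhRatio:
    def test_noiseless_ratio_matches_generator(self, control_preset, control_refs_clean):
        spec, _ = make_raman(control_preset, 1, noise_snr=None)
        result = ch_oh_ratio(spec, control_refs_clean)
        assert result.ratio == pytest.approx(raman_truth_areas(control_preset)["ratio"], rel=0.02)

    def test_scale_invariance(self, control_preset, control_refs_clean):
        spec, _ = make_raman(control_preset, 1, noise_snr=None)
        r0 = ch_oh_ratio(spec, control_refs_clean).ratio
        doubled = spec.copy(intensity=2.0 * spec.intensity)
        refs2 = type(control_refs_clean)(
            pdms=control_refs_clean.pdms.copy(intensity=2 * control_refs_clean.pdms.intensity),
            medium=control_refs_clean.medium.copy(intensity=2 * control_refs_clean.medium.intensity),
            offchip=control_refs_clean.offchip.copy(intensity=2 * control_refs_clean.offchip.intensity),
        )
        assert ch_oh_ratio(doubled, refs2).ratio == pytest.approx(r0, rel=1e-9)

    def test_pure_water_ratio_near_zero(self, control_refs_clean):
        preset = PRESETS["control"].replace(phi_ecm=0.5, w_cell=0.999)
        spec, _ = make_raman(preset, 1, with_pdms=False, with_medium=False, noise_snr=None)
        result = ch_oh_ratio(spec, control_refs_clean)
        assert result.ratio < 0.02

    def test_monotone_decreasing_in_water_fraction(self, control_preset, control_refs_clean):
        """R strictly decreases as the ECM (water) fraction grows."""
        ratios = []
        for phi in np.linspace(0.0, 0.5, 11):
            preset = control_preset.replace(phi_ecm=float(phi))
            spec, _ = make_raman(preset, 5, with_pdms=False, with_medium=False, noise_snr=None)
            ratios.append(ch_oh_ratio(spec, control_refs_clean).ratio)
        assert np.all(np.diff(ratios) < 0)

    def test_idempotence_of_subtraction_chain(self, control_preset, control_refs_clean):
        """Re-running the chain on an already-processed spectrum with
        re-optimized factors changes R by < 1%."""
        spec, _ = make_raman(control_preset, 1, noise_snr=None)
        first = ch_oh_ratio(spec, control_refs_clean)
        corrected, _ = remove_baseline(spec)
        processed = corrected.copy(
            intensity=corrected.intensity
            - first.alpha_pdms * control_refs_clean.pdms.intensity
            - first.alpha_medium * control_refs_clean.medium.intensity
        )
        second = ch_oh_ratio(processed, control_refs_clean)
        assert second.ratio == pytest.approx(first.ratio, rel=0.01)
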