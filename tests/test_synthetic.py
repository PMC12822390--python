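"""Generator contracts: determinism, analytic truths, dataset assembly."""

import numpy as np
import pytest

from brisma.exceptions import BrismaError, ConfigurationError
from brisma.io import read_manifest, read_spectrum
from brisma.raman import BandWindows, integrate_band
from brisma.synthetic import (
    PRESETS,
    make_brillouin,
    make_dataset,
    make_invasion_masks,
    make_nuclei_image,
    make_raman,
    make_reference_set,
    raman_truth_areas,
)


class TestDeterminism:
    def test_brillouin_same_seed_bit_identical(self):
        a, _ = make_brillouin(PRESETS["control"], seed=9)
        b, _ = make_brillouin(PRESETS["control"], seed=9)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        c, _ = make_brillouin(PRESETS["control"], seed=10)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_raman_same_seed_bit_identical(self):
        a, _ = make_raman(PRESETS["rock"], seed=9)
        b, _ = make_raman(PRESETS["rock"], seed=9)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_nuclei_same_seed_identical_labels(self):
        a = make_nuclei_image(n=40, size=256, seed=3)
        b = make_nuclei_image(n=40, size=256, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_invasion_same_seed_identical_masks(self):
        a = make_invasion_masks(seed=5)
        b = make_invasion_masks(seed=5)
        np.testing.assert_array_equal(a[1], b[1])


class TestBrillouinGenerator:
    def test_span_must_cover_peaks(self):
        with pytest.raises(ConfigurationError):
            make_brillouin(PRESETS["control"], seed=0, span=(-9.0, 9.0))

    def test_mixture_truth_recorded(self):
        _, truth = make_brillouin(PRESETS["control"], seed=0)
        expected = 0.15 * 8.0 + 0.85 * 8.20
        assert truth["omega_b_mix"] == pytest.approx(expected)

    def test_poisson_noise_scale(self):
        """Peak counts approximate noise_snr**2 (Poisson photon counting)."""
        spec, _ = make_brillouin(PRESETS["compressed"], seed=0, noise_snr=50)
        near_peak = spec.intensity[np.abs(np.abs(spec.axis) - 8.2) < 0.05]
        assert near_peak.max() == pytest.approx(2500, rel=0.2)


class TestRamanGenerator:
    def test_pure_water_preset_has_zero_ch_area(self):
        preset = PRESETS["control"].replace(phi_ecm=0.5, w_cell=0.9999)
        areas = raman_truth_areas(preset)
        assert areas["a_ch"] == pytest.approx(0.0, abs=0.1)

    def test_analytic_areas_match_numeric_integration(self):
        """Clean generated bands integrate to the closed-form truth."""
        preset = PRESETS["control"]
        spec, truth = make_raman(
            preset, 0, with_pdms=False, with_medium=False, with_baseline=False, noise_snr=None
        )
        w = BandWindows()
        # windowed integrals shave the band tails; whole-axis split at the
        # window boundary captures the full areas
        a_ch = integrate_band(spec, (spec.axis[0], w.ch_window[1]))
        a_oh = integrate_band(spec, (w.ch_window[1], spec.axis[-1]))
        assert a_ch + a_oh == pytest.approx(truth["a_ch"] + truth["a_oh"], rel=0.01)
        assert a_ch == pytest.approx(truth["a_ch"], rel=0.03)
        assert a_oh == pytest.approx(truth["a_oh"], rel=0.03)


class TestReferenceSet:
    def test_medium_is_oh_only(self):
        refs = make_reference_set(0, noise_snr=None)
        w = BandWindows()
        ch = integrate_band(refs.medium, w.ch_window)
        oh = integrate_band(refs.medium, w.oh_window)
        assert ch < 0.01 * oh

    def test_pdms_has_no_oh(self):
        refs = make_reference_set(0, noise_snr=None)
        w = BandWindows()
        assert integrate_band(refs.pdms, w.oh_window) < 0.01 * integrate_band(
            refs.pdms, w.ch_window
        )

    def test_offchip_matches_analytic_ch_area(self):
        refs = make_reference_set(0, noise_snr=None)
        truth = raman_truth_areas(PRESETS["control"])
        w = BandWindows()
        assert integrate_band(refs.offchip, w.ch_window) == pytest.approx(
            truth["a_ch"], rel=0.02
        )


class TestNucleiGenerator:
    def test_null_zone_effect_gives_no_zone_difference(self):
        from brisma.morphometry import classify_zone, nucleus_shapes

        nuc = make_nuclei_image(n=200, zone_effect=0.0, seed=21)
        shapes, _ = nucleus_shapes(nuc.labels)
        shapes = classify_zone(shapes, nuc.mask, band=nuc.truth["band"])
        per = [s.aspect_ratio for s in shapes if s.zone == "periphery"]
        cen = [s.aspect_ratio for s in shapes if s.zone == "center"]
        assert abs(np.mean(per) - np.mean(cen)) <= 0.05

    def test_zone_effect_recovered(self):
        from brisma.morphometry import classify_zone, nucleus_shapes

        nuc = make_nuclei_image(n=200, zone_effect=0.4, seed=22)
        shapes, _ = nucleus_shapes(nuc.labels)
        shapes = classify_zone(shapes, nuc.mask, band=nuc.truth["band"])
        per = [s.aspect_ratio for s in shapes if s.zone == "periphery"]
        cen = [s.aspect_ratio for s in shapes if s.zone == "center"]
        assert np.mean(per) - np.mean(cen) == pytest.approx(0.4, abs=0.1)

    def test_per_nucleus_truth_matches_measurement(self):
        from brisma.morphometry import nucleus_shapes

        nuc = make_nuclei_image(n=60, size=256, seed=23)
        shapes, _ = nucleus_shapes(nuc.labels)
        truth_ar = {r["label"]: r["aspect_ratio"] for r in nuc.truth["nuclei"]}
        errors = [s.aspect_ratio - truth_ar[s.label] for s in shapes]
        assert np.mean(np.abs(errors)) < 0.05


class TestMakeDataset:
    def test_counts_and_manifest_round_trip(self, tmp_path):
        manifest = make_dataset(["control", "rock"], 3, seed=1, outdir=tmp_path / "d")
        records = read_manifest(manifest)
        assert len(records) == 6
        for rec in records:
            read_spectrum(rec.brillouin_path, "brillouin")
            read_spectrum(rec.raman_path, "raman")

    def test_same_seed_byte_identical_trees(self, tmp_path):
        m1 = make_dataset(["control"], 2, seed=7, outdir=tmp_path / "a", with_images=False)
        m2 = make_dataset(["control"], 2, seed=7, outdir=tmp_path / "b", with_images=False)
        files1 = sorted(p.relative_to(m1.parent) for p in m1.parent.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(m2.parent) for p in m2.parent.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (m1.parent / rel).read_bytes() == (m2.parent / rel).read_bytes()

    def test_existing_nonempty_outdir_is_safety_error(self, tmp_path):
        d = tmp_path / "d"
        d.mkdir()
        (d / "stale.txt").write_text("x")
        with pytest.raises(BrismaError):
            make_dataset(["control"], 1, seed=1, outdir=d)
        make_dataset(["control"], 1, seed=1, outdir=d, overwrite=True)
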