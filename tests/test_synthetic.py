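"""Forward simulator: modal depth, layer weights, mixtures, noise trends."""

import math

import numpy as np
import pytest

from fibrospec import (
    FIBER_DISTANCES_UM,
    TissueOpticalModel,
    compute_snr,
    default_grid,
    depth_sensitivity,
    enumerate_study_classes,
    layer_weights,
    mean_normalize,
    reference_spectrum,
    simulate_spectrum,
    simulate_study,
)
from fibrospec.spectra import calibrate
from fibrospec.synthetic import STANDARD_REFLECTANCE


class TestDepthSensitivity:
    def test_closed_form_for_all_probe_distances(self):
        for r in FIBER_DISTANCES_UM.values():
            assert depth_sensitivity(r) == pytest.approx(r / (2 * math.sqrt(2)), abs=1e-9)

    def test_printed_modal_depths(self):
        assert round(depth_sensitivity(210)) == 74
        assert round(depth_sensitivity(750)) == 265

    def test_degenerate_and_invalid(self):
        assert depth_sensitivity(0) == 0
        with pytest.raises(ValueError):
            depth_sensitivity(-1)


class TestLayerWeights:
    def test_weights_positive_and_sum_to_one(self, model_small):
        for fiber in FIBER_DISTANCES_UM:
            w = layer_weights(fiber, model_small)
            assert w.shape == (8,)
            assert np.all(w > 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_distal_fiber_peaks_deeper(self, model_small):
        assert np.argmax(layer_weights("R5", model_small)) >= np.argmax(
            layer_weights("R1", model_small)
        )

    def test_infinite_decay_limit_is_uniform(self, small_grid):
        model = TissueOpticalModel(wavelengths=small_grid, sensitivity_decay_um=1e12)
        np.testing.assert_allclose(layer_weights("R3", model), 1 / 8, atol=1e-9)


class TestSimulateSpectrum:
    def test_pure_myocardium_proportional_to_lamp_times_base(self, model_clean):
        expected_shape = model_clean.lamp * model_clean.base_myocardium
        for fiber in FIBER_DISTANCES_UM:
            s = simulate_spectrum("00000000", fiber, model_clean, seed=3)
            ratio = s.intensities / expected_shape
            np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_pure_construct_ratio_equals_base_ratio(self, model_clean):
        a = simulate_spectrum("11111111", "R3", model_clean, seed=3)
        m = simulate_spectrum("00000000", "R3", model_clean, seed=3)
        np.testing.assert_allclose(
            a.intensities / m.intensities,
            model_clean.base_aorta / model_clean.base_myocardium,
            rtol=1e-9,
        )

    def test_half_construct_matches_mixture_oracle(self, model_clean):
        w = layer_weights("R2", model_clean)
        aortic_weight = w[:4].sum()  # top four layers are aortic in 11110000
        mix = (
            aortic_weight * model_clean.base_aorta
            + (1 - aortic_weight) * model_clean.base_myocardium
        )
        s = simulate_spectrum("11110000", "R2", model_clean, seed=3)
        amp = (210.0 / FIBER_DISTANCES_UM["R2"]) ** model_clean.attenuation_exponent
        np.testing.assert_allclose(s.intensities, model_clean.lamp * mix * amp, rtol=1e-9)

    def test_deterministic_and_validated(self, model_small):
        s1 = simulate_spectrum("11110000", "R4", model_small, rebuild_id=1, seed=9)
        s2 = simulate_spectrum("11110000", "R4", model_small, rebuild_id=1, seed=9)
        np.testing.assert_array_equal(s1.intensities, s2.intensities)
        with pytest.raises(ValueError):
            simulate_spectrum("1111000", "R4", model_small)
        with pytest.raises(ValueError):
            simulate_spectrum("11110000", "R7", model_small)
        with pytest.raises(ValueError):
            simulate_spectrum("11110000", "R4", model_small, exposure_ms=0)

    def test_exposure_scales_clean_signal(self, model_clean):
        s30 = simulate_spectrum("00000000", "R1", model_clean, exposure_ms=30)
        s10 = simulate_spectrum("00000000", "R1", model_clean, exposure_ms=10)
        np.testing.assert_allclose(s30.intensities, 3.0 * s10.intensities, rtol=1e-9)


class TestReferenceSpectrum:
    def test_noise_free_closed_form(self, model_clean):
        s = reference_spectrum(model_clean, exposure_ms=60.0)
        np.testing.assert_allclose(
            s.intensities, STANDARD_REFLECTANCE * model_clean.lamp * 2.0, rtol=1e-12
        )
        assert s.fiber_id == "standard"

    def test_calibration_removes_lamp_envelope(self, small_grid):
        # with flat tissue bases the calibrated tissue spectrum is flat
        flat = TissueOpticalModel(
            wavelengths=small_grid,
            base_myocardium=np.full(small_grid.size, 0.5),
            base_aorta=np.full(small_grid.size, 1.2),
        ).noise_free()
        tissue = mean_normalize(simulate_spectrum("00000000", "R1", flat))
        ref = mean_normalize(reference_spectrum(flat))
        out = calibrate(tissue, ref)
        np.testing.assert_allclose(out.intensities, 1.0, atol=1e-9)

    def test_snr_grows_with_exposure(self, model_small):
        def snr(exposure):
            reps = [
                reference_spectrum(model_small, exposure_ms=exposure, seed=5, spectrum_index=k)
                for k in range(100)
            ]
            return compute_snr(reps)

        assert snr(30.0) > snr(1.0)


class TestNoiseTrends:
    def _tissue_snr(self, model, fiber, exposure, n_rep=60):
        reps = [
            simulate_spectrum(
                "00000000", fiber, model, rebuild_id=0,
                exposure_ms=exposure, seed=17, spectrum_index=k,
            )
            for k in range(n_rep)
        ]
        return compute_snr(reps)

    def test_snr_decreases_with_fiber_distance(self, model_small):
        snrs = [self._tissue_snr(model_small, f, 30.0) for f in FIBER_DISTANCES_UM]
        assert all(a >= b for a, b in zip(snrs, snrs[1:]))

    def test_snr_increases_with_exposure(self, model_small):
        snrs = [self._tissue_snr(model_small, "R3", e) for e in (1.0, 10.0, 30.0, 50.0)]
        assert all(a <= b for a, b in zip(snrs, snrs[1:]))

    def test_r5_snr_near_instrument_working_point(self):
        # per native pixel (full 3587-sample grid) the default noise level
        # targets single-digit SNR at the most distal fiber at 30 ms
        native = TissueOpticalModel()
        snr = self._tissue_snr(native, "R5", 30.0, n_rep=60)
        assert 3.0 < snr < 20.0

    def test_reduced_grid_bins_noise_down(self, model_small, small_grid):
        # one 257-sample bin stands for ~14 native pixels, so the per-sample
        # SNR rises by the square root of the bin factor
        assert model_small.noise_bin_factor == pytest.approx(
            np.sqrt(3587 / small_grid.size), abs=1e-12
        )
        assert TissueOpticalModel().noise_bin_factor == 1.0


class TestSimulateStudy:
    @pytest.mark.parametrize("study,expected", [("volume", 1350), ("permuted", 900)])
    def test_protocol_spectrum_counts(self, study, expected, model_small):
        design = enumerate_study_classes(study)
        ds = simulate_study(design, model_small, seed=2)
        assert len(ds) == expected
        assert len(ds.manifest) == (
            design.n_classes * design.n_rebuilds * len(design.fibers)
            * design.spectra_per_fiber_per_rebuild
        )

    def test_same_seed_reproduces_dataset_exactly(self, model_small):
        design = enumerate_study_classes("binary", spectra_per_fiber_per_rebuild=2)
        a = simulate_study(design, model_small, seed=11)
        b = simulate_study(design, model_small, seed=11)
        assert a.manifest.equals(b.manifest)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        c = simulate_study(design, model_small, seed=12)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_reference_rows_appended(self, model_small):
        design = enumerate_study_classes("binary", spectra_per_fiber_per_rebuild=2)
        ds = simulate_study(design, model_small, seed=1, n_reference_spectra=5)
        assert (ds.manifest["role"] == "standard").sum() == 5


class TestIdentifiability:
    def test_noise_free_volume_classes_pairwise_distinct(self, model_clean):
        design = enumerate_study_classes("volume")
        for fiber in FIBER_DISTANCES_UM:
            specs = [
                mean_normalize(simulate_spectrum(c, fiber, model_clean)).intensities
                for c in design.classes
            ]
            for i in range(len(specs)):
                for j in range(i + 1, len(specs)):
                    assert np.max(np.abs(specs[i] - specs[j])) > 1e-6

    def test_nearest_centroid_classifies_noisy_binary_perfectly(self, model_small, model_clean):
        templates = {
            c: mean_normalize(simulate_spectrum(c, "R3", model_clean)).intensities
            for c in ("00000000", "11111111")
        }
        for truth in templates:
            for k in range(10):
                s = mean_normalize(
                    simulate_spectrum(truth, "R3", model_small, rebuild_id=k % 3,
                                      seed=23, spectrum_index=k)
                )
                dists = {
                    c: np.linalg.norm(s.intensities - t) for c, t in templates.items()
                }
                assert min(dists, key=dists.get) == truth

    def test_depth_information_gradient(self, model_clean):
        # proximal fiber R1 separates the shallow inset pair more than the
        # deep pair; the deep/shallow separation ratio improves for R5
        def sep(fiber, a, b):
            sa = mean_normalize(simulate_spectrum(a, fiber, model_clean)).intensities
            sb = mean_normalize(simulate_spectrum(b, fiber, model_clean)).intensities
            return np.linalg.norm(sa - sb)

        shallow_r1 = sep("R1", "11000000", "00110000")
        deep_r1 = sep("R1", "00001100", "00000011")
        shallow_r5 = sep("R5", "11000000", "00110000")
        deep_r5 = sep("R5", "00001100", "00000011")
        assert shallow_r1 > deep_r1
        assert deep_r5 / shallow_r5 > deep_r1 / shallow_r1
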