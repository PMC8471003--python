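"""Spectrum preprocessing: normalization, calibration, correlation, SNR,
smoothing, and fiber concatenation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fibrospec.spectra import (
    FeatureVector,
    Spectrum,
    calibrate,
    compute_snr,
    concatenate_fiber_spectra,
    default_grid,
    mean_normalize,
    pearson_correlation,
    smoothed_difference,
)


def make(intensities, wavelengths=None, **meta):
    y = np.asarray(intensities, dtype=float)
    wl = np.arange(y.size, dtype=float) if wavelengths is None else wavelengths
    return Spectrum(wavelengths=wl, intensities=y, **meta)


class TestSpectrum:
    def test_default_grid_spans_instrument_range(self):
        grid = default_grid()
        assert grid.size == 3587
        assert grid[0] == 500.0 and grid[-1] == 1100.0

    @pytest.mark.parametrize(
        "wl,y",
        [
            ([1.0], [1.0]),  # too short
            ([1.0, 1.0, 2.0], [1, 1, 1]),  # not strictly increasing
            ([1.0, 2.0], [1.0, -0.5]),  # negative intensity
            ([1.0, 2.0], [1.0, np.nan]),  # non-finite
            ([1.0, 2.0, 3.0], [1.0, 2.0]),  # length mismatch
        ],
    )
    def test_invalid_construction_rejected(self, wl, y):
        with pytest.raises(ValueError):
            Spectrum(wavelengths=np.array(wl, dtype=float), intensities=np.array(y, dtype=float))

    def test_metadata_validation(self):
        with pytest.raises(ValueError):
            make([1, 2], fiber_id="R9")
        with pytest.raises(ValueError):
            make([1, 2], exposure_ms=0)


class TestMeanNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [([2, 2, 2, 2], [1, 1, 1, 1]), ([1, 3], [0.5, 1.5])],
    )
    def test_examples(self, raw, expected):
        out = mean_normalize(make(raw))
        np.testing.assert_allclose(out.intensities, expected, atol=1e-12)

    def test_output_mean_is_one_and_idempotent(self):
        rng = np.random.default_rng(7)
        s = make(rng.uniform(0.1, 5.0, 200), fiber_id="R2", rebuild_id=1)
        n1 = mean_normalize(s)
        assert abs(np.mean(n1.intensities) - 1.0) <= 1e-9
        n2 = mean_normalize(n1)
        np.testing.assert_allclose(n1.intensities, n2.intensities, atol=1e-9)
        assert n1.fiber_id == "R2" and n1.rebuild_id == 1  # metadata preserved

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            mean_normalize(make([0.0, 0.0]))

    @settings(derandomize=True, max_examples=50)
    @given(
        y=arrays(np.float64, st.integers(2, 50),
                 elements=st.floats(0.01, 1e6)),
        scale=st.floats(1e-3, 1e3),
    )
    def test_normalization_is_scale_invariant(self, y, scale):
        a = mean_normalize(make(y)).intensities
        b = mean_normalize(make(scale * y)).intensities
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestCalibrate:
    def test_self_calibration_is_flat(self):
        rng = np.random.default_rng(0)
        s = mean_normalize(make(rng.uniform(0.5, 2.0, 64)))
        out = calibrate(s, s)
        np.testing.assert_allclose(out.intensities, 1.0, atol=1e-12)

    def test_hand_evaluated_ratio_then_renormalize(self):
        # ratios [2, 2/3] have mean 4/3; renormalized -> [1.5, 0.5]
        s = make([1.0, 1.0])
        ref = make([0.5, 1.5])
        out = calibrate(s, ref)
        np.testing.assert_allclose(out.intensities, [1.5, 0.5], atol=1e-12)

    def test_errors(self):
        s = make([1.0, 1.0])
        with pytest.raises(ValueError):  # zero in reference
            calibrate(s, make([0.0, 2.0]))
        with pytest.raises(ValueError):  # mismatched grid
            calibrate(s, make([1.0, 1.0], wavelengths=np.array([5.0, 6.0])))
        with pytest.raises(ValueError):  # not normalized
            calibrate(make([2.0, 4.0]), make([1.0, 1.0]))


def eq1_oracle(x, y):
    """Brute-force evaluation of the correlation formula."""
    xb, yb = np.mean(x), np.mean(y)
    num = np.sum((x - xb) * (y - yb))
    return num / np.sqrt(np.sum((x - xb) ** 2)) / np.sqrt(np.sum((y - yb) ** 2))


class TestPearsonCorrelation:
    def test_perfect_and_anti_correlation(self):
        wl = np.arange(5.0)
        x = make([1, 2, 3, 5, 8], wavelengths=wl)
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        neg = make(np.max(x.intensities) - x.intensities, wavelengths=wl)
        assert pearson_correlation(x, neg) == pytest.approx(-1.0)

    def test_matches_brute_force_formula_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 30)
            wl = np.arange(float(n))
            a, b = rng.normal(2.0, 1.0, n) ** 2, rng.normal(2.0, 1.0, n) ** 2
            got = pearson_correlation(make(a, wavelengths=wl), make(b, wavelengths=wl))
            assert got == pytest.approx(eq1_oracle(a, b), abs=1e-12)

    def test_affine_invariance_with_positive_slope(self):
        wl = np.arange(4.0)
        x = make([1.0, 2.0, 3.0, 1.0], wavelengths=wl)
        y = make([1.0, 2.0, 4.0, 2.0], wavelengths=wl)
        r = pearson_correlation(x, y)
        assert pearson_correlation(make(3.0 * x.intensities + 1.0, wavelengths=wl), y) == pytest.approx(r)

    def test_zero_variance_rejected(self):
        x = make([1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_correlation(x, make([1.0, 1.0]))


class TestComputeSnr:
    def test_monte_carlo_recovers_mean_over_sigma(self):
        rng = np.random.default_rng(3)
        m, sigma, n_rep, n_wl = 5.0, 0.5, 100, 40
        reps = [
            make(np.clip(m + rng.normal(0, sigma, n_wl), 0, None), fiber_id="R1")
            for _ in range(n_rep)
        ]
        assert compute_snr(reps) == pytest.approx(m / sigma, rel=0.10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        reps = [make(rng.uniform(1, 2, 30)) for _ in range(10)]
        scaled = [make(3.7 * r.intensities) for r in reps]
        assert compute_snr(scaled) == pytest.approx(compute_snr(reps), rel=1e-12)

    def test_identical_replicates_give_infinite_snr(self):
        s = make([1.0, 2.0, 3.0])
        assert compute_snr([s, s]) == np.inf

    def test_band_selection_and_errors(self):
        wl = np.linspace(500, 1100, 50)
        rng = np.random.default_rng(1)
        reps = [make(rng.uniform(1, 2, 50), wavelengths=wl) for _ in range(5)]
        assert compute_snr(reps, band_nm=(600, 900)) > 0
        with pytest.raises(ValueError):
            compute_snr(reps[:1])
        with pytest.raises(ValueError):
            compute_snr(reps, band_nm=(2000, 3000))


class TestSmoothedDifference:
    def test_self_difference_is_zero(self):
        rng = np.random.default_rng(11)
        group = [make(rng.uniform(0.5, 1.5, 100)) for _ in range(4)]
        mean_curve, _ = smoothed_difference(group, group)
        np.testing.assert_allclose(mean_curve, 0.0, atol=1e-12)

    def test_spike_smooths_to_gaussian_of_equal_area(self):
        n, h = 401, 2.5
        base = np.ones(n)
        spike = base.copy()
        spike[n // 2] += h
        mean_curve, _ = smoothed_difference([make(spike)], [make(base)], kernel_stddev_samples=20)
        assert mean_curve.size == n
        # kernel support well inside the grid -> total area preserved
        assert np.sum(mean_curve) == pytest.approx(h, rel=1e-6)
        # peak matches the Gaussian normalization h / (sigma sqrt(2 pi))
        assert mean_curve.max() == pytest.approx(h / (20 * np.sqrt(2 * np.pi)), rel=1e-3)

    def test_default_kernel_width_on_instrument_grid_is_3p3_nm(self):
        grid = default_grid()
        spacing = grid[1] - grid[0]
        assert 20 * spacing == pytest.approx(3.3, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            smoothed_difference([], [make([1.0, 2.0])])


class TestConcatenateFiberSpectra:
    def make_pair(self, n=10):
        wl = np.arange(float(n))
        rng = np.random.default_rng(2)
        mk = lambda f: mean_normalize(
            make(rng.uniform(0.5, 1.5, n), wavelengths=wl, fiber_id=f,
                 construct_label="11110000", rebuild_id=0)
        )
        return mk("R1"), mk("R5")

    def test_length_is_sum_and_order_canonical(self):
        s1, s5 = self.make_pair()
        fv = concatenate_fiber_spectra(s5, s1)  # reversed input order
        assert len(fv) == len(s1) + len(s5)
        assert fv.source_fibers == ("R1", "R5")
        np.testing.assert_array_equal(fv.values[: len(s1)], s1.intensities)
        assert fv.label == "11110000" and fv.rebuild_id == 0

    def test_default_grid_pair_has_length_7174(self):
        wl = default_grid()
        mk = lambda f: Spectrum(wl, np.ones(wl.size), fiber_id=f,
                                construct_label="11110000", rebuild_id=0)
        assert len(concatenate_fiber_spectra(mk("R1"), mk("R5"))) == 7174

    def test_precondition_errors(self):
        s1, s5 = self.make_pair()
        with pytest.raises(ValueError):  # same fiber twice
            concatenate_fiber_spectra(s1, s1)
        other = Spectrum(s5.wavelengths, s5.intensities, fiber_id="R5",
                         construct_label="11110000", rebuild_id=3)
        with pytest.raises(ValueError):  # mismatched rebuild
            concatenate_fiber_spectra(s1, other)

    def test_feature_vector_validation(self):
        with pytest.raises(ValueError):
            FeatureVector(values=np.ones(6), source_fibers=("R5", "R1"),
                          label=None, rebuild_id=None)
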