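import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from brixspec import (
    SGParams, SpectraSet, SynthConfig, black_white_correct, generate_spectra,
    mean_roi_spectrum, msc, sg_coefficients, sg_smooth, snv, split_train_test,
    trim_bands,
)
from brixspec.exceptions import (
    ConfigurationError, DegenerateDataError, DimensionError, EmptySelectionError,
)


def _spectra(matrix, wl=None, brix=None):
    matrix = np.atleast_2d(np.asarray(matrix, float))
    if wl is None:
        wl = np.arange(matrix.shape[1], dtype=float) + 400.0
    return SpectraSet(matrix, wl, brix=brix)


class TestBlackWhiteCorrect:
    def test_endpoints_and_midpoint(self):
        black = np.full((2, 2, 3), 0.1)
        white = np.full((2, 2, 3), 0.9)
        assert np.allclose(black_white_correct(black, black, white), 0.0)
        assert np.allclose(black_white_correct(white, black, white), 1.0)
        mid = np.full((2, 2, 3), 0.5)
        assert np.allclose(black_white_correct(mid, black, white), 0.5)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            black_white_correct(np.zeros((2, 2)), np.zeros((3, 2)), np.ones((2, 2)))

    def test_degenerate_calibration_names_index(self):
        black = np.zeros((2, 3))
        white = np.ones((2, 3))
        white[1, 2] = 0.0
        with pytest.raises(DegenerateDataError, match=r"\(1, 2\)"):
            black_white_correct(black, black, white)


class TestMeanRoiSpectrum:
    def test_uniform_single_and_two_pixel(self):
        cube = np.full((2, 2, 4), 0.7)
        mask = np.ones((2, 2), bool)
        assert np.allclose(mean_roi_spectrum(cube, mask), 0.7)
        cube[0, 0] = 0.2
        cube[0, 1] = 0.4
        two = np.zeros((2, 2), bool)
        two[0, :] = True
        assert np.allclose(mean_roi_spectrum(cube, two), 0.3)
        one = np.zeros((2, 2), bool)
        one[1, 0] = True
        assert np.allclose(mean_roi_spectrum(cube, one), cube[1, 0])

    def test_empty_mask(self):
        with pytest.raises(EmptySelectionError):
            mean_roi_spectrum(np.ones((2, 2, 3)), np.zeros((2, 2), bool))


class TestTrimBands:
    def test_closed_interval_boundaries(self):
        s = _spectra(np.ones((1, 3)), wl=[390.0, 400.0, 410.0])
        out = trim_bands(s, 400.0, 1000.0)
        assert out.wavelengths_nm.tolist() == [400.0, 410.0]

    def test_identity_when_bounds_cover_axis(self, random_spectra):
        out = trim_bands(random_spectra, 0.0, 2000.0)
        assert np.array_equal(out.wavelengths_nm, random_spectra.wavelengths_nm)

    def test_count_matches_bruteforce_on_instrument_axis(self):
        axis = np.linspace(387.0, 1034.0, 256)
        expected = sum(1 for wl in axis if 400.0 <= wl <= 1000.0)
        s = _spectra(np.ones((2, 256)), wl=axis)
        assert trim_bands(s, 400.0, 1000.0).n_bands == expected

    def test_idempotent(self, random_spectra):
        once = trim_bands(random_spectra, 450.0, 900.0)
        twice = trim_bands(once, 450.0, 900.0)
        assert np.array_equal(once.reflectance, twice.reflectance)

    def test_empty_selection(self, random_spectra):
        with pytest.raises(EmptySelectionError):
            trim_bands(random_spectra, 2000.0, 3000.0)


class TestSplit:
    def test_seven_three_split_of_168(self):
        s, _ = generate_spectra(SynthConfig(seed=0))
        split = split_train_test(s, 0.7, seed=0)
        assert len(split.train_indices) == 118
        assert len(split.test_indices) == 50

    def test_partition_covers_all_disjointly(self):
        s, _ = generate_spectra(SynthConfig(n_samples=31, seed=1))
        split = split_train_test(s, 0.7, seed=4)
        merged = np.sort(np.concatenate([split.train_indices, split.test_indices]))
        assert np.array_equal(merged, np.arange(31))

    def test_two_samples_half_ratio(self):
        s, _ = generate_spectra(SynthConfig(n_samples=2, seed=0))
        split = split_train_test(s, 0.5, seed=0)
        assert len(split.train_indices) == len(split.test_indices) == 1

    def test_same_seed_identical(self):
        s, _ = generate_spectra(SynthConfig(seed=0))
        a = split_train_test(s, 0.7, seed=9)
        b = split_train_test(s, 0.7, seed=9)
        assert np.array_equal(a.train_indices, b.train_indices)

    def test_bad_ratio(self, random_spectra):
        with pytest.raises(ConfigurationError):
            split_train_test(random_spectra, 1.5, seed=0)


class TestSGCoefficients:
    @pytest.mark.parametrize("window,order", [(5, 2), (7, 2), (7, 3), (11, 2), (11, 4)])
    def test_matches_independent_least_squares(self, window, order):
        # oracle 1: explicit normal-equations solve on the window design
        m = window // 2
        x = np.arange(-m, m + 1, dtype=float)
        X = np.vander(x, order + 1, increasing=True)
        oracle = (X @ np.linalg.inv(X.T @ X) @ X.T)[m]
        w = sg_coefficients(SGParams(window, order))
        np.testing.assert_allclose(w, oracle, atol=1e-10)
        # oracle 2: scipy's closed-form coefficients
        np.testing.assert_allclose(w, savgol_coeffs(window, order), atol=1e-10)

    def test_three_point_quadratic_is_identity(self):
        np.testing.assert_allclose(sg_coefficients(SGParams(3, 2)),
                                   [0.0, 1.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("window,order", [(5, 2), (9, 3), (15, 4)])
    def test_weights_sum_to_one_and_symmetric(self, window, order):
        w = sg_coefficients(SGParams(window, order))
        assert abs(w.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ConfigurationError):
            SGParams(window=4, polyorder=2)
        with pytest.raises(ConfigurationError):
            SGParams(window=5, polyorder=5)


class TestSGSmooth:
    def test_constant_unchanged(self):
        s = _spectra(np.full((2, 30), 0.6))
        out = sg_smooth(s, SGParams(7, 2))
        np.testing.assert_allclose(out.reflectance, 0.6, atol=1e-12)

    @pytest.mark.parametrize("edge_mode", ["truncate_fit", "reflect"])
    def test_polynomial_reproduced_on_interior(self, edge_mode):
        x = np.arange(40, dtype=float)
        row = 0.3 + 0.01 * x - 2e-4 * x**2
        out = sg_smooth(_spectra(row), SGParams(9, 2, edge_mode))
        np.testing.assert_allclose(out.reflectance[0, 4:-4], row[4:-4], atol=1e-10)

    def test_truncate_fit_reproduces_polynomial_at_edges_too(self):
        x = np.arange(40, dtype=float)
        row = 1.0 - 0.02 * x + 3e-4 * x**2
        out = sg_smooth(_spectra(row), SGParams(11, 2, "truncate_fit"))
        np.testing.assert_allclose(out.reflectance[0], row, atol=1e-10)

    def test_interior_matches_sliding_polyfit_oracle(self, rng):
        row = rng.random(50)
        window, order, m = 7, 3, 3
        out = sg_smooth(_spectra(row), SGParams(window, order))
        for i in range(m, 50 - m):
            fit = np.polynomial.polynomial.polyfit(
                np.arange(-m, m + 1, dtype=float), row[i - m:i + m + 1], order)
            assert abs(out.reflectance[0, i] - fit[0]) < 1e-10

    def test_linearity(self, rng):
        a, b = rng.random((2, 40))
        p = SGParams(9, 2)
        lhs = sg_smooth(_spectra(2.0 * a + 3.0 * b), p).reflectance
        rhs = (2.0 * sg_smooth(_spectra(a), p).reflectance
               + 3.0 * sg_smooth(_spectra(b), p).reflectance)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_window_exceeding_band_count(self):
        with pytest.raises(DimensionError):
            sg_smooth(_spectra(np.ones((1, 5))), SGParams(7, 2))


class TestSNV:
    def test_hand_example(self):
        out = snv(_spectra([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.reflectance[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_rows_standardised(self, random_spectra):
        out = snv(random_spectra).reflectance
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_idempotent(self, random_spectra):
        once = snv(random_spectra)
        np.testing.assert_allclose(snv(once).reflectance, once.reflectance,
                                   atol=1e-10)

    def test_constant_spectrum_names_sample(self):
        s = SpectraSet(np.vstack([np.ones(5), np.arange(5.0)]),
                       np.arange(5.0) + 400, sample_ids=["flat", "ok"])
        with pytest.raises(DegenerateDataError, match="flat"):
            snv(s)


class TestMSC:
    def test_identical_spectra_unchanged(self):
        row = np.linspace(0.2, 0.8, 25)
        s = _spectra(np.tile(row, (4, 1)))
        out, ref = msc(s)
        np.testing.assert_allclose(out.reflectance, s.reflectance, atol=1e-10)
        np.testing.assert_allclose(ref, row, atol=1e-12)

    def test_affine_distortion_inverted_exactly(self, rng):
        ref = np.sort(rng.random(30))
        rows = np.array([b1 * ref + b0
                         for b1, b0 in [(2.0, 1.0), (0.5, -0.2), (1.3, 0.05)]])
        out, _ = msc(_spectra(rows), reference=ref)
        for row in out.reflectance:
            np.testing.assert_allclose(row, ref, atol=1e-10)

    def test_reference_maps_to_itself(self, rng):
        ref = rng.random(20)
        out, _ = msc(_spectra(ref[None, :].repeat(2, axis=0) * [[1.0], [3.0]]),
                     reference=ref)
        np.testing.assert_allclose(out.reflectance[0], ref, atol=1e-10)

    def test_scatter_only_simulation_recovered(self):
        # with the Brix signal off, every clean spectrum equals the shared
        # baseline; MSC against that baseline must undo the per-sample affine
        # scatter to machine precision
        cfg = SynthConfig(n_samples=20, n_bands=50, signal_gain=0.0,
                          noise_sd=0.0, seed=11)
        s, t = generate_spectra(cfg)
        baseline = t.clean_reflectance[0]
        out, _ = msc(s, reference=baseline)
        np.testing.assert_allclose(
            out.reflectance, np.tile(baseline, (20, 1)), atol=1e-10)

    def test_degenerate_slope_rejected(self, rng):
        ref = np.linspace(0.0, 1.0, 20)
        flat = np.ones((1, 20)) * 0.5  # zero covariance with the reference
        with pytest.raises(DegenerateDataError):
            msc(_spectra(flat), reference=ref)
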