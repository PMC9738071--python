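"""Texture features: normalization, GLCM difference entropy, run lengths, CI."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from periocort import (
    EmptyRoiError,
    GlcmParams,
    InsufficientExtentError,
    NormalizedRoi,
    ParameterError,
    RadiographImage,
    RoiSizeWarning,
    UndefinedCIWarning,
    analyze_roi,
    corticalization_index,
    difference_entropy,
    directional_average,
    first_order_mean,
    glcm_difference_histogram,
    long_run_emphasis,
    normalize_and_quantize,
    quantize_value,
    run_length_matrix,
)
from _oracles import brute_diff_hist, brute_lre, brute_runs

from conftest import full_roi


def make_image(levels, bit_depth=8):
    return RadiographImage(np.asarray(levels, dtype=np.int64), bit_depth)


class TestQuantization:
    @pytest.mark.parametrize(
        "x,expected",
        [(70, 1), (100, 33), (135, 64), (69, 1), (130, 64), (128.5, 63)],
    )
    def test_window_mapping(self, x, expected):
        # mu = 100, sigma = 10 -> window [70, 130] over 64 levels
        assert quantize_value(x, 100.0, 10.0) == expected

    def test_constant_roi_is_degenerate(self):
        img = make_image(np.full((5, 5), 42))
        nroi = normalize_and_quantize(img, full_roi((5, 5)))
        assert nroi.degenerate
        assert np.all(nroi.masked_levels() == 1)

    def test_levels_match_scalar_formula(self, rng):
        img = make_image(rng.integers(0, 256, (20, 20)))
        roi = full_roi((20, 20))
        nroi = normalize_and_quantize(img, roi)
        vals = img.pixels[roi[:, 0], roi[:, 1]]
        mu, sigma = vals.mean(), vals.std()
        expected = [quantize_value(v, mu, sigma) for v in vals]
        np.testing.assert_array_equal(nroi.masked_levels(), expected)
        assert nroi.source_mu == pytest.approx(mu)
        assert nroi.source_sigma == pytest.approx(sigma)

    def test_empty_roi_rejected(self):
        img = make_image(np.zeros((5, 5)))
        with pytest.raises(EmptyRoiError):
            normalize_and_quantize(img, np.empty((0, 2), dtype=int))

    def test_ng_from_bits(self):
        img = make_image(np.arange(64).reshape(8, 8))
        nroi = normalize_and_quantize(img, full_roi((8, 8)), bits=4)
        assert nroi.ng == 16
        assert nroi.masked_levels().max() <= 16

    @given(
        a=st.integers(1, 17),
        b=st.integers(0, 900),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance_property(self, a, b, seed):
        """Integer rescaling x -> a*x + b leaves the levels bit-identical."""
        r = np.random.default_rng(seed)
        base = r.integers(0, 3000, (12, 12))
        roi = full_roi((12, 12))
        img1 = make_image(base, 16)
        img2 = make_image(a * base + b, 16)
        n1 = normalize_and_quantize(img1, roi)
        n2 = normalize_and_quantize(img2, roi)
        np.testing.assert_array_equal(n1.levels, n2.levels)


class TestFirstOrderMean:
    def test_spike_histogram(self):
        nroi = NormalizedRoi.from_levels(np.full((4, 4), 10), ng=64)
        assert first_order_mean(nroi) == 10.0

    def test_uniform_histogram(self):
        nroi = NormalizedRoi.from_levels(np.arange(1, 65).reshape(8, 8), ng=64)
        assert first_order_mean(nroi) == pytest.approx(32.5)

    def test_weighted_sum(self):
        levels = np.array([[1, 64, 64, 64]])
        nroi = NormalizedRoi.from_levels(levels, ng=64)
        # p = {1: 0.25, 64: 0.75} -> 48.25
        assert first_order_mean(nroi) == pytest.approx(48.25)


class TestDifferenceHistogram:
    def test_horizontal_pairs_of_two_band_image(self):
        nroi = NormalizedRoi.from_levels([[1, 1], [2, 2]], ng=4)
        dh = glcm_difference_histogram(nroi, (0, 1))
        assert dh.probs[0] == 1.0
        assert dh.pair_count == 4  # 2 ordered pairs per row

    def test_vertical_pairs_of_two_band_image(self):
        nroi = NormalizedRoi.from_levels([[1, 1], [2, 2]], ng=4)
        dh = glcm_difference_histogram(nroi, (1, 0))
        assert dh.probs[1] == 1.0
        assert dh.probs[0] == 0.0

    def test_offset_exceeding_extent(self):
        nroi = NormalizedRoi.from_levels(np.ones((3, 3), dtype=int), ng=4)
        with pytest.raises(InsufficientExtentError):
            glcm_difference_histogram(nroi, (0, 5))

    def test_probs_sum_to_one(self, rng):
        nroi = NormalizedRoi.from_levels(rng.integers(1, 65, (30, 30)), ng=64)
        for off in GlcmParams().directions:
            dh = glcm_difference_histogram(nroi, off)
            assert dh.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(dh.probs >= 0)


class TestDifferenceEntropy:
    def test_certain_distribution(self):
        nroi = NormalizedRoi.from_levels(np.ones((2, 4), dtype=int), ng=4)
        dh = glcm_difference_histogram(nroi, (0, 1))
        assert difference_entropy(dh) == 0.0

    def test_two_point_uniform(self):
        from periocort import DifferenceHistogram

        dh = DifferenceHistogram(probs=np.array([0.5, 0.5]), pair_count=4)
        assert difference_entropy(dh) == pytest.approx(math.log10(2), abs=1e-9)

    def test_four_point_uniform(self):
        from periocort import DifferenceHistogram

        dh = DifferenceHistogram(probs=np.full(4, 0.25), pair_count=8)
        assert difference_entropy(dh) == pytest.approx(math.log10(4), abs=1e-9)


class TestRunLengthMatrix:
    def test_row_runs(self):
        nroi = NormalizedRoi.from_levels([[5, 5, 5, 2]], ng=8)
        rlm = run_length_matrix(nroi, (0, 1))
        assert rlm.counts[4, 2] == 1  # level 5, length 3
        assert rlm.counts[1, 0] == 1  # level 2, length 1
        assert rlm.total_runs == 2

    def test_alternating_row(self):
        nroi = NormalizedRoi.from_levels([[1, 2, 1, 2]], ng=4)
        rlm = run_length_matrix(nroi, (0, 1))
        assert rlm.counts.shape[1] == 1
        assert rlm.total_runs == 4

    def test_single_pixel(self):
        nroi = NormalizedRoi.from_levels([[3]], ng=4)
        rlm = run_length_matrix(nroi, (0, 1))
        assert rlm.counts[2, 0] == 1
        assert rlm.total_runs == 1

    def test_offset_reduced_to_primitive_step(self):
        nroi = NormalizedRoi.from_levels([[5, 5, 5, 2]], ng=8)
        a = run_length_matrix(nroi, (0, 5))
        b = run_length_matrix(nroi, (0, 1))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_pixel_cover_identity(self, rng):
        """sum_k k * counts equals the number of ROI pixels, per direction."""
        mask = rng.random((15, 15)) < 0.7
        levels = rng.integers(1, 5, (15, 15)) * mask
        nroi = NormalizedRoi(levels=levels, mask=mask, ng=4)
        for off in ((0, 1), (-1, 1), (-1, 0), (-1, -1)):
            rlm = run_length_matrix(nroi, off)
            k = np.arange(1, rlm.counts.shape[1] + 1)
            assert (rlm.counts.sum(axis=0) * k).sum() == mask.sum()


class TestLongRunEmphasis:
    def test_mixed_runs(self):
        nroi = NormalizedRoi.from_levels([[5, 5, 5, 2]], ng=8)
        assert long_run_emphasis(run_length_matrix(nroi, (0, 1))) == 5.0

    def test_single_long_run(self):
        nroi = NormalizedRoi.from_levels([[7, 7, 7, 7]], ng=8)
        assert long_run_emphasis(run_length_matrix(nroi, (0, 1))) == 16.0

    def test_alternating_minimum(self):
        nroi = NormalizedRoi.from_levels([[1, 2, 1, 2]], ng=4)
        assert long_run_emphasis(run_length_matrix(nroi, (0, 1))) == 1.0


class TestAggregation:
    @pytest.mark.parametrize(
        "values,expected", [((1, 2, 3, 4), 2.5), ((7, 7, 7, 7), 7.0), ((0, 0, 0, 2), 0.5)]
    )
    def test_directional_average(self, values, expected):
        assert directional_average(values) == expected

    def test_directional_average_rejects_wrong_arity(self):
        with pytest.raises(ParameterError):
            directional_average((1.0, 2.0, 3.0))

    def test_directional_average_rejects_nonfinite(self):
        with pytest.raises(ParameterError):
            directional_average((1.0, float("inf"), 2.0, 3.0))

    def test_ci_arithmetic(self):
        assert corticalization_index(30.0, 10.0, 1.5) == pytest.approx(200.0)
        assert corticalization_index(32.5, 1.0, math.log10(4)) == pytest.approx(
            53.98, abs=0.005
        )

    def test_ci_undefined_on_zero_entropy(self):
        with pytest.warns(UndefinedCIWarning):
            assert math.isnan(corticalization_index(30.0, 10.0, 0.0))


class TestAnalyzeRoi:
    def test_constant_roi_flags_undefined_ci(self):
        img = make_image(np.full((40, 40), 99))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RoiSizeWarning)
            feats = analyze_roi(img, full_roi((40, 40)))
        assert feats.degenerate
        assert feats.difentr_avg == 0.0
        assert math.isnan(feats.ci)
        assert not feats.ci_defined

    def test_checkerboard_matches_enumeration_oracle(self):
        """12x12 period-1 checkerboard, d = 5, against the brute oracles."""
        board = (np.indices((12, 12)).sum(axis=0) % 2) * 200 + 20
        img = make_image(board)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RoiSizeWarning)
            feats = analyze_roi(img, full_roi((12, 12)))
            nroi = normalize_and_quantize(img, full_roi((12, 12)))
        mask = [[True] * 12] * 12
        lv = nroi.levels.tolist()
        params = GlcmParams()
        for i, off in enumerate(params.directions):
            probs, _ = brute_diff_hist(lv, mask, off, 64)
            expected_de = -sum(p * math.log10(p) for p in probs.values())
            assert feats.difentr_dir[i] == pytest.approx(expected_de, abs=1e-12)
        for i, off in enumerate(params.run_directions()):
            runs = brute_runs(lv, mask, off)
            assert feats.lngremph_dir[i] == pytest.approx(brute_lre(runs), abs=1e-12)
        if feats.difentr_avg > 0:
            assert feats.ci == pytest.approx(
                feats.mean_od * feats.lngremph_avg / feats.difentr_avg
            )
        else:  # two-level periodic pattern: every difference is certain
            assert math.isnan(feats.ci)

    def test_averages_are_arithmetic_means(self, random_image):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RoiSizeWarning)
            feats = analyze_roi(random_image, full_roi(random_image.shape))
        assert feats.difentr_avg == pytest.approx(np.mean(feats.difentr_dir))
        assert feats.lngremph_avg == pytest.approx(np.mean(feats.lngremph_dir))

    def test_feature_bounds(self, rng):
        """1 <= mean_od <= Ng; 0 <= DifEntr <= log10 Ng; LngREmph >= 1; CI >= 0."""
        for trial in range(5):
            img = make_image(rng.integers(0, 256, (25, 25)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RoiSizeWarning)
                feats = analyze_roi(img, full_roi((25, 25)))
            assert 1.0 <= feats.mean_od <= 64.0
            assert 0.0 <= feats.difentr_avg <= math.log10(64)
            assert feats.lngremph_avg >= 1.0
            assert feats.ci >= 0.0

    def test_mean_on_raw_option(self, random_image):
        roi = full_roi(random_image.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RoiSizeWarning)
            feats = analyze_roi(random_image, roi, mean_on_raw=True)
        raw_mean = random_image.pixels[roi[:, 0], roi[:, 1]].mean()
        assert feats.mean_od == pytest.approx(raw_mean)


@st.composite
def small_masked_image(draw):
    h = draw(st.integers(2, 6))
    w = draw(st.integers(2, 6))
    levels = draw(
        st.lists(
            st.lists(st.integers(1, 4), min_size=w, max_size=w), min_size=h, max_size=h
        )
    )
    mask = draw(
        st.lists(
            st.lists(st.booleans(), min_size=w, max_size=w), min_size=h, max_size=h
        )
    )
    return levels, mask


class TestOracleEquivalence:
    """Vectorized GLCM/RLM vs brute-force enumerators on random small images."""

    @given(data=small_masked_image(), direction=st.sampled_from([(0, 1), (-1, 1), (-1, 0), (-1, -1)]))
    @settings(max_examples=150, deadline=None)
    def test_random_masked_images(self, data, direction):
        levels, mask = data
        mask_arr = np.array(mask, dtype=bool)
        lv_arr = np.array(levels) * mask_arr
        nroi = NormalizedRoi(levels=lv_arr, mask=mask_arr, ng=4)

        probs, pairs = brute_diff_hist(levels, mask, direction, 4)
        if pairs == 0:
            with pytest.raises((InsufficientExtentError, EmptyRoiError)):
                glcm_difference_histogram(nroi, direction)
        else:
            dh = glcm_difference_histogram(nroi, direction)
            assert dh.pair_count == pairs
            for k in range(4):
                assert dh.probs[k] == pytest.approx(probs.get(k, 0.0), abs=1e-12)

        runs = brute_runs(levels, mask, direction)
        if mask_arr.any():
            rlm = run_length_matrix(nroi, direction)
            got = {
                (i + 1, k + 1): int(rlm.counts[i, k])
                for i in range(rlm.counts.shape[0])
                for k in range(rlm.counts.shape[1])
                if rlm.counts[i, k]
            }
            assert got == runs
        else:
            with pytest.raises(EmptyRoiError):
                run_length_matrix(nroi, direction)
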