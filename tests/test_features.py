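"""Texture and geometry feature correctness: hand examples, brute-force
oracle equivalence and symmetry properties."""

import numpy as np
import pytest

from lvradiomics.errors import DataError
from lvradiomics.features import (
    ar_features,
    default_manifest,
    extract_all,
    geometry_features,
    glcm,
    glcm_features,
    gradient_features,
    histogram_features,
    rlm_features,
    wavelet_features,
)
from lvradiomics.features.manifest import RLM_DIRECTIONS

from conftest import random_level_image
from oracles import (
    brute_ar_stats,
    brute_glcm,
    brute_glcm_stats,
    brute_gradient_stats,
    brute_histogram_stats,
    brute_rlm_stats,
    brute_wavelet_stats,
)


class TestManifest:
    def test_total_and_family_counts(self):
        m = default_manifest()
        assert len(m) == 377
        assert m.family_counts() == {
            "histogram": 9, "gradient": 5, "cooccurrence": 220,
            "runlength": 20, "ar_model": 5, "wavelet": 20, "geometry": 98,
        }
        assert len(set(m.names)) == 377  # unique names

    def test_named_features_present(self):
        names = set(default_manifest().names)
        for expected in ("S(1,0)DifEntrp", "S(5,-5)DifEntrp", "Horzl_RLNonUni",
                         "135dr_RLNonUni", "GrNonZeros", "WavEnLH_s-4",
                         "GeoF", "GeoEl", "GeoW12", "GeoW5b", "GeoSxL"):
            assert expected in names


class TestGLCM:
    def test_hand_example_counts(self):
        levels = np.array([[1, 1, 2], [1, 2, 2]])
        P = glcm(levels, np.ones((2, 3), bool), (1, 0))
        assert P.shape == (2, 2)
        assert np.allclose(P, [[0.25, 0.25], [0.25, 0.25]])
        assert np.isclose(P.sum(), 1.0)

    def test_difference_entropy_hand_value(self):
        levels = np.array([[1, 1, 2], [1, 2, 2]])
        stats = glcm_features(glcm(levels, np.ones((2, 3), bool), (1, 0)))
        # p_{x-y}: diff 0 -> 0.5, diff 1 -> 0.5 -> DifEntrp = ln 2
        assert np.isclose(stats["DifEntrp"], np.log(2.0))

    def test_constant_roi(self):
        levels = np.full((4, 4), 3)
        stats = glcm_features(glcm(levels, np.ones((4, 4), bool), (1, 0)))
        assert stats["Entropy"] == 0.0
        assert stats["DifEntrp"] == 0.0
        assert stats["AngScMom"] == 1.0

    def test_checkerboard_contrast(self):
        levels = 1 + (np.indices((6, 6)).sum(axis=0) % 2)
        stats = glcm_features(glcm(levels, np.ones((6, 6), bool), (1, 0)))
        assert np.isclose(stats["Contrast"], 1.0)

    def test_pairs_crossing_mask_discarded(self):
        levels = np.array([[1, 9, 2]])
        mask = np.array([[True, False, True]])
        with pytest.raises(DataError):
            glcm(levels, mask, (1, 0))  # no adjacent in-mask pair

    def test_normalization_sums_to_one(self, rng):
        for _ in range(10):
            levels, mask = random_level_image(rng)
            P = glcm(levels, mask, (1, 1))
            assert np.isclose(P.sum(), 1.0)
            assert np.allclose(P, P.T)


class TestRLM:
    def test_single_row_hand_example(self):
        levels = np.array([[1, 1, 2, 2, 2]])
        stats = rlm_features(levels, np.ones((1, 5), bool), (0, 1))
        # runs {(1, len 2), (2, len 3)}
        assert np.isclose(stats["RLNonUni"], 1.0)
        assert np.isclose(stats["GLevNonU"], 1.0)
        assert np.isclose(stats["Fraction"], 2 / 5)

    def test_constant_row(self):
        n = 7
        stats = rlm_features(np.ones((1, n), int), np.ones((1, n), bool), (0, 1))
        assert np.isclose(stats["RLNonUni"], 1.0)
        assert np.isclose(stats["LngREmph"], n**2)

    def test_transpose_swaps_horizontal_vertical(self, rng):
        levels, mask = random_level_image(rng)
        h = rlm_features(levels, mask, RLM_DIRECTIONS["Horzl"])
        v_t = rlm_features(levels.T, mask.T, RLM_DIRECTIONS["Vertl"])
        for k in h:
            assert np.isclose(h[k], v_t[k])

    def test_rot90_permutes_diagonals(self, rng):
        levels, mask = random_level_image(rng)
        d45 = rlm_features(levels, mask, RLM_DIRECTIONS["45dgr"])
        rot_l, rot_m = np.rot90(levels), np.rot90(mask)
        d135 = rlm_features(rot_l, rot_m, RLM_DIRECTIONS["135dr"])
        for k in d45:
            assert np.isclose(d45[k], d135[k])

    def test_mask_gap_truncates_runs(self):
        levels = np.array([[1, 1, 1, 1, 1]])
        mask = np.array([[True, True, False, True, True]])
        stats = rlm_features(levels, mask, (0, 1))
        # two runs of length 2, not one of length 5
        assert np.isclose(stats["LngREmph"], 4.0)
        assert np.isclose(stats["Fraction"], 2 / 4)


class TestHistogram:
    def test_hand_example(self):
        levels = np.array([[1, 2], [3, 4]])
        stats = histogram_features(levels, np.ones((2, 2), bool))
        assert stats["Mean"] == 2.5
        assert stats["Variance"] == 1.25

    def test_constant_roi(self):
        stats = histogram_features(np.full((3, 3), 5), np.ones((3, 3), bool))
        assert stats["Variance"] == 0.0 and stats["Skewness"] == 0.0

    def test_median_nearest_rank(self):
        stats = histogram_features(np.array([[1, 1, 2, 2]]), np.ones((1, 4), bool))
        assert stats["Perc50"] == 1  # nearest rank: ceil(0.5 * 4) = 2nd value


class TestGradient:
    def test_constant_roi_has_zero_nonzeros(self):
        stats = gradient_features(np.full((6, 6), 9), np.ones((6, 6), bool))
        assert stats["GrNonZeros"] == 0.0

    def test_horizontal_ramp(self):
        levels = np.tile(np.arange(8), (8, 1))
        stats = gradient_features(levels, np.ones((8, 8), bool))
        assert stats["GrNonZeros"] == 1.0
        assert np.isclose(stats["GrVariance"], 0.0)
        assert np.isclose(stats["GrMean"], 1.0)

    def test_no_interior_pixels_flagged_missing(self):
        mask = np.zeros((5, 5), bool)
        mask[0, :] = True  # a line has no 4-neighbor interior
        stats = gradient_features(np.ones((5, 5)), mask)
        assert all(np.isnan(v) for v in stats.values())


class TestAR:
    def test_left_copy_process(self):
        rng = np.random.default_rng(5)
        # each pixel equals its left neighbor: rows are constant
        levels = np.tile(rng.normal(0, 1, (30, 1)), (1, 30))
        stats = ar_features(levels, np.ones((30, 30), bool))
        assert np.isclose(stats["Teta1"], 1.0, atol=1e-8)
        assert abs(stats["Teta2"]) < 1e-8 and abs(stats["Teta3"]) < 1e-8
        assert stats["Sigma"] < 1e-10

    def test_white_noise_thetas_near_zero(self):
        rng = np.random.default_rng(11)
        hits = []
        for _ in range(20):
            levels = rng.normal(0, 1, (50, 50))
            stats = ar_features(levels, np.ones((50, 50), bool))
            hits.append(max(abs(stats[f"Teta{k}"]) for k in range(1, 5)))
        assert np.mean(np.array(hits) < 0.1) >= 0.95

    def test_insufficient_support_flagged(self):
        stats = ar_features(np.ones((4, 4)), np.ones((4, 4), bool), min_support=20)
        assert np.isnan(stats["Teta1"])


class TestWavelet:
    def test_constant_roi_zero_detail(self):
        stats = wavelet_features(np.full((32, 32), 7.0), np.ones((32, 32), bool))
        for s in (1, 2, 3):
            assert np.isclose(stats[f"WavEnLH_s-{s}"], 0.0)
            assert np.isclose(stats[f"WavEnHL_s-{s}"], 0.0)
            assert np.isclose(stats[f"WavEnHH_s-{s}"], 0.0)

    def test_horizontal_stripes_respond_in_lh(self):
        levels = np.tile(np.array([[1.0], [3.0]]), (8, 16))  # rows alternate
        stats = wavelet_features(levels, np.ones((16, 16), bool))
        assert stats["WavEnLH_s-1"] > 0
        assert np.isclose(stats["WavEnHL_s-1"], 0.0)
        assert np.isclose(stats["WavEnHH_s-1"], 0.0)

    def test_quadratic_scaling(self, rng):
        levels = rng.normal(10, 2, (16, 16))
        mask = np.ones((16, 16), bool)
        s1 = wavelet_features(levels, mask)
        s2 = wavelet_features(2.0 * levels, mask)
        for k, v in s1.items():
            if not np.isnan(v):
                assert np.isclose(s2[k], 4.0 * v)

    def test_small_roi_scales_flagged_missing(self):
        stats = wavelet_features(np.ones((4, 4)), np.ones((4, 4), bool))
        assert np.isnan(stats["WavEnLL_s-5"])


class TestGeometry:
    def test_filled_square(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        g = geometry_features(mask)
        assert g["GeoF"] == 100
        assert np.isclose(g["GeoEl"], 1.0)

    def test_rectangle_elongation_exact(self):
        mask = np.zeros((50, 50), bool)
        mask[5:15, 5:45] = True  # 10 x 40
        g = geometry_features(mask)
        assert np.isclose(g["GeoEl"], 4.0)
        assert g["GeoSxL"] == 40 and g["GeoSyL"] == 10

    def test_rotation_invariance_of_area(self):
        mask = np.zeros((30, 30), bool)
        mask[4:14, 8:26] = True
        g0 = geometry_features(mask)
        g90 = geometry_features(np.rot90(mask))
        assert g0["GeoF"] == g90["GeoF"]
        assert np.isclose(g0["GeoEl"], g90["GeoEl"])
        assert np.isclose(g0["GeoEqDiam"], g90["GeoEqDiam"])

    def test_translation_invariance(self):
        mask = np.zeros((40, 40), bool)
        mask[3:13, 4:20] = True
        g1 = geometry_features(mask)
        g2 = geometry_features(np.roll(np.roll(mask, 11, axis=0), 9, axis=1))
        for k in ("GeoF", "GeoPerim", "GeoEl", "GeoCompact", "GeoEqDiam",
                  "GeoHu1", "GeoRadMean"):
            assert np.isclose(g1[k], g2[k]), k


class TestOracleEquivalence:
    """All texture statistics match independent brute-force implementations
    on random small multi-level images (the core correctness guarantee)."""

    N_TRIALS = 40  # per family here; the acceptance suite runs 200

    def test_glcm_against_brute_force(self, rng):
        for t in range(self.N_TRIALS):
            levels, mask = random_level_image(rng)
            offset = [(1, 0), (0, 1), (1, 1), (1, -1), (2, 0)][t % 5]
            try:
                P = glcm(levels, mask, offset)
            except DataError:
                continue
            assert np.allclose(P, brute_glcm(levels, mask, offset), atol=1e-12)
            mine = glcm_features(P)
            ref = brute_glcm_stats(P)
            for k, v in ref.items():
                assert np.isclose(mine[k], v, atol=1e-9), k

    def test_rlm_against_brute_force(self, rng):
        dirs = list(RLM_DIRECTIONS.values())
        for t in range(self.N_TRIALS):
            levels, mask = random_level_image(rng)
            step = dirs[t % 4]
            mine = rlm_features(levels, mask, step)
            ref = brute_rlm_stats(levels, mask, step)
            for k, v in ref.items():
                assert np.isclose(mine[k], v, atol=1e-9), k

    def test_histogram_against_brute_force(self, rng):
        for _ in range(self.N_TRIALS):
            levels, mask = random_level_image(rng)
            mine = histogram_features(levels, mask)
            ref = brute_histogram_stats(levels[mask])
            for k, v in ref.items():
                assert np.isclose(mine[k], v, atol=1e-9), k

    def test_gradient_against_brute_force(self, rng):
        for _ in range(self.N_TRIALS):
            levels, mask = random_level_image(rng)
            mine = gradient_features(levels, mask)
            ref = brute_gradient_stats(levels, mask)
            for k, v in ref.items():
                if np.isnan(v):
                    assert np.isnan(mine[k])
                else:
                    assert np.isclose(mine[k], v, atol=1e-9), k

    def test_ar_against_normal_equations(self, rng):
        for _ in range(self.N_TRIALS):
            levels = rng.normal(50, 10, (12, 12))
            mask = rng.random((12, 12)) < 0.95
            mine = ar_features(levels, mask)
            ref = brute_ar_stats(levels, mask)
            for k, v in ref.items():
                if np.isnan(v):
                    assert np.isnan(mine[k])
                else:
                    assert np.isclose(mine[k], v, atol=1e-8), k

    def test_wavelet_against_direct_haar(self, rng):
        for _ in range(self.N_TRIALS):
            levels, mask = random_level_image(rng, size=16, ng=8)
            mine = wavelet_features(levels, mask)
            ref = brute_wavelet_stats(levels, mask)
            for k, v in ref.items():
                if np.isnan(v):
                    assert np.isnan(mine[k])
                else:
                    assert np.isclose(mine[k], v, atol=1e-9), k


class TestExtractAll:
    def test_full_vector_length_and_determinism(self, tiny_cohort):
        img, roi, _ = tiny_cohort[0]
        v1 = extract_all(img, roi)
        v2 = extract_all(img, roi)
        assert len(v1) == 377
        assert v1.equals(v2)

    def test_affine_gray_change_leaves_quantized_families_unchanged(self, tiny_cohort):
        from lvradiomics.imaging import GrayImage
        img, roi, _ = tiny_cohort[1]
        v1 = extract_all(img, roi)
        v2 = extract_all(GrayImage(img.pixels * 3, bit_depth=18), roi)
        for name in v1.index:
            if name.startswith(("S(", "Horzl", "Vertl", "45dgr", "135dr", "Geo")):
                assert np.isclose(v1[name], v2[name]), name
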