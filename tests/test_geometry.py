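"""Downscaling, rotation search, Otsu, contour landmarks, opening, centroid."""
import numpy as np
import pytest
from scipy import ndimage

from handspec import geometry as G
from handspec.phantom import generate_hand_mask


class TestDownscale:
    def test_paper_frame_dimensions(self):
        out = G.downscale(np.zeros((899, 1312)), 0.1)
        assert out.shape == (90, 131)

    def test_factor_one_is_identity(self, rng):
        x = rng.random((13, 9))
        np.testing.assert_array_equal(G.downscale(x, 1.0), x)

    def test_matches_nearest_source_index_oracle(self, rng):
        x = rng.random((4, 4))
        out = G.downscale(x, 0.5)
        assert out.shape == (2, 2)
        for i in range(2):
            for j in range(2):
                assert out[i, j] == x[int(i / 0.5), int(j / 0.5)]

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            G.downscale(np.zeros((4, 4)), 0.0)
        with pytest.raises(ValueError):
            G.downscale(np.zeros((4, 4)), 1.5)


class TestEstimateRotation:
    def test_vertical_bar_returns_grid_value_closest_to_zero(self):
        img = np.zeros((41, 41))
        img[5:36, 20] = 1.0
        res = G.estimate_rotation(img, step_deg=1.0)
        assert res.alpha_deg == 1.0  # 0 is outside the open (0, 180) grid

    def test_score_equals_independent_scorer(self, rng):
        """The exhaustive search must reproduce an independently coded
        rotate-and-project scorer on the same grid."""
        img = rng.random((12, 15))
        res = G.estimate_rotation(img, step_deg=10.0)
        angles = np.arange(10.0, 180.0, 10.0)
        scores = []
        for a in angles:
            rot = ndimage.rotate(
                img, a, axes=(1, 0), reshape=False, order=0, mode="constant", cval=0.0
            )
            scores.append(rot.sum(axis=0).max())
        assert res.score == pytest.approx(max(scores))
        assert res.alpha_deg == angles[int(np.argmax(scores))]
        np.testing.assert_allclose(res.scores, scores)

    def test_empty_or_zero_image_rejected(self):
        with pytest.raises(ValueError):
            G.estimate_rotation(np.zeros((0, 3)))
        with pytest.raises(ValueError):
            G.estimate_rotation(np.zeros((5, 5)))


class TestOtsu:
    def test_two_valued_image_threshold_between_modes(self):
        img = np.array([[0.1] * 8 + [0.9] * 8]).reshape(4, 4)
        t = G.otsu_threshold(img)
        assert 0.1 < t < 0.9

    def test_matches_brute_force_variance_cut(self, rng):
        x = rng.random(300)
        t = G.otsu_threshold(x)
        hist, edges = np.histogram((x - x.min()) / np.ptp(x), bins=256, range=(0, 1))
        centers = (edges[:-1] + edges[1:]) / 2
        best_var, best_k = -1.0, None
        for k in range(255):
            w0, w1 = hist[: k + 1].sum(), hist[k + 1 :].sum()
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
            mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / w1
            var = w0 * w1 * (mu0 - mu1) ** 2
            if var > best_var:
                best_var, best_k = var, k
        expected = x.min() + edges[best_k + 1] * np.ptp(x)
        assert t == pytest.approx(expected)

    def test_shift_equivariance(self, rng):
        x = rng.random((8, 8))
        assert G.otsu_threshold(x + 5.0) == pytest.approx(G.otsu_threshold(x) + 5.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            G.otsu_threshold(np.full((4, 4), 1.0))


class TestBinarize:
    def test_all_above_gives_ones(self):
        np.testing.assert_array_equal(
            G.binarize(np.full((3, 3), 2.0), 1.0), np.ones((3, 3), np.uint8)
        )

    def test_equality_maps_to_zero(self):
        assert G.binarize(np.array([[0.5]]), 0.5)[0, 0] == 0

    def test_count_matches_counting_oracle(self, rng):
        x = rng.random((20, 20))
        t = 0.4
        assert G.binarize(x, t).sum() == int((x > t).sum())


class TestContourCurve:
    def test_full_frame_mask_gives_zeros(self):
        np.testing.assert_array_equal(
            G.contour_curve(np.ones((5, 7), np.uint8)), np.zeros(7, int)
        )

    def test_single_pixel(self):
        mask = np.zeros((10, 6), np.uint8)
        mask[7, 3] = 1
        curve = G.contour_curve(mask)
        assert curve[3] == 7
        assert all(curve[c] == G.CONTOUR_SENTINEL for c in range(6) if c != 3)

    def test_matches_linear_scan_oracle(self, rng):
        mask = (rng.random((15, 12)) < 0.3).astype(np.uint8)
        mask[0, 0] = 1  # ensure non-empty
        curve = G.contour_curve(mask)
        for n in range(12):
            rows = [m for m in range(15) if mask[m, n]]
            assert curve[n] == (rows[0] if rows else G.CONTOUR_SENTINEL)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            G.contour_curve(np.zeros((4, 4), np.uint8))


class TestTipLandmarks:
    def test_comb_profile_yields_tooth_minima(self):
        """Four teeth protruding from a flat baseline are the 4 fingertips."""
        curve = np.full(60, 40.0)
        teeth = [8, 22, 36, 50]
        for i, c in enumerate(teeth):
            curve[c] = 10.0 + i
        lm = G.find_tip_landmarks(curve, min_separation=5, min_prominence=5)
        assert lm.visible[:4].all() and not lm.visible[4]
        np.testing.assert_array_equal(lm.cols[:4], teeth)
        np.testing.assert_allclose(lm.rows[:4], [10.0, 11.0, 12.0, 13.0])

    def test_matches_exhaustive_local_minimum_scan(self, rng):
        """With no prominence/separation constraints the detected minima
        are exactly the points lower than both neighbours."""
        curve = np.round(rng.random(40) * 100)
        curve += np.linspace(0, 0.01, 40)  # break ties -> strict extrema
        peaks, _ = G.contour_minima(curve, min_separation=1, min_prominence=1e-9)
        expected = [
            i
            for i in range(1, 39)
            if curve[i] < curve[i - 1] and curve[i] < curve[i + 1]
        ]
        assert peaks.tolist() == expected

    def test_phantom_noiseless_tips_within_two_working_pixels(self, noiseless_spec):
        mask, truth = generate_hand_mask(noiseless_spec)
        work = G.downscale(mask.astype(float), 0.5)
        curve = G.contour_curve(G.binarize(work, 0.5))
        lm = G.find_tip_landmarks(curve, min_separation=3, min_prominence=3)
        assert lm.visible[:5].all()
        tr = (truth.landmarks.rows[:5] + 0.5) * 0.5 - 0.5
        tc = (truth.landmarks.cols[:5] + 0.5) * 0.5 - 0.5
        err = np.hypot(lm.rows[:5] - tr, lm.cols[:5] - tc)
        assert err.max() <= 2.0

    def test_no_minima_is_error(self):
        with pytest.raises(ValueError, match="landmark"):
            G.find_tip_landmarks(np.arange(20.0), min_separation=1, min_prominence=50)


def _brute_opening(mask, se):
    h = se // 2
    m, n = mask.shape
    pad = np.zeros((m + 2 * h, n + 2 * h), mask.dtype)
    pad[h : h + m, h : h + n] = mask
    eroded = np.zeros_like(mask)
    for i in range(m):
        for j in range(n):
            eroded[i, j] = pad[i : i + se, j : j + se].min()
    padE = np.zeros_like(pad)
    padE[h : h + m, h : h + n] = eroded
    out = np.zeros_like(mask)
    for i in range(m):
        for j in range(n):
            out[i, j] = padE[i : i + se, j : j + se].max()
    return out


class TestOpening:
    def test_matches_min_max_sliding_window_oracle(self, rng):
        mask = (rng.random((64, 64)) < 0.6).astype(np.uint8)
        mask[20:50, 10:40] = 1  # a block the 21-px element can survive
        np.testing.assert_array_equal(G.opening(mask, 21), _brute_opening(mask, 21))

    def test_thin_structure_annihilated(self):
        mask = np.zeros((40, 40), np.uint8)
        mask[5:35, 18:23] = 1  # 5 px wide, thinner than the element
        assert G.opening(mask, 7).sum() == 0

    def test_idempotent(self, rng):
        mask = (rng.random((30, 30)) < 0.5).astype(np.uint8)
        once = G.opening(mask, 5)
        np.testing.assert_array_equal(G.opening(once, 5), once)

    def test_oversized_element_rejected(self):
        with pytest.raises(ValueError):
            G.opening(np.ones((10, 10), np.uint8), 11)
        with pytest.raises(ValueError):
            G.opening(np.ones((10, 10), np.uint8), 4)


class TestWristCentroid:
    def test_centred_block_gives_centre(self):
        mask = np.zeros((9, 9))
        mask[3:6, 3:6] = 1
        assert G.wrist_centroid(mask) == (4.0, 4.0)

    def test_translation_equivariance(self, rng):
        mask = np.zeros((20, 20))
        mask[2:7, 3:9] = rng.random((5, 6)) + 0.5
        m0, n0 = G.wrist_centroid(mask)
        shifted = np.roll(np.roll(mask, 4, axis=0), 5, axis=1)
        m1, n1 = G.wrist_centroid(shifted)
        assert (m1 - m0, n1 - n0) == pytest.approx((4.0, 5.0))

    def test_matches_literal_formula_oracle(self, rng):
        w = rng.random((7, 8))
        m, n = G.wrist_centroid(w)
        num_m = num_n = den = 0.0
        for i in range(7):
            for j in range(8):
                num_m += w[i, j] * i
                num_n += w[i, j] * j
                den += w[i, j]
        assert (m, n) == pytest.approx((num_m / den, num_n / den))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            G.wrist_centroid(np.zeros((4, 4)))
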