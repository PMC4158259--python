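"""Affine estimation, algebra, warping and the NCC/SSD scores."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import endograph as eg
from endograph import transforms as tf
from endograph.exceptions import (
    DegenerateGeometryError,
    InsufficientCorrespondencesError,
    InsufficientOverlapError,
    InvalidInputError,
)
from endograph.features import FeatureSet, Keypoint, MatchSet
from conftest import random_affine


def _corr(points):
    pts = np.asarray(points, dtype=float)
    kps = [Keypoint(float(x), float(y), 1.5, 0.0) for x, y in pts]
    return FeatureSet(kps, np.zeros((len(kps), 32)))


@st.composite
def affines(draw):
    seed = draw(st.integers(0, 10_000))
    return random_affine(np.random.default_rng(seed))


class TestAffineType:
    def test_last_row_fixed(self):
        m = np.eye(3)
        m[2] = (5, 5, 5)
        t = eg.AffineTransform(m)
        assert tuple(t.matrix[2]) == (0.0, 0.0, 1.0)

    def test_singular_rejected(self):
        m = np.eye(3)
        m[0, 0] = 0.0
        m[0, 1] = 0.0
        with pytest.raises(DegenerateGeometryError):
            eg.AffineTransform(m)

    def test_serialization_roundtrip(self):
        t = random_affine(np.random.default_rng(4))
        back = eg.AffineTransform.from_list(t.to_list())
        assert np.array_equal(back.matrix, t.matrix)


class TestInvertCompose:
    def test_identity_inverts_to_identity(self):
        assert tf.invert(tf.identity_transform()).almost_equal(tf.identity_transform())

    def test_translation_inverts_to_negative(self):
        assert tf.invert(tf.translation(3, -4)).almost_equal(tf.translation(-3, 4))

    def test_unit_translations_compose(self):
        t = tf.compose([tf.translation(1, 0), tf.translation(0, 1)])
        assert t.almost_equal(tf.translation(1, 1))

    def test_empty_chain_rejected(self):
        with pytest.raises(InvalidInputError):
            tf.compose([])

    def test_single_element_chain(self):
        t = random_affine(np.random.default_rng(7))
        assert tf.compose([t]).almost_equal(t)

    def test_chain_equals_sequential_point_mapping(self):
        """Composition oracle: apply each transform left-to-right to points."""
        rng = np.random.default_rng(11)
        chain = [random_affine(rng) for _ in range(5)]
        pts = rng.uniform(-100, 100, (20, 2))
        expected = pts.copy()
        for t in chain:
            expected = t.apply(expected)
        got = tf.compose(chain).apply(pts)
        assert np.abs(got - expected).max() < 1e-6

    @settings(max_examples=60, derandomize=True)
    @given(affines())
    def test_invert_is_involution_and_inverse(self, t):
        assert np.abs(tf.invert(tf.invert(t)).matrix - t.matrix).max() < 1e-9
        assert np.abs(tf.compose([t, tf.invert(t)]).matrix - np.eye(3)).max() < 1e-9

    @settings(max_examples=40, derandomize=True)
    @given(affines(), affines(), affines())
    def test_compose_associative(self, a, b, c):
        left = tf.compose([a, tf.compose([b, c])])
        right = tf.compose([tf.compose([a, b]), c])
        assert np.abs(left.matrix - right.matrix).max() < 1e-9


class TestEstimateAffine:
    def test_exact_correspondences_recovered(self):
        rng = np.random.default_rng(2)
        A = random_affine(rng)
        src = rng.uniform(0, 400, (10, 2))
        m = MatchSet([(i, i) for i in range(10)])
        est, inliers = tf.estimate_affine(m, _corr(src), _corr(A.apply(src)), seed=5)
        assert np.abs(est.matrix - A.matrix).max() < 1e-6
        assert len(inliers) == 10

    def test_outliers_identified(self):
        rng = np.random.default_rng(3)
        A = random_affine(rng)
        src = rng.uniform(50, 400, (15, 2))
        dst = A.apply(src)
        dst[10:] += rng.uniform(30, 120, (5, 2))  # gross outliers
        m = MatchSet([(i, i) for i in range(15)])
        est, inliers = tf.estimate_affine(
            m, _corr(src), _corr(dst), inlier_tol=2.0, seed=5
        )
        assert sorted(inliers) == list(range(10))

    def test_collinear_points_degenerate(self):
        src = np.array([[0, 0], [10, 10], [20, 20]], dtype=float)
        m = MatchSet([(i, i) for i in range(3)])
        with pytest.raises(DegenerateGeometryError):
            tf.estimate_affine(m, _corr(src), _corr(src + 1), seed=0)

    def test_too_few_matches(self):
        m = MatchSet([(0, 0), (1, 1)])
        pts = np.array([[0.0, 0], [5, 5]])
        with pytest.raises(InsufficientCorrespondencesError):
            tf.estimate_affine(m, _corr(pts), _corr(pts), seed=0)

    def test_agrees_with_skimage_ransac(self):
        """Independent robust estimator recovers the same transform."""
        from skimage.measure import ransac as sk_ransac
        from skimage.transform import AffineTransform as SkAffine

        rng = np.random.default_rng(14)
        A = random_affine(rng, max_rot=0.3, max_t=20)
        src = rng.uniform(20, 400, (30, 2))
        dst = A.apply(src) + rng.normal(0, 0.3, (30, 2))
        dst[24:] += rng.uniform(40, 100, (6, 2))
        m = MatchSet([(i, i) for i in range(30)])
        est, _ = tf.estimate_affine(m, _corr(src), _corr(dst),
                                    inlier_tol=3.0, seed=0)
        model, _ = sk_ransac(
            (src, dst), SkAffine, min_samples=3, residual_threshold=3.0,
            max_trials=2000, rng=0,
        )
        probe = rng.uniform(0, 450, (50, 2))
        assert np.abs(est.apply(probe) - model(probe)).max() < 0.5

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        A = random_affine(rng)
        src = rng.uniform(0, 300, (25, 2))
        dst = A.apply(src) + rng.normal(0, 0.5, (25, 2))
        dst[20:] += 80
        m = MatchSet([(i, i) for i in range(25)])
        r1 = tf.estimate_affine(m, _corr(src), _corr(dst), seed=42)
        r2 = tf.estimate_affine(m, _corr(src), _corr(dst), seed=42)
        assert np.array_equal(r1[0].matrix, r2[0].matrix) and r1[1] == r2[1]


def _bilinear(img, x, y):
    """Hand-rolled bilinear sampling used as the warp oracle."""
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - x0, y - y0
    return (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x0 + 1] * fx * (1 - fy)
        + img[y0 + 1, x0] * (1 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )


class TestWarpImage:
    def test_identity_preserves_image(self, texture):
        res = tf.warp_image(texture, tf.identity_transform(), texture.shape)
        assert np.allclose(res.image, texture)
        assert res.validity_mask.all()

    def test_full_offscreen_translation(self, texture):
        h, w = texture.shape
        res = tf.warp_image(texture, tf.translation(w, 0), (h, w))
        assert not res.validity_mask.any()

    def test_rotation_against_coordinate_oracle(self, texture):
        theta = np.deg2rad(30)
        c, s = np.cos(theta), np.sin(theta)
        m = np.eye(3)
        m[:2, :2] = [[c, -s], [s, c]]
        m[:2, 2] = (20, 40)
        t = eg.AffineTransform(m)
        res = tf.warp_image(texture, t, (128, 128))
        rng = np.random.default_rng(6)
        errs = []
        for _ in range(300):
            x, y = rng.integers(0, 128, 2)
            if not res.validity_mask[y, x]:
                continue
            sx, sy = t.apply((x, y))[0]
            if sx >= texture.shape[1] - 1 or sy >= texture.shape[0] - 1:
                continue
            errs.append(abs(res.image[y, x] - _bilinear(texture, sx, sy)))
        # < 2 gray levels on the 8-bit scale
        assert np.mean(errs) < 2.0 / 255.0


class TestNccScore:
    def test_self_correlation(self, texture):
        s = tf.ncc_score(texture, texture, tf.identity_transform())
        assert s.dif_h == pytest.approx(1.0)
        assert s.overlap_fraction == 1.0

    def test_inverted_image_anticorrelates(self, texture):
        s = tf.ncc_score(texture, 1.0 - texture, tf.identity_transform())
        assert s.dif_h == pytest.approx(-1.0)

    def test_offset_invariant(self, texture):
        ref = texture * 0.5  # keep headroom so the offset does not clip
        s = tf.ncc_score(ref, ref + 0.3, tf.identity_transform())
        assert s.dif_h == pytest.approx(1.0)

    def test_insufficient_overlap_raises(self, texture):
        h, w = texture.shape
        with pytest.raises(InsufficientOverlapError):
            tf.ncc_score(texture, texture, tf.translation(0.9 * w, 0))


class TestSsdScore:
    def _full(self, img):
        return tf.WarpResult(image=np.asarray(img, dtype=float),
                             validity_mask=np.ones(np.shape(img), dtype=bool))

    def test_identical_is_zero(self, texture):
        assert tf.ssd_score(self._full(texture), self._full(texture)) == 0.0

    def test_constant_offset_squares(self):
        a = np.zeros((16, 16))
        assert tf.ssd_score(self._full(a), self._full(a + 10)) == pytest.approx(100.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 1, (12, 14))
        b = rng.uniform(0, 1, (12, 14))
        ma = rng.uniform(0, 1, (12, 14)) > 0.3
        mb = rng.uniform(0, 1, (12, 14)) > 0.3
        total, n = 0.0, 0
        for i in range(12):
            for j in range(14):
                if ma[i, j] and mb[i, j]:
                    total += (a[i, j] - b[i, j]) ** 2
                    n += 1
        wa = tf.WarpResult(image=a, validity_mask=ma)
        wb = tf.WarpResult(image=b, validity_mask=mb)
        assert tf.ssd_score(wa, wb) == pytest.approx(total / n, abs=1e-9)
        assert tf.ssd_score(wb, wa) == tf.ssd_score(wa, wb)

    def test_disjoint_masks_raise(self):
        a = tf.WarpResult(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))
        with pytest.raises(InsufficientOverlapError):
            tf.ssd_score(a, a)
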