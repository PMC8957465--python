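"""Canny chain: kernels, gradients, NMS, hysteresis, full-chain oracle."""

import math

import numpy as np
import pytest
from scipy import ndimage

from arthromri.edges import (CannyParams, EdgeMap, approximation_degree,
                             auto_thresholds, canny, extract_synovial_contour,
                             gaussian_kernel, hysteresis_link, nonmax_suppress,
                             smooth, sobel_gradients)

from _naive import (naive_canny, naive_hysteresis, naive_smooth)


class TestGaussianKernel:
    def test_normalised(self):
        for delta, radius in [(0.5, 1), (1.0, 3), (2.7, 5)]:
            k = gaussian_kernel(delta, radius)
            assert k.shape == (2 * radius + 1, 2 * radius + 1)
            assert k.sum() == pytest.approx(1.0, abs=1e-12)

    def test_center_weight_delta1_radius1(self):
        # direct evaluation at offsets 0, 1, sqrt(2), then normalisation
        expected = 1.0 / (1 + 4 * math.exp(-0.5) + 4 * math.exp(-1.0))
        k = gaussian_kernel(1.0, 1)
        assert k[1, 1] == pytest.approx(expected, rel=1e-12)
        assert k[1, 1] == pytest.approx(0.2042, abs=5e-5)

    def test_near_identity_limit(self):
        k = gaussian_kernel(1e-3, 1)
        assert k[1, 1] >= 1 - 1e-6

    def test_rejects_bad_delta(self):
        with pytest.raises(ValueError):
            gaussian_kernel(0.0, 1)
        with pytest.raises(ValueError):
            gaussian_kernel(-1.0, 1)


class TestSmooth:
    def test_constant_fixed_point(self):
        img = np.full((9, 9), 100.0)
        out = smooth(img, delta=1.3)
        np.testing.assert_allclose(out, img, atol=1e-10)

    def test_impulse_reproduces_kernel(self):
        img = np.zeros((7, 7))
        img[3, 3] = 1.0
        out = smooth(img, delta=1.0, radius=1)
        np.testing.assert_allclose(out[2:5, 2:5], gaussian_kernel(1.0, 1),
                                   atol=1e-12)

    def test_linearity(self, rng):
        a, b = 2.5, -0.7
        I = rng.uniform(0, 255, (8, 8))
        J = rng.uniform(0, 255, (8, 8))
        lhs = smooth(a * I + b * J, 1.2, 2)
        rhs = a * smooth(I, 1.2, 2) + b * smooth(J, 1.2, 2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_matches_naive_convolution(self, rng):
        img = rng.uniform(0, 255, (10, 10))
        out = smooth(img, 1.4, 3)
        ref = naive_smooth(img.tolist(), 1.4, 3)
        np.testing.assert_allclose(out, np.array(ref), rtol=1e-12, atol=1e-9)


class TestSobel:
    def test_constant_image_zero_gradient(self):
        f = sobel_gradients(np.full((5, 5), 42.0))
        assert not f.gx.any() and not f.gy.any()
        assert not f.magnitude.any() and not f.direction.any()

    def test_vertical_step(self):
        # columns 0..3 are 0, columns 4..7 are 1; at the boundary the right
        # neighbours contribute 1+2+1 = 4
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        f = sobel_gradients(img)
        assert f.gx[4, 3] == pytest.approx(4.0)
        assert f.gy[4, 3] == pytest.approx(0.0)
        assert f.magnitude[4, 3] == pytest.approx(4.0)

    def test_magnitude_consistency(self, rng):
        f = sobel_gradients(rng.uniform(0, 255, (12, 12)))
        np.testing.assert_allclose(f.magnitude, np.hypot(f.gx, f.gy),
                                   atol=1e-12)

    def test_rotation_equivariance(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        f = sobel_gradients(img)
        g = sobel_gradients(np.rot90(img))
        # rot90 CCW maps the y-up gradient (gx, gy) to (-gy, gx)
        np.testing.assert_allclose(g.gx, -np.rot90(f.gy), atol=1e-9)
        np.testing.assert_allclose(g.gy, np.rot90(f.gx), atol=1e-9)
        np.testing.assert_allclose(g.magnitude, np.rot90(f.magnitude),
                                   atol=1e-9)

    def test_rejects_small_image(self):
        with pytest.raises(ValueError):
            sobel_gradients(np.zeros((2, 5)))


class TestNonmaxSuppress:
    def test_single_peak_kept(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        f = sobel_gradients(img)
        # build a synthetic field instead: lone nonzero magnitude survives
        mag = np.zeros((5, 5))
        mag[2, 2] = 3.0
        from arthromri.edges import GradientField

        field = GradientField(gx=mag.copy(), gy=np.zeros_like(mag),
                              magnitude=mag, direction=np.zeros_like(mag))
        out = nonmax_suppress(field)
        assert out[2, 2] == 3.0
        assert out.sum() == 3.0

    def test_flat_plateau_fully_suppressed(self):
        from arthromri.edges import GradientField

        mag = np.full((6, 6), 5.0)
        field = GradientField(gx=mag.copy(), gy=np.zeros_like(mag),
                              magnitude=mag, direction=np.zeros_like(mag))
        out = nonmax_suppress(field)
        assert not out[1:-1, 1:-1].any()  # strict-greater rule kills plateaus

    def test_vertical_ridge_preserved(self):
        from arthromri.edges import GradientField

        mag = np.zeros((7, 7))
        mag[:, 3] = 4.0
        field = GradientField(gx=np.full_like(mag, 4.0) * (mag > 0),
                              gy=np.zeros_like(mag), magnitude=mag,
                              direction=np.zeros_like(mag))
        out = nonmax_suppress(field)
        np.testing.assert_array_equal(out, mag)

    def test_never_increases_or_creates(self, rng):
        f = sobel_gradients(rng.uniform(0, 255, (16, 16)))
        out = nonmax_suppress(f)
        assert np.all(out <= f.magnitude)
        assert not out[f.magnitude == 0].any()


class TestAutoThresholds:
    def test_nearest_rank_quantile(self):
        sup = np.arange(101, dtype=float).reshape(1, -1)  # nonzero 1..100
        t_low, t_high = auto_thresholds(sup, 0.90, 0.4)
        assert t_high == 90.0
        assert t_low == pytest.approx(36.0)

    def test_low_ratio_one(self):
        sup = np.arange(101, dtype=float).reshape(1, -1)
        t_low, t_high = auto_thresholds(sup, 0.5, 1.0)
        assert t_low == t_high

    def test_all_zero_returns_zero_pair(self):
        assert auto_thresholds(np.zeros((4, 4))) == (0.0, 0.0)


class TestHysteresis:
    def test_single_pixel_classification(self):
        sup = np.zeros((5, 5))
        sup[2, 2] = 10.0
        assert hysteresis_link(sup, 2.0, 5.0, 8).edges[2, 2]
        sup[2, 2] = 3.0  # weak and isolated
        assert not hysteresis_link(sup, 2.0, 5.0, 8).edges[2, 2]

    def test_transitive_weak_chain(self):
        sup = np.zeros((3, 5))
        sup[1, 1], sup[1, 2], sup[1, 3] = 3.0, 3.0, 10.0  # weak-weak-strong
        edges = hysteresis_link(sup, 2.0, 5.0, 8).edges
        assert edges[1, 1] and edges[1, 2] and edges[1, 3]

    def test_rejects_inverted_thresholds(self):
        with pytest.raises(ValueError):
            hysteresis_link(np.zeros((3, 3)), 5.0, 2.0)

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(25):
            sup = rng.uniform(0, 10, (8, 8)) * (rng.random((8, 8)) < 0.6)
            for conn in (4, 8):
                got = hysteresis_link(sup, 3.0, 7.0, conn).edges
                ref = np.array(naive_hysteresis(sup.tolist(), 3.0, 7.0, conn))
                np.testing.assert_array_equal(got, ref)

    def test_monotonicity_in_thresholds(self, rng):
        sup = rng.uniform(0, 10, (12, 12)) * (rng.random((12, 12)) < 0.5)
        base = hysteresis_link(sup, 3.0, 7.0).edges
        lower_tlow = hysteresis_link(sup, 1.0, 7.0).edges
        higher_thigh = hysteresis_link(sup, 3.0, 9.0).edges
        assert np.all(base <= lower_tlow)   # lowering t_low only adds
        assert np.all(higher_thigh <= base)  # raising t_high only removes


class TestFullChain:
    def test_blank_image_empty_edges(self):
        em = canny(np.zeros((16, 16)))
        assert not em.edges.any()

    def test_disk_yields_closed_ring(self, disk_image):
        em = canny(disk_image, CannyParams(delta=1.4))
        labels, n = ndimage.label(em.edges,
                                  ndimage.generate_binary_structure(2, 2))
        assert n == 1  # one 8-connected component
        r, c = np.nonzero(em.edges)
        dist = np.abs(np.hypot(r - 32, c - 32) - 20)
        assert dist.max() <= 1.5
        _, closed = extract_synovial_contour(em)
        assert closed

    def test_matches_independent_reference(self, rng):
        params = CannyParams(delta=1.4, q_high=0.9, low_ratio=0.4)
        for _ in range(20):
            img = rng.uniform(0, 255, (16, 16))
            got = canny(img, params).edges
            ref = np.array(naive_canny(img.tolist(), params.delta,
                                       params.radius, params.q_high,
                                       params.low_ratio, params.connectivity))
            np.testing.assert_array_equal(got, ref)


class TestApproximationDegree:
    def test_identical_is_zero(self, rng):
        img = rng.uniform(0, 255, (6, 6))
        assert approximation_degree(img, img) == 0.0

    def test_hand_value(self):
        f = np.zeros((2, 2))
        g = np.full((2, 2), 3.0)
        assert approximation_degree(f, g) == pytest.approx(6.0)

    def test_triangle_inequality(self, rng):
        f, g, h = (rng.uniform(0, 255, (5, 5)) for _ in range(3))
        assert approximation_degree(f, h) <= (
            approximation_degree(f, g) + approximation_degree(g, h) + 1e-9
        )

    def test_rejects_mismatched_shapes(self):
        with pytest.raises(ValueError):
            approximation_degree(np.zeros((2, 2)), np.zeros((3, 3)))


class TestContourExtraction:
    def test_ring_closed(self):
        edges = np.zeros((9, 9), dtype=bool)
        edges[2, 2:7] = edges[6, 2:7] = True
        edges[2:7, 2] = edges[2:7, 6] = True
        em = EdgeMap(edges=edges, provenance=edges.astype(np.int8) * 2)
        mask, closed = extract_synovial_contour(em)
        np.testing.assert_array_equal(mask, edges)
        assert closed

    def test_largest_component_wins(self):
        edges = np.zeros((12, 20), dtype=bool)
        edges[1, 1:8] = True   # size 7
        edges[5:10, 12:14] = True  # size 10
        em = EdgeMap(edges=edges, provenance=edges.astype(np.int8) * 2)
        mask, _ = extract_synovial_contour(em)
        assert mask.sum() == 10
        assert mask[5, 12]

    def test_tie_breaks_lexicographically(self):
        edges = np.zeros((6, 12), dtype=bool)
        edges[3, 8:11] = True   # later in raster order
        edges[4, 1:4] = True    # earlier min (row, col)? no: row 4 > row 3
        em = EdgeMap(edges=edges, provenance=edges.astype(np.int8) * 2)
        mask, _ = extract_synovial_contour(em)
        assert mask[3, 8] and not mask[4, 1]

    def test_empty_map(self):
        em = EdgeMap(edges=np.zeros((4, 4), dtype=bool),
                     provenance=np.zeros((4, 4), dtype=np.int8))
        mask, closed = extract_synovial_contour(em)
        assert not mask.any() and not closed
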