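"""Gray-gradient center detection: banding, radial diagnostic, threshold,
centroid."""

import numpy as np
import pytest

import canopycenter as cc
from canopycenter.center_detection import DEFAULT_ISOHYPSE_LEVELS, IsohypseBands


def _radial_gray(shape=(64, 64), cx=32, cy=32, slope=4.0, floor=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r = np.hypot(xx - cx, yy - cy)
    return cc.GrayImage(np.clip(floor + slope * r, 0, 255).astype(np.uint8))


class TestBandQuantize:
    @pytest.mark.parametrize(
        "g, band",
        [(0, 0), (14, 0), (15, 1), (29, 1), (30, 2), (254, 16), (255, 16)],
    )
    def test_half_open_bands(self, g, band):
        gray = cc.GrayImage(np.array([[g]]))
        assert cc.band_quantize(gray)[0, 0] == band

    def test_partition_of_domain(self, rng):
        gray = cc.GrayImage(rng.integers(0, 256, (20, 20)))
        domain = cc.BinaryMask((rng.random((20, 20)) < 0.6).astype(np.uint8))
        idx = cc.band_quantize(gray, domain=domain)
        inside = domain.pixels == 1
        assert (idx[inside] >= 0).all() and (idx[inside] < 17).all()
        assert (idx[~inside] == -1).all()
        # band boundaries match the printed cut points
        levels = np.array(DEFAULT_ISOHYPSE_LEVELS)
        lo = np.concatenate([[0], levels[:-1]])
        g = gray.pixels[inside]
        b = idx[inside]
        assert (g >= lo[b]).all()
        assert ((g < levels[b]) | (g == 255)).all()

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            IsohypseBands((30, 15, 255))
        with pytest.raises(ValueError):
            IsohypseBands((15, 30))


class TestRadialGradientCheck:
    def test_synthetic_gradient_is_monotone(self):
        gray = _radial_gray()
        domain = cc.BinaryMask(np.ones((64, 64), dtype=np.uint8))
        prof = cc.radial_gradient_check(gray, domain, cc.PixelCoord(32, 32), n_rings=6)
        assert prof.monotone
        assert (np.diff(prof.ring_means) > 0).all()
        assert prof.spearman == pytest.approx(1.0)

    def test_constant_image(self):
        gray = cc.GrayImage(np.full((20, 20), 80, dtype=np.uint8))
        domain = cc.BinaryMask(np.ones((20, 20), dtype=np.uint8))
        prof = cc.radial_gradient_check(gray, domain, cc.PixelCoord(10, 10), n_rings=4)
        assert prof.monotone
        assert prof.spearman == 0.0

    def test_inverted_gradient_fails(self):
        gray = _radial_gray()
        inv = cc.GrayImage(255 - gray.pixels)
        domain = cc.BinaryMask(np.ones((64, 64), dtype=np.uint8))
        prof = cc.radial_gradient_check(inv, domain, cc.PixelCoord(32, 32), n_rings=6)
        assert not prof.monotone

    def test_center_outside_domain_rejected(self):
        gray = _radial_gray((16, 16), 8, 8)
        domain = cc.BinaryMask.zeros((16, 16))
        with pytest.raises(ValueError):
            cc.radial_gradient_check(gray, domain, cc.PixelCoord(8, 8))


class TestThresholdCenter:
    def test_strict_threshold(self):
        gray = cc.GrayImage(np.array([[29, 30]]))
        domain = cc.BinaryMask(np.ones((1, 2), dtype=np.uint8))
        out = cc.threshold_center(gray, domain, T=30)
        assert out.pixels.tolist() == [[1, 0]]

    def test_empty_domain(self):
        gray = cc.GrayImage(np.zeros((4, 4), dtype=np.uint8))
        assert cc.threshold_center(gray, cc.BinaryMask.zeros((4, 4))).area == 0

    def test_monotone_in_T(self, rng):
        gray = cc.GrayImage(rng.integers(0, 256, (25, 25)))
        domain = cc.BinaryMask((rng.random((25, 25)) < 0.7).astype(np.uint8))
        prev = cc.threshold_center(gray, domain, T=0)
        for T in (20, 30, 100, 256):
            cur = cc.threshold_center(gray, domain, T=T)
            assert (prev.pixels <= cur.pixels).all()
            prev = cur


class TestCentroid:
    def test_single_pixel(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[7, 5] = 1
        assert cc.centroid(cc.BinaryMask(m)) == cc.PixelCoord(5, 7)

    def test_symmetric_disc(self):
        yy, xx = np.mgrid[0:101, 0:101]
        m = (np.hypot(xx - 50, yy - 50) <= 20).astype(np.uint8)
        assert cc.centroid(cc.BinaryMask(m)) == cc.PixelCoord(50, 50)

    def test_midpoint(self):
        m = np.zeros((3, 3), dtype=np.uint8)
        m[0, 0] = m[0, 2] = 1
        assert cc.centroid(cc.BinaryMask(m)) == cc.PixelCoord(1, 0)

    def test_empty_mask_gives_none(self):
        assert cc.centroid(cc.BinaryMask.zeros((4, 4))) is None


class TestDetectCenter:
    def test_recovers_fixture_center(self):
        img, truth = cc.generate_canopy_image(cc.FixtureParams(seed=5, weed_count=0))
        gray = cc.rgb_to_gray(img)
        res = cc.detect_center(gray, truth.roi)
        assert res.found
        assert res.center.distance_to(truth.center) <= 2

    def test_all_bright_roi_not_found(self):
        gray = cc.GrayImage(np.full((10, 10), 200, dtype=np.uint8))
        roi = cc.BinaryMask(np.ones((10, 10), dtype=np.uint8))
        res = cc.detect_center(gray, roi)
        assert not res.found and res.center is None

    def test_keeps_larger_dark_patch(self):
        gray = np.full((20, 30), 100, dtype=np.uint8)
        gray[2:4, 2:4] = 5        # small dark patch
        gray[10:16, 20:26] = 5    # large dark patch
        roi = cc.BinaryMask(np.ones((20, 30), dtype=np.uint8))
        res = cc.detect_center(cc.GrayImage(gray), roi)
        assert res.found
        assert res.center == cc.PixelCoord(22, 12)  # centroid of rows 10-15, cols 20-25

    def test_center_inside_roi_bbox(self, rng):
        for seed in range(5):
            img, truth = cc.generate_canopy_image(cc.FixtureParams(seed=seed))
            gray = cc.rgb_to_gray(img)
            res = cc.detect_center(gray, truth.roi)
            if res.found:
                ys, xs = np.nonzero(truth.roi.pixels)
                assert xs.min() <= res.center.x <= xs.max()
                assert ys.min() <= res.center.y <= ys.max()

    def test_adaptive_threshold_compensates_gain(self):
        gray = _radial_gray(floor=60.0, slope=2.0)  # nothing below 30
        roi = cc.BinaryMask(np.ones((64, 64), dtype=np.uint8))
        assert not cc.detect_center(gray, roi, T=30).found
        res = cc.detect_center(gray, roi, T=30, adaptive=True)
        assert res.found
        assert res.center.distance_to(cc.PixelCoord(32, 32)) <= 2
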