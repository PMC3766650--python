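"""Masked ratiometric SHG metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tacsquant import (
    BinaryMask,
    Channel,
    compute_pair_metrics,
    fb_ratio,
    normalized_bshg,
    resolve_threshold,
    shg_emission_nm,
    threshold_mask,
)
from tacsquant.ratiometrics import EXCITATION_NM, BSHG_FILTER_CENTER_NM, EmptyMaskWarning

from oracles import fb_mean_loop, normalized_bshg_loop, threshold_count_loop


def mask_of(pixels, channel=Channel.IF, threshold=0.0):
    return BinaryMask(np.asarray(pixels, dtype=bool), threshold, channel)


class TestThreshold:
    def test_uniform_below_threshold_empty(self, make_image):
        m = threshold_mask(make_image(np.full((4, 4), 2.0)), 5.0)
        assert m.n_true == 0

    def test_zero_threshold_selects_all_positive(self, make_image):
        m = threshold_mask(make_image(np.ones((4, 4))), 0.0)
        assert m.n_true == 16

    def test_matches_loop_oracle(self, make_image, rng):
        img = rng.random((16, 16))
        m = threshold_mask(make_image(img), 0.4)
        assert m.n_true == threshold_count_loop(img, 0.4)
        assert m.threshold_used == 0.4

    def test_negative_threshold_rejected(self, make_image):
        with pytest.raises(ValueError):
            threshold_mask(make_image(np.ones((4, 4))), -1.0)

    def test_resolve_threshold_modes(self, make_image, rng):
        img = make_image(rng.random((32, 32)) * 10)
        assert resolve_threshold(img, "fixed:3.5") == 3.5
        assert resolve_threshold(img, "quantile:0.9") == pytest.approx(
            np.quantile(img.pixels, 0.9))
        with pytest.raises(ValueError):
            resolve_threshold(img, "otsu")


class TestNormalizedBshg:
    def test_identity(self, make_image, rng):
        img = rng.random((8, 8)) + 0.1
        mask = mask_of(img > 0.5)
        a = make_image(img, Channel.BSHG)
        b = make_image(img, Channel.IF)
        assert normalized_bshg(a, b, mask) == pytest.approx(1.0)

    def test_linearity(self, make_image, rng):
        img = rng.random((8, 8)) + 0.1
        mask = mask_of(img > 0.5)
        assert normalized_bshg(make_image(2 * img, Channel.BSHG),
                               make_image(img, Channel.IF), mask) == pytest.approx(2.0)

    def test_worked_example(self, make_image):
        """Hand arithmetic: mean B {5,5,10,20}=10, mean IF {10,20,30,40}=25 -> 0.4."""
        ifimg = np.zeros((4, 4))
        bimg = np.zeros((4, 4))
        coords = [(0, 0), (1, 1), (2, 2), (3, 3)]
        for (y, x), vi, vb in zip(coords, [10, 20, 30, 40], [5, 5, 10, 20]):
            ifimg[y, x] = vi
            bimg[y, x] = vb
        mask = mask_of(ifimg > 0)
        assert normalized_bshg(make_image(bimg, Channel.BSHG),
                               make_image(ifimg, Channel.IF), mask) == pytest.approx(0.4)

    def test_matches_loop_oracle(self, make_image, rng):
        b, i = rng.random((12, 12)), rng.random((12, 12)) + 0.2
        mask = mask_of(i > 0.6)
        got = normalized_bshg(make_image(b, Channel.BSHG), make_image(i, Channel.IF), mask)
        assert got == pytest.approx(normalized_bshg_loop(b, i, mask.pixels), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.01, 100), b=st.floats(0.01, 100))
    def test_ratio_homogeneity(self, a, b):
        from conftest import as_image as make_image
        rng = np.random.default_rng(5)
        bimg, iimg = rng.random((8, 8)) + 0.1, rng.random((8, 8)) + 0.1
        mask = mask_of(iimg > 0.5)
        base = normalized_bshg(make_image(bimg, Channel.BSHG), make_image(iimg, Channel.IF), mask)
        scaled = normalized_bshg(make_image(a * bimg, Channel.BSHG),
                                 make_image(b * iimg, Channel.IF), mask)
        assert scaled == pytest.approx((a / b) * base, rel=1e-12)

    def test_empty_mask_gives_absent_metric(self, make_image):
        with pytest.warns(EmptyMaskWarning):
            out = normalized_bshg(make_image(np.ones((4, 4)), Channel.BSHG),
                                  make_image(np.ones((4, 4)), Channel.IF),
                                  mask_of(np.zeros((4, 4))))
        assert out is None

    def test_zero_if_mean_rejected(self, make_image):
        with pytest.raises(ZeroDivisionError):
            normalized_bshg(make_image(np.ones((4, 4)), Channel.BSHG),
                            make_image(np.zeros((4, 4)), Channel.IF),
                            mask_of(np.ones((4, 4))))

    def test_mask_subset_matches_loop_recomputation(self, make_image, rng):
        b, i = rng.random((10, 10)), rng.random((10, 10)) + 0.2
        full = i > 0.4
        subset = full & (rng.random((10, 10)) > 0.5)
        if subset.any():
            got = normalized_bshg(make_image(b, Channel.BSHG), make_image(i, Channel.IF),
                                  mask_of(subset))
            assert got == pytest.approx(normalized_bshg_loop(b, i, subset), abs=1e-12)


class TestFbRatio:
    def test_equal_channels_unit_ratio(self, make_image, rng):
        b = rng.random((8, 8)) + 0.5
        mask = mask_of(b > 0.8, Channel.BSHG)
        ratio, mean = fb_ratio(make_image(b, Channel.FSHG), make_image(b, Channel.BSHG), mask)
        assert mean == pytest.approx(1.0)
        assert np.all(ratio[mask.pixels] == 1.0)
        assert np.all(np.isnan(ratio[~mask.pixels]))

    def test_uniform_ratio(self, make_image):
        mask = mask_of(np.ones((4, 4)), Channel.BSHG)
        _, mean = fb_ratio(make_image(np.full((4, 4), 4.0), Channel.FSHG),
                           make_image(np.full((4, 4), 2.0), Channel.BSHG), mask)
        assert mean == pytest.approx(2.0)

    def test_common_scale_invariance(self, make_image, rng):
        f, b = rng.random((8, 8)) + 0.2, rng.random((8, 8)) + 0.2
        mask = mask_of(b > 0.5, Channel.BSHG)
        _, m1 = fb_ratio(make_image(f, Channel.FSHG), make_image(b, Channel.BSHG), mask)
        _, m2 = fb_ratio(make_image(7 * f, Channel.FSHG), make_image(7 * b, Channel.BSHG), mask)
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_matches_loop_oracle(self, make_image, rng):
        f, b = rng.random((12, 12)), rng.random((12, 12)) + 0.2
        mask = mask_of(b > 0.5, Channel.BSHG)
        _, mean = fb_ratio(make_image(f, Channel.FSHG), make_image(b, Channel.BSHG), mask)
        assert mean == pytest.approx(fb_mean_loop(f, b, mask.pixels), abs=1e-12)

    def test_zero_denominator_inside_mask_rejected(self, make_image):
        b = np.zeros((4, 4))
        with pytest.raises(ValueError):
            fb_ratio(make_image(np.ones((4, 4)), Channel.FSHG),
                     make_image(b, Channel.BSHG), mask_of(np.ones((4, 4)), Channel.BSHG))

    def test_empty_mask_absent(self, make_image):
        with pytest.warns(EmptyMaskWarning):
            _, mean = fb_ratio(make_image(np.ones((4, 4)), Channel.FSHG),
                               make_image(np.ones((4, 4)), Channel.BSHG),
                               mask_of(np.zeros((4, 4)), Channel.BSHG))
        assert mean is None


class TestPairMetrics:
    def test_missing_fshg_leaves_fb_absent(self, make_image, rng):
        i = rng.random((32, 32)) + 0.1
        b = rng.random((32, 32)) + 0.1
        m = compute_pair_metrics(make_image(i, Channel.IF), make_image(b, Channel.BSHG), None,
                                 fov_id="f1", group="WT", animal="a1")
        assert m.normalized_bshg is not None
        assert m.mean_fb_ratio is None
        assert m.n_if_mask_pixels > 0 and m.n_fb_mask_pixels == 0

    def test_masks_never_interchanged(self, make_image):
        """IF mask gates normalized B_SHG; B mask gates F/B: distinct pixels
        give distinct counts."""
        i = np.zeros((32, 32)); i[:8] = 10.0
        b = np.zeros((32, 32)); b[-4:] = 10.0
        f = b * 2
        m = compute_pair_metrics(make_image(i, Channel.IF), make_image(b, Channel.BSHG),
                                 make_image(f, Channel.FSHG),
                                 if_threshold_mode="fixed:1.0", fb_threshold_mode="fixed:1.0")
        assert m.n_if_mask_pixels == 8 * 32
        assert m.n_fb_mask_pixels == 4 * 32
        assert m.mean_fb_ratio == pytest.approx(2.0)


def test_shg_emission_is_half_the_excitation():
    assert shg_emission_nm(EXCITATION_NM) == pytest.approx(BSHG_FILTER_CENTER_NM)
    assert shg_emission_nm(900.0) == 450.0
    with pytest.raises(ValueError):
        shg_emission_nm(0.0)
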