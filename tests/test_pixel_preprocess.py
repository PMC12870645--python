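"""Pixel-cleanup rules checked against straight-line brute-force oracles."""

import numpy as np
import pytest

from lymphoniche.io_formats import ChannelImage
from lymphoniche.pixel_preprocess import (
    PreprocessParams,
    percentile_normalize,
    preprocess_rois,
    subtract_global_medians,
    zero_hot_pixels_summed,
    zero_multichannel_artifacts,
)


def image(data, names=None, roi="r1"):
    data = np.asarray(data, dtype=float)
    names = names or [f"ch{i}" for i in range(data.shape[0])]
    return ChannelImage(data, names, roi)


def oracle_preprocess(stacks, marker_idx, params):
    """Independent straight-line implementation of all four rules."""
    stacks = [s.astype(float).copy() for s in stacks]
    counts = []
    for s in stacks:
        summed = s.sum(axis=0)
        thr = np.percentile(summed, params.hot_pixel_percentile)
        hot = summed > thr
        s[:, hot] = 0
        n_exceed = np.zeros(s.shape[1:], dtype=int)
        for c in range(s.shape[0]):
            n_exceed += s[c] > np.percentile(s[c], params.hot_pixel_percentile)
        art = n_exceed >= params.multi_channel_min_count
        s[:, art] = 0
        counts.append((int(hot.sum()), int(art.sum())))
    for c in marker_idx:
        med = np.median(np.concatenate([s[c].ravel() for s in stacks]))
        for s in stacks:
            s[c] = np.clip(s[c] - med, 0, None)
    for s in stacks:
        for c in range(s.shape[0]):
            p = np.percentile(s[c], params.normalize_percentile)
            s[c] = 0.0 if p <= 0 else np.minimum(s[c] / p, 1.0) * params.normalize_max
    return stacks, counts


class TestHotPixels:
    def test_constant_image_untouched(self):
        img = image(np.full((2, 10, 10), 3.0))
        out, n = zero_hot_pixels_summed(img)
        assert n == 0
        np.testing.assert_array_equal(out.data, img.data)

    def test_single_planted_hot_pixel(self):
        # 100x100, 9999 pixels at 1 and one at 1000: the 99.99th percentile of
        # the summed image sits between the two values, so exactly one pixel
        # is zeroed (verified by brute-force percentile + comparison).
        data = np.ones((1, 100, 100))
        data[0, 37, 42] = 1000.0
        out, n = zero_hot_pixels_summed(image(data))
        assert n == 1
        assert out.data[0, 37, 42] == 0.0
        assert out.data[0].sum() == 9999.0

    def test_monotone_in_threshold(self, rng):
        data = rng.gamma(1.0, 2.0, size=(3, 40, 40))
        img = image(data)
        counts = [
            zero_hot_pixels_summed(img, PreprocessParams(hot_pixel_percentile=p))[1]
            for p in (90.0, 99.0, 99.9, 99.99)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_zeroed_count_bounded(self, rng):
        data = rng.gamma(1.0, 2.0, size=(2, 50, 50))
        _, n = zero_hot_pixels_summed(image(data))
        n_pix = 50 * 50
        assert n <= int(np.ceil((1 - 0.9999) * n_pix)) + 1


class TestMultichannelArtifacts:
    def test_extreme_in_one_channel_untouched(self):
        data = np.ones((3, 20, 20))
        data[0, 5, 5] = 500.0  # hot in channel 0 only
        out, n = zero_multichannel_artifacts(image(data))
        assert n == 0
        assert out.data[0, 5, 5] == 500.0

    def test_extreme_in_two_of_three_channels_zeroed(self):
        data = np.ones((3, 20, 20))
        data[0, 5, 5] = 500.0
        data[1, 5, 5] = 500.0
        # independent oracle: per-channel 99.99th percentiles of 400 values
        thr = [np.percentile(data[c], 99.99) for c in range(3)]
        assert sum(data[c, 5, 5] > thr[c] for c in range(3)) == 2
        out, n = zero_multichannel_artifacts(image(data))
        assert n == 1
        assert (out.data[:, 5, 5] == 0).all()

    def test_unknown_channel_rejected(self):
        img = image(np.ones((2, 4, 4)))
        with pytest.raises(ValueError, match="nope"):
            zero_multichannel_artifacts(
                img, PreprocessParams(artifact_channel_set=["nope"])
            )


class TestGlobalMedians:
    def test_constant_channel_maps_to_zero(self, marker_panel):
        img = image(np.full((1, 4, 4), 7.0), ["ch0"])
        out, med = subtract_global_medians([img], marker_panel(1))
        assert med["ch0"] == 7.0
        assert (out[0].data == 0).all()

    def test_pooled_median_over_two_images(self, marker_panel):
        a = image(np.array([[[1.0, 1.0], [1.0, 3.0]]]), ["ch0"], "a")
        b = image(np.array([[[3.0, 3.0], [3.0, 5.0]]]), ["ch0"], "b")
        out, med = subtract_global_medians([a, b], marker_panel(1))
        assert med["ch0"] == 3.0  # median of pooled {1,1,1,3,3,3,3,5}
        np.testing.assert_array_equal(out[0].data[0], [[0, 0], [0, 0]])
        np.testing.assert_array_equal(out[1].data[0], [[0, 0], [0, 2]])

    def test_nuclear_and_segmentation_channels_untouched(self, small_panel):
        data = np.stack([np.full((4, 4), v) for v in [5.0, 5.0, 5.0, 9.0, 9.0, 9.0]])
        img = ChannelImage(data, small_panel.channel_names, "r1")
        out, med = subtract_global_medians([img], small_panel)
        assert set(med) == {"CD19", "CD4", "Ki67"}
        for name in ("DNA1", "DNA2", "SegKit"):
            assert (out[0].channel(name) == 9.0).all()
        for name in ("CD19", "CD4", "Ki67"):
            assert (out[0].channel(name) == 0.0).all()


class TestPercentileNormalize:
    def test_pixel_at_p99_maps_to_full_scale(self):
        vals = np.arange(1.0, 101.0).reshape(1, 10, 10)
        out, scales = percentile_normalize(image(vals))
        p99 = np.percentile(vals[0], 99)
        at = np.isclose(vals[0], p99)
        if at.any():
            assert np.allclose(out.data[0][at], 100.0)
        assert out.data[0].max() == 100.0

    def test_all_zero_channel_stays_zero(self):
        out, scales = percentile_normalize(image(np.zeros((1, 5, 5))))
        assert scales["ch0"] == 0.0
        assert (out.data == 0).all()

    def test_against_sort_interpolate_oracle(self, rng):
        vals = rng.gamma(2.0, 5.0, size=(1, 25, 40))
        out, _ = percentile_normalize(image(vals))
        flat = np.sort(vals[0].ravel())
        # linear-interpolation percentile computed by hand
        idx = 0.99 * (flat.size - 1)
        lo, hi = int(np.floor(idx)), int(np.ceil(idx))
        p99 = flat[lo] + (idx - lo) * (flat[hi] - flat[lo])
        expected = np.minimum(vals[0] / p99, 1.0) * 100.0
        np.testing.assert_allclose(out.data[0], expected, rtol=1e-9)

    def test_output_bounded(self, rng):
        vals = rng.gamma(2.0, 5.0, size=(3, 20, 20))
        out, _ = percentile_normalize(image(vals))
        assert out.data.min() >= 0.0 and out.data.max() <= 100.0


class TestFullPipeline:
    def test_all_zero_stack(self, marker_panel):
        imgs = [image(np.zeros((2, 8, 8)), roi="a"), image(np.zeros((2, 8, 8)), roi="b")]
        out, report = preprocess_rois(imgs, marker_panel(2))
        assert all((o.data == 0).all() for o in out)
        assert all(v == 0 for v in report.hot_pixels_zeroed.values())
        assert all(v == 0 for v in report.artifact_pixels_zeroed.values())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_straight_line_oracle(self, marker_panel, seed):
        rng = np.random.default_rng(seed)
        panel = marker_panel(5)
        stacks = [rng.gamma(1.0, 3.0, size=(5, 48, 64)) for _ in range(3)]
        # plant a few artifacts
        for s in stacks:
            s[:, 3, 3] = 800.0
            s[0, 10, 10] = 900.0
            s[1, 10, 10] = 900.0
        imgs = [image(s.copy(), panel.channel_names, f"r{i}") for i, s in enumerate(stacks)]
        params = PreprocessParams()
        out, report = preprocess_rois(imgs, panel, params)
        expected, counts = oracle_preprocess(stacks, range(5), params)
        for o, e, (roi, (nh, na)) in zip(
            out, expected, [(f"r{i}", c) for i, c in enumerate(counts)]
        ):
            np.testing.assert_allclose(o.data, e, atol=1e-9)
            assert report.hot_pixels_zeroed[roi] == nh
            assert report.artifact_pixels_zeroed[roi] == na

    def test_bounds_invariant(self, marker_panel, rng):
        imgs = [
            image(rng.gamma(1.0, 3.0, size=(3, 32, 32)), roi=f"r{i}") for i in range(2)
        ]
        out, _ = preprocess_rois(imgs, marker_panel(3))
        for o in out:
            assert o.data.min() >= 0.0 and o.data.max() <= 100.0
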