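"""Level-one detection: thresholding, separation, measurement, filtering."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fluorospot as fs
from fluorospot.detect import (
    estimate_background,
    filter_spots,
    measure_spot,
    segment_candidates,
    separate_touching,
    to_grayscale,
)
from fluorospot.synth import _add_spot


def _disc_pixels(center, radius, shape):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


class TestToGrayscale:
    def test_grayscale_identity(self):
        img = np.arange(12, dtype=np.uint8).reshape(3, 4)
        assert to_grayscale(img) is img

    def test_equal_luminance_hues_give_equal_gray(self):
        # two pure hues scaled to unit luminance; detection must not care
        luma = np.array([0.2125, 0.7154, 0.0721])
        g = np.random.default_rng(0).uniform(0, 200, size=(32, 32))
        out = []
        for hue in ([1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [1.0, 1.0, 1.0]):
            hue = np.array(hue) / (luma @ hue)
            rgb = g[..., None] * hue
            out.append(to_grayscale(rgb))
        np.testing.assert_allclose(out[0], out[1], atol=1e-9)
        np.testing.assert_allclose(out[0], out[2], atol=1e-9)
        np.testing.assert_allclose(out[0], g, atol=1e-9)

    def test_all_zero_and_bad_shapes(self):
        assert to_grayscale(np.zeros((4, 4, 3))).sum() == 0.0
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 2)))


class TestEstimateBackground:
    def test_constant_image(self):
        level, scale = estimate_background(np.full((16, 16), 7.0))
        assert level == 7.0 and scale == 0.0

    def test_median_robust_to_sparse_spots(self):
        rng = np.random.default_rng(1)
        img = np.full(10_000, 10.0)
        idx = rng.choice(img.size, size=100, replace=False)  # 1% spot pixels
        img[idx] = 200.0
        level, _ = estimate_background(img.reshape(100, 100))
        assert 9.0 <= level <= 11.0

    def test_scale_recovers_gaussian_sigma(self):
        rng = np.random.default_rng(2)
        img = rng.normal(50.0, 3.0, size=(120, 120))
        _, scale = estimate_background(img)
        assert abs(scale - 3.0) / 3.0 < 0.2


class TestSegmentCandidates:
    def test_blank_image_no_regions(self, default_params):
        labels = segment_candidates(np.zeros((32, 32)), fs.DetectionParams(
            threshold_mode="absolute", intensity_threshold=1.0))
        assert labels.max() == 0

    def test_two_disjoint_discs(self):
        img = np.zeros((64, 64))
        img[_disc_pixels((16, 16), 5, img.shape)] = 100.0
        img[_disc_pixels((48, 48), 5, img.shape)] = 100.0
        labels = segment_candidates(img, fs.DetectionParams(
            threshold_mode="absolute", intensity_threshold=50.0))
        assert labels.max() == 2

    def test_threshold_sweep_matches_bruteforce_components(self):
        # oracle: DFS connected components (8-connectivity) on small arrays
        def brute_count(mask):
            seen = np.zeros_like(mask, dtype=bool)
            n = 0
            for r in range(mask.shape[0]):
                for c in range(mask.shape[1]):
                    if mask[r, c] and not seen[r, c]:
                        n += 1
                        stack = [(r, c)]
                        seen[r, c] = True
                        while stack:
                            y, x = stack.pop()
                            for dy in (-1, 0, 1):
                                for dx in (-1, 0, 1):
                                    yy, xx = y + dy, x + dx
                                    if (0 <= yy < mask.shape[0]
                                            and 0 <= xx < mask.shape[1]
                                            and mask[yy, xx]
                                            and not seen[yy, xx]):
                                        seen[yy, xx] = True
                                        stack.append((yy, xx))
            return n

        rng = np.random.default_rng(3)
        img = rng.integers(0, 10, size=(12, 12)).astype(float)
        counts = []
        for t in range(0, 12):
            params = fs.DetectionParams(threshold_mode="absolute",
                                        intensity_threshold=float(t))
            labels = segment_candidates(img, params)
            assert labels.max() == brute_count(img >= t)
            counts.append(labels.max())
        assert counts[-1] == 0  # threshold above global max


class TestSeparateTouching:
    def _params(self, **kw):
        base = dict(threshold_mode="absolute", intensity_threshold=20.0,
                    smoothing_sigma_px=1.0, separation_min_distance_px=5)
        base.update(kw)
        return fs.DetectionParams(**base)

    def test_single_spot_unchanged(self):
        img = np.zeros((48, 48))
        _add_spot(img, (24.0, 24.0), 8.0, 120.0, 2.0)
        params = self._params()
        labels = segment_candidates(img, params)
        out = separate_touching(labels, img, params)
        assert labels.max() == out.max() == 1
        np.testing.assert_array_equal(labels > 0, out > 0)

    def test_two_touching_equal_spots_split_near_midline(self):
        img = np.zeros((64, 96))
        _add_spot(img, (32.0, 33.0), 10.0, 150.0, 1.0)
        _add_spot(img, (32.0, 47.0), 10.0, 150.0, 1.0)
        params = self._params(intensity_threshold=5.0)
        labels = segment_candidates(img, params)
        assert labels.max() == 1  # merged at this threshold
        out = separate_touching(labels, img, params)
        assert out.max() == 2
        # equal spots centered at cols 33 and 47: split within 1 px of col 40
        cols1 = np.nonzero(out == 1)[1]
        cols2 = np.nonzero(out == 2)[1]
        left, right = (cols1, cols2) if cols1.mean() < cols2.mean() \
            else (cols2, cols1)
        assert left.max() <= 41 and right.min() >= 39

    def test_area_conserved_and_disabled_passthrough(self, small_well):
        img = to_grayscale(small_well.images["FITC"].pixels).astype(float)
        params = self._params(intensity_threshold=30.0)
        labels = segment_candidates(img, params)
        out = separate_touching(labels, img, params)
        assert (out > 0).sum() == (labels > 0).sum()
        off = dataclasses.replace(params, separation_enabled=False)
        np.testing.assert_array_equal(
            separate_touching(labels, img, off), labels)


class TestMeasureSpot:
    def test_uniform_disc(self):
        shape = (32, 32)
        mask = _disc_pixels((16, 16), 6, shape)
        img = np.where(mask, 80.0, 0.0)
        pix = np.argwhere(mask)
        spot = measure_spot(pix, img, 3.0, channel_id="A")
        assert spot.gradient_score == pytest.approx(1.0)
        assert spot.radial_cv <= 0.08          # pixelation bound
        assert spot.center_rc == pytest.approx((16.0, 16.0), abs=1e-9)
        assert spot.peak_intensity == spot.mean_intensity == 80.0

    @pytest.mark.parametrize("offset", [(20.3, 18.7), (15.0, 15.5)])
    def test_subpixel_centroid_recovery(self, offset):
        img = np.zeros((40, 40))
        _add_spot(img, offset, 7.0, 150.0, 2.0)
        pix = np.argwhere(img > 3.0)
        spot = measure_spot(pix, img, 3.0)
        assert abs(spot.center_rc[0] - offset[0]) < 0.25
        assert abs(spot.center_rc[1] - offset[1]) < 0.25

    def test_gradient_score_increases_with_decay_exponent(self):
        scores = []
        for shape_exp in (0.5, 1.5, 3.0):
            img = np.zeros((40, 40))
            _add_spot(img, (20.0, 20.0), 9.0, 200.0, shape_exp)
            pix = np.argwhere(img > 1.0)
            scores.append(measure_spot(pix, img, 3.0).gradient_score)
        assert scores[0] > 1.0
        assert scores == sorted(scores)

    def test_single_pixel_conventions(self):
        img = np.zeros((5, 5))
        img[2, 2] = 9.0
        spot = measure_spot(np.array([[2, 2]]), img, 3.0)
        assert spot.gradient_score == 1.0
        assert spot.radial_cv == 0.0
        assert spot.area_px == 1


class TestFilterSpots:
    def _spots(self, small_well, default_params):
        img = small_well.images["FITC"]
        permissive = fs.DetectionParams(min_area_px=1, max_area_px=10**6,
                                        min_peak_intensity=0.0)
        spots, _ = fs.detect_spots(img, permissive)
        return spots

    def test_permissive_keeps_all(self, small_well, default_params):
        spots = self._spots(small_well, default_params)
        kept, tally = filter_spots(spots, fs.DetectionParams(
            min_area_px=1, max_area_px=10**6, min_peak_intensity=0.0))
        assert len(kept) == len(spots) and tally.total == 0

    def test_impossible_area_rejects_all_as_size(self, small_well,
                                                 default_params):
        spots = self._spots(small_well, default_params)
        huge = max(s.area_px for s in spots) + 1
        kept, tally = filter_spots(spots, fs.DetectionParams(
            min_area_px=huge, max_area_px=huge + 1, min_peak_intensity=0.0))
        assert kept == [] and tally.area == len(spots)

    def test_matches_independent_predicate(self, small_well):
        spots = self._spots(small_well, None)
        params = fs.DetectionParams(min_area_px=20, max_area_px=150,
                                    min_peak_intensity=60.0,
                                    min_gradient_score=1.05,
                                    max_radial_cv=0.5)
        kept, tally = filter_spots(spots, params)
        expected = [s for s in spots
                    if 20 <= s.area_px <= 150 and s.peak_intensity >= 60.0
                    and s.gradient_score >= 1.05 and s.radial_cv <= 0.5]
        assert kept == expected
        assert tally.total == len(spots) - len(expected)


class TestDetectSpots:
    def test_recall_precision_on_simulated_well(self):
        cfg = fs.SimulationConfig(n_cells=30, seed=17)
        sim = fs.simulate_well(cfg)
        for ch in cfg.channels:
            spots, _ = fs.detect_spots(sim.images[ch], fs.DetectionParams())
            truth = [c.per_channel_center_rc[ch] for c in sim.truth
                     if ch in c.true_pattern]
            hits = 0
            for t in truth:
                if any(np.hypot(s.center_rc[0] - t[0],
                                s.center_rc[1] - t[1]) <= 3.0 for s in spots):
                    hits += 1
            recall = hits / len(truth) if truth else 1.0
            precision = hits / len(spots) if spots else 1.0
            assert recall >= 0.95 and precision >= 0.95

    def test_determinism(self, small_well, default_params):
        img = small_well.images["Cy3"]
        a, _ = fs.detect_spots(img, default_params)
        b, _ = fs.detect_spots(img, default_params)
        assert [s.center_rc for s in a] == [s.center_rc for s in b]
        assert [s.area_px for s in a] == [s.area_px for s in b]

    @given(st.floats(min_value=0.0, max_value=200.0))
    def test_count_monotone_in_peak_threshold(self, thr):
        sim = fs.simulate_well(
            fs.SimulationConfig(image_shape=(256, 256), n_cells=15, seed=11))
        img = sim.images["FITC"]
        base, _ = fs.detect_spots(img, fs.DetectionParams())
        raised, _ = fs.detect_spots(
            img, fs.DetectionParams(min_peak_intensity=thr))
        if thr >= 25.0:  # default threshold
            assert len(raised) <= len(base)

    def test_count_monotone_in_min_area(self, small_well):
        img = small_well.images["FITC"]
        counts = [len(fs.detect_spots(
            img, fs.DetectionParams(min_area_px=a))[0])
            for a in (1, 5, 20, 60, 200)]
        assert counts == sorted(counts, reverse=True)

    def test_sorted_by_center(self, small_well, default_params):
        spots, _ = fs.detect_spots(small_well.images["Cy5"], default_params)
        centers = [s.center_rc for s in spots]
        assert centers == sorted(centers)

    def test_colormap_change_leaves_spots_identical(self, small_well,
                                                    default_params):
        # render the same gray data as two different pure-hue color images;
        # after luminance reduction the detected spot lists are identical
        luma = np.array([0.2125, 0.7154, 0.0721])
        gray = small_well.images["FITC"].pixels.astype(float)
        results = []
        for hue in ([0.0, 1.0, 0.0], [1.0, 0.0, 1.0]):
            hue = np.array(hue) / (luma @ hue)
            g = to_grayscale(gray[..., None] * hue)
            img = fs.ChannelImage("FITC", g, bit_depth=8, pixel_size_um=3.0)
            spots, _ = fs.detect_spots(img, default_params)
            results.append(spots)
        assert len(results[0]) == len(results[1])
        for a, b in zip(*results):
            assert a.center_rc == pytest.approx(b.center_rc, abs=1e-9)
            assert a.area_px == b.area_px
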