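"""Otsu statistic, acceptance threshold T = mean - min, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from halocell import discriminability as disc
from halocell.heatmap import DetectionRecord


def brute_force_otsu(values, bins=256):
    """Independent oracle: exhaustive search over all candidate splits.

    Works on the quantised pixel values directly with plain means —
    no histogram/cumulative-sum machinery shared with the implementation.
    """
    x = np.asarray(values, float).ravel()
    q = np.clip((x * bins).astype(int), 0, bins - 1)   # bin index per pixel
    centres = (np.arange(bins) + 0.5) / bins
    variances = np.full(bins, -1.0)
    for k in range(bins):
        low = q <= k
        n0 = low.sum()
        if n0 == 0 or n0 == q.size:
            continue
        w0 = n0 / q.size
        mu0 = centres[q[low]].mean()
        mu1 = centres[q[~low]].mean()
        variances[k] = w0 * (1 - w0) * (mu0 - mu1) ** 2
    first = int(np.argmax(variances))
    tol = max(1e-15, abs(variances[first]) * 1e-12)
    last = first
    while last + 1 < bins and abs(variances[last + 1] - variances[first]) <= tol:
        last += 1
    return (centres[first] + centres[last]) / 2.0


class TestPreprocess:
    def test_constant_crop_gives_flat_then_zero_contrast(self):
        crop = np.full((32, 32, 3), 0.7)
        flat = disc.preprocess(crop, gaussian_sigma=1.0, enhance=False)
        assert np.allclose(flat.values, flat.values.flat[0])
        enhanced = disc.preprocess(crop, gaussian_sigma=1.0, enhance=True)
        assert np.allclose(enhanced.values, 0.0)

    def test_zero_sigma_is_identity_smoothing(self, rng):
        crop = rng.random((16, 16, 3))
        a = disc.preprocess(crop, gaussian_sigma=0.0, enhance=False,
                            signal_channel="luminance")
        lum = 1.0 - crop @ np.array([0.2126, 0.7152, 0.0722])
        assert np.allclose(a.values, np.clip(lum, 0, 1))

    def test_stain_channel_ranks_weak_below_strong_ring(self):
        from halocell.synthetic import ring_colour
        weak = np.tile(ring_colour(0.10), (8, 8, 1))
        strong = np.tile(ring_colour(0.60), (8, 8, 1))
        nucleus = np.tile([0.42, 0.46, 0.62], (8, 8, 1))
        sw = disc.preprocess(weak, enhance=False).values.mean()
        ss = disc.preprocess(strong, enhance=False).values.mean()
        sn = disc.preprocess(nucleus, enhance=False).values.mean()
        assert ss > 3 * sw          # deconvolution tracks stain strength
        assert sn < ss / 3          # counterstain stays far below strong stain

    def test_ring_signal_exceeds_background(self):
        yy, xx = np.mgrid[:64, :64]
        r = np.hypot(xx - 32, yy - 32)
        crop = np.full((64, 64, 3), 0.95)
        crop[(r > 10) & (r < 16)] = [0.5, 0.35, 0.2]   # dark brown ring
        patch = disc.preprocess(crop, gaussian_sigma=1.0, enhance=True)
        ring = (r > 10) & (r < 16)
        assert patch.values[ring].mean() > patch.values[r > 25].mean()

    def test_unknown_enhance_method_rejected(self, rng):
        with pytest.raises(ValueError, match="enhance_method"):
            disc.preprocess(rng.random((8, 8, 3)), enhance_method="nope")


class TestOtsuStatistic:
    def test_symmetric_bimodal_splits_in_the_middle(self):
        signal = np.array([0.2] * 500 + [0.8] * 500)
        assert disc.otsu_statistic(signal) == pytest.approx(0.5, abs=1 / 256)

    def test_matches_brute_force_on_random_patches(self, rng):
        for _ in range(50):
            signal = rng.random((24, 24))
            assert disc.otsu_statistic(signal) == pytest.approx(
                brute_force_otsu(signal), abs=1e-12)

    def test_matches_skimage_within_a_bin(self, rng):
        from skimage.filters import threshold_otsu
        for _ in range(10):
            # dense mixture: no structural plateaus, unique argmax
            signal = np.clip(np.concatenate([
                rng.normal(0.35, 0.15, 600), rng.normal(0.7, 0.1, 400),
            ]).reshape(-1), 0, 1)
            ours = disc.otsu_statistic(signal)
            ref = threshold_otsu(signal, nbins=256)
            # skimage bins over the data range, we bin over [0, 1]: allow
            # the two grids to disagree by a couple of bin widths
            assert abs(ours - ref) <= 2 / 256

    def test_two_gaussian_mixture(self, rng):
        signal = np.concatenate([rng.normal(0.3, 0.05, 2000),
                                 rng.normal(0.7, 0.05, 2000)])
        sigma = disc.otsu_statistic(np.clip(signal, 0, 1))
        assert 0.4 < sigma < 0.6

    def test_constant_image_rejected(self):
        with pytest.raises(disc.ConstantImageError):
            disc.otsu_statistic(np.full((8, 8), 0.5))


class TestAcceptanceThreshold:
    def test_worked_example(self):
        summary = disc.acceptance_threshold([0.010, 0.030, 0.050])
        assert summary.T == pytest.approx(0.020)
        assert summary.t_min == pytest.approx(0.010)
        assert summary.n == 3
        assert summary.sigma_sum == pytest.approx(0.090)

    def test_equal_sigmas_give_zero(self):
        assert disc.acceptance_threshold([0.3] * 7).T == pytest.approx(0.0)

    def test_matches_mean_minus_min_on_random_lists(self, rng):
        for _ in range(1000):
            sig = rng.random(int(rng.integers(1, 40)))
            assert disc.acceptance_threshold(sig).T == np.mean(sig) - np.min(sig)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            disc.acceptance_threshold([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_nonnegative_and_permutation_invariant(self, sigmas):
        summary = disc.acceptance_threshold(sigmas)
        assert summary.T >= -1e-12
        # permutation changes only the float summation order
        assert disc.acceptance_threshold(sigmas[::-1]).T == \
            pytest.approx(summary.T, rel=1e-9, abs=1e-12)

    def test_scales_linearly_under_positive_scaling(self, rng):
        sig = rng.random(20)
        t = disc.acceptance_threshold(sig).T
        assert disc.acceptance_threshold(3.0 * sig).T == pytest.approx(3 * t)


def _records(sigmas):
    return [DetectionRecord(centre=(0, 0), score=1.0, sigma=s) for s in sigmas]


class TestPartition:
    def test_worked_example_partition(self):
        recs = _records([0.010, 0.030, 0.050])
        summary = disc.acceptance_threshold([r.sigma for r in recs])
        keep, drop = disc.partition(recs, summary)
        assert sorted(r.sigma for r in keep) == [0.030, 0.050]
        assert [r.sigma for r in drop] == [0.010]
        assert all(r.threshold_T == pytest.approx(0.020) for r in recs)

    def test_equal_sigmas_all_discriminable(self):
        recs = _records([0.2] * 5)
        keep, drop = disc.partition(recs, disc.acceptance_threshold([0.2] * 5))
        assert len(keep) == 5 and drop == []

    def test_partition_is_complete(self, rng):
        sig = rng.random(200)
        recs = _records(sig)
        keep, drop = disc.partition(recs, disc.acceptance_threshold(sig))
        assert len(keep) + len(drop) == 200
        assert {id(r) for r in keep} | {id(r) for r in drop} == \
            {id(r) for r in recs}

    def test_minimum_record_kept_iff_double_min_exceeds_mean(self, rng):
        for _ in range(50):
            sig = rng.random(10)
            recs = _records(sig)
            keep, _ = disc.partition(recs, disc.acceptance_threshold(sig))
            t_min = sig.min()
            expected = 2 * t_min > sig.mean()
            got = any(np.isclose(r.sigma, t_min) for r in keep)
            assert got == expected

    def test_strictness_configurable(self):
        sig = [0.1, 0.3]   # T = 0.2 - 0.1 = 0.1; record 0.1 is borderline
        recs = _records(sig)
        summary = disc.acceptance_threshold(sig)
        keep_strict, _ = disc.partition(recs, summary, strict=True)
        assert len(keep_strict) == 1
        keep_loose, _ = disc.partition(_records(sig), summary, strict=False)
        assert len(keep_loose) == 2

    def test_missing_sigma_rejected(self):
        rec = DetectionRecord(centre=(0, 0), score=1.0)
        with pytest.raises(ValueError, match="Otsu"):
            disc.partition([rec], disc.acceptance_threshold([0.1]))
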