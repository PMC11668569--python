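"""Thresholder tests against 256-candidate brute-force criterion oracles."""

import numpy as np
import pytest

from phytoseg.io import BinaryMask
from phytoseg.synthetic import generate_bimodal_gray
from phytoseg.thresholding import (
    METHODS,
    DegenerateImageError,
    ThresholdParams,
    binarize,
    block_otsu,
    combined_global_local,
    double_peak,
    iterative_threshold,
    local_dynamic,
    max_entropy,
    min_error,
    otsu,
    quantize,
    segment,
    segment_all,
    wellner_adaptive,
)

# ---------------------------------------------------------------------------
# brute-force criterion oracles (independent scalar transcriptions)
# ---------------------------------------------------------------------------


def _hist(levels):
    return np.bincount(levels.ravel(), minlength=256).astype(float)


def _first_max_t(crits):
    """Smallest threshold attaining the maximum, up to a 1e-10 relative
    tolerance (criterion plateaus over empty histogram bins are exact ties
    that float summation order would otherwise break arbitrarily)."""
    finite = [c for _, c in crits if np.isfinite(c)]
    m = max(finite)
    tol = 1e-10 * max(1.0, abs(m))
    return next(t for t, c in crits if c >= m - tol)


def _first_min_t(crits):
    finite = [c for _, c in crits if np.isfinite(c)]
    m = min(finite)
    tol = 1e-10 * max(1.0, abs(m))
    return next(t for t, c in crits if c <= m + tol)


def brute_otsu(levels):
    hist = _hist(levels)
    p = hist / hist.sum()
    mu = sum(i * p[i] for i in range(256))
    crits = []
    for t in range(1, 256):
        w0 = p[:t].sum()
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(i * p[i] for i in range(t)) / w0
        mu1 = sum(i * p[i] for i in range(t, 256)) / w1
        crits.append((t, w0 * (mu0 - mu) ** 2 + w1 * (mu1 - mu) ** 2))
    return _first_max_t(crits)


def brute_max_entropy(levels):
    hist = _hist(levels)
    p = hist / hist.sum()
    crits = []
    for t in range(1, 256):
        p0 = p[:t].sum()
        p1 = 1 - p0
        if p0 <= 0 or p1 <= 0:
            continue
        h0 = -sum(pi / p0 * np.log(pi / p0) for pi in p[:t] if pi > 0)
        h1 = -sum(pi / p1 * np.log(pi / p1) for pi in p[t:] if pi > 0)
        crits.append((t, h0 + h1))
    return _first_max_t(crits)


def brute_min_error(levels):
    hist = _hist(levels)
    p = hist / hist.sum()
    crits = []
    for t in range(1, 256):
        w0 = p[:t].sum()
        w1 = 1 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = sum(i * p[i] for i in range(t)) / w0
        mu1 = sum(i * p[i] for i in range(t, 256)) / w1
        var0 = sum((i - mu0) ** 2 * p[i] for i in range(t)) / w0
        var1 = sum((i - mu1) ** 2 * p[i] for i in range(t, 256)) / w1
        crits.append((t, w0 * var0 + w1 * var1))
    return _first_min_t(crits)


def brute_double_peak(levels):
    hist = _hist(levels)
    peak1 = int(np.argmax(hist))
    d = [(x - peak1) ** 2 * hist[x] for x in range(256)]
    peak2 = int(np.argmax(d))
    lo, hi = min(peak1, peak2), max(peak1, peak2)
    if hi - lo < 2:
        return hi
    between = hist[lo + 1 : hi]
    return lo + 1 + int(np.argmin(between))


def _random_images(n, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        kind = rng.integers(0, 3)
        if kind == 0:
            img = rng.uniform(size=(24, 24))
        elif kind == 1:
            img = generate_bimodal_gray(
                levels=tuple(sorted(rng.uniform(size=2))),
                weight=rng.uniform(0.2, 0.8),
                noise_sd=rng.uniform(0, 0.1),
                size=(24, 24),
                seed=int(rng.integers(0, 2**31)),
            )
        else:
            img = np.clip(rng.normal(0.5, 0.2, size=(24, 24)), 0, 1)
        yield img


@pytest.mark.parametrize(
    "method,oracle",
    [(otsu, brute_otsu), (max_entropy, brute_max_entropy),
     (min_error, brute_min_error), (double_peak, brute_double_peak)],
    ids=["otsu", "max_entropy", "min_error", "double_peak"],
)
def test_global_methods_match_exhaustive_search(method, oracle):
    """Each histogram criterion equals its 256-candidate brute-force optimum
    (smallest-level tie rule) on 50 random images."""
    for img in _random_images(50, seed=99):
        levels = quantize(img)
        if levels.min() == levels.max():
            continue
        assert method(img) == oracle(levels)


class TestBinarize:
    def test_low_is_positive(self):
        mask = binarize(np.array([[10 / 255, 200 / 255]]), 128)
        assert np.array_equal(mask.array, [[1, 0]])

    def test_zero_threshold_gives_empty_mask(self, rng):
        img = rng.uniform(size=(8, 8))
        assert binarize(img, 0).array.sum() == 0

    def test_polarity_inversion_complements(self, rng):
        img = rng.uniform(size=(8, 8))
        low = binarize(img, 128, "low_is_positive").array
        high = binarize(img, 128, "high_is_positive").array
        assert np.array_equal(low ^ high, np.ones_like(low))

    def test_auto_polarity_picks_dark_class(self):
        img = np.array([[0.1, 0.1, 0.9, 0.9, 0.9, 0.9]])
        auto = binarize(img, 128, "auto").array
        assert np.array_equal(auto, [[1, 1, 0, 0, 0, 0]])
        # inverted threshold sense still yields a dark positive class
        auto_inv = binarize(1 - img, 128, "auto").array
        assert np.array_equal(auto_inv, [[0, 0, 1, 1, 1, 1]])


class TestOtsu:
    def test_two_value_image_threshold_separates(self):
        img = np.array([50 / 255] * 40 + [200 / 255] * 60).reshape(10, 10)
        t = otsu(img)
        assert 50 < t <= 200

    def test_extreme_bimodal_tie_rule(self):
        img = np.array([0.0, 1.0] * 32).reshape(8, 8)
        t = otsu(img)
        assert t == 1  # smallest maximizer

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            otsu(np.full((4, 4), 0.5))


class TestBlockOtsu:
    def test_matches_per_cell_oracle_on_two_contrasts(self):
        rng = np.random.default_rng(5)
        left = generate_bimodal_gray((0.1, 0.4), 0.5, 0.02, (32, 16), seed=1)
        right = generate_bimodal_gray((0.6, 0.95), 0.5, 0.02, (32, 16), seed=2)
        img = np.hstack([left, right])
        params = ThresholdParams(method="botsu", block=16, polarity="low_is_positive")
        mask = block_otsu(img, params).array
        levels = quantize(img)
        expected = np.zeros_like(levels, dtype=bool)
        for r0 in range(0, 32, 16):
            for c0 in range(0, 32, 16):
                cell = levels[r0 : r0 + 16, c0 : c0 + 16]
                t = brute_otsu(cell)
                expected[r0 : r0 + 16, c0 : c0 + 16] = cell < t
        assert np.array_equal(mask.astype(bool), expected)

    def test_image_smaller_than_block_equals_global_otsu(self):
        img = generate_bimodal_gray(size=(32, 32), seed=3)
        params = ThresholdParams(method="botsu", block=100, polarity="low_is_positive")
        mask = block_otsu(img, params).array
        t = otsu(img)
        assert np.array_equal(mask, (quantize(img) < t).astype(np.uint8))

    def test_constant_image_single_class_fallback(self):
        mask = block_otsu(np.full((20, 20), 0.3))
        assert mask.array.min() == mask.array.max()


class TestLocalDynamic:
    def test_constant_image_closed_form(self):
        """On a constant image s=0, so T = c*(1-k) < c: nothing below."""
        params = ThresholdParams(method="ldt", k=0.2, polarity="low_is_positive")
        mask = local_dynamic(np.full((16, 16), 0.5), params)
        assert mask.array.sum() == 0

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(11)
        img = rng.uniform(size=(9, 9))
        params = ThresholdParams(method="ldt", window_r=3, k=0.3, R=128.0,
                                 polarity="low_is_positive")
        mask = local_dynamic(img, params).array
        levels = quantize(img).astype(float)
        # edge-repeating reflection, matching the filter's border handling
        padded = np.pad(levels, 1, mode="symmetric")
        expected = np.zeros((9, 9), dtype=np.uint8)
        for i in range(9):
            for j in range(9):
                win = padded[i : i + 3, j : j + 3]
                m = win.mean()
                s = win.std()
                T = m * (1 + 0.3 * (s / 128.0 - 1))
                expected[i, j] = levels[i, j] < T
        assert np.array_equal(mask, expected)

    def test_k_to_zero_limit_is_local_mean(self):
        rng = np.random.default_rng(12)
        img = rng.uniform(size=(15, 15))
        params = ThresholdParams(method="ldt", window_r=5, k=1e-9,
                                 polarity="low_is_positive")
        mask = local_dynamic(img, params).array
        from scipy.ndimage import uniform_filter

        levels = quantize(img).astype(float)
        m = uniform_filter(levels, size=5, mode="reflect")
        assert np.array_equal(mask, (levels < m).astype(np.uint8))


class TestWellner:
    def test_constant_image_single_class(self):
        params = ThresholdParams(method="wat", s=4, polarity="low_is_positive")
        mask = wellner_adaptive(np.full((8, 8), 0.5), params)
        assert mask.array.sum() == 0

    def test_matches_scalar_transcription(self):
        rng = np.random.default_rng(21)
        img = rng.uniform(size=(6, 10))
        s, t_pct = 4, 15.0
        params = ThresholdParams(method="wat", s=s, t_pct=t_pct,
                                 polarity="low_is_positive")
        mask = wellner_adaptive(img, params).array
        levels = quantize(img).astype(float)
        serp = levels.copy()
        serp[1::2] = serp[1::2, ::-1]
        flat = serp.ravel()
        f = s * flat[0]
        expected = np.zeros(flat.size, dtype=np.uint8)
        for n, p in enumerate(flat):
            f = f * (1 - 1 / s) + p
            expected[n] = p < (f / s) * ((100 - t_pct) / 100)
        expected = expected.reshape(6, 10)
        expected[1::2] = expected[1::2, ::-1]
        assert np.array_equal(mask, expected)

    def test_zero_margin_compares_to_full_running_mean(self):
        img = np.array([[0.9, 0.9, 0.9, 0.1]])
        params = ThresholdParams(method="wat", s=2, t_pct=0.0,
                                 polarity="low_is_positive")
        mask = wellner_adaptive(img, params).array
        assert mask[0, -1] == 1  # the dark pixel falls below the running mean


class TestIterativeMethods:
    def test_two_value_image_converges_to_midpoint(self):
        img = np.array([40 / 255] * 50 + [220 / 255] * 50).reshape(10, 10)
        th = iterative_threshold(img)
        assert th == pytest.approx((40 + 220) / 2, abs=1.0)

    def test_large_eps_returns_initial_mean(self):
        img = generate_bimodal_gray(size=(16, 16), seed=4)
        th = iterative_threshold(img, eps=256.0)
        assert th == pytest.approx(quantize(img).mean(), abs=256)

    def test_cglt_agrees_with_itm_within_one_level(self):
        for img in _random_images(10, seed=55):
            if quantize(img).min() == quantize(img).max():
                continue
            assert abs(combined_global_local(img) - iterative_threshold(img, 1e-9)) <= 1.0

    def test_cglt_two_value_midpoint(self):
        img = np.array([40 / 255] * 50 + [220 / 255] * 50).reshape(10, 10)
        assert combined_global_local(img) == 130

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            iterative_threshold(np.full((4, 4), 0.2))
        with pytest.raises(DegenerateImageError):
            combined_global_local(np.full((4, 4), 0.2))


class TestDoublePeak:
    def test_constructed_valley(self):
        """Spikes at 50 and 200 with the histogram minimum at 120 between."""
        levels = np.concatenate([
            np.full(400, 50), np.full(300, 200),
            np.repeat(np.arange(51, 200), 2), [120],  # flat bridge, dip absent
        ])
        # carve a unique valley at 120 by removing its bridge counts
        levels = levels[levels != 120]
        img = levels / 255.0
        rng = np.random.default_rng(0)
        img = rng.permutation(img).reshape(1, -1)
        assert double_peak(img) == 120

    def test_extreme_second_peak(self):
        levels = np.concatenate([np.full(500, 0), np.full(10, 255), [128]])
        img = (levels / 255.0).reshape(1, -1)
        t = double_peak(img)
        assert 0 < t < 255


class TestMinErrorVariant:
    def test_kittler_variant_runs_and_differs_in_general(self):
        img = generate_bimodal_gray((0.25, 0.7), 0.3, 0.05, (32, 32), seed=8)
        t_lit = min_error(img)
        t_kit = min_error(img, kittler=True)
        assert 0 < t_lit <= 255 and 0 < t_kit <= 255

    def test_gaussian_mixture_recovery(self):
        rng = np.random.default_rng(17)
        a = rng.normal(60, 10, 600)
        b = rng.normal(180, 10, 400)
        img = np.clip(np.concatenate([a, b]) / 255.0, 0, 1).reshape(25, 40)
        t = min_error(img)
        assert t == brute_min_error(quantize(img))
        assert 60 < t < 180


class TestSegmentDispatch:
    def test_otsu_dispatch_equals_manual(self, rng):
        img = rng.uniform(size=(16, 16))
        t = otsu(img)
        manual = binarize(img, t, "low_is_positive").array
        via = segment(img, ThresholdParams(method="otsu", polarity="low_is_positive")).array
        assert np.array_equal(via, manual)

    def test_all_nine_methods_same_shape(self, rng):
        img = rng.uniform(size=(24, 24))
        masks = segment_all(img)
        assert set(masks) == set(METHODS)
        assert all(m.array.shape == (24, 24) for m in masks.values())

    def test_constant_plane_all_healthy_with_warning(self):
        with pytest.warns(UserWarning, match="all-healthy"):
            mask = segment(np.full((8, 8), 0.4), "otsu")
        assert mask.array.sum() == 0

    def test_scale_quantization_commutes(self, rng):
        img = rng.uniform(size=(12, 12))
        assert otsu(img) == otsu((img * 255).round() / 255)

    def test_all_nine_positive_csi_on_separable_scene(self, small_scene, small_stack):
        """Sanity floor: every thresholder achieves CSI > 0 on the scene's
        most informative index plane."""
        from phytoseg.metrics import confusion, csi

        _, truth = small_scene
        plane = small_stack.plane("ExGR")
        for method, mask in segment_all(plane).items():
            assert csi(confusion(mask, truth)) > 0, method
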