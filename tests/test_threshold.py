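"""Adaptive PWM-curve threshold selection."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from numpy.polynomial import Polynomial

from spherostack.threshold import (
    candidate_thresholds,
    compute_histogram,
    pwm_curve,
    score_candidate,
    select_initial_threshold,
)
from spherostack.types import GrayImage


def naive_pwm(hist):
    """Independent brute-force cumulative weighted mean (double loop)."""
    out = np.zeros(256)
    for p in range(256):
        num = den = 0.0
        for i in range(p + 1):
            num += hist[i] * i
            den += hist[i]
        out[p] = num / den if den > 0 else 0.0
    return out


class TestHistogram:
    def test_uniform_image_single_bin(self):
        img = GrayImage(np.full((2, 2), 7.0))
        h = compute_histogram(img)
        assert h[7] == 4 and h.sum() == 4

    def test_two_values(self):
        vals = np.zeros((8, 8))
        vals[:, 4:] = 255
        h = compute_histogram(GrayImage(vals))
        assert h[0] == 32 and h[255] == 32

    def test_conservation(self):
        rng = np.random.default_rng(0)
        img = GrayImage(rng.uniform(0, 255, (32, 32)))
        assert compute_histogram(img).sum() == 1024


class TestPWMCurve:
    def test_delta_mass(self):
        h = np.zeros(256, dtype=int)
        h[100] = 50
        curve = pwm_curve(h)
        assert np.all(curve[100:] == 100.0) and np.all(curve[:100] == 0.0)

    def test_symmetric_mass_midpoint(self):
        h = np.zeros(256, dtype=int)
        h[0] = 10
        h[200] = 10
        assert pwm_curve(h)[255] == pytest.approx(100.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            h = rng.integers(0, 500, 256)
            if h.sum() == 0:
                h[10] = 1
            np.testing.assert_allclose(pwm_curve(h), naive_pwm(h), atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pwm_curve(np.zeros(256))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(arrays(np.int64, (256,), elements=st.integers(0, 1000)))
    def test_monotone_and_bounded(self, h):
        if h.sum() == 0:
            h[0] = 1
        curve = pwm_curve(h)
        assert np.all(np.diff(curve) >= -1e-12)
        assert np.all(curve >= 0)
        assert np.all(curve <= np.arange(256) + 1e-12)


class TestCandidates:
    def test_cubic_inflection_recovered(self):
        p = np.arange(256.0)
        cubic = 1e-5 * (p - 128) ** 3 + 0.3 * (p - 128) + 60
        cands = candidate_thresholds(cubic - cubic.min())
        assert any(abs(c - 128) <= 1 for c in cands)
        assert all(abs(c - 128) <= 1 for c in cands)

    def test_constant_curve_no_inflection(self):
        assert candidate_thresholds(np.full(256, 5.0)) == []

    def test_candidates_are_sign_changes_of_fit(self, small_stack):
        """Every candidate sits at a concavity change of the fitted
        polynomial (dense second-difference scan as oracle)."""
        from spherostack.stack_io import extract_channel

        stack, _ = small_stack
        img = extract_channel(stack, "membrane", 20)
        curve = pwm_curve(compute_histogram(img))
        cands = candidate_thresholds(curve)
        assert cands, "multimodal membrane slice must yield candidates"
        poly = Polynomial.fit(np.arange(256.0), curve, 10, domain=[0, 255])
        grid = np.linspace(0, 255, 20001)
        d2 = np.diff(poly(grid), 2)
        sign = np.sign(d2)
        for c in cands:
            lo = np.searchsorted(grid, max(c - 1.5, 0))
            hi = np.searchsorted(grid, min(c + 1.5, 255))
            assert len(set(sign[lo:hi]) - {0.0}) == 2, f"no sign change at {c}"

    def test_in_range_integers(self, small_stack):
        from spherostack.stack_io import extract_channel

        stack, _ = small_stack
        for z in (10, 20):
            curve = pwm_curve(
                compute_histogram(extract_channel(stack, "membrane", z))
            )
            for c in candidate_thresholds(curve):
                assert isinstance(c, int) and 0 <= c <= 255


class TestScoring:
    def test_homogeneous_object_zero_std(self):
        img = np.full((20, 20), 10.0)
        img[5:15, 5:15] = 200.0
        cand = score_candidate(GrayImage(img), 100)
        assert cand.object_intensity_std == 0.0 and cand.n_objects == 1

    def test_two_value_foreground_sample_std(self):
        img = np.full((10, 10), 10.0)
        img[0:2, :] = 150.0
        img[2:4, :] = 250.0
        cand = score_candidate(GrayImage(img), 100)
        pixels = np.array([150.0] * 20 + [250.0] * 20)
        assert cand.object_intensity_std == pytest.approx(pixels.std(ddof=1))

    def test_max_threshold_invalid(self):
        img = GrayImage(np.full((10, 10), 128.0))
        cand = score_candidate(img, 255)
        assert not cand.valid and cand.n_objects == 0

    def test_min_object_area_excludes_debris(self):
        img = np.full((30, 30), 5.0)
        img[0, 0] = 200.0  # single-pixel speck
        img[10:20, 10:20] = 200.0
        cand = score_candidate(GrayImage(img), 100, min_object_area_px=4)
        assert cand.n_objects == 1 and cand.n_object_pixels == 100


class TestSelection:
    def test_bright_blob_isolated_from_background(self):
        """Graded bright blob on black: the selected threshold detects
        (part of) the blob and nothing of the background."""
        rng = np.random.default_rng(1)
        img = np.clip(rng.normal(8, 3, (80, 80)), 0, 255)
        yy, xx = np.ogrid[:80, :80]
        q = ((yy - 40) ** 2 + (xx - 40) ** 2) / 25**2
        blob = q <= 1.0
        img[blob] = 200.0 * (1.15 - 0.3 * q[blob])
        t = select_initial_threshold(GrayImage(img))
        mask = img > t
        assert mask.sum() > 200
        assert not mask[~blob].any()

    def test_invariant_under_tiling(self):
        rng = np.random.default_rng(2)
        img = np.clip(rng.normal(10, 4, (60, 60)), 0, 255)
        img[15:45, 15:45] = np.clip(rng.normal(180, 8, (30, 30)), 0, 255)
        t1 = select_initial_threshold(GrayImage(img))
        t2 = select_initial_threshold(GrayImage(np.tile(img, (2, 2))))
        assert t1 == t2

    def test_constant_image_yields_empty_foreground(self):
        img = GrayImage(np.full((16, 16), 40.0))
        t = select_initial_threshold(img)
        assert not (img.values8 > t).any()

    def test_otsu_fallback_when_no_candidate_valid(self, caplog):
        """Pure two-level image whose candidates all fail validity."""
        img = np.full((40, 40), 3.0)
        img[10:12, 10:12] = 250.0  # object far below any plausible min area
        t = select_initial_threshold(
            GrayImage(img), min_object_area_px=500
        )
        assert 0 <= t <= 255  # fallback always yields a threshold
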