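"""Segmentation agreement metrics and their identities."""
import numpy as np
import pytest

from conftest import disc_mask
from spherostack.metrics import (
    ConfusionCounts,
    confusion,
    count_agreement,
    scores,
    shell_scores,
)
from spherostack.types import BinaryMask

PX = 0.345


def naive_confusion(a, b):
    """Independent per-pixel triple count."""
    tp = fp = fn = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if a[i, j] and b[i, j]:
                tp += 1
            elif b[i, j]:
                fp += 1
            elif a[i, j]:
                fn += 1
    return tp, fp, fn


def random_pair(rng, shape=(24, 24)):
    return (
        BinaryMask(rng.uniform(size=shape) > 0.5, PX),
        BinaryMask(rng.uniform(size=shape) > 0.5, PX),
    )


class TestConfusion:
    def test_identical(self):
        m = BinaryMask(disc_mask((40, 40), (20, 20), 12), PX)
        c = confusion(m, m)
        assert (c.tp, c.fp, c.fn) == (int(m.values.sum()), 0, 0)

    def test_disjoint(self):
        a = np.zeros((30, 30), dtype=bool)
        a[:10, :10] = True
        b = np.zeros((30, 30), dtype=bool)
        b[15:25, 5:25] = True
        c = confusion(BinaryMask(a, PX), BinaryMask(b, PX))
        assert (c.tp, c.fn, c.fp) == (0, 100, 200)

    def test_subset(self):
        a = np.zeros((20, 20), dtype=bool)
        a[0:10, 0:10] = True  # 100 px manual
        b = np.zeros((20, 20), dtype=bool)
        b[0:10, 0:8] = True  # 80 px subset
        c = confusion(BinaryMask(a, PX), BinaryMask(b, PX))
        assert (c.tp, c.fn, c.fp) == (80, 20, 0)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_pair(rng, (16, 16))
            c = confusion(a, b)
            assert (c.tp, c.fp, c.fn) == naive_confusion(a.values, b.values)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion(
                BinaryMask(np.zeros((4, 4), bool), PX),
                BinaryMask(np.zeros((5, 5), bool), PX),
            )


class TestScores:
    def test_worked_subset_case(self):
        rep = scores(ConfusionCounts(tp=80, fp=0, fn=20))
        assert rep.recall == pytest.approx(0.8)
        assert rep.precision == pytest.approx(1.0)
        assert rep.f1 == pytest.approx(8.0 / 9.0, abs=1e-4)
        assert rep.jaccard == pytest.approx(0.8)

    def test_identity_and_disjoint(self):
        perfect = scores(ConfusionCounts(500, 0, 0))
        assert (perfect.recall, perfect.precision, perfect.f1, perfect.jaccard) == (
            1.0,
            1.0,
            1.0,
            1.0,
        )
        nothing = scores(ConfusionCounts(0, 200, 100))
        assert (nothing.recall, nothing.precision, nothing.f1, nothing.jaccard) == (
            0.0,
            0.0,
            0.0,
            0.0,
        )

    def test_empty_masks_flagged_not_raising(self):
        rep = scores(ConfusionCounts(0, 0, 0))
        assert rep.degenerate and rep.f1 == 0.0

    def test_identities_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = random_pair(rng)
            ra = scores(confusion(a, b))
            rb = scores(confusion(b, a))
            if ra.recall + ra.precision > 0:
                assert ra.f1 == pytest.approx(
                    2 * ra.recall * ra.precision / (ra.recall + ra.precision)
                )
            c = confusion(a, b)
            assert ra.jaccard == pytest.approx(c.tp / (c.tp + c.fp + c.fn))
            if ra.f1 > 0:
                assert ra.jaccard == pytest.approx(ra.f1 / (2 - ra.f1))
            assert ra.recall == pytest.approx(rb.precision)
            assert ra.jaccard == pytest.approx(rb.jaccard)
            assert 0 <= ra.jaccard <= ra.f1 <= 1


class TestShellScores:
    def _scene(self):
        membrane = BinaryMask(disc_mask((140, 140), (70, 70), 50), PX)
        manual = BinaryMask(disc_mask((140, 140), (70, 70), 30), PX)
        return membrane, manual

    def test_zero_width_shell_degenerate(self):
        membrane, manual = self._scene()
        inner, outer = shell_scores(manual, manual, membrane, shell_width_um=0.0)
        assert outer.degenerate
        glob = scores(confusion(manual, manual))
        assert inner.recall == glob.recall and inner.jaccard == glob.jaccard

    def test_errors_in_outer_ring_lower_outer_precision_only(self):
        membrane, manual = self._scene()
        auto = manual.values.copy()
        ring = disc_mask((140, 140), (70, 70), 48) & ~disc_mask(
            (140, 140), (70, 70), 44
        )
        auto |= ring  # false positives placed only near the border
        inner, outer = shell_scores(
            manual, BinaryMask(auto, PX), membrane, shell_width_um=10 * PX
        )
        assert inner.precision == pytest.approx(1.0)
        assert outer.precision < 1.0

    def test_tp_conservation_across_shells(self):
        rng = np.random.default_rng(2)
        membrane, _ = self._scene()
        a = BinaryMask((rng.uniform(size=(140, 140)) > 0.5) & membrane.values, PX)
        b = BinaryMask((rng.uniform(size=(140, 140)) > 0.5) & membrane.values, PX)
        for width in (3.0, 7.0, 20.0):
            inner, outer = shell_scores(a, b, membrane, shell_width_um=width)
            glob = confusion(
                BinaryMask(a.values & membrane.values, PX),
                BinaryMask(b.values & membrane.values, PX),
            )
            itp = scores_tp(a, b, membrane, width)
            assert itp == glob.tp

    def test_uniform_errors_similar_inner_outer(self):
        rng = np.random.default_rng(3)
        membrane, manual = self._scene()
        flips = rng.uniform(size=(140, 140)) > 0.9
        auto = BinaryMask(np.where(flips, ~manual.values, manual.values) & membrane.values, PX)
        manual_g = BinaryMask(manual.values & membrane.values, PX)
        inner, outer = shell_scores(manual_g, auto, membrane, shell_width_um=8.0)
        assert abs(inner.recall - outer.recall) < 0.1


def scores_tp(a, b, membrane, width):
    from scipy import ndimage

    depth = ndimage.distance_transform_edt(membrane.values)
    shell_px = width / membrane.pixel_size_xy
    inner = membrane.values & (depth > shell_px)
    outer = membrane.values & (depth <= shell_px)
    tp_i = int((a.values & b.values & inner).sum())
    tp_o = int((a.values & b.values & outer).sum())
    return tp_i + tp_o


class TestCountAgreement:
    @pytest.mark.parametrize(
        "manual,auto,diff,rel",
        [(80, 80, 0, 0.0), (100, 90, -10, -0.10), (50, 60, 10, 0.20)],
    )
    def test_arithmetic(self, manual, auto, diff, rel):
        d, r = count_agreement(manual, auto)
        assert d == diff and r == pytest.approx(rel)

    def test_zero_manual_guarded(self):
        d, r = count_agreement(0, 3)
        assert d == 3 and r is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            count_agreement(-1, 2)
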