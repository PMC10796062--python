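"""Metric suite vs hand counts and a brute-force distance oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from denseunet.containers import RegionMasks, ValidationError
from denseunet.losses import dice_loss
from denseunet.metrics import (
    ConfusionCounts,
    confusion,
    dice,
    evaluate,
    hausdorff,
    iou,
    ppv,
    sensitivity,
)

PRED = np.array([[1, 1], [1, 0]], dtype=bool)
TARGET = np.array([[0, 1], [1, 1]], dtype=bool)


def brute_force_hausdorff(a: np.ndarray, b: np.ndarray, percentile: float) -> float:
    """Exhaustive all-pairs oracle for the (percentile) Hausdorff distance."""
    pa, pb = np.argwhere(a), np.argwhere(b)
    d_ab = [min(np.linalg.norm(p - q) for q in pb) for p in pa]
    d_ba = [min(np.linalg.norm(q - p) for p in pa) for q in pb]
    if percentile >= 100:
        return max(max(d_ab), max(d_ba))
    return float(np.percentile(np.array(d_ab + d_ba), percentile))


class TestConfusion:
    def test_hand_count(self):
        c = confusion(PRED, TARGET)
        assert (c.tp, c.fp, c.fn) == (2, 1, 1)

    def test_identical_masks(self):
        c = confusion(TARGET, TARGET)
        assert c.fp == 0 and c.fn == 0 and c.tp == int(TARGET.sum())

    def test_all_ones_vs_all_zeros(self):
        c = confusion(np.ones((3, 3), bool), np.zeros((3, 3), bool))
        assert (c.tp, c.fp, c.fn) == (0, 9, 0)

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError, match="binary"):
            confusion(np.array([[0, 2]]), np.array([[0, 1]]))


class TestOverlapMetrics:
    def test_hand_counts_give_two_thirds(self):
        c = ConfusionCounts(tp=2, fp=1, fn=1)
        assert dice(c) == pytest.approx(2 / 3)
        assert ppv(c) == pytest.approx(2 / 3)
        assert sensitivity(c) == pytest.approx(2 / 3)

    def test_perfect_segmentation(self):
        c = ConfusionCounts(tp=5, fp=0, fn=0)
        assert dice(c) == ppv(c) == sensitivity(c) == 1.0

    def test_both_empty_convention(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0)
        assert dice(c) == ppv(c) == sensitivity(c) == 1.0

    def test_one_sided_empty_conventions(self):
        assert ppv(ConfusionCounts(0, 0, 3)) == 0.0  # empty prediction
        assert sensitivity(ConfusionCounts(0, 3, 0)) == 0.0  # empty target

    @settings(deadline=None, max_examples=60)
    @given(
        arrays(np.int8, (6, 6), elements=st.sampled_from([0, 1])),
        arrays(np.int8, (6, 6), elements=st.sampled_from([0, 1])),
    )
    def test_harmonic_identity_and_symmetries(self, a, b):
        a, b = a.astype(bool), b.astype(bool)
        c = confusion(a, b)
        d, p, s = dice(c), ppv(c), sensitivity(c)
        if p + s > 0:
            assert d == pytest.approx(2 * p * s / (p + s), abs=1e-12)
        cr = confusion(b, a)
        assert dice(cr) == pytest.approx(d, abs=1e-12)
        assert ppv(cr) == pytest.approx(sensitivity(c), abs=1e-12)

    def test_iou_hand_count_and_extremes(self):
        assert iou(PRED, TARGET) == pytest.approx(0.5)  # 2 / (2+1+1)
        assert iou(TARGET, TARGET) == 1.0
        a = np.zeros((3, 3), bool)
        a[0, 0] = True
        b = np.zeros((3, 3), bool)
        b[2, 2] = True
        assert iou(a, b) == 0.0

    def test_dice_count_equals_one_minus_soft_dice_loss(self, rng):
        a = rng.uniform(size=(7, 7)) > 0.5
        b = rng.uniform(size=(7, 7)) > 0.5
        c = confusion(a, b)
        assert dice(c) == pytest.approx(
            1 - dice_loss(a.astype(float), b.astype(float), smooth=1e-12).item(),
            abs=1e-9,
        )


class TestHausdorff:
    def test_two_single_points(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hausdorff(a, b, percentile=100) == pytest.approx(5.0)

    def test_identical_masks_zero(self):
        assert hausdorff(TARGET, TARGET, percentile=100) == 0.0
        assert hausdorff(TARGET, TARGET, percentile=95) == 0.0

    @settings(deadline=None, max_examples=40)
    @given(
        arrays(np.int8, (8, 8), elements=st.sampled_from([0, 1])),
        arrays(np.int8, (8, 8), elements=st.sampled_from([0, 1])),
        st.sampled_from([95.0, 100.0]),
    )
    def test_matches_brute_force_oracle(self, a, b, percentile):
        a, b = a.astype(bool), b.astype(bool)
        if not a.any() or not b.any():
            return
        got = hausdorff(a, b, percentile=percentile)
        want = brute_force_hausdorff(a, b, percentile)
        assert got == pytest.approx(want, abs=1e-9)

    def test_symmetric_at_percentile_100(self, rng):
        a = rng.uniform(size=(8, 8)) > 0.6
        b = rng.uniform(size=(8, 8)) > 0.6
        assert hausdorff(a, b, 100) == pytest.approx(hausdorff(b, a, 100))

    def test_scaled_max_variant(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        got = hausdorff(a, b, percentile=95, method="scaled_max")
        assert got == pytest.approx(0.95 * 5.0)

    def test_empty_mask_sentinel_and_both_empty(self):
        empty = np.zeros((6, 8), bool)
        full = ~empty
        assert hausdorff(empty, empty) == 0.0
        assert hausdorff(empty, full) == pytest.approx(np.hypot(6, 8))


class TestEvaluate:
    @staticmethod
    def _masks(labels):
        from denseunet.preprocess import labels_to_regions

        return labels_to_regions(labels)

    def test_perfect_predictions_score_one(self, rng):
        labels = rng.choice([0, 1, 2, 4], size=(12, 12))
        m = self._masks(labels)
        report = evaluate([m, m], [m, m])
        for region in ("wt", "tc", "et"):
            row = report.summary.loc[region]
            assert row["dice"] == row["ppv"] == row["sensitivity"] == row["iou"] == 1.0
            assert row["hd95"] == 0.0

    def test_single_sample_matches_direct_ops(self, rng):
        a = self._masks(rng.choice([0, 1, 2, 4], size=(10, 10)))
        b = self._masks(rng.choice([0, 1, 2, 4], size=(10, 10)))
        report = evaluate([a], [b])
        row = report.per_sample.set_index("region").loc["tc"]
        c = confusion(a.tc, b.tc)
        assert row["dice"] == pytest.approx(dice(c))
        assert row["hd95"] == pytest.approx(hausdorff(a.tc, b.tc, 95))
        assert row["iou"] == pytest.approx(iou(a.tc, b.tc))

    def test_degenerate_samples_are_flagged(self):
        empty = RegionMasks(*(np.zeros((4, 4), bool),) * 3)
        some = self._masks(np.full((4, 4), 4))
        report = evaluate([empty], [some])
        assert report.per_sample["flag"].all()
        assert (report.summary["dice"] == 0.0).all()

    def test_length_mismatch_rejected(self):
        m = self._masks(np.zeros((4, 4), dtype=int))
        with pytest.raises(ValidationError):
            evaluate([m], [m, m])

    def test_report_serializes(self, tmp_path, rng):
        m = self._masks(rng.choice([0, 1, 2, 4], size=(8, 8)))
        report = evaluate([m], [m])
        report.to_csv(tmp_path / "r.csv")
        report.to_json(tmp_path / "r.json")
        import json

        summary = json.loads((tmp_path / "r.json").read_text())
        assert set(summary) == {"wt", "tc", "et"}
        assert summary["wt"]["dice"] == 1.0
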