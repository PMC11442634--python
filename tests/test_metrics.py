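"""Metric and loss correctness against hand-computed values and
independent oracles (brute-force Hausdorff, erosion-based boundaries)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import cdist

from polypnextlstm.metrics import (
    MetricReport,
    aggregate_by_attribute,
    bce_loss,
    boundary_pixels,
    dice_bce_loss,
    dice_loss,
    dice_score,
    hd95,
    iou_score,
    recall_score,
)


def random_mask(rng, shape=(16, 16), p=0.3):
    return rng.random(shape) < p


# ---------------------------------------------------------------------------
# losses


class TestLoss:
    def test_perfect_binary_prediction_is_zero(self):
        target = np.zeros((4, 4))
        target[1:3, 1:3] = 1
        # smoothing cancels exactly in the dice term; bce only the clip eps
        assert dice_loss(target, target) == 0.0
        assert dice_bce_loss(target, target) < 1e-5

    def test_dice_term_all_ones_two_positives(self):
        probs = np.ones((2, 2))
        target = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert dice_loss(probs, target) == pytest.approx(1 - 5 / 7)

    def test_bce_half_probs(self):
        probs = np.full((3, 3), 0.5)
        target = np.ones((3, 3))
        assert bce_loss(probs, target) == pytest.approx(np.log(2), rel=1e-9)

    def test_out_of_range_probs_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dice_bce_loss(np.full((2, 2), 1.5), np.ones((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_bce_loss(np.ones((2, 2)), np.ones((3, 3)))

    def test_dice_term_averages_over_frames(self):
        probs = np.stack([np.ones((2, 2)), np.zeros((2, 2))])
        target = np.stack([np.ones((2, 2)), np.zeros((2, 2))])
        # frame 1 perfect, frame 2 both-empty (dice term 0 via smoothing)
        assert dice_loss(probs, target) == 0.0

    def test_loss_positive_for_imperfect_prediction(self, rng):
        probs = rng.random((4, 4))
        target = (rng.random((4, 4)) < 0.5).astype(float)
        assert dice_bce_loss(probs, target) > 0


# ---------------------------------------------------------------------------
# overlap metrics


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        m = random_mask(rng)
        assert dice_score(m, m) == 1.0
        assert iou_score(m, m) == 1.0
        assert recall_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert dice_score(a, b) == 0.0
        assert iou_score(a, b) == 0.0
        assert recall_score(a, b) == 0.0

    def test_hand_computed_overlaps(self):
        pred = np.zeros((4, 4), bool)
        gt = np.zeros((4, 4), bool)
        pred[0, :4] = True          # |P| = 4
        gt[0, :2] = True            # |G| = 2, |P&G| = 2
        assert dice_score(pred, gt) == pytest.approx(2 * 2 / 6)
        assert iou_score(pred, gt) == pytest.approx(0.5)

    def test_recall_three_of_four(self):
        gt = np.zeros((4, 4), bool)
        gt[0, :4] = True
        pred = gt.copy()
        pred[0, 3] = False
        assert recall_score(pred, gt) == 0.75

    def test_superset_prediction_full_recall(self, rng):
        gt = random_mask(rng)
        gt[0, 0] = True
        pred = gt | random_mask(rng)
        assert recall_score(pred, gt) == 1.0

    def test_empty_conventions(self):
        empty = np.zeros((4, 4), bool)
        some = ~empty
        assert dice_score(empty, empty) == 1.0
        assert iou_score(empty, empty) == 1.0
        assert recall_score(some, empty) == 1.0

    def test_dim_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_score(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_dice_iou_identity_on_random_pairs(self, rng):
        for _ in range(200):
            a, b = random_mask(rng), random_mask(rng)
            d, i = dice_score(a, b), iou_score(a, b)
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_dice_iou_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask(rng, (8, 8)), random_mask(rng, (8, 8))
        d, i = dice_score(a, b), iou_score(a, b)
        assert abs(d - 2 * i / (1 + i)) < 1e-12


# ---------------------------------------------------------------------------
# HD95


def brute_force_hd95(pred, gt):
    """Independent oracle: erosion-based boundaries + full distance matrix."""
    plus = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)

    def boundary(mask):
        interior = binary_erosion(mask, structure=plus, border_value=0)
        return np.argwhere(mask & ~interior)

    bp, bg = boundary(pred), boundary(gt)
    d = cdist(bp, bg)
    return max(np.percentile(d.min(axis=1), 95),
               np.percentile(d.min(axis=0), 95))


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        m[5, 5] = True
        assert hd95(m, m) == 0.0

    def test_single_pixel_distance(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hd95(a, b) == pytest.approx(5.0)

    def test_percentile_interpolation_case(self):
        pred = np.zeros((1, 11), bool)
        pred[0, 0] = pred[0, 10] = True
        gt = np.zeros((1, 11), bool)
        gt[0, 0] = True
        # directed pred->gt distances {0, 10}: perc95 = 9.5
        assert hd95(pred, gt) == pytest.approx(9.5)

    def test_matches_brute_force_on_random_masks(self, rng):
        checked = 0
        while checked < 20:
            a = random_mask(rng, (12, 12), p=0.2)
            b = random_mask(rng, (12, 12), p=0.2)
            if not (a.any() and b.any()):
                continue
            if len(boundary_pixels(a)) > 50 or len(boundary_pixels(b)) > 50:
                continue
            assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b))
            checked += 1

    def test_never_exceeds_full_hausdorff(self, rng):
        for _ in range(20):
            a, b = random_mask(rng, (10, 10)), random_mask(rng, (10, 10))
            if not (a.any() and b.any()):
                continue
            bp, bg = boundary_pixels(a), boundary_pixels(b)
            d = cdist(bp, bg)
            full = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hd95(a, b) <= full + 1e-12

    def test_empty_mask_conventions(self):
        empty = np.zeros((3, 4), bool)
        one = np.zeros((3, 4), bool)
        one[1, 1] = True
        assert hd95(empty, empty) == 0.0
        assert hd95(one, empty) == pytest.approx(5.0)  # image diagonal

    def test_boundary_definition(self):
        # a filled 3x3 square: centre pixel is interior, ring is boundary
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        bpix = {tuple(p) for p in boundary_pixels(m)}
        assert (2, 2) not in bpix
        assert len(bpix) == 8
        # edge-touching pixels are boundary even when 4-neighboured
        m2 = np.ones((3, 3), bool)
        assert len(boundary_pixels(m2)) == 8


# ---------------------------------------------------------------------------
# aggregation


class TestAggregation:
    def test_single_clip_single_attribute(self):
        out = aggregate_by_attribute({"c1": 0.8}, {"c1": {"FM"}})
        assert out == {"FM": 0.8}

    def test_clip_contributes_to_every_attribute(self):
        out = aggregate_by_attribute(
            {"a": 0.6, "b": 0.8},
            {"a": {"FM", "SO"}, "b": {"FM"}},
        )
        assert out["FM"] == pytest.approx(0.7)
        assert out["SO"] == pytest.approx(0.6)

    def test_absent_attribute_not_reported(self):
        out = aggregate_by_attribute({"a": 0.5}, {"a": {"SO"}})
        assert "LO" not in out

    def test_unknown_attribute_rejected(self):
        with pytest.raises(ValueError, match="unknown attribute"):
            aggregate_by_attribute({"a": 0.5}, {"a": {"XX"}})

    def test_report_aggregate_and_frame(self):
        report = MetricReport(per_clip={
            "c1": {"dice": 0.8, "iou": 0.7, "hd95": 2.0, "recall": 0.9},
            "c2": {"dice": 0.6, "iou": 0.5, "hd95": 4.0, "recall": 0.7},
        })
        assert report.aggregate["dice"] == pytest.approx(0.7)
        assert report.aggregate["hd95"] == pytest.approx(3.0)
        df = report.to_frame()
        assert list(df.columns) == ["clip_id", "dice", "iou", "hd95", "recall"]
        assert len(df) == 2
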