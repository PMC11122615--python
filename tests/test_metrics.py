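"""Dice, distance-to-agreement, and the edge/area error decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fafseg import (
    ae_ratio_curve,
    confusion,
    dice,
    dice_ae,
    dice_ae_curve,
    distance_to_tp,
    image_diagonal,
    mean_dice_ae,
    partition_errors,
)

from conftest import random_blob_mask


def row_mask(shape, cols):
    m = np.zeros(shape, dtype=bool)
    m[0, list(cols)] = True
    return m


def oracle_dice_ae(pred, ref, mu_ee):
    """Independent recomputation: brute-force pairwise distances to TP."""
    tp = pred & ref
    err = pred ^ ref
    n_tp = tp.sum()
    if err.sum() == 0:
        d = np.zeros(0)
    elif n_tp == 0:
        d = np.full(err.sum(), image_diagonal(pred.shape))
    else:
        ty, tx = np.nonzero(tp)
        ey, ex = np.nonzero(err)
        d = np.sqrt(
            (ey[:, None] - ty[None, :]) ** 2 + (ex[:, None] - tx[None, :]) ** 2
        ).min(axis=1)
    n_ae = int((d > mu_ee).sum())
    denom = 2 * n_tp + n_ae
    return 1.0 if denom == 0 else 2.0 * n_tp / denom


class TestConfusionAndDice:
    @pytest.mark.parametrize(
        "pred_cols, ref_cols, expect",
        [
            (range(5), range(5), (5, 0, 0)),  # identical
            ((), range(5), (0, 0, 5)),  # prediction empty
            (range(0, 4), range(2, 6), (2, 2, 2)),  # partial overlap
        ],
    )
    def test_counts(self, pred_cols, ref_cols, expect):
        pred, ref = row_mask((4, 8), pred_cols), row_mask((4, 8), ref_cols)
        c = confusion(pred, ref)
        assert (c.tp, c.fp, c.fn) == expect
        assert c.tp + c.fp + c.fn + c.tn == pred.size

    @pytest.mark.parametrize(
        "pred_cols, ref_cols, expect",
        [(range(3), range(3), 1.0), (range(3), range(4, 7), 0.0), (range(0, 4), range(2, 6), 0.5)],
    )
    def test_dice_values(self, pred_cols, ref_cols, expect):
        assert dice(row_mask((4, 8), pred_cols), row_mask((4, 8), ref_cols)) == expect

    def test_both_empty_convention(self):
        empty = np.zeros((5, 5), dtype=bool)
        assert dice(empty, empty) == 1.0

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestDistanceToAgreement:
    def test_adjacent_and_pythagorean_distances(self):
        pred = np.zeros((8, 8), bool)
        ref = np.zeros((8, 8), bool)
        pred[0, 0] = ref[0, 0] = True  # TP at origin
        pred[3, 4] = True  # FP at (3,4)
        pred[0, 1] = True  # FP 4-adjacent to TP
        d = distance_to_tp(pred, ref)
        assert d[0, 0] == 0.0
        assert d[0, 1] == 1.0
        assert d[3, 4] == pytest.approx(5.0)

    def test_empty_tp_uses_image_diagonal(self):
        pred = np.zeros((768, 768), bool)
        ref = np.zeros((768, 768), bool)
        ref[10, 10] = True
        d = distance_to_tp(pred, ref)
        assert d[10, 10] == pytest.approx(math.sqrt(2 * 768**2))
        assert d[10, 10] == pytest.approx(1086.1, abs=0.05)


class TestErrorPartition:
    def test_threshold_zero_gives_no_edge_errors(self):
        pred, ref = row_mask((4, 8), range(0, 4)), row_mask((4, 8), range(2, 6))
        part = partition_errors(pred, ref, mu_ee=0)
        assert part.n_ee == 0
        assert part.n_ae == part.fp + part.fn

    def test_distance_exactly_at_threshold_is_edge_error(self):
        pred = np.zeros((8, 12), bool)
        ref = np.zeros((8, 12), bool)
        pred[0, 0] = ref[0, 0] = True
        pred[0, 5] = True  # error pixel at distance exactly 5
        part = partition_errors(pred, ref, mu_ee=5)
        assert part.n_ee == 1 and part.n_ae == 0

    def test_huge_threshold_absorbs_everything(self):
        pred, ref = row_mask((4, 8), range(0, 4)), row_mask((4, 8), range(2, 6))
        part = partition_errors(pred, ref, mu_ee=image_diagonal((4, 8)))
        assert part.n_ae == 0

    def test_partition_is_exhaustive_and_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = random_blob_mask(rng, (48, 48))
            b = random_blob_mask(rng, (48, 48))
            mu = rng.uniform(0, 15)
            pa, pb = partition_errors(a, b, mu), partition_errors(b, a, mu)
            assert pa.n_ee + pa.n_ae == pa.fp + pa.fn
            assert (pa.n_ee, pa.n_ae) == (pb.n_ee, pb.n_ae)


class TestAdjustedDice:
    def test_hand_value(self):
        # 2 TP, 2 remaining area errors -> 4/6
        pred = np.zeros((1, 16), bool)
        ref = np.zeros((1, 16), bool)
        pred[0, [0, 1]] = ref[0, [0, 1]] = True
        pred[0, 10] = True
        ref[0, 14] = True
        assert dice_ae(pred, ref, mu_ee=2) == pytest.approx(2 * 2 / (2 * 2 + 2))

    def test_matches_dice_at_zero_and_one_beyond_diagonal(self):
        rng = np.random.default_rng(1)
        a, b = random_blob_mask(rng, (48, 48)), random_blob_mask(rng, (48, 48))
        assert dice_ae(a, b, 0) == pytest.approx(dice(a, b), abs=1e-12)
        if (a & b).any():
            assert dice_ae(a, b, image_diagonal(a.shape)) == 1.0

    def test_curve_monotone_and_bounded_below_by_dice(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = random_blob_mask(rng, (48, 48)), random_blob_mask(rng, (48, 48))
            curve = dice_ae_curve(a, b, mu_ee_max=40)
            assert (np.diff(curve) >= -1e-12).all()
            assert (curve >= dice(a, b) - 1e-12).all()

    def test_mean_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = random_blob_mask(rng, (40, 40)), random_blob_mask(rng, (40, 40))
            expected = np.mean([oracle_dice_ae(a, b, t) for t in range(31)])
            assert mean_dice_ae(a, b, mu_ee_max=30) == pytest.approx(expected, abs=1e-9)

    def test_identical_masks_score_one(self):
        rng = np.random.default_rng(4)
        a = random_blob_mask(rng, (32, 32))
        assert mean_dice_ae(a, a) == 1.0

    def test_no_overlap_scores_zero(self):
        pred = np.zeros((768, 768), bool)
        ref = np.zeros((768, 768), bool)
        ref[:20, :20] = True
        assert mean_dice_ae(pred, ref, mu_ee_max=100) == 0.0


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000), mu=st.floats(0, 30))
def test_adjusted_dice_never_below_dice(seed, mu):
    rng = np.random.default_rng(seed)
    a, b = random_blob_mask(rng, (32, 32)), random_blob_mask(rng, (32, 32))
    assert dice_ae(a, b, mu) >= dice(a, b) - 1e-12
    assert dice(a, b) == pytest.approx(dice(b, a), abs=1e-12)


class TestAeRatioCurve:
    def test_identical_annotations_give_empty_curve(self):
        m = random_blob_mask(np.random.default_rng(5), (32, 32))
        assert ae_ratio_curve(np.stack([m, m, m])).size == 0

    def test_disjoint_pair_pins_ratio_at_one(self):
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[2:6, 2:6] = True
        b[20:24, 20:24] = True
        curve = ae_ratio_curve(np.stack([a, b]), thresholds=np.arange(20))
        assert (curve == 1.0).all()  # no mutual overlap: area error by default

    def test_curve_non_increasing(self, expert_stack):
        curve = ae_ratio_curve(expert_stack, thresholds=np.arange(30))
        assert (np.diff(curve) <= 1e-12).all()

    def test_needs_two_annotations(self):
        with pytest.raises(ValueError):
            ae_ratio_curve(np.zeros((1, 8, 8), bool))
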