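"""Ternary map construction rules and the six-metric agreement suite."""

import numpy as np
import pytest

from fafseg import (
    B,
    C,
    P,
    aggregate_reports,
    ternary_collapse,
    ternary_from_annotation_stack,
    ternary_from_mean_variance,
    ternary_from_probability,
    ternary_metrics,
)


class TestFromMeanVariance:
    def test_zero_variance_splits_on_mean(self):
        mean = np.zeros((4, 4))
        mean[:2] = 1.0
        t = ternary_from_mean_variance(mean, np.zeros((4, 4)))
        assert (t[:2] == C).all() and (t[2:] == B).all()

    def test_high_variance_wins_over_mean(self):
        t = ternary_from_mean_variance(np.full((1, 1), 0.5), np.full((1, 1), 0.25), 0.2, 0.1)
        assert t[0, 0] == P

    def test_low_mean_low_variance_is_confident_above_strict_threshold(self):
        t = ternary_from_mean_variance(np.full((1, 1), 0.3), np.full((1, 1), 0.01), 0.2, 0.1)
        assert t[0, 0] == C

    def test_mean_exactly_at_threshold_is_background(self):
        t = ternary_from_mean_variance(np.full((1, 1), 0.2), np.zeros((1, 1)), 0.2, 0.1)
        assert t[0, 0] == B


class TestFromProbability:
    def test_hard_binary_map_has_no_potential(self):
        p = (np.arange(16).reshape(4, 4) % 2).astype(float)
        t = ternary_from_probability(p, 0.9, 0.1)
        assert not (t == P).any()
        assert ((t == C) == (p == 1)).all()

    def test_intermediate_values_are_potential(self):
        assert (ternary_from_probability(np.full((3, 3), 0.5)) == P).all()

    def test_thresholds_are_inclusive(self):
        t = ternary_from_probability(np.array([[0.9, 0.1]]), 0.9, 0.1)
        assert t[0, 0] == C and t[0, 1] == B

    def test_rejects_inverted_thresholds(self):
        with pytest.raises(ValueError):
            ternary_from_probability(np.zeros((2, 2)), mu_c=0.1, mu_p=0.9)


class TestFromAnnotationStack:
    def test_count_thresholds(self):
        stack = np.zeros((5, 1, 4), dtype=bool)
        stack[:, 0, 0] = True  # all five raters
        stack[:2, 0, 1] = True  # two raters
        stack[:1, 0, 2] = True  # one rater
        t = ternary_from_annotation_stack(stack, mu_a_c=5, mu_a_p=2)
        assert list(t[0]) == [C, P, B, B]

    def test_single_rater_path_has_no_potential(self):
        stack = np.random.default_rng(0).random((1, 8, 8)) > 0.5
        t = ternary_from_annotation_stack(stack, mu_a_c=1, mu_a_p=1)
        assert not (t == P).any()

    def test_thresholds_must_fit_rater_count(self):
        with pytest.raises(ValueError):
            ternary_from_annotation_stack(np.zeros((3, 2, 2), bool), mu_a_c=5, mu_a_p=2)


class TestCollapse:
    def test_all_p_is_uniform(self, expert_stack):
        t = ternary_from_annotation_stack(expert_stack, 5, 2)
        assert (ternary_collapse(t, "all_P") == P).all()

    def test_all_c_merges_potential_into_confident(self):
        t = np.full((4, 4), B, dtype=np.uint8)
        t[0, 0] = C
        t[0, 1] = t[0, 2] = P
        out = ternary_collapse(t, "all_C")
        assert (out == C).sum() == 3 and (out == B).sum() == 13

    def test_all_c_without_potential_is_identity(self):
        t = np.full((3, 3), B, dtype=np.uint8)
        t[1, 1] = C
        assert (ternary_collapse(t, "all_C") == t).all()


class TestTernaryMetrics:
    def test_perfect_agreement(self):
        t = np.full((4, 4), B, dtype=np.uint8)
        t[:2, :2] = C
        r = ternary_metrics(t, t)
        assert r.precision_c == 1.0 and r.recall_cp == 1.0 and r.dcs_cp == 1.0

    def test_worked_two_by_two_example(self):
        annot = np.array([[C, P], [B, B]], dtype=np.uint8)
        pred = np.array([[C, P], [C, B]], dtype=np.uint8)
        r = ternary_metrics(pred, annot)
        assert r.precision_c == 0.5
        assert r.recall_cp == 1.0
        assert r.precision_c_to_cp == 0.5
        assert r.recall_cp_to_c == 1.0
        assert r.precision_cp == pytest.approx(2 / 3)
        assert r.dcs_cp == pytest.approx(0.8)

    def test_single_annotation_collapses_metric_pairs(self):
        rng = np.random.default_rng(1)
        annot = np.where(rng.random((16, 16)) > 0.6, C, B).astype(np.uint8)
        pred = np.select(
            [rng.random((16, 16)) > 0.7, rng.random((16, 16)) > 0.5],
            [C, P], default=B).astype(np.uint8)
        r = ternary_metrics(pred, annot)
        assert r.precision_c == r.precision_c_to_cp
        assert r.recall_cp == r.recall_cp_to_c

    def test_all_potential_predictor_degenerates(self, expert_stack):
        annot = ternary_from_annotation_stack(expert_stack, 5, 2)
        assert (annot != B).any()
        r = ternary_metrics(ternary_collapse(annot, "all_P"), annot)
        assert r.recall_cp == 1.0 and r.recall_cp_to_c == 1.0
        assert r.precision_c is None and r.precision_c_to_cp is None
        assert r.precision_cp is not None and r.dcs_cp is not None

    def test_dice_is_harmonic_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pred = rng.integers(0, 3, (12, 12)).astype(np.uint8)
            annot = rng.integers(0, 3, (12, 12)).astype(np.uint8)
            r = ternary_metrics(pred, annot)
            if r.precision_cp and r.recall_cp:
                expect = 2 * r.precision_cp * r.recall_cp / (r.precision_cp + r.recall_cp)
                assert r.dcs_cp == pytest.approx(expect, abs=1e-12)
            for v in r.to_dict().values():
                assert v is None or 0.0 <= v <= 1.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(0, 3, (10, 10)).astype(np.uint8)
        annot = rng.integers(0, 3, (10, 10)).astype(np.uint8)
        padded_pred = np.pad(pred, ((3, 3), (5, 5)), constant_values=B)
        padded_annot = np.pad(annot, ((3, 3), (5, 5)), constant_values=B)
        assert ternary_metrics(pred, annot).to_dict() == ternary_metrics(
            padded_pred, padded_annot).to_dict()

    def test_aggregation_skips_undefined(self):
        t = np.full((2, 2), B, dtype=np.uint8)
        t[0, 0] = C
        defined = ternary_metrics(t, t)
        undefined = ternary_metrics(np.full((2, 2), B, np.uint8), t)
        agg = aggregate_reports([defined, undefined])
        assert agg["precision_c"] == {"mean": 1.0, "n_defined": 1}
        assert agg["recall_cp"]["n_defined"] == 2
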