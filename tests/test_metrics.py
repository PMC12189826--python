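"""Point-wise and event-level scoring, matching, alignment errors, AP."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psgdetect.events import EventInterval
from psgdetect.metrics import (
    alignment_errors,
    event_scores,
    macro_average,
    match_events,
    pointwise_scores,
    pr_curve_ap,
)


def ev(onset, offset, cls="LM"):
    return EventInterval(onset, offset, cls)


class TestPointwise:
    def test_perfect_prediction(self):
        truth = np.zeros((100, 2), dtype=int)
        truth[10:30, 0] = 1
        truth[50:90, 1] = 1
        r = pointwise_scores(truth, truth)
        for cls in ("LM", "SDB"):
            assert r.pointwise[cls]["f1"] == 1.0

    def test_hand_confusion_counts(self):
        truth = np.zeros((20, 2), dtype=int)
        pred = np.zeros((20, 2), dtype=int)
        for j in range(2):
            truth[:10, j] = 1  # 10 positives
            pred[2:12, j] = 1  # TP=8, FP=2, FN=2
        r = pointwise_scores(pred, truth)
        for cls in ("LM", "SDB"):
            s = r.pointwise[cls]
            assert (s["tp"], s["fp"], s["fn"]) == (8, 2, 2)
            for key in ("precision", "recall", "f1"):
                assert s[key] == pytest.approx(0.8)

    def test_zero_denominator_scores_zero(self):
        pred = np.zeros((50, 2), dtype=int)
        truth = np.zeros((50, 2), dtype=int)
        truth[:5, 0] = 1
        r = pointwise_scores(pred, truth)
        assert r.pointwise["LM"]["precision"] == 0.0
        assert r.pointwise["LM"]["recall"] == 0.0
        assert r.pointwise["LM"]["f1"] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pointwise_scores(np.zeros((10, 2)), np.zeros((11, 2)))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_confusion(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((1000, 2)) < 0.3).astype(int)
        truth = (rng.random((1000, 2)) < 0.1).astype(int)
        r = pointwise_scores(pred, truth)
        for j, cls in enumerate(("LM", "SDB")):
            tp = sum(1 for i in range(1000) if pred[i, j] and truth[i, j])
            fp = sum(1 for i in range(1000) if pred[i, j] and not truth[i, j])
            fn = sum(1 for i in range(1000) if not pred[i, j] and truth[i, j])
            s = r.pointwise[cls]
            assert (s["tp"], s["fp"], s["fn"]) == (tp, fp, fn)

    def test_macro_average_is_arithmetic_mean(self):
        assert macro_average([0.848, 0.728]) == pytest.approx((0.848 + 0.728) / 2)


class TestMatching:
    def test_identical_lists_all_matched(self):
        events = [ev(0, 2), ev(5, 7), ev(10, 30)]
        res = match_events(events, events)
        assert res.counts == (3, 0, 0)
        assert all(v == 1.0 for _, _, v in res.matches)

    def test_low_iou_pair_not_matched(self):
        res = match_events([ev(0.0, 2.5)], [ev(2.0, 10.0)])
        # IoU = 0.5/10 = 0.05 < 0.3
        assert res.counts == (0, 1, 1)

    def test_threshold_is_strict(self):
        # construct IoU exactly 0.3: inter 3, union 10
        res = match_events([ev(0.0, 7.0)], [ev(4.0, 10.0)])
        assert res.counts == (0, 1, 1)

    def test_two_predictions_one_truth(self):
        preds = [ev(0.0, 4.0), ev(0.5, 4.5)]
        truth = [ev(0.4, 4.4)]
        res = match_events(preds, truth)
        assert res.counts == (1, 1, 0)
        assert res.matches[0][0] is preds[1]  # the higher-IoU prediction wins

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_greedy_matching_is_maximal_and_bounded(self, seed):
        """Greedy one-to-one matching leaves no augmentable candidate pair
        and never exceeds the exhaustive maximum matching on <=4x4 events."""
        rng = np.random.default_rng(seed)
        preds = []
        t = 0.0
        for _ in range(rng.integers(1, 5)):
            t += rng.uniform(0.5, 4.0)
            preds.append(ev(t, t + rng.uniform(0.5, 3.0)))
        truths = []
        t = 0.0
        for _ in range(rng.integers(1, 5)):
            t += rng.uniform(0.5, 4.0)
            truths.append(ev(t, t + rng.uniform(0.5, 3.0)))
        res = match_events(preds, truths)
        from psgdetect.events import iou as iou_fn

        adj = [
            [j for j in range(len(truths)) if iou_fn(p, truths[j]) > 0.3] for p in preds
        ]

        def max_matching(i, used):
            if i == len(preds):
                return 0
            best = max_matching(i + 1, used)  # leave pred i unmatched
            for j in adj[i]:
                if j not in used:
                    best = max(best, 1 + max_matching(i + 1, used | {j}))
            return best

        assert len(res.matches) <= max_matching(0, frozenset())
        # maximality: every leftover candidate pair involves a matched event
        for p in res.fp:
            for t in res.fn:
                assert iou_fn(p, t) <= 0.3

    def test_hungarian_agrees_with_greedy_on_count(self):
        preds = [ev(0, 4), ev(3, 7), ev(10, 14)]
        truths = [ev(1, 5), ev(4, 8), ev(11, 15)]
        g = match_events(preds, truths, assignment="greedy")
        h = match_events(preds, truths, assignment="hungarian")
        assert len(g.matches) == len(h.matches)


class TestAlignmentErrors:
    def test_perfect_alignment(self):
        res = match_events([ev(1, 5)], [ev(1, 5)])
        err = alignment_errors(res)
        assert (err["onset_error_s"], err["offset_error_s"], err["duration_error_s"]) == (0, 0, 0)

    def test_hand_computed_pair(self):
        res = match_events([ev(1.1, 4.9)], [ev(1.0, 5.0)])
        err = alignment_errors(res)
        assert err["onset_error_s"] == pytest.approx(0.1)
        assert err["offset_error_s"] == pytest.approx(-0.1)
        assert err["duration_error_s"] == pytest.approx(-0.2)

    def test_positive_means_delayed(self):
        res = match_events([ev(2.0, 6.0)], [ev(1.0, 5.0)])
        err = alignment_errors(res)
        assert err["onset_error_s"] > 0 and err["offset_error_s"] > 0

    def test_duration_identity(self):
        preds = [ev(0.9, 5.2), ev(10.4, 13.9), ev(20.0, 26.0)]
        truths = [ev(1.0, 5.0), ev(10.0, 14.0), ev(20.5, 26.5)]
        err = alignment_errors(match_events(preds, truths))
        assert err["duration_error_s"] == pytest.approx(
            err["offset_error_s"] - err["onset_error_s"]
        )

    def test_empty_matches_undefined(self):
        err = alignment_errors(match_events([], [ev(0, 1)]))
        assert math.isnan(err["onset_error_s"])
        assert err["n_matches"] == 0


class TestEventScores:
    def test_monotone_in_iou_threshold(self):
        rng = np.random.default_rng(3)
        truths, preds = [], []
        t = 0.0
        for _ in range(30):
            t += rng.uniform(3, 10)
            d = rng.uniform(1, 5)
            truths.append(ev(t, t + d))
            if rng.random() < 0.8:
                j = rng.uniform(-1.5, 1.5)
                preds.append(ev(max(0.0, t + j), t + d + rng.uniform(-1, 1.5)))
        f1_0 = event_scores(preds, truths, iou_threshold=0.0)["f1"]
        f1_03 = event_scores(preds, truths, iou_threshold=0.3)["f1"]
        assert f1_0 >= f1_03


class TestAveragePrecision:
    def test_perfect_separation(self):
        truth = np.array([1] * 50 + [0] * 50)
        probs = np.array([0.9] * 50 + [0.1] * 50)
        _, _, ap = pr_curve_ap(probs, truth)
        assert ap == pytest.approx(1.0)

    def test_random_probs_ap_near_prevalence(self):
        rng = np.random.default_rng(0)
        truth = (rng.random(20000) < 0.5).astype(int)
        probs = rng.random(20000)
        _, _, ap = pr_curve_ap(probs, truth)
        assert ap == pytest.approx(truth.mean(), abs=0.05)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        truth = (rng.random(500) < 0.3).astype(int)
        probs = rng.random(500)
        _, _, ap1 = pr_curve_ap(probs, truth)
        _, _, ap2 = pr_curve_ap(probs**3, truth)
        assert ap1 == pytest.approx(ap2, abs=1e-12)

    def test_all_negative_truth_undefined(self):
        _, _, ap = pr_curve_ap(np.array([0.2, 0.8]), np.array([0, 0]))
        assert math.isnan(ap)
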