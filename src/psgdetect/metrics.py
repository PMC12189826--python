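"""Point-wise and event-level evaluation.

Point-wise scores compare binary label rasters sample by sample: per-class
precision TP/(TP+FP), recall TP/(TP+FN), their harmonic-mean F1, and the
macro average F1 over the two classes.  Zero-denominator cases score 0.

Event-level scores treat whole events as the unit: predicted and ground-truth
intervals of one class are matched one-to-one, greedily in descending IoU
order (ties broken toward the earlier ground-truth event), accepting a pair
only when its IoU strictly exceeds the threshold (default 0.3).  Matched
pairs yield temporal alignment errors — onset, offset and duration, each
``predicted - truth`` so a positive value indicates a delayed prediction —
and unmatched events count as false positives / negatives.

Precision-recall sweeps over the per-sample probabilities yield average
precision via the interpolated (precision-envelope) step area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import EventInterval, iou

__all__ = [
    "MatchResult",
    "ScoreReport",
    "pointwise_scores",
    "match_events",
    "alignment_errors",
    "pr_curve_ap",
    "event_scores",
]

CLASS_COLUMNS = ("LM", "SDB")


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


@dataclass
class MatchResult:
    """One-to-one event matches above the IoU threshold, plus leftovers."""

    matches: list[tuple[EventInterval, EventInterval, float]]
    fp: list[EventInterval]
    fn: list[EventInterval]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.matches), len(self.fp), len(self.fn)


@dataclass
class ScoreReport:
    """Per-class point-wise and event-level scores for one evaluation run."""

    pointwise: dict[str, dict[str, float]] = field(default_factory=dict)
    event: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def average_f1(self) -> float:
        return float(np.mean([self.pointwise[c]["f1"] for c in CLASS_COLUMNS]))

    def to_dict(self) -> dict:
        return {
            "pointwise": self.pointwise,
            "event": self.event,
            "average_f1": self.average_f1 if self.pointwise else None,
        }

    def table(self) -> str:
        lines = [f"{'':6s} {'F1':>7s} {'Pr':>7s} {'Re':>7s}"]
        for c in CLASS_COLUMNS:
            if c in self.pointwise:
                s = self.pointwise[c]
                lines.append(f"{c:6s} {s['f1']:7.3f} {s['precision']:7.3f} {s['recall']:7.3f}")
        if self.pointwise:
            lines.append(f"{'Avg':6s} {self.average_f1:7.3f}")
        return "\n".join(lines)


def macro_average(per_class_values: list[float]) -> float:
    """Arithmetic mean over classes (macro averaging of F1 or any score)."""
    return float(np.mean(per_class_values))


def pointwise_scores(pred: np.ndarray, truth: np.ndarray) -> ScoreReport:
    """Per-sample confusion scores for a T x 2 binary raster pair."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    report = ScoreReport()
    for j, cls in enumerate(CLASS_COLUMNS[: pred.shape[1]]):
        p, t = pred[:, j].astype(bool), truth[:, j].astype(bool)
        tp = int((p & t).sum())
        fp = int((p & ~t).sum())
        fn = int((~p & t).sum())
        pr, re, f1 = _prf(tp, fp, fn)
        report.pointwise[cls] = {
            "precision": pr, "recall": re, "f1": f1, "tp": tp, "fp": fp, "fn": fn,
        }
    return report


def match_events(
    pred: list[EventInterval],
    truth: list[EventInterval],
    iou_threshold: float = 0.3,
    assignment: str = "greedy",
) -> MatchResult:
    """One-to-one matching of predicted to ground-truth events.

    ``assignment="greedy"`` takes candidate pairs in descending IoU order
    (ties: earlier truth, then earlier prediction); ``"hungarian"`` solves the
    maximum-total-IoU assignment over the same candidate set and serves as a
    cross-check.  A pair is a candidate only when IoU strictly exceeds the
    threshold.
    """
    cands = [
        (iou(p, t), pi, ti)
        for pi, p in enumerate(pred)
        for ti, t in enumerate(truth)
        if iou(p, t) > iou_threshold
    ]
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[EventInterval, EventInterval, float]] = []
    if assignment == "greedy":
        for v, pi, ti in sorted(cands, key=lambda x: (-x[0], truth[x[2]].onset_s, pred[x[1]].onset_s)):
            if pi in used_p or ti in used_t:
                continue
            used_p.add(pi)
            used_t.add(ti)
            matches.append((pred[pi], truth[ti], v))
    elif assignment == "hungarian":
        from scipy.optimize import linear_sum_assignment

        if cands:
            cost = np.zeros((len(pred), len(truth)))
            for v, pi, ti in cands:
                cost[pi, ti] = -v
            rows, cols = linear_sum_assignment(cost)
            for pi, ti in zip(rows, cols):
                if cost[pi, ti] < 0:
                    used_p.add(pi)
                    used_t.add(ti)
                    matches.append((pred[pi], truth[ti], -cost[pi, ti]))
    else:
        raise ValueError("assignment must be 'greedy' or 'hungarian'")
    matches.sort(key=lambda m: m[1].onset_s)
    fp = [p for i, p in enumerate(pred) if i not in used_p]
    fn = [t for i, t in enumerate(truth) if i not in used_t]
    return MatchResult(matches=matches, fp=fp, fn=fn)


def alignment_errors(result: MatchResult) -> dict[str, float]:
    """Mean onset/offset/duration errors (s) over matched pairs.

    Each error is predicted minus truth; positive means the prediction is
    late.  With no matches the means are NaN (undefined, not zero).
    """
    if not result.matches:
        return {"onset_error_s": math.nan, "offset_error_s": math.nan,
                "duration_error_s": math.nan, "n_matches": 0}
    on = [p.onset_s - t.onset_s for p, t, _ in result.matches]
    off = [p.offset_s - t.offset_s for p, t, _ in result.matches]
    dur = [p.duration_s - t.duration_s for p, t, _ in result.matches]
    return {
        "onset_error_s": float(np.mean(on)),
        "offset_error_s": float(np.mean(off)),
        "duration_error_s": float(np.mean(dur)),
        "n_matches": len(result.matches),
    }


def event_scores(
    pred: list[EventInterval],
    truth: list[EventInterval],
    iou_threshold: float = 0.3,
) -> dict[str, float]:
    """Event-level P/R/F1 and alignment errors for one class."""
    res = match_events(pred, truth, iou_threshold)
    tp, fp, fn = res.counts
    p, r, f1 = _prf(tp, fp, fn)
    out = {"precision": p, "recall": r, "f1": f1, "tp": tp, "fp": fp, "fn": fn}
    out.update(alignment_errors(res))
    return out


def pr_curve_ap(probs: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Point-wise precision-recall curve and interpolated average precision.

    Sweeps the unique probability values as thresholds (prediction = prob >=
    threshold), computes point-wise precision/recall at each, and integrates
    the precision envelope over recall increments.  With no positive samples
    in the truth, AP is NaN (undefined).
    """
    probs = np.asarray(probs, float).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    if probs.shape != truth.shape:
        raise ValueError("shape mismatch")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    n_pos = int(truth.sum())
    if n_pos == 0:
        return np.array([]), np.array([]), math.nan

    order = np.argsort(-probs, kind="stable")
    sorted_truth = truth[order]
    sorted_probs = probs[order]
    tp = np.cumsum(sorted_truth)
    n_pred = np.arange(1, len(probs) + 1)
    # keep only the last index of each distinct threshold value
    distinct = np.flatnonzero(np.diff(sorted_probs, append=-np.inf) != 0)
    precision = tp[distinct] / n_pred[distinct]
    recall = tp[distinct] / n_pos

    # precision envelope, then step-wise area over recall increments
    env = np.maximum.accumulate(precision[::-1])[::-1]
    rec = np.concatenate([[0.0], recall])
    ap = float(np.sum((rec[1:] - rec[:-1]) * env))
    return precision, recall, ap


def evaluate_intervals(
    pred_events: list[EventInterval],
    truth_events: list[EventInterval],
    pred_raster: np.ndarray,
    truth_raster: np.ndarray,
    iou_threshold: float = 0.3,
) -> ScoreReport:
    """Full report: point-wise scores plus per-class event-level scores."""
    from .events import by_class

    report = pointwise_scores(pred_raster, truth_raster)
    for cls in CLASS_COLUMNS:
        report.event[cls] = event_scores(
            by_class(pred_events, cls), by_class(truth_events, cls), iou_threshold
        )
    return report
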