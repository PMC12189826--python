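"""Model/Results interface tying the pipeline together.

:class:`JointDetectionModel` is built from raw recordings plus their
ground-truth annotations, preprocesses them once, and on :meth:`fit` splits
patients 9:1, trains the segmentation network on event-containing segments
of the training patients, and returns a :class:`DetectionResults` that
carries the trained network, the loss history, and the split.  The results
object predicts and evaluates full recordings through the complete pipeline
(network -> CRF smoothing -> rule refinement -> RRLM/PLMS flagging) and
prints a statsmodels-style summary.

Three strategies are supported: ``joint`` (all five channels, both classes,
RRLM exclusion driven by the detected SDB events), ``single-LM`` (leg
channels only, LM class only, PLMS from periodicity alone) and
``single-SDB`` (respiratory channels only, SDB class only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .crf import CRFParams, crf_smooth_raster
from .events import EventInterval, by_class, raster_to_intervals
from .metrics import CLASS_COLUMNS, ScoreReport, _prf, alignment_errors, match_events, pr_curve_ap
from .network import AttentionUNet, ModelConfig
from .preprocess import (
    SignalRecord,
    TARGET_RATE_HZ,
    preprocess_record,
    rasterize_events,
    segment_and_rasterize,
    stitch_rasters,
)
from .rules import RuleConfig, apply_rules
from .training import TrainConfig, split_patients, train

__all__ = ["JointDetectionModel", "DetectionResults", "detect_record", "STRATEGIES"]

STRATEGIES = {
    "joint": (("Leg/L", "Leg/R", "Abdo", "Thor", "Nasal"), ("LM", "SDB")),
    "single-LM": (("Leg/L", "Leg/R"), ("LM",)),
    "single-SDB": (("Abdo", "Thor", "Nasal"), ("SDB",)),
}


@dataclass
class DetectionOutput:
    """Full-pipeline output for one recording."""

    events: list[EventInterval]
    prob_raster: np.ndarray  # T x 2 on the record timeline (absent class = 0)
    label_raster: np.ndarray  # T x 2 binary, after CRF
    t0: float
    rate: float = TARGET_RATE_HZ


def _class_indices(classes: tuple[str, ...]) -> list[int]:
    return [CLASS_COLUMNS.index(c) for c in classes]


def detect_record(
    net: AttentionUNet,
    record: SignalRecord,
    channels: tuple[str, ...],
    classes: tuple[str, ...],
    crf_params: CRFParams | None = CRFParams(),
    rule_config: RuleConfig | None = RuleConfig(),
    joint: bool = True,
    preprocessed: bool = False,
) -> DetectionOutput:
    """Run preprocess -> network -> CRF -> intervals -> rules on one record.

    Pass ``crf_params=None`` to threshold the network output at 0.5 instead
    of CRF smoothing, and ``rule_config=None`` to skip refinement/flagging.
    """
    pre = record if preprocessed else preprocess_record(record)
    segments = segment_and_rasterize(pre, [], require_event=False, channel_order=list(channels))
    if not segments:
        raise ValueError("record shorter than one 60 s segment")
    probs = net.predict_probs(np.stack([s.signals for s in segments]))
    if crf_params is not None:
        labels = [crf_smooth_raster(p, crf_params, TARGET_RATE_HZ) for p in probs]
    else:
        labels = [(p > 0.5).astype(np.int8) for p in probs]

    full_probs, t0 = stitch_rasters(segments, list(probs))
    full_labels, _ = stitch_rasters(segments, labels)

    T = full_probs.shape[0]
    prob2 = np.zeros((T, 2))
    lab2 = np.zeros((T, 2), dtype=np.int8)
    for k, cls in enumerate(classes):
        j = CLASS_COLUMNS.index(cls)
        prob2[:, j] = full_probs[:, k]
        lab2[:, j] = full_labels[:, k]

    lm = raster_to_intervals(lab2[:, 0], TARGET_RATE_HZ, t0, "LM")
    sdb = raster_to_intervals(lab2[:, 1], TARGET_RATE_HZ, t0, "SDB")
    if rule_config is not None:
        events = apply_rules(lm, sdb, rule_config, joint=joint)
    else:
        events = sorted(lm + sdb, key=lambda e: (e.onset_s, e.cls))
    return DetectionOutput(events=events, prob_raster=prob2, label_raster=lab2, t0=t0)


class JointDetectionModel:
    """Event-detection model over a corpus of annotated recordings.

    Parameters
    ----------
    records
        Raw (unpreprocessed) recordings; ``record.record_id`` doubles as the
        patient identifier for splitting.
    annotations
        Ground-truth events per recording, parallel to ``records``.
    strategy
        ``"joint"``, ``"single-LM"`` or ``"single-SDB"``; fixes the input
        channels and output classes.
    """

    def __init__(
        self,
        records: list[SignalRecord],
        annotations: list[list[EventInterval]],
        strategy: str = "joint",
        model_config: ModelConfig | None = None,
        train_config: TrainConfig = TrainConfig(),
        crf_params: CRFParams = CRFParams(),
        rule_config: RuleConfig = RuleConfig(),
        channels: tuple[str, ...] | None = None,
    ):
        if len(records) != len(annotations):
            raise ValueError("records and annotations must be parallel lists")
        if strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {sorted(STRATEGIES)}")
        self.strategy = strategy
        self.channels, self.classes = STRATEGIES[strategy]
        if channels is not None:
            # channel-combination experiments: any subset of the five inputs
            unknown = set(channels) - set(STRATEGIES["joint"][0])
            if unknown:
                raise ValueError(f"unknown channels {sorted(unknown)}")
            self.channels = tuple(channels)
        if model_config is None:
            model_config = ModelConfig()
        self.model_config = replace(
            model_config,
            in_channels=len(self.channels),
            out_classes=len(self.classes),
        )
        self.train_config = train_config
        self.crf_params = crf_params
        self.rule_config = rule_config
        self.records = records
        self.annotations = annotations
        self._pre = [preprocess_record(r) for r in records]

    @classmethod
    def from_simulator(cls, configs, **kwargs) -> "JointDetectionModel":
        """Build from a list of :class:`~psgdetect.synth.SynthConfig`."""
        from .synth import simulate_record

        records, annotations = [], []
        for cfg in configs:
            rec, schedule = simulate_record(cfg)
            records.append(rec)
            annotations.append(schedule.events)
        return cls(records, annotations, **kwargs)

    def _segments(self, record_ids, require_event: bool):
        cols = _class_indices(self.classes)
        segs = []
        for pre, events in zip(self._pre, self.annotations):
            if pre.record_id not in record_ids:
                continue
            for s in segment_and_rasterize(
                pre, events, require_event=False, channel_order=list(self.channels)
            ):
                s.labels = s.labels[:, cols]
                if require_event and not s.labels.any():
                    continue
                segs.append(s)
        return segs

    def fit(self, progress: bool = False, log_path=None) -> "DetectionResults":
        """Patient split, Dice training, best-epoch checkpoint."""
        ids = [r.record_id for r in self.records]
        train_ids, test_ids = split_patients(
            ids, self.train_config.test_fraction, self.train_config.seed
        )
        segments = self._segments(set(train_ids), require_event=True)
        net, history = train(
            segments, self.model_config, self.train_config, log_path=log_path, progress=progress
        )
        return DetectionResults(self, net, history, train_ids, test_ids)


@dataclass
class DetectionResults:
    """Fitted detector: trained network + split + diagnostics."""

    model: JointDetectionModel
    net: AttentionUNet
    history: list[dict] = field(default_factory=list)
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)

    def predict(
        self, record: SignalRecord, use_crf: bool = True, use_rules: bool = True
    ) -> DetectionOutput:
        m = self.model
        return detect_record(
            self.net,
            record,
            m.channels,
            m.classes,
            m.crf_params if use_crf else None,
            m.rule_config if use_rules else None,
            joint=(m.strategy == "joint"),
        )

    def evaluate(
        self,
        record_ids=None,
        use_crf: bool = True,
        use_rules: bool = True,
        iou_threshold: float = 0.3,
    ) -> ScoreReport:
        """Pooled point-wise + event-level scores over the given records.

        Defaults to the held-out test patients.  Rasters are stitched back to
        the full record before event extraction, so events crossing segment
        borders count once; confusion counts, matches and boundary errors are
        pooled over records.
        """
        m = self.model
        ids = set(self.test_ids if record_ids is None else record_ids)
        conf = {c: np.zeros(3, dtype=np.int64) for c in CLASS_COLUMNS}  # tp, fp, fn
        matches = {c: [] for c in CLASS_COLUMNS}
        unmatched = {c: [0, 0] for c in CLASS_COLUMNS}  # fp, fn events
        probs_all, truth_all = [], []
        for rec, truth in zip(m.records, m.annotations):
            if rec.record_id not in ids:
                continue
            out = self.predict(rec, use_crf=use_crf, use_rules=use_rules)
            T = out.label_raster.shape[0]
            truth_raster = rasterize_events(truth, T, out.rate, out.t0)
            probs_all.append(out.prob_raster)
            truth_all.append(truth_raster)
            for j, cls in enumerate(CLASS_COLUMNS):
                p, t = out.label_raster[:, j].astype(bool), truth_raster[:, j].astype(bool)
                conf[cls] += (int((p & t).sum()), int((p & ~t).sum()), int((~p & t).sum()))
                res = match_events(
                    by_class(out.events, cls), by_class(truth, cls), iou_threshold
                )
                matches[cls].extend(res.matches)
                unmatched[cls][0] += len(res.fp)
                unmatched[cls][1] += len(res.fn)

        report = ScoreReport()
        P = np.concatenate(probs_all) if probs_all else np.zeros((0, 2))
        Tr = np.concatenate(truth_all) if truth_all else np.zeros((0, 2))
        for j, cls in enumerate(CLASS_COLUMNS):
            tp, fp, fn = conf[cls]
            pr, re, f1 = _prf(tp, fp, fn)
            _, _, ap = pr_curve_ap(P[:, j], Tr[:, j]) if len(P) else (None, None, float("nan"))
            report.pointwise[cls] = {
                "precision": pr, "recall": re, "f1": f1,
                "tp": int(tp), "fp": int(fp), "fn": int(fn), "ap": ap,
            }
            n_match = len(matches[cls])
            efp, efn = unmatched[cls]
            epr, ere, ef1 = _prf(n_match, efp, efn)
            ev = {"precision": epr, "recall": ere, "f1": ef1,
                  "tp": n_match, "fp": efp, "fn": efn}
            from .metrics import MatchResult

            ev.update(alignment_errors(MatchResult(matches[cls], [], [])))
            report.event[cls] = ev
        return report

    def summary(self) -> str:
        m = self.model
        lines = [
            "Joint PSG event detection results",
            "=" * 50,
            f"strategy:        {m.strategy}",
            f"channels:        {', '.join(m.channels)}",
            f"classes:         {', '.join(m.classes)}",
            f"parameters:      {self.net.n_parameters():,}",
            f"train patients:  {len(self.train_ids)}",
            f"test patients:   {len(self.test_ids)}",
            f"epochs run:      {len(self.history)}",
        ]
        if self.history:
            best = min(h["loss"] for h in self.history)
            lines.append(f"final loss:      {self.history[-1]['loss']:.4f}")
            lines.append(f"best loss:       {best:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        from .network import save_checkpoint

        save_checkpoint(
            path,
            self.net,
            extra={
                "strategy": self.model.strategy,
                "history": self.history,
                "train_ids": self.train_ids,
                "test_ids": self.test_ids,
            },
        )
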