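"""Interval algebra shared by every pipeline stage.

Events are half-open temporal intervals ``[onset_s, offset_s)`` carrying a
class label (``"LM"`` for leg movements, ``"SDB"`` for sleep-disordered
breathing) and optional flags (``"RRLM"``, ``"PLMS"``, only meaningful on LM
events).  Binary per-sample rasters and interval lists are two views of the
same annotation; the conversions here are exact to one sample, so touching
intervals such as [0, 1) and [1, 2) remain distinct events with IoU 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EventInterval",
    "iou",
    "raster_to_intervals",
    "intervals_to_raster",
    "write_annotations",
    "read_annotations",
    "AnnotationError",
]

VALID_CLASSES = ("LM", "SDB")
VALID_FLAGS = ("RRLM", "PLMS")


@dataclass(frozen=True)
class EventInterval:
    """One annotated or predicted event, half-open in seconds."""

    onset_s: float
    offset_s: float
    cls: str
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"offset_s must exceed onset_s, got [{self.onset_s}, {self.offset_s})"
            )
        if self.cls not in VALID_CLASSES:
            raise ValueError(f"cls must be one of {VALID_CLASSES}, got {self.cls!r}")
        object.__setattr__(self, "flags", frozenset(self.flags))
        unknown = self.flags - set(VALID_FLAGS)
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)}")
        if self.flags and self.cls != "LM":
            raise ValueError("flags are only meaningful on LM events")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def with_flags(self, *flags: str) -> "EventInterval":
        return replace(self, flags=self.flags | set(flags))

    def intersects(self, onset_s: float, offset_s: float) -> bool:
        """True if this interval overlaps [onset_s, offset_s] (closed window)."""
        return self.onset_s <= offset_s and self.offset_s >= onset_s


def iou(a: EventInterval, b: EventInterval) -> float:
    """Intersection-over-union of two temporal intervals, in [0, 1]."""
    inter = min(a.offset_s, b.offset_s) - max(a.onset_s, b.onset_s)
    if inter <= 0.0:
        return 0.0
    union = max(a.offset_s, b.offset_s) - min(a.onset_s, b.onset_s)
    return inter / union


def raster_to_intervals(
    raster: np.ndarray, rate: float, t0: float = 0.0, cls: str = "LM"
) -> list[EventInterval]:
    """Map maximal runs of 1s in a binary raster to half-open intervals.

    Sample ``i`` covers ``[t0 + i/rate, t0 + (i+1)/rate)``; a run spanning
    samples i..j-1 therefore becomes the interval ``[t0 + i/rate, t0 + j/rate)``.
    """
    r = np.asarray(raster).ravel()
    if r.size and not np.isin(r, (0, 1)).all():
        raise ValueError("raster must be binary (0/1)")
    r = r.astype(np.int8)
    padded = np.concatenate([[0], r, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [
        EventInterval(t0 + i / rate, t0 + j / rate, cls) for i, j in zip(starts, stops)
    ]


def intervals_to_raster(
    intervals: list[EventInterval],
    n_samples: int,
    rate: float,
    t0: float = 0.0,
) -> np.ndarray:
    """Rasterize half-open intervals onto a per-sample binary vector.

    The onset sample is ``floor((onset - t0) * rate)`` and the interval is
    half-open, so an event of duration d covers round(d * rate) samples up to
    one-sample quantization.
    """
    out = np.zeros(n_samples, dtype=np.int8)
    for ev in intervals:
        i = int(np.floor((ev.onset_s - t0) * rate))
        j = int(np.floor((ev.offset_s - t0) * rate))
        i, j = max(i, 0), min(j, n_samples)
        if j > i:
            out[i:j] = 1
    return out


class AnnotationError(ValueError):
    """Raised when an annotation file cannot be parsed."""


_HEADER = "onset_s,offset_s,class,flags"


def write_annotations(events: list[EventInterval], path) -> None:
    """Write events as UTF-8 CSV: onset_s,offset_s,class,flags (ms precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for ev in sorted(events, key=lambda e: (e.onset_s, e.cls)):
            flags = "|".join(sorted(ev.flags))
            fh.write(f"{ev.onset_s:.3f},{ev.offset_s:.3f},{ev.cls},{flags}\n")


def read_annotations(path) -> list[EventInterval]:
    """Read the columnar annotation format written by :func:`write_annotations`.

    A missing ``flags`` column defaults to no flags.  Malformed rows raise
    :class:`AnnotationError` naming the offending line.
    """
    events: list[EventInterval] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise AnnotationError(f"{path}: empty annotation file")
    header = [c.strip() for c in lines[0].split(",")]
    if header[:3] != ["onset_s", "offset_s", "class"]:
        raise AnnotationError(f"{path}: line 1: unrecognized header {lines[0]!r}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 3:
            raise AnnotationError(f"{path}: line {lineno}: expected >=3 columns")
        try:
            onset, offset = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise AnnotationError(f"{path}: line {lineno}: non-numeric time") from exc
        flags = frozenset(f for f in parts[3].split("|") if f) if len(parts) > 3 else frozenset()
        try:
            events.append(EventInterval(onset, offset, parts[2], flags))
        except ValueError as exc:
            raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
    return events


def by_class(events: list[EventInterval], cls: str) -> list[EventInterval]:
    """Events of one class, sorted by onset."""
    return sorted((e for e in events if e.cls == cls), key=lambda e: e.onset_s)
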