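"""Channel-specific filtering, down-sampling, normalization and segmentation.

The detector consumes five channels: two tibialis-anterior EMG channels
(``Leg/L``, ``Leg/R``) and three respiratory channels (``Abdo``, ``Thor``,
``Nasal``).  Each channel is band-pass filtered at its native rate with a
zero-phase Butterworth filter (EMG 10-50 Hz order 4; effort belts 0.1-15 Hz
order 2; nasal airflow 0.03-50 Hz order 2), anti-alias decimated to a common
100 Hz, and z-scored per channel with the sample (N-1) standard deviation.
Records are then cut into non-overlapping 60 s segments whose per-sample
labels form a T x 2 binary raster with columns ordered [LM, SDB]; overlapping
LM and SDB events may both be 1 at the same sample (no prioritization).

Filtering precedes decimation so that the EMG passband's 50 Hz upper edge is
valid at the native rate; zero-phase (forward-backward) filtering is used so
filtering does not shift event boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .events import EventInterval, by_class, intervals_to_raster

__all__ = [
    "SignalRecord",
    "Segment",
    "TARGET_RATE_HZ",
    "EPOCH_S",
    "DEFAULT_CHANNEL_FILTERS",
    "bandpass_filter",
    "zscore",
    "preprocess_record",
    "segment_and_rasterize",
]

TARGET_RATE_HZ = 100.0
EPOCH_S = 60.0
#: channel -> (low Hz, high Hz, Butterworth order), applied at the native rate
DEFAULT_CHANNEL_FILTERS: dict[str, tuple[float, float, int]] = {
    "Leg/L": (10.0, 50.0, 4),
    "Leg/R": (10.0, 50.0, 4),
    "Thor": (0.1, 15.0, 2),
    "Abdo": (0.1, 15.0, 2),
    "Nasal": (0.03, 50.0, 2),
}
CLASS_COLUMNS = ("LM", "SDB")


@dataclass
class SignalRecord:
    """Named multichannel time series with a common sampling rate."""

    channels: dict[str, np.ndarray]
    rate: float
    units: dict[str, str] = field(default_factory=dict)
    record_id: str = "record"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        lengths = {len(x) for x in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def to_matrix(self, channel_order: list[str] | None = None) -> np.ndarray:
        """Stack channels into a T x C float matrix in the given order."""
        names = channel_order or list(self.channels)
        missing = [c for c in names if c not in self.channels]
        if missing:
            raise KeyError(f"channels {missing} not in record {list(self.channels)}")
        return np.stack([np.asarray(self.channels[c], float) for c in names], axis=1)


@dataclass
class Segment:
    """One 60 s window of preprocessed signals with its point-wise labels."""

    signals: np.ndarray  # T x C, z-scored, 100 Hz
    labels: np.ndarray  # T x 2 binary, columns [LM, SDB]
    record_id: str
    start_s: float

    def __post_init__(self) -> None:
        if self.signals.shape[0] != self.labels.shape[0]:
            raise ValueError("signals and labels must share the time axis")
        if self.labels.shape[1] != 2:
            raise ValueError("labels must have two columns [LM, SDB]")

    @property
    def has_event(self) -> bool:
        return bool(self.labels.any())


def bandpass_filter(
    x: np.ndarray, rate: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length.

    The stated order is the order of the underlying one-pass design; the
    forward-backward application squares the magnitude response, leaving the
    -3 dB points of the one-pass filter at the cutoffs.
    """
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= rate / 2:
        raise ValueError(
            f"high cutoff {high} Hz >= Nyquist {rate / 2} Hz; filter at the native rate"
        )
    x = np.asarray(x, dtype=float)
    if len(x) <= 3 * order:
        raise ValueError(f"signal too short ({len(x)} samples) for order {order}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def zscore(x: np.ndarray) -> np.ndarray:
    """Per-channel z-score with the N-1 (sample) standard deviation.

    A constant channel (s = 0) maps to all zeros rather than raising, so a
    dead electrode does not abort a whole-night run.
    """
    x = np.asarray(x, dtype=float)
    s = x.std(ddof=1) if len(x) > 1 else 0.0
    if s == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def _resample_to(x: np.ndarray, rate: float, target: float) -> np.ndarray:
    if rate == target:
        return np.asarray(x, dtype=float)
    frac = Fraction(target / rate).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def preprocess_record(
    record: SignalRecord,
    channel_filters: dict[str, tuple[float, float, int]] | None = None,
    target_rate: float = TARGET_RATE_HZ,
) -> SignalRecord:
    """Filter each channel at its native rate, decimate to 100 Hz, z-score."""
    filters = dict(DEFAULT_CHANNEL_FILTERS if channel_filters is None else channel_filters)
    out: dict[str, np.ndarray] = {}
    for name, x in record.channels.items():
        if name not in filters:
            raise KeyError(
                f"no filter configured for channel {name!r}; configured: {sorted(filters)}"
            )
        low, high, order = filters[name]
        try:
            y = bandpass_filter(x, record.rate, low, high, order)
        except ValueError as exc:
            raise ValueError(f"channel {name!r}: {exc}") from exc
        y = _resample_to(y, record.rate, target_rate)
        out[name] = zscore(y)
    return SignalRecord(
        channels=out,
        rate=target_rate,
        units={c: "z" for c in out},
        record_id=record.record_id,
    )


def read_edf(path, channel_map: dict[str, str] | None = None) -> SignalRecord:
    """Optional EDF reader (requires ``mne``).

    ``channel_map`` renames dataset-dialect channel labels to the canonical
    names (e.g. ``{"Leg-L": "Leg/L"}``); unmapped channels keep their label.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rename = channel_map or {}
    channels = {
        rename.get(name, name): raw.get_data(picks=[i])[0]
        for i, name in enumerate(raw.ch_names)
    }
    return SignalRecord(
        channels=channels, rate=float(raw.info["sfreq"]),
        record_id=str(path),
    )


def rasterize_events(
    events: list[EventInterval], n_samples: int, rate: float, t0: float = 0.0
) -> np.ndarray:
    """T x 2 binary label raster, columns [LM, SDB], both set under overlap."""
    cols = [
        intervals_to_raster(by_class(events, cls), n_samples, rate, t0)
        for cls in CLASS_COLUMNS
    ]
    return np.stack(cols, axis=1)


def segment_and_rasterize(
    record: SignalRecord,
    events: list[EventInterval],
    epoch_s: float = EPOCH_S,
    require_event: bool = False,
    channel_order: list[str] | None = None,
) -> list[Segment]:
    """Cut a preprocessed record into consecutive epochs with label rasters.

    Windows are non-overlapping; the trailing partial window is dropped.  With
    ``require_event`` (training mode) windows whose label raster is all zero
    are dropped as well; evaluation keeps every window.
    """
    mat = record.to_matrix(channel_order)
    labels = rasterize_events(events, mat.shape[0], record.rate)
    win = int(round(epoch_s * record.rate))
    segments: list[Segment] = []
    for start in range(0, mat.shape[0] - win + 1, win):
        seg = Segment(
            signals=mat[start : start + win],
            labels=labels[start : start + win],
            record_id=record.record_id,
            start_s=start / record.rate,
        )
        if require_event and not seg.has_event:
            continue
        segments.append(seg)
    return segments


def stitch_rasters(segments: list[Segment], values: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Re-assemble per-segment T x 2 arrays onto the record timeline.

    Returns the stitched array and the rate-relative offset (t0) of its first
    sample, so events split across a segment border are counted once at
    evaluation time.
    """
    if not segments:
        raise ValueError("no segments to stitch")
    order = np.argsort([s.start_s for s in segments])
    rate = TARGET_RATE_HZ
    win = segments[0].signals.shape[0]
    first = segments[order[0]].start_s
    last = segments[order[-1]].start_s
    total = int(round((last - first) * rate)) + win
    out = np.zeros((total, values[0].shape[1]), dtype=values[0].dtype)
    for idx in order:
        i = int(round((segments[idx].start_s - first) * rate))
        out[i : i + win] = values[idx]
    return out, first
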