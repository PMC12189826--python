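"""Ground-truthed synthetic polysomnography.

No public dataset with joint leg-movement (LM) and sleep-disordered-breathing
(SDB) annotations exists at the channel set this package targets, so every
downstream stage is exercised on simulated recordings whose event statistics
mirror the clinical scoring rules:

* LM: tibialis EMG burst lasting 0.5-10 s (log-normal, median ~1.85 s) whose
  envelope exceeds the quiet baseline by more than 8 uV;
* SDB: airflow amplitude reduction of >=90 % (apnea) or 30-70 % (hypopnea)
  lasting >=10 s (log-normal, median ~27.5 s);
* PLMS trains: >=4 LMs at periodic onset-to-onset intervals within 5-90 s;
* RRLM coupling: with probability ``p_rrlm`` an SDB event spawns an LM
  intersecting the SDB interval padded by 0.5 s on both sides (the leg jerk at
  airway re-opening).

The generator first samples an event schedule (intervals + flags), then
renders five channels at ``raw_rate`` (default 200 Hz, exercising the
down-sampling stage): two leg EMG channels with 10-50 Hz band-limited bursts
over Gaussian baseline noise, a nasal-airflow quasi-sinusoid whose amplitude
collapses during SDB with ~1 s smooth ramps, and two correlated effort belts
(Thor/Abdo) with partial reduction.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .events import EventInterval, by_class
from .preprocess import SignalRecord

__all__ = [
    "SynthConfig",
    "EventSchedule",
    "SynthCapacityError",
    "sample_event_schedule",
    "render_signals",
    "simulate_record",
]

# Log-normal duration shapes matched to the published descriptive statistics:
# medians 1.85 s (LM) and 27.55 s (SDB); sigma from the IQR upper quartile,
# sigma = ln(q3/median) / 0.6745.
LM_DUR_MEDIAN_S = 1.85
LM_DUR_SIGMA = math.log(2.67 / 1.85) / 0.6745
SDB_DUR_MEDIAN_S = 27.55
SDB_DUR_SIGMA = math.log(35.44 / 27.55) / 0.6745

_MIN_LM_SEP_S = 0.6  # keep distinct LMs mergeable-rule safe (> 0.5 s apart)
_MIN_SDB_SEP_S = 5.0  # breathing recovery between consecutive SDB events


class SynthCapacityError(RuntimeError):
    """Requested event rates cannot be placed in the configured duration."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    Rates are per hour of recording; the defaults describe a moderate OSA
    night with frequent periodic limb movements (AHI ~25/h, a few PLMS trains
    per hour), matching the cohort this detector is aimed at.
    """

    duration_s: float = 600.0
    raw_rate: float = 200.0
    sdb_rate_per_h: float = 25.0
    plms_train_rate_per_h: float = 4.0
    lm_isolated_rate_per_h: float = 15.0
    p_rrlm: float = 0.3
    apnea_frac: float = 0.4
    lm_burst_amp_uV: tuple[float, float] = (10.0, 40.0)
    emg_baseline_sd_uV: float = 2.0
    resp_freq_hz: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("sdb_rate_per_h", "plms_train_rate_per_h", "lm_isolated_rate_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_rrlm <= 1.0:
            raise ValueError("p_rrlm must be in [0, 1]")
        if not 0.0 <= self.apnea_frac <= 1.0:
            raise ValueError("apnea_frac must be in [0, 1]")
        lo, hi = self.lm_burst_amp_uV
        if not 0 < lo < hi:
            raise ValueError("lm_burst_amp_uV must be a positive ordered range")
        if self.raw_rate <= 0 or self.resp_freq_hz <= 0 or self.emg_baseline_sd_uV < 0:
            raise ValueError("raw_rate, resp_freq_hz positive; baseline sd nonnegative")


@dataclass
class EventSchedule:
    """Ground-truth events of one synthetic recording."""

    events: list[EventInterval]
    duration_s: float
    #: apnea (vs hypopnea) subtype per SDB event, parallel to by_class(events,"SDB")
    sdb_is_apnea: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.onset_s < 0 or ev.offset_s > self.duration_s + 1e-9:
                raise ValueError(f"event {ev} outside [0, {self.duration_s}]")
            if ev.cls == "LM" and not 0.5 - 1e-9 <= ev.duration_s <= 10.0 + 1e-9:
                raise ValueError(f"LM duration {ev.duration_s} outside [0.5, 10]")
            if ev.cls == "SDB" and ev.duration_s < 10.0 - 1e-9:
                raise ValueError(f"SDB duration {ev.duration_s} below 10 s")

    @property
    def lm(self) -> list[EventInterval]:
        return by_class(self.events, "LM")

    @property
    def sdb(self) -> list[EventInterval]:
        return by_class(self.events, "SDB")


def _lognormal_duration(rng, median, sigma, lo, hi):
    return float(np.clip(rng.lognormal(math.log(median), sigma), lo, hi))


def _overlaps(onset, offset, taken, sep):
    return any(onset < b + sep and offset > a - sep for a, b in taken)


def _place(rng, dur, taken, sep, duration_s, tries=2000):
    """Uniform non-overlapping placement with bounded rejection sampling."""
    hi = duration_s - dur
    if hi <= 0:
        raise SynthCapacityError(f"event of {dur:.1f}s does not fit in {duration_s}s")
    for _ in range(tries):
        onset = rng.uniform(0.0, hi)
        if not _overlaps(onset, onset + dur, taken, sep):
            return onset
    raise SynthCapacityError(
        f"could not place a {dur:.1f}s event among {len(taken)} existing ones; "
        "reduce the event rates or lengthen the recording"
    )


def sample_event_schedule(config: SynthConfig) -> EventSchedule:
    """Draw one ground-truth event schedule.

    SDB events are placed first (non-overlapping within class), then PLMS
    trains of >=4 LMs with onset-to-onset gaps uniform in [10, 60] s, then one
    RRLM-coupled LM per SDB event with probability ``p_rrlm`` (onset near the
    SDB offset, guaranteeing intersection with the +-0.5 s padded window), and
    finally isolated LMs.  RRLM/PLMS flags are assigned from the definitional
    predicates, so accidental periodicity among isolated LMs is labeled as the
    scoring rules would label it.
    """
    rng = np.random.default_rng(config.seed)
    hours = config.duration_s / 3600.0

    sdb_spans: list[tuple[float, float]] = []
    sdb_is_apnea: list[bool] = []
    n_sdb = rng.poisson(config.sdb_rate_per_h * hours)
    for _ in range(n_sdb):
        dur = _lognormal_duration(rng, SDB_DUR_MEDIAN_S, SDB_DUR_SIGMA, 10.0, 151.32)
        dur = min(dur, max(10.0, config.duration_s / 3.0))
        onset = _place(rng, dur, sdb_spans, _MIN_SDB_SEP_S, config.duration_s)
        sdb_spans.append((onset, onset + dur))
    order = np.argsort([a for a, _ in sdb_spans])
    sdb_spans = [sdb_spans[i] for i in order]
    sdb_is_apnea = [bool(rng.random() < config.apnea_frac) for _ in sdb_spans]

    lm_spans: list[tuple[float, float]] = []

    # PLMS trains: only the member LMs must avoid other LMs, so trains may
    # interleave with other activity as they do in real nights
    n_trains = rng.poisson(config.plms_train_rate_per_h * hours)
    for _ in range(n_trains):
        placed = False
        for _round in range(10):
            count = 4 + int(rng.poisson(2.0))
            gaps = rng.uniform(10.0, 60.0, size=count - 1)
            durs = [
                _lognormal_duration(rng, LM_DUR_MEDIAN_S, LM_DUR_SIGMA, 0.5, 8.0)
                for _ in range(count)
            ]
            durs = [min(d, g - _MIN_LM_SEP_S) for d, g in zip(durs, list(gaps) + [np.inf])]
            span = float(gaps.sum() + durs[-1])
            if span >= config.duration_s:
                continue
            onsets = np.concatenate([[0.0], np.cumsum(gaps)])
            for _try in range(200):
                start = rng.uniform(0.0, config.duration_s - span)
                cand = [(start + o, start + o + d) for o, d in zip(onsets, durs)]
                if not any(_overlaps(a, b, lm_spans, _MIN_LM_SEP_S) for a, b in cand):
                    lm_spans.extend(cand)
                    lm_spans.sort()
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise SynthCapacityError(
                "could not place a PLMS train; reduce rates or lengthen the recording"
            )

    # RRLM-coupled LMs: onset drawn around the SDB offset so the LM interval
    # intersects [sdb.onset - 0.5, sdb.offset + 0.5]
    for (a, b) in sdb_spans:
        if rng.random() >= config.p_rrlm:
            continue
        dur = _lognormal_duration(rng, LM_DUR_MEDIAN_S, LM_DUR_SIGMA, 0.5, 10.0)
        placed = False
        # preferred: onset near the SDB offset (arousal at airway re-opening);
        # fallback: anywhere intersecting the padded window
        for lo, hi in ((max(0.0, b - 0.3), b + 0.4), (max(0.0, a - 0.4 - dur), b + 0.4)):
            for _ in range(200):
                onset = rng.uniform(lo, hi)
                intersects = onset <= b + 0.5 and onset + dur >= a - 0.5
                if (
                    intersects
                    and onset >= 0.0
                    and onset + dur <= config.duration_s
                    and not _overlaps(onset, onset + dur, lm_spans, _MIN_LM_SEP_S)
                ):
                    lm_spans.append((onset, onset + dur))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise SynthCapacityError("could not place an RRLM-coupled LM")

    n_iso = rng.poisson(config.lm_isolated_rate_per_h * hours)
    for _ in range(n_iso):
        dur = _lognormal_duration(rng, LM_DUR_MEDIAN_S, LM_DUR_SIGMA, 0.5, 10.0)
        onset = _place(rng, dur, lm_spans, _MIN_LM_SEP_S, config.duration_s)
        lm_spans.append((onset, onset + dur))

    events = [EventInterval(a, b, "SDB") for a, b in sdb_spans]
    events += [EventInterval(a, b, "LM") for a, b in sorted(lm_spans)]
    events = _assign_truth_flags(events)
    return EventSchedule(events=events, duration_s=config.duration_s, sdb_is_apnea=sdb_is_apnea)


def _assign_truth_flags(events: list[EventInterval]) -> list[EventInterval]:
    """Assign RRLM/PLMS flags by the scoring definitions themselves."""
    from .rules import RuleConfig, detect_plms, flag_rrlm

    cfg = RuleConfig()
    sdb = by_class(events, "SDB")
    lm = flag_rrlm(by_class(events, "LM"), sdb, cfg)
    non_rrlm = [e for e in lm if "RRLM" not in e.flags]
    flagged, _series = detect_plms(non_rrlm, cfg)
    merged = {(e.onset_s, e.offset_s): e for e in lm}
    merged.update({(e.onset_s, e.offset_s): e for e in flagged})
    out = sdb + sorted(merged.values(), key=lambda e: e.onset_s)
    return sorted(out, key=lambda e: (e.onset_s, e.cls))


def _smooth_envelope(env: np.ndarray, rate: float, ramp_s: float = 1.0) -> np.ndarray:
    n = max(3, int(round(ramp_s * rate)) | 1)
    win = np.hanning(n)
    win /= win.sum()
    return np.convolve(env, win, mode="same")


def _bursty_emg(rng, n, rate, schedule_lm, amp_range, baseline_sd):
    x = rng.normal(0.0, baseline_sd, size=n)
    sos = sps.butter(4, [10.0, min(50.0, 0.45 * rate)], btype="bandpass", fs=rate, output="sos")
    for ev in schedule_lm:
        i, j = int(ev.onset_s * rate), int(ev.offset_s * rate)
        if j <= i + 4:
            continue
        burst = sps.sosfilt(sos, rng.normal(0.0, 1.0, size=j - i))
        rms = np.sqrt(np.mean(burst**2))
        if rms > 0:
            burst /= rms
        amp = rng.uniform(*amp_range)
        ramp = min((j - i) // 4, int(0.1 * rate)) or 1
        env = np.ones(j - i)
        env[:ramp] = np.linspace(0, 1, ramp)
        env[-ramp:] = np.linspace(1, 0, ramp)
        x[i:j] += amp * env * burst
    return x


def render_signals(schedule: EventSchedule, config: SynthConfig) -> SignalRecord:
    """Render the five input channels for a schedule at the raw rate."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rate = config.raw_rate
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate

    # shared breathing phase with slow frequency jitter
    f_jitter = 1.0 + 0.05 * _smooth_envelope(rng.normal(0, 1, n), rate, 10.0)
    phase = 2 * np.pi * np.cumsum(config.resp_freq_hz * f_jitter) / rate

    nasal_env = np.ones(n)
    effort_env = np.ones(n)
    for ev, is_apnea in zip(schedule.sdb, schedule.sdb_is_apnea):
        i, j = int(ev.onset_s * rate), int(ev.offset_s * rate)
        if is_apnea:
            nasal_env[i:j] = rng.uniform(0.02, 0.07)
            effort_env[i:j] = rng.uniform(0.4, 0.8)
        else:
            nasal_env[i:j] = rng.uniform(0.3, 0.7)
            effort_env[i:j] = rng.uniform(0.5, 0.9)
    nasal_env = _smooth_envelope(nasal_env, rate, 1.0)
    effort_env = _smooth_envelope(effort_env, rate, 1.0)

    noise = lambda sd: rng.normal(0.0, sd, size=n)  # noqa: E731
    nasal = nasal_env * np.sin(phase) + noise(0.03)
    thor = 0.8 * effort_env * np.sin(phase - 0.3) + noise(0.03)
    abdo = 0.9 * effort_env * np.sin(phase - 0.1) + noise(0.03)

    lm = schedule.lm
    leg_l = _bursty_emg(rng, n, rate, lm, config.lm_burst_amp_uV, config.emg_baseline_sd_uV)
    leg_r = _bursty_emg(rng, n, rate, lm, config.lm_burst_amp_uV, config.emg_baseline_sd_uV)

    return SignalRecord(
        channels={"Leg/L": leg_l, "Leg/R": leg_r, "Abdo": abdo, "Thor": thor, "Nasal": nasal},
        rate=rate,
        units={"Leg/L": "uV", "Leg/R": "uV", "Abdo": "a.u.", "Thor": "a.u.", "Nasal": "a.u."},
        record_id=f"synth-{config.seed}",
    )


def simulate_record(config: SynthConfig) -> tuple[SignalRecord, EventSchedule]:
    """Convenience wrapper: schedule + rendered signals for one config."""
    schedule = sample_event_schedule(config)
    return render_signals(schedule, config), schedule
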