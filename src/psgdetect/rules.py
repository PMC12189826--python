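"""AASM-guided refinement and joint-detection logic.

After CRF smoothing, predictions are made physiologically plausible: LM
candidates closer than 0.5 s are merged (transitively) and then filtered to
the 0.5-10 s duration band; SDB candidates shorter than 10 s are dropped.
The joint-detection step flags respiratory-related leg movements (RRLM: an LM
intersecting an SDB interval padded by 0.5 s on each side), excludes them
from PLMS candidacy, and identifies PLMS series as maximal chains of >=4 LMs
whose consecutive onset-to-onset intervals lie within 5-90 s.  The per-hour
indices LMI, PLMI and AHI summarize a night.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .events import EventInterval

__all__ = [
    "RuleConfig",
    "refine_lm",
    "refine_sdb",
    "flag_rrlm",
    "detect_plms",
    "indices",
    "apply_rules",
]


@dataclass(frozen=True)
class RuleConfig:
    lm_merge_gap_s: float = 0.5
    lm_min_s: float = 0.5
    lm_max_s: float = 10.0
    sdb_min_s: float = 10.0
    rrlm_pad_s: float = 0.5
    plms_min_count: int = 4
    plms_interval_lo_s: float = 5.0
    plms_interval_hi_s: float = 90.0
    #: inter-movement interval measured onset-to-onset (WASM/AASM convention)
    #: or offset-to-onset
    plms_interval_mode: str = "onset"
    #: RRLM coupling read as interval intersection with the padded SDB window
    #: ("intersect") or as LM-onset containment ("onset")
    rrlm_mode: str = "intersect"

    def __post_init__(self) -> None:
        if min(self.lm_merge_gap_s, self.lm_min_s, self.sdb_min_s) <= 0 or self.rrlm_pad_s < 0:
            raise ValueError("rule thresholds must be positive (rrlm_pad_s >= 0)")
        if not self.lm_min_s < self.lm_max_s:
            raise ValueError("lm_min_s must be < lm_max_s")
        if not self.plms_interval_lo_s < self.plms_interval_hi_s:
            raise ValueError("plms interval bounds must be ordered")
        if self.plms_min_count < 2:
            raise ValueError("plms_min_count must be >= 2")


def _check_sorted(intervals: list[EventInterval]) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if b.onset_s < a.onset_s:
            raise ValueError("intervals must be sorted by onset")


def refine_lm(intervals: list[EventInterval], cfg: RuleConfig = RuleConfig()) -> list[EventInterval]:
    """Merge close LM candidates, then drop out-of-band durations.

    Merging runs first (transitively over gaps < ``lm_merge_gap_s``) so two
    valid sub-events split by a momentary dropout survive as one event; the
    duration thresholds then remove fragments and implausibly long movements.
    Idempotent: merged events are separated by >= the merge gap, and the kept
    durations are already in band.
    """
    _check_sorted(intervals)
    merged: list[EventInterval] = []
    for ev in intervals:
        if merged and ev.onset_s - merged[-1].offset_s < cfg.lm_merge_gap_s:
            prev = merged.pop()
            ev = EventInterval(
                prev.onset_s, max(prev.offset_s, ev.offset_s), "LM", prev.flags | ev.flags
            )
        merged.append(ev)
    return [e for e in merged if cfg.lm_min_s <= e.duration_s <= cfg.lm_max_s]


def refine_sdb(intervals: list[EventInterval], cfg: RuleConfig = RuleConfig()) -> list[EventInterval]:
    """Drop SDB candidates shorter than the 10 s scoring minimum (no upper bound)."""
    _check_sorted(intervals)
    return [e for e in intervals if e.duration_s >= cfg.sdb_min_s]


def flag_rrlm(
    lm_intervals: list[EventInterval],
    sdb_intervals: list[EventInterval],
    cfg: RuleConfig = RuleConfig(),
) -> list[EventInterval]:
    """Flag respiratory-related leg movements.

    An LM is RRLM iff it falls within 0.5 s before to 0.5 s after an SDB
    event; by default this is read as intersection of the LM interval with
    the padded SDB interval ``[onset - pad, offset + pad]``.
    """
    _check_sorted(lm_intervals)
    _check_sorted(sdb_intervals)
    out = []
    for lm in lm_intervals:
        coupled = False
        for sdb in sdb_intervals:
            lo, hi = sdb.onset_s - cfg.rrlm_pad_s, sdb.offset_s + cfg.rrlm_pad_s
            if cfg.rrlm_mode == "intersect":
                coupled = lm.intersects(lo, hi)
            else:
                coupled = lo <= lm.onset_s <= hi
            if coupled:
                break
        out.append(lm.with_flags("RRLM") if coupled else replace(lm, flags=lm.flags - {"RRLM"}))
    return out


def detect_plms(
    lm_intervals: list[EventInterval], cfg: RuleConfig = RuleConfig()
) -> tuple[list[EventInterval], list[list[EventInterval]]]:
    """Identify PLMS series among (non-RRLM) LM candidates.

    Scans the sorted LMs once: consecutive inter-movement intervals within
    [lo, hi] chain events together; a maximal chain with >= ``plms_min_count``
    members is a PLMS series and all its members are flagged.  An interval
    below ``lo`` breaks the chain (it does not merge the movements).

    Returns the flag-annotated list and the series as lists of members.
    """
    _check_sorted(lm_intervals)
    cleaned = [replace(e, flags=e.flags - {"PLMS"}) for e in lm_intervals]
    chains: list[list[int]] = []
    current: list[int] = []
    for i, ev in enumerate(cleaned):
        if not current:
            current = [i]
            continue
        prev = cleaned[current[-1]]
        gap = (
            ev.onset_s - prev.onset_s
            if cfg.plms_interval_mode == "onset"
            else ev.onset_s - prev.offset_s
        )
        if cfg.plms_interval_lo_s <= gap <= cfg.plms_interval_hi_s:
            current.append(i)
        else:
            chains.append(current)
            current = [i]
    if current:
        chains.append(current)

    series: list[list[EventInterval]] = []
    flagged = list(cleaned)
    for chain in chains:
        if len(chain) >= cfg.plms_min_count:
            for i in chain:
                flagged[i] = flagged[i].with_flags("PLMS")
            series.append([flagged[i] for i in chain])
    return flagged, series


def indices(events: list[EventInterval], total_sleep_time_h: float) -> dict[str, float]:
    """Per-hour event indices: LMI (all LMs), PLMI (PLMS-flagged LMs), AHI (SDB)."""
    if total_sleep_time_h <= 0:
        raise ValueError("total sleep time must be positive")
    n_lm = sum(1 for e in events if e.cls == "LM")
    n_plms = sum(1 for e in events if e.cls == "LM" and "PLMS" in e.flags)
    n_sdb = sum(1 for e in events if e.cls == "SDB")
    return {
        "LMI": n_lm / total_sleep_time_h,
        "PLMI": n_plms / total_sleep_time_h,
        "AHI": n_sdb / total_sleep_time_h,
    }


def apply_rules(
    lm_intervals: list[EventInterval],
    sdb_intervals: list[EventInterval],
    cfg: RuleConfig = RuleConfig(),
    joint: bool = True,
) -> list[EventInterval]:
    """Full refinement: merge/threshold both classes, then flag RRLM and PLMS.

    With ``joint=True`` the detected SDB events drive RRLM exclusion before
    PLMS chaining; with ``joint=False`` (single-event strategy) PLMS rests on
    periodicity alone and no RRLM flags are assigned.
    """
    lm = refine_lm(lm_intervals, cfg)
    sdb = refine_sdb(sdb_intervals, cfg)
    if joint:
        lm = flag_rrlm(lm, sdb, cfg)
        candidates = [e for e in lm if "RRLM" not in e.flags]
        flagged, _ = detect_plms(candidates, cfg)
        fmap = {(e.onset_s, e.offset_s): e for e in flagged}
        lm = [fmap.get((e.onset_s, e.offset_s), e) for e in lm]
    else:
        lm, _ = detect_plms(lm, cfg)
    return sorted(lm + sdb, key=lambda e: (e.onset_s, e.cls))
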