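"""AASM refinement rules: merging, thresholds, RRLM, PLMS chains, indices."""

import pytest

from psgdetect.events import EventInterval
from psgdetect.rules import (
    RuleConfig,
    apply_rules,
    detect_plms,
    flag_rrlm,
    indices,
    refine_lm,
    refine_sdb,
)


def lm(onset, offset, *flags):
    return EventInterval(onset, offset, "LM", frozenset(flags))


def sdb(onset, offset):
    return EventInterval(onset, offset, "SDB")


class TestRefineLM:
    def test_close_pair_merged(self):
        out = refine_lm([lm(0.0, 1.0), lm(1.3, 2.0)])
        assert [(e.onset_s, e.offset_s) for e in out] == [(0.0, 2.0)]

    def test_transitive_merge(self):
        out = refine_lm([lm(0.0, 1.0), lm(1.3, 2.0), lm(2.4, 3.0)])
        assert [(e.onset_s, e.offset_s) for e in out] == [(0.0, 3.0)]

    def test_short_event_dropped(self):
        assert refine_lm([lm(5.0, 5.2)]) == []

    def test_long_event_dropped(self):
        assert refine_lm([lm(5.0, 17.0)]) == []

    def test_gap_at_threshold_not_merged(self):
        out = refine_lm([lm(0.0, 1.0), lm(1.5, 2.5)])
        assert len(out) == 2

    def test_idempotent(self):
        evs = [lm(0.0, 1.0), lm(1.2, 1.9), lm(4.0, 4.3), lm(8.0, 9.5), lm(20.0, 31.0)]
        once = refine_lm(evs)
        assert refine_lm(once) == once

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            refine_lm([lm(5.0, 6.0), lm(0.0, 1.0)])


class TestRefineSDB:
    def test_sub_minimum_dropped_typical_kept(self):
        out = refine_sdb([sdb(0.0, 8.0), sdb(20.0, 47.0)])
        assert [(e.onset_s, e.offset_s) for e in out] == [(20.0, 47.0)]

    def test_no_upper_bound(self):
        assert len(refine_sdb([sdb(0.0, 151.0)])) == 1

    def test_empty(self):
        assert refine_sdb([]) == []


class TestFlagRRLM:
    def test_intersecting_padded_window_flagged(self):
        out = flag_rrlm([lm(30.0, 31.0)], [sdb(10.0, 29.8)])
        assert "RRLM" in out[0].flags  # padded window is (9.5, 30.3)

    def test_outside_padded_window_not_flagged(self):
        out = flag_rrlm([lm(31.0, 32.0)], [sdb(10.0, 29.8)])
        assert "RRLM" not in out[0].flags

    def test_no_sdb_no_flags(self):
        out = flag_rrlm([lm(1.0, 2.0), lm(5.0, 6.0)], [])
        assert all("RRLM" not in e.flags for e in out)

    def test_zero_pad_flags_exactly_overlapping(self):
        cfg = RuleConfig(rrlm_pad_s=0.0)
        events = [lm(9.0, 9.9), lm(9.95, 11.0), lm(30.1, 31.0)]
        out = flag_rrlm(events, [sdb(10.0, 30.0)], cfg)
        flags = ["RRLM" in e.flags for e in out]
        overlaps = [e.onset_s < 30.0 and e.offset_s > 10.0 for e in events]
        assert flags == overlaps


class TestDetectPLMS:
    def test_four_periodic_lms_form_series(self):
        evs = [lm(o, o + 1.0) for o in (0.0, 10.0, 20.0, 30.0)]
        flagged, series = detect_plms(evs)
        assert len(series) == 1 and len(series[0]) == 4
        assert all("PLMS" in e.flags for e in flagged)

    def test_three_lms_no_series(self):
        evs = [lm(o, o + 1.0) for o in (0.0, 10.0, 20.0)]
        flagged, series = detect_plms(evs)
        assert series == []
        assert all("PLMS" not in e.flags for e in flagged)

    def test_short_gap_breaks_chain(self):
        # gap of 4.5 s splits the sequence into chains of 2 and 3 -> no series
        evs = [lm(o, o + 1.0) for o in (0.0, 10.0, 14.5, 24.5, 34.5)]
        flagged, series = detect_plms(evs)
        assert series == []
        assert all("PLMS" not in e.flags for e in flagged)

    def test_long_gap_breaks_chain_but_both_sides_can_qualify(self):
        onsets = [0, 10, 20, 30, 200, 210, 220, 230]
        evs = [lm(float(o), float(o) + 1.0) for o in onsets]
        _, series = detect_plms(evs)
        assert [len(s) for s in series] == [4, 4]

    def test_interval_mode_offset(self):
        cfg = RuleConfig(plms_interval_mode="offset")
        # onset-to-onset gaps 10 s; offset-to-onset gaps 4 s -> chain broken
        evs = [lm(o, o + 6.0) for o in (0.0, 10.0, 20.0, 30.0)]
        _, series = detect_plms(evs, cfg)
        assert series == []


class TestIndices:
    def test_plmi_counts_only_plms_flagged(self):
        events = [lm(i * 10.0, i * 10.0 + 1, "PLMS") for i in range(40)]
        events += [lm(2000.0 + i * 200.0, 2000.0 + i * 200.0 + 1) for i in range(5)]
        idx = indices(events, 8.0)
        assert idx["PLMI"] == pytest.approx(5.0)
        assert idx["LMI"] == pytest.approx(45 / 8)

    def test_zero_sdb_gives_zero_ahi(self):
        assert indices([lm(0.0, 1.0)], 4.0)["AHI"] == 0.0

    def test_osa_range_classification(self):
        events = [sdb(i * 100.0, i * 100.0 + 20.0) for i in range(48)]
        assert indices(events, 8.0)["AHI"] >= 5.0

    def test_nonpositive_tst_rejected(self):
        with pytest.raises(ValueError):
            indices([], 0.0)


class TestJointPipeline:
    def test_rrlm_excluded_from_plms_candidacy(self):
        # 5 periodic LMs; the middle one is respiratory-coupled.  Joint
        # refinement must exclude it, leaving gaps of 20 s (still chainable).
        lms = [lm(o, o + 1.0) for o in (0.0, 10.0, 20.0, 30.0, 40.0)]
        sdbs = [sdb(11.6, 28.4)]  # padded window (11.1, 28.9) contains only the 20 s LM
        out = apply_rules(lms, sdbs, joint=True)
        lm_out = [e for e in out if e.cls == "LM"]
        rrlm = [e for e in lm_out if "RRLM" in e.flags]
        assert len(rrlm) == 1 and rrlm[0].onset_s == 20.0
        assert all("PLMS" not in e.flags for e in rrlm)
        plms = [e for e in lm_out if "PLMS" in e.flags]
        assert len(plms) == 4

    def test_single_strategy_flags_by_periodicity_alone(self):
        lms = [lm(o, o + 1.0) for o in (0.0, 10.0, 20.0, 30.0, 40.0)]
        sdbs = [sdb(9.0, 19.9)]
        out = apply_rules(lms, sdbs, joint=False)
        assert sum("PLMS" in e.flags for e in out if e.cls == "LM") == 5
        assert all("RRLM" not in e.flags for e in out)

    def test_simulator_rrlm_coupling_is_recovered(self, small_sim):
        _, _, sched = small_sim
        out = apply_rules(sched.lm, sched.sdb, joint=True)
        truth_rrlm = {e.onset_s for e in sched.lm if "RRLM" in e.flags}
        got_rrlm = {e.onset_s for e in out if e.cls == "LM" and "RRLM" in e.flags}
        assert truth_rrlm == got_rrlm
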