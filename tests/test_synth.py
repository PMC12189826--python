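"""Synthetic PSG generator: schedule statistics, rendering, determinism."""

import numpy as np
import pytest

from psgdetect.events import by_class
from psgdetect.synth import (
    SynthCapacityError,
    SynthConfig,
    render_signals,
    sample_event_schedule,
    simulate_record,
)


def _quiet(**kw):
    base = dict(duration_s=600.0, sdb_rate_per_h=0.0, plms_train_rate_per_h=0.0,
                lm_isolated_rate_per_h=0.0, p_rrlm=0.0, seed=1)
    base.update(kw)
    return SynthConfig(**base)


class TestSchedule:
    def test_all_rates_zero_gives_empty_schedule(self):
        assert sample_event_schedule(_quiet()).events == []

    def test_plms_train_gaps_within_rule_window(self):
        cfg = _quiet(plms_train_rate_per_h=6.0, seed=4)
        sched = sample_event_schedule(cfg)
        lms = sched.lm
        assert len(lms) >= 4
        gaps = np.diff([e.onset_s for e in lms])
        # within one train gaps fall in the scoring rule's 5-90 s periodic band
        assert ((gaps >= 5.0) & (gaps <= 90.0)).mean() > 0.8

    def test_rrlm_always_intersects_padded_window(self):
        cfg = _quiet(sdb_rate_per_h=20.0, p_rrlm=1.0, seed=5)
        sched = sample_event_schedule(cfg)
        sdbs = sched.sdb
        assert sdbs
        # brute-force interval-intersection oracle per SDB event
        for sdb in sdbs:
            hits = [
                lm for lm in sched.lm
                if lm.onset_s <= sdb.offset_s + 0.5 and lm.offset_s >= sdb.onset_s - 0.5
            ]
            assert len(hits) >= 1
        for lm in sched.lm:
            assert "RRLM" in lm.flags

    def test_duration_invariants_and_sorting(self, small_sim):
        _, _, sched = small_sim
        for e in sched.lm:
            assert 0.5 <= e.duration_s <= 10.0
        for e in sched.sdb:
            assert e.duration_s >= 10.0
        for cls in ("LM", "SDB"):
            evs = by_class(sched.events, cls)
            onsets = [e.onset_s for e in evs]
            assert onsets == sorted(onsets)
            for a, b in zip(evs, evs[1:]):
                assert a.offset_s <= b.onset_s  # within-class non-overlap

    def test_reproducible_for_fixed_seed(self):
        cfg = SynthConfig(duration_s=400.0, seed=11)
        assert sample_event_schedule(cfg).events == sample_event_schedule(cfg).events

    def test_different_seed_changes_schedule(self):
        a = sample_event_schedule(SynthConfig(duration_s=400.0, seed=1)).events
        b = sample_event_schedule(SynthConfig(duration_s=400.0, seed=2)).events
        assert a != b

    def test_median_durations_match_reference_statistics(self):
        # pool many short records; compare with clinical medians 1.85 s / 27.55 s
        lm_durs, sdb_durs = [], []
        seed = 0
        while len(lm_durs) < 500:
            cfg = SynthConfig(duration_s=1200.0, lm_isolated_rate_per_h=60.0,
                              sdb_rate_per_h=45.0, plms_train_rate_per_h=6.0, seed=seed)
            sched = sample_event_schedule(cfg)
            lm_durs += [e.duration_s for e in sched.lm]
            sdb_durs += [e.duration_s for e in sched.sdb]
            seed += 1
        assert 1.4 <= np.median(lm_durs) <= 2.4
        assert 22.0 <= np.median(sdb_durs) <= 34.0

    def test_capacity_error_when_rates_cannot_fit(self):
        with pytest.raises(SynthCapacityError):
            sample_event_schedule(SynthConfig(duration_s=60.0, sdb_rate_per_h=2000.0, seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(duration_s=-5.0)
        with pytest.raises(ValueError):
            SynthConfig(p_rrlm=1.5)
        with pytest.raises(ValueError):
            SynthConfig(lm_burst_amp_uV=(40.0, 10.0))


def _envelope_rms(x, rate, lo, hi):
    return float(np.sqrt(np.mean(np.asarray(x[int(lo * rate):int(hi * rate)]) ** 2)))


class TestRendering:
    def test_empty_schedule_leg_channels_are_baseline(self):
        cfg = _quiet(duration_s=120.0, seed=2)
        rec = render_signals(sample_event_schedule(cfg), cfg)
        for ch in ("Leg/L", "Leg/R"):
            sd = float(np.std(rec.channels[ch]))
            assert abs(sd - cfg.emg_baseline_sd_uV) / cfg.emg_baseline_sd_uV < 0.2

    def test_apnea_collapses_nasal_envelope(self):
        cfg = _quiet(duration_s=180.0, sdb_rate_per_h=20.0, apnea_frac=1.0, seed=9)
        sched = sample_event_schedule(cfg)
        assert sched.sdb
        rec = render_signals(sched, cfg)
        sdb = sched.sdb[0]
        inside = _envelope_rms(rec.channels["Nasal"], cfg.raw_rate,
                               sdb.onset_s + 2, sdb.offset_s - 2)
        before = _envelope_rms(rec.channels["Nasal"], cfg.raw_rate,
                               max(0.0, sdb.onset_s - 30), max(1.0, sdb.onset_s - 1))
        assert inside <= 0.10 * before

    def test_lm_burst_exceeds_emg_amplitude_criterion(self):
        cfg = _quiet(duration_s=120.0, lm_isolated_rate_per_h=30.0, seed=4)
        sched = sample_event_schedule(cfg)
        assert sched.lm
        rec = render_signals(sched, cfg)
        lm = sched.lm[0]
        inside = _envelope_rms(rec.channels["Leg/L"], cfg.raw_rate, lm.onset_s, lm.offset_s)
        # burst RMS must clear the quiet baseline by > 8 uV (scoring criterion)
        assert inside > cfg.emg_baseline_sd_uV + 8.0

    def test_rendering_deterministic(self):
        cfg = SynthConfig(duration_s=60.0, seed=13)
        r1, _ = simulate_record(cfg)
        r2, _ = simulate_record(cfg)
        for ch in r1.channels:
            assert np.array_equal(r1.channels[ch], r2.channels[ch])

    def test_five_channels_at_raw_rate(self, small_sim):
        cfg, rec, _ = small_sim
        assert set(rec.channels) == {"Leg/L", "Leg/R", "Abdo", "Thor", "Nasal"}
        assert rec.rate == cfg.raw_rate
        assert rec.n_samples == int(cfg.duration_s * cfg.raw_rate)
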