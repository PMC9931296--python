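"""Synthetic physiome generator: durations, determinism, structure."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import chisquare, pearsonr, ranksums

from seizewear.features import hrv_freq_domain, hrv_time_domain
from seizewear.preprocess import hr_to_rri
from seizewear.simulate import (
    DURATION_BINS,
    EffectSizes,
    SimConfig,
    generate_cohort,
    generate_subject,
    inject_seizure_signature,
    sample_seizure_duration,
    sample_seizure_durations,
)
from seizewear.streams import Channel, validate_subject


class TestDurationSampler:
    def test_degenerate_config_single_bin(self, rng):
        cfg = SimConfig(duration_probs=(1.0, 0, 0, 0, 0, 0))
        d = sample_seizure_durations(cfg, rng, 1000)
        assert np.all((d >= 1.0) & (d < 60.0))

    def test_sub_minute_fraction_matches_reported_distribution(self):
        # 81.3% of recorded seizures lasted under one minute
        rng = np.random.default_rng(2024)
        d = sample_seizure_durations(SimConfig(), rng, 100_000)
        frac = np.mean(d < 60.0)
        assert frac == pytest.approx(0.813, abs=0.004)

    def test_bin_frequencies_multinomial_oracle(self):
        rng = np.random.default_rng(7)
        n = 100_000
        d = sample_seizure_durations(SimConfig(), rng, n)
        edges = [lo for lo, _, _ in DURATION_BINS] + [600.0]
        counts, _ = np.histogram(d, bins=edges)
        probs = np.array([p for _, _, p in DURATION_BINS])
        # within 3 Monte-Carlo standard errors per bin
        se = np.sqrt(probs * (1 - probs) * n)
        assert np.all(np.abs(counts - probs * n) < 3.5 * se)
        # chi-square goodness of fit not rejected at alpha = 0.01
        _, p = chisquare(counts, probs * n)
        assert p > 0.01

    def test_cap_configurable(self, rng):
        cfg = SimConfig(duration_probs=(0, 0, 0, 0, 0, 1.0), max_seizure_duration_s=420.0)
        d = sample_seizure_durations(cfg, rng, 500)
        assert np.all((d >= 300.0) & (d <= 420.0))

    def test_single_draw_wrapper(self, rng):
        assert 1.0 <= sample_seizure_duration(SimConfig(), rng) <= 600.0


class TestGenerateSubject:
    def test_infant_mean_hr_near_115(self):
        cfg = SimConfig(duration_hours=4.0, seed=5, age_min_months=6, age_max_months=6)
        rec, truth = generate_subject(cfg, 0)
        assert truth.hr_baseline_bpm == 115.0
        hr = rec.streams[Channel.HR].values
        assert 108.0 <= hr.mean() <= 122.0

    def test_zero_duration_empty(self):
        rec, truth = generate_subject(SimConfig(duration_hours=0.0), 3)
        assert rec.streams == {} and rec.events == []

    def test_poisson_event_rate(self):
        # 2/day over a 96-h wear horizon: mean placed-event count ~8 within
        # 3 Monte-Carlo standard errors of the Poisson expectation
        from seizewear.simulate import _place_events

        cfg = SimConfig(seizures_per_day=2.0)
        reps = 200
        wear = [(0.0, 96.0 * 3600.0)]
        counts = [
            len(_place_events(cfg, np.random.default_rng(1000 + k), wear))
            for k in range(reps)
        ]
        lam = 8.0
        se = np.sqrt(lam / reps)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_records_satisfy_invariants(self, small_subject):
        _, record, truth = small_subject
        assert validate_subject(record) == []
        assert record.events == truth.events

    def test_determinism(self):
        cfg = SimConfig(duration_hours=1.0, seed=77)
        a, _ = generate_subject(cfg, 4)
        b, _ = generate_subject(cfg, 4)
        for ch in a.streams:
            np.testing.assert_array_equal(a.streams[ch].values, b.streams[ch].values)
            np.testing.assert_array_equal(
                a.streams[ch].timestamps_ms, b.streams[ch].timestamps_ms
            )
        assert a.events == b.events


class TestInjection:
    def _flat_record(self, hr_bpm=80.0, n_s=600):
        cfg = SimConfig(duration_hours=n_s / 3600.0, seed=1, seizures_per_day=0.0,
                        missing_rate=0.0, nonwear_rate=0.0)
        rec, _ = generate_subject(cfg, 0)
        return rec

    def test_identity_effects_leave_record_unchanged(self):
        from seizewear.streams import SeizureEvent

        rec = self._flat_record()
        before = {ch: s.values.copy() for ch, s in rec.streams.items()}
        ident = EffectSizes(hr_delta_bpm=0, gsr_delta_us=0, acc_burst_g=0,
                            gyr_burst_dps=0, hrv_suppression_factor=1.0, lfhf_gain=1.0)
        t0 = rec.span_ms()[0]
        ev = SeizureEvent(t0 + 100_000, t0 + 160_000, "simulated")
        out = inject_seizure_signature(rec, ev, ident, np.random.default_rng(0))
        for ch in before:
            np.testing.assert_array_equal(out.streams[ch].values, before[ch])

    def test_hr_delta_additive(self):
        from seizewear.streams import SeizureEvent

        rec = self._flat_record()
        hr = rec.streams[Channel.HR]
        t0 = rec.span_ms()[0]
        ev = SeizureEvent(t0 + 100_000, t0 + 200_000, "simulated")
        mask = (hr.timestamps_ms >= ev.onset_ms) & (hr.timestamps_ms < ev.offset_ms)
        before_mean = hr.values[mask].mean()
        eff = EffectSizes(hr_delta_bpm=30.0, hrv_suppression_factor=1.0, lfhf_gain=1.0,
                          gsr_delta_us=0, acc_burst_g=0, gyr_burst_dps=0)
        out = inject_seizure_signature(rec, ev, eff, np.random.default_rng(0))
        after_mean = out.streams[Channel.HR].values[mask].mean()
        assert after_mean == pytest.approx(before_mean + 30.0, abs=1.0)

    def test_event_outside_span_rejected(self):
        from seizewear.streams import SeizureEvent

        rec = self._flat_record()
        with pytest.raises(ValueError):
            inject_seizure_signature(
                rec, SeizureEvent(0, 1000, "simulated"), EffectSizes(),
                np.random.default_rng(0),
            )

    def test_hrv_suppression_and_lfhf_on_derived_rri(self):
        # on the clean derived RRI: in-event SDNN/RMSSD lower, LF/HF higher
        from seizewear.streams import SeizureEvent

        cfg = SimConfig(duration_hours=1.0, seed=21, seizures_per_day=0.0,
                        missing_rate=0.0, nonwear_rate=0.0)
        rec, _ = generate_subject(cfg, 2)
        t0 = rec.span_ms()[0]
        ev = SeizureEvent(t0 + 600_000, t0 + 900_000, "simulated")
        eff = EffectSizes(hrv_suppression_factor=0.3, lfhf_gain=3.0, hr_delta_bpm=0,
                          gsr_delta_us=0, acc_burst_g=0, gyr_burst_dps=0)
        out = inject_seizure_signature(rec, ev, eff, np.random.default_rng(0))
        hr = out.streams[Channel.HR]
        m = (hr.timestamps_ms >= ev.onset_ms) & (hr.timestamps_ms < ev.offset_ms)
        rri_in = hr_to_rri(hr.values[m])
        rri_out = hr_to_rri(hr.values[~m][:m.sum()])
        t_in, t_out = hrv_time_domain(rri_in), hrv_time_domain(rri_out)
        f_in, f_out = hrv_freq_domain(rri_in), hrv_freq_domain(rri_out)
        assert t_in["sdnn"] < t_out["sdnn"]
        assert t_in["rmssd"] < t_out["rmssd"]
        assert f_in["lf_hf"] > f_out["lf_hf"]


class TestCohort:
    def test_single_subject(self):
        c = generate_cohort(SimConfig(n_subjects=1, duration_hours=0.5, seed=2))
        assert len(c) == 1

    def test_bad_n_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(SimConfig(n_subjects=0))

    def test_same_seed_identical(self):
        cfg = SimConfig(n_subjects=3, duration_hours=0.5, seed=31)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for sa, sb in zip(a.subjects, b.subjects):
            for ch in sa.streams:
                np.testing.assert_array_equal(sa.streams[ch].values, sb.streams[ch].values)

    def test_age_hr_anticorrelation(self):
        cfg = SimConfig(n_subjects=60, duration_hours=0.25, seed=13,
                        seizures_per_day=0.0, missing_rate=0.0, nonwear_rate=0.0)
        cohort = generate_cohort(cfg)
        ages = [s.age_months for s in cohort.subjects]
        means = [s.streams[Channel.HR].values.mean() for s in cohort.subjects]
        r, _ = pearsonr(ages, means)
        assert r < -0.6

    def test_infant_daynight_flat_older_contrast(self):
        # infants: ~no day/night HR difference; >1 y: clear positive contrast
        import pandas as pd

        def day_night_delta(age):
            cfg = SimConfig(n_subjects=1, duration_hours=24.0, seed=19,
                            age_min_months=age, age_max_months=age,
                            seizures_per_day=0.0, missing_rate=0.0, nonwear_rate=0.0,
                            activity_bouts_per_hour=0.0)
            deltas = []
            for i in range(6):
                rec, _ = generate_subject(cfg, i)
                hr = rec.streams[Channel.HR]
                h = (hr.timestamps_ms / 3.6e6) % 24
                day = hr.values[(h >= 8) & (h < 20)].mean()
                night = hr.values[(h >= 21) | (h < 7)].mean()
                deltas.append(day - night)
            return np.mean(deltas)

        assert abs(day_night_delta(6)) < 2.0
        assert day_night_delta(100) > 3.0
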