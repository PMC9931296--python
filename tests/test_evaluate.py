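"""Alarm chaining, event-level sensitivity/FAR, curves, linearity."""

import numpy as np
import pandas as pd
import pytest

from seizewear.evaluate import (
    AlarmSeries,
    absolute_linearity,
    epochs_to_alarms,
    evaluate_detection,
    precision_recall,
    roc_far_sens,
    select_threshold,
)
from seizewear.streams import SeizureEvent


def _windows(times_s, scores, label="negative", length_s=60):
    return pd.DataFrame(
        {
            "start_ms": np.asarray(times_s) * 1000,
            "end_ms": (np.asarray(times_s) + length_s) * 1000,
            "score": scores,
            "label": [label] * len(times_s),
        }
    )


class TestAlarmChaining:
    def test_no_firing_epochs(self):
        w = _windows([0, 30, 60], [0.1, 0.2, 0.3])
        assert len(epochs_to_alarms(w, 0.5)) == 0

    def test_three_minute_merge(self):
        # positives at t = 0, 100, 200 s chain into one alarm (gaps <= 180 s)
        w = _windows([0, 100, 200], [0.9, 0.9, 0.9])
        alarms = epochs_to_alarms(w, 0.5)
        assert alarms.alarms == [(0, 260_000)]

    def test_gap_over_three_minutes_splits(self):
        w = _windows([0, 400], [0.9, 0.9])
        alarms = epochs_to_alarms(w, 0.5)
        assert len(alarms) == 2

    def test_excluded_windows_never_fire(self):
        w = _windows([0, 30], [0.9, 0.9], label="resting_excluded")
        assert len(epochs_to_alarms(w, 0.5)) == 0

    def test_merging_idempotent(self, rng):
        times = np.sort(rng.choice(np.arange(0, 4000, 30), 40, replace=False))
        w = _windows(times, rng.random(40))
        a1 = epochs_to_alarms(w, 0.4)
        spans = pd.DataFrame(
            {
                "start_ms": [a for a, _ in a1.alarms],
                "end_ms": [b for _, b in a1.alarms],
                "score": 1.0,
                "label": "negative",
            }
        )
        a2 = epochs_to_alarms(spans, 0.5)
        assert a2.alarms == a1.alarms

    def test_chaining_matches_bruteforce_oracle(self, rng):
        # 500 random layouts vs an interval-algebra oracle
        for trial in range(500):
            r = np.random.default_rng(trial)
            n = r.integers(1, 15)
            starts = np.sort(r.choice(np.arange(0, 3000, 30), n, replace=False))
            scores = r.random(n)
            w = _windows(starts, scores)
            got = epochs_to_alarms(w, 0.5).alarms
            # oracle: greedy chaining over firing windows
            firing = [(s * 1000, (s + 60) * 1000) for s, sc in zip(starts, scores) if sc >= 0.5]
            expected = []
            for s, e in firing:
                if expected and s - expected[-1][1] <= 180_000:
                    expected[-1] = (expected[-1][0], max(expected[-1][1], e))
                else:
                    expected.append((s, e))
            assert got == expected


class TestDetectionReport:
    def test_reported_discovery_arithmetic(self):
        # 1,148 of 1,290 seizures detected -> 89%; 125 false alarms over
        # 5,543 h -> 0.54 per 24 h
        rep_like = type("R", (), {})
        from seizewear.evaluate import DetectionReport

        rep = DetectionReport(1290, 1148, 125, 5543.0)
        assert round(rep.sensitivity_pct) == 89
        assert round(rep.far_per_24h, 2) == 0.54

    def test_reported_replication_arithmetic(self):
        from seizewear.evaluate import DetectionReport

        rep = DetectionReport(35, 28, 10, 264.0)
        assert round(rep.sensitivity_pct) == 80

    def test_zero_alarms(self):
        rep = evaluate_detection(
            AlarmSeries([], 0.5), [SeizureEvent(0, 30_000)], monitored_hours=10.0
        )
        assert rep.sensitivity_pct == 0.0 and rep.far_per_24h == 0.0

    def test_overlap_detection_rule(self):
        alarms = AlarmSeries([(100_000, 160_000)], 0.5)
        rep = evaluate_detection(alarms, [SeizureEvent(150_000, 170_000)], 24.0)
        assert rep.n_detected == 1 and rep.n_false_alarms == 0

    def test_buffer_touching_alarm_neither_tp_nor_fa(self):
        # alarm inside the post-event buffer: not a detection, not a false alarm
        alarms = AlarmSeries([(170_000, 200_000)], 0.5)
        rep = evaluate_detection(alarms, [SeizureEvent(100_000, 160_000)], 24.0)
        assert rep.n_detected == 0 and rep.n_false_alarms == 0

    def test_far_counts_unmatched_alarms(self):
        alarms = AlarmSeries([(0, 60_000), (500_000, 560_000)], 0.5)
        rep = evaluate_detection(alarms, [SeizureEvent(10_000, 20_000)], 48.0)
        assert rep.n_false_alarms == 1
        assert rep.far_per_24h == pytest.approx(0.5)

    def test_invalid_hours(self):
        with pytest.raises(ValueError):
            evaluate_detection(AlarmSeries([], 0.5), [], 0.0)

    def test_random_layouts_match_interval_oracle(self):
        for trial in range(200):
            r = np.random.default_rng(10_000 + trial)
            alarms = []
            t = 0
            for _ in range(r.integers(0, 8)):
                t += int(r.integers(10_000, 400_000))
                alarms.append((t, t + int(r.integers(10_000, 120_000))))
                t = alarms[-1][1]
            events = []
            t = 5000
            for _ in range(r.integers(1, 6)):
                t += int(r.integers(200_000, 600_000))
                events.append(SeizureEvent(t, t + int(r.integers(5_000, 90_000))))
                t = events[-1].offset_ms
            rep = evaluate_detection(AlarmSeries(alarms, 0.5), events, 24.0)
            det = sum(
                1
                for e in events
                if any(a < e.offset_ms and b > e.onset_ms for a, b in alarms)
            )
            fa = sum(
                1
                for a, b in alarms
                if not any(
                    a < e.offset_ms + 60_000 and b > e.onset_ms - 60_000 for e in events
                )
            )
            assert rep.n_detected == det and rep.n_false_alarms == fa


class TestCurves:
    def _scored(self):
        starts = np.arange(0, 3600, 30)
        scores = np.zeros(len(starts))
        labels = np.array(["negative"] * len(starts), dtype=object)
        # one seizure at [600, 660); its windows score high
        ev = SeizureEvent(600_000, 660_000)
        for i, s in enumerate(starts):
            if s * 1000 < ev.offset_ms and (s + 60) * 1000 > ev.onset_ms:
                labels[i] = "positive"
                scores[i] = 0.9
        scores[labels == "negative"] = np.linspace(0, 0.4, np.sum(labels == "negative"))
        df = _windows(starts, scores)
        df["label"] = labels
        df["subject_id"] = "s0"
        return df, {"s0": [ev]}, {"s0": 1.0}

    def test_oracle_scores_hit_perfect_corner(self):
        df, ev, hours = self._scored()
        curve = roc_far_sens(df, ev, hours)
        perfect = curve[(curve.far_per_24h == 0) & (curve.sensitivity_pct == 100)]
        assert len(perfect) > 0

    def test_extreme_thresholds(self):
        df, ev, hours = self._scored()
        curve = roc_far_sens(df, ev, hours)
        assert curve.iloc[0].far_per_24h == 0 and curve.iloc[0].sensitivity_pct == 0

    def test_sens_monotone_as_threshold_drops(self):
        df, ev, hours = self._scored()
        curve = roc_far_sens(df, ev, hours)
        sens = curve.sensitivity_pct.to_numpy()
        assert np.all(np.diff(sens) >= 0)

    def test_precision_recall_against_reference(self, rng):
        from sklearn.metrics import average_precision_score

        n = 2000
        df = _windows(np.arange(n) * 30, rng.random(n))
        df["label"] = np.where(rng.random(n) < 0.01, "positive", "negative")
        if (df["label"] == "positive").sum() == 0:
            df.loc[0, "label"] = "positive"
        pr = precision_recall(df)
        y = (df["label"] == "positive").astype(int)
        ap = average_precision_score(y, df["score"])
        assert ap == pytest.approx(y.mean(), abs=0.02)  # prevalence baseline
        assert (pr["precision"] >= 0).all() and (pr["recall"] <= 1).all()

    def test_select_threshold_geometry(self):
        curve = pd.DataFrame(
            {
                "threshold": [0.9, 0.7, 0.5, 0.3],
                "far_per_24h": [0.0, 0.2, 1.0, 5.0],
                "sensitivity_pct": [10.0, 95.0, 97.0, 100.0],
            }
        )
        assert select_threshold(curve) == 0.7

    def test_select_threshold_degenerate_default(self):
        assert select_threshold(pd.DataFrame({"threshold": [0.5], "far_per_24h": [0],
                                              "sensitivity_pct": [50]})) == 0.5


class TestAbsoluteLinearity:
    def test_identical_series_zero(self, rng):
        x = rng.uniform(60, 120, 50)
        assert absolute_linearity(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_offset_absorbed(self, rng):
        x = rng.uniform(60, 120, 50)
        assert absolute_linearity(x, x + 7.5) == pytest.approx(0.0, abs=1e-9)

    def test_five_point_outlier_closed_form(self):
        # reference [0,1,2,3,4], test equal except +1 at the middle point:
        # OLS residuals of y = x + e3 on x; hand-computed max |residual| = 0.8,
        # reference range 4 -> 20%
        ref = np.arange(5.0)
        test = ref.copy()
        test[2] += 1.0
        slope, intercept = np.polyfit(ref, test, 1)
        resid = np.max(np.abs(test - (slope * ref + intercept)))
        assert absolute_linearity(ref, test) == pytest.approx(resid / 4.0 * 100.0)
        assert absolute_linearity(ref, test) == pytest.approx(20.0, abs=1e-9)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            absolute_linearity(np.full(10, 5.0), np.arange(10.0))

    def test_nearest_neighbor_alignment(self):
        ref_ts = np.array([0.0, 10.0, 20.0])
        test_ts = np.array([0.0, 1.0, 9.0, 11.0, 19.5, 30.0])
        test_vals = np.array([1.0, 99.0, 2.0, 99.0, 3.0, 99.0])
        ref = np.array([1.0, 2.0, 3.0])
        err = absolute_linearity(ref, test_vals, reference_ts=ref_ts, test_ts=test_ts)
        assert err == pytest.approx(0.0, abs=1e-9)
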