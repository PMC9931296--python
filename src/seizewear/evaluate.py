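"""Event-level evaluation: alarms, sensitivity, false-alarm rate, curves.

Window scores become alarms by greedy chaining: every scored, non-excluded
window at or above the decision threshold extends the current alarm unless
more than 180 s separate it from the previous positive window, in which
case a new alarm begins.  A seizure counts as detected when at least one
alarm overlaps its ``[onset, offset)`` interval; alarms overlapping neither
a seizure nor its 60-s buffer zones are false alarms.  Sensitivity is the
percentage of seizures detected; FAR is false alarms per 24 monitored
hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .streams import SeizureEvent

__all__ = [
    "AlarmSeries",
    "DetectionReport",
    "epochs_to_alarms",
    "evaluate_detection",
    "roc_far_sens",
    "precision_recall",
    "select_threshold",
    "absolute_linearity",
    "window_auroc",
]

MERGE_GAP_S = 180
EXCLUDED_LABELS = ("qc_excluded", "resting_excluded", "buffer_excluded")


@dataclass
class AlarmSeries:
    """Disjoint alarm intervals [start_ms, end_ms) at one threshold."""

    alarms: list[tuple[int, int]]
    threshold: float

    def __len__(self) -> int:
        return len(self.alarms)


@dataclass
class DetectionReport:
    n_seizures: int
    n_detected: int
    n_false_alarms: int
    monitored_hours: float
    detected_flags: list[bool] = field(default_factory=list)

    @property
    def sensitivity_pct(self) -> float:
        if self.n_seizures == 0:
            return float("nan")
        return 100.0 * self.n_detected / self.n_seizures

    @property
    def far_per_24h(self) -> float:
        return self.n_false_alarms / (self.monitored_hours / 24.0)

    def rounded(self) -> dict:
        """Presentation convention: integer-percent sensitivity, 2-dp FAR."""
        return {
            "sensitivity_pct": round(self.sensitivity_pct),
            "far_per_24h": round(self.far_per_24h, 2),
            "n_seizures": self.n_seizures,
            "n_detected": self.n_detected,
            "n_false_alarms": self.n_false_alarms,
            "monitored_hours": round(self.monitored_hours, 1),
        }


def epochs_to_alarms(
    windows: pd.DataFrame,
    threshold: float,
    merge_gap_s: int = MERGE_GAP_S,
) -> AlarmSeries:
    """Chain positive-scoring windows into alarms.

    ``windows`` needs ``start_ms``, ``end_ms``, ``score`` and ``label``
    columns, time-sorted.  Excluded windows (qc/resting/buffer) never open
    or extend an alarm.  A window whose gap from the previous firing
    window's end exceeds ``merge_gap_s`` starts a new alarm; anything
    closer is merged, matching the rule that alerts within 3 minutes of
    each other count once.
    """
    df = windows
    firing = (df["score"].to_numpy() >= threshold) & ~df["label"].isin(EXCLUDED_LABELS).to_numpy()
    starts = df["start_ms"].to_numpy()[firing]
    ends = df["end_ms"].to_numpy()[firing]
    alarms: list[tuple[int, int]] = []
    gap_ms = merge_gap_s * 1000
    for s, e in zip(starts, ends):
        if alarms and s - alarms[-1][1] <= gap_ms:
            alarms[-1] = (alarms[-1][0], max(alarms[-1][1], int(e)))
        else:
            alarms.append((int(s), int(e)))
    return AlarmSeries(alarms, threshold)


def _overlaps_any(lo: int, hi: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(lo < b and hi > a for a, b in intervals)


def evaluate_detection(
    alarms: AlarmSeries,
    events: Sequence[SeizureEvent],
    monitored_hours: float,
    buffer_s: int = 60,
) -> DetectionReport:
    """Score an alarm series against annotated seizures.

    A seizure is detected iff any alarm overlaps it; an alarm is a false
    alarm iff it overlaps neither a seizure nor the 60-s buffer zone around
    one (buffer-touching alarms count as neither true nor false).
    """
    if monitored_hours <= 0:
        raise ValueError("monitored_hours must be positive")
    ev = sorted(events, key=lambda e: e.onset_ms)
    seiz = [(e.onset_ms, e.offset_ms) for e in ev]
    buffered = [(a - buffer_s * 1000, b + buffer_s * 1000) for a, b in seiz]
    flags = [_overlaps_any(a, b, alarms.alarms) for a, b in seiz]
    n_fa = sum(1 for a, b in alarms.alarms if not _overlaps_any(a, b, buffered))
    return DetectionReport(
        n_seizures=len(seiz),
        n_detected=int(sum(flags)),
        n_false_alarms=n_fa,
        monitored_hours=float(monitored_hours),
        detected_flags=[bool(f) for f in flags],
    )


def _evaluate_grouped(
    windows: pd.DataFrame,
    events_by_subject: dict[str, list[SeizureEvent]],
    hours_by_subject: dict[str, float],
    threshold: float,
) -> DetectionReport:
    """Pool per-subject alarm evaluation into one report."""
    n_s = n_d = n_fa = 0
    hours = 0.0
    flags: list[bool] = []
    for sid, g in windows.groupby("subject_id", sort=True):
        rep = evaluate_detection(
            epochs_to_alarms(g.sort_values("start_ms"), threshold),
            events_by_subject.get(sid, []),
            max(hours_by_subject.get(sid, 0.0), 1e-9),
        )
        n_s += rep.n_seizures
        n_d += rep.n_detected
        n_fa += rep.n_false_alarms
        hours += hours_by_subject.get(sid, 0.0)
        flags.extend(rep.detected_flags)
    return DetectionReport(n_s, n_d, n_fa, hours, flags)


def roc_far_sens(
    windows: pd.DataFrame,
    events_by_subject: dict[str, list[SeizureEvent]],
    hours_by_subject: dict[str, float],
    max_thresholds: int = 200,
) -> pd.DataFrame:
    """(FAR, Sens) operating points over descending decision thresholds.

    Candidate thresholds are the unique window scores (quantile-thinned to
    ``max_thresholds`` when there are more), preceded by an unattainable
    threshold that yields the (0, 0) corner.
    """
    if sum(len(v) for v in events_by_subject.values()) == 0:
        raise ValueError("need at least one seizure event to build a FAR/Sens curve")
    scores = windows["score"].to_numpy()
    uniq = np.unique(scores[np.isfinite(scores)])
    if len(uniq) > max_thresholds:
        uniq = np.unique(np.quantile(uniq, np.linspace(0, 1, max_thresholds)))
    thresholds = np.concatenate([[uniq.max() + 1.0], uniq[::-1]])
    rows = []
    for th in thresholds:
        rep = _evaluate_grouped(windows, events_by_subject, hours_by_subject, th)
        rows.append({"threshold": th, "far_per_24h": rep.far_per_24h,
                     "sensitivity_pct": rep.sensitivity_pct})
    return pd.DataFrame(rows)


def precision_recall(windows: pd.DataFrame) -> pd.DataFrame:
    """Window-level precision/recall over thresholds, on positive vs
    negative windows only (excluded windows are dropped)."""
    df = windows[windows["label"].isin(["positive", "negative"])]
    y = (df["label"] == "positive").to_numpy().astype(int)
    if y.sum() == 0:
        raise ValueError("need at least one positive window")
    prec, rec, thr = precision_recall_curve(y, df["score"].to_numpy())
    return pd.DataFrame(
        {"precision": prec[:-1], "recall": rec[:-1], "threshold": thr}
    )


def window_auroc(windows: pd.DataFrame) -> float:
    """Pooled window-level AUROC on positive vs negative windows."""
    df = windows[windows["label"].isin(["positive", "negative"])]
    y = (df["label"] == "positive").to_numpy().astype(int)
    return float(roc_auc_score(y, df["score"].to_numpy()))


def select_threshold(curve: pd.DataFrame, default: float = 0.5) -> float:
    """Operating threshold closest to the ideal corner (Sens 100%, FAR 0)
    on min-max-normalized axes; degenerate curves fall back to the 0.5
    deployment default."""
    if len(curve) < 2:
        return default
    far = curve["far_per_24h"].to_numpy(dtype=float)
    sens = curve["sensitivity_pct"].to_numpy(dtype=float) / 100.0
    far_range = far.max() - far.min()
    far_n = (far - far.min()) / far_range if far_range > 0 else np.zeros_like(far)
    dist = np.hypot(far_n, 1.0 - sens)
    return float(curve["threshold"].to_numpy()[np.argmin(dist)])


def absolute_linearity(
    reference: np.ndarray,
    test: np.ndarray,
    reference_ts: np.ndarray | None = None,
    test_ts: np.ndarray | None = None,
) -> float:
    """Absolute-linearity percent error between two aligned series.

    The test series is regressed on the reference (ordinary least squares
    line, so constant offsets and gain are absorbed); the error is the
    maximum absolute residual divided by the reference range, times 100.
    When timestamps are supplied the test series is first aligned to the
    reference ticks by nearest-neighbor matching.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if reference_ts is not None and test_ts is not None:
        rts = np.asarray(reference_ts, dtype=float)
        tts = np.asarray(test_ts, dtype=float)
        pos = np.searchsorted(tts, rts)
        pos = np.clip(pos, 1, len(tts) - 1)
        left, right = tts[pos - 1], tts[pos]
        nearest = np.where(np.abs(rts - left) <= np.abs(right - rts), pos - 1, pos)
        tst = tst[nearest]
    if len(ref) != len(tst) or len(ref) < 2:
        raise ValueError("need two aligned series of equal length >= 2")
    rng = ref.max() - ref.min()
    if rng == 0:
        raise ValueError("reference series is constant (zero range)")
    slope, intercept = np.polyfit(ref, tst, 1)
    resid = tst - (slope * ref + intercept)
    return float(np.max(np.abs(resid)) / rng * 100.0)
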