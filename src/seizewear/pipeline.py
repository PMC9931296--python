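"""End-to-end orchestration: preprocessed subject -> window feature table ->
cross-validated scores -> event-level report, plus the streaming monitor.

The batch featurizer is vectorized over windows but computes exactly the
same statistics as the per-window operations in :mod:`seizewear.features`;
the streaming monitor re-uses the identical featurization on a tick-anchored
window grid, so batch and streaming alarms agree exactly on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import features as ft
from .evaluate import (
    AlarmSeries,
    DetectionReport,
    MERGE_GAP_S,
    _evaluate_grouped,
    window_auroc,
)
from .model import BoosterConfig, EnsembleModel, assign_cv_folds, cross_validate
from .preprocess import PreprocessedSubject, preprocess_subject
from .segment import CLASSIFY_SPEC, RESTING_SIGMA_G, Label, WindowSpec, label_windows, make_windows
from .streams import Cohort, SubjectRecord

__all__ = [
    "featurize_subject",
    "featurize_cohort",
    "run_cohort_detection",
    "streaming_monitor",
    "DetectionExperiment",
]

MAX_WINDOW_MISSING = 0.60  # windows with more than 60% data missing are excluded

_FAMS = ("HR", "GSR", "ACC_MAG", "GYR_MAG")  # channels checked for missingness


def _window_rows(grid: np.ndarray, rate_hz: float, spec: WindowSpec, n_windows: int) -> np.ndarray:
    """View of ``grid`` as (n_windows, samples-per-window)."""
    win_n = int(round(spec.length_s * rate_hz))
    step_n = int(round(spec.step_s * rate_hz))
    if len(grid) < win_n:
        return np.full((n_windows, max(win_n, 1)), np.nan)
    rows = sliding_window_view(grid, win_n)[::step_n]
    return rows[:n_windows]


def _grids(
    pre: PreprocessedSubject, residuals: bool
) -> tuple[dict[str, tuple[np.ndarray, float]], dict[str, np.ndarray]]:
    """Variable name -> (grid array, rate) plus raw-observation masks.

    ACC/GYR magnitudes are computed from the processed (pre-residual) axis
    values — the net-acceleration norm — and then themselves median-centered
    when residuals are requested.
    """
    out: dict[str, tuple[np.ndarray, float]] = {}
    observed: dict[str, np.ndarray] = {}
    for name, ch in pre.channels.items():
        arr = ch.residuals if residuals else ch.values
        out[name] = (arr, 1000.0 / ch.period_ms)
        observed[name] = ch.observed
    # magnitudes are first-class preprocessed channels; fall back to a
    # direct norm of the axis values only if they are absent
    for fam in ("ACC", "GYR"):
        if f"{fam}_MAG" not in out and all(f"{fam}_{a}" in pre.channels for a in "XYZ"):
            chans = [pre.channels[f"{fam}_{a}"] for a in "XYZ"]
            mag = np.sqrt(sum(c.values**2 for c in chans))
            if residuals and np.isfinite(mag).any():
                mag = mag - np.nanmedian(mag)
            out[f"{fam}_MAG"] = (mag, 1000.0 / chans[0].period_ms)
            observed[f"{fam}_MAG"] = chans[0].observed & chans[1].observed & chans[2].observed
    return out, observed


def featurize_subject(
    pre: PreprocessedSubject,
    spec: WindowSpec = CLASSIFY_SPEC,
    buffer_s: int = 60,
    use_residuals: bool = True,
) -> pd.DataFrame:
    """Build the labeled 120-feature table for one subject's windows.

    Windows with more than 60% of any core channel (HR, GSR, ACC or GYR
    magnitude) missing — or lying outside wear time — are ``qc_excluded``.
    Low-motion windows (ACC-magnitude sigma < 0.1 g) that are not seizure
    windows become ``resting_excluded``; all resting windows are flagged in
    the boolean ``resting`` column and will be forced to score 0.
    """
    record = pre.record
    starts = make_windows((pre.t0_ms, pre.t1_ms), spec)
    n = len(starts)
    cols: dict[str, np.ndarray] = {}
    grids, observed = _grids(pre, use_residuals)
    missing_frac: dict[str, np.ndarray] = {}

    for var in ("HR", "RRI", "GSR", "ACC_X", "ACC_Y", "ACC_Z", "ACC_MAG",
                "GYR_X", "GYR_Y", "GYR_Z", "GYR_MAG"):
        if var in grids:
            grid, rate = grids[var]
            rows = _window_rows(grid, rate, spec, n)
            stats = ft.summary_stats_matrix(rows)
            if var in _FAMS:
                obs_rows = _window_rows(observed[var].astype(float), rate, spec, n)
                missing_frac[var] = 1.0 - np.nan_to_num(obs_rows).mean(axis=-1)
            if var == "RRI":
                hrv = ft.hrv_time_matrix(rows)
                hrv.update(ft.hrv_freq_matrix(rows, fs_hz=rate))
                for k in ft.HRV_NAMES:
                    cols[f"HRV_{k}"] = hrv[k]
        else:
            stats = {s: np.full(n, np.nan) for s in ft.SUMMARY_STAT_NAMES}
            if var == "RRI":
                for k in ft.HRV_NAMES:
                    cols[f"HRV_{k}"] = np.full(n, np.nan)
        for k, v in stats.items():
            cols[f"{var}_{k}"] = v

    labels = label_windows(starts, spec.length_s, record.events, buffer_s=buffer_s)

    qc_bad = np.zeros(n, dtype=bool)
    for fam, frac in missing_frac.items():
        qc_bad |= frac > MAX_WINDOW_MISSING
    ends = starts + spec.length_s * 1000
    if record.wear_intervals:
        worn = np.zeros(n, dtype=bool)
        for a, b in record.wear_intervals:
            worn |= (starts >= a) & (ends <= b)
        qc_bad |= ~worn

    # motion-state sigma from the denoised, pre-trim ACC magnitude (the
    # 0.1-g rest threshold is calibrated for unsmoothed dynamic acceleration)
    acc_mag = pre.channels.get("ACC_MAG")
    if acc_mag is not None and acc_mag.pretrim is not None:
        rate = 1000.0 / acc_mag.period_ms
        rows = _window_rows(acc_mag.pretrim, rate, spec, n)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            counts = np.isfinite(rows).sum(axis=-1)
            sigma = np.where(counts >= 2, np.nanstd(rows, axis=-1, ddof=1), np.nan)
    else:
        sigma = cols.get("ACC_MAG_std", np.full(n, np.nan))
    resting = np.isfinite(sigma) & (sigma < RESTING_SIGMA_G)
    labels = labels.copy()
    labels[qc_bad] = Label.QC_EXCLUDED.value
    rest_neg = resting & ~qc_bad & (labels != Label.POSITIVE.value)
    labels[rest_neg] = Label.RESTING_EXCLUDED.value

    meta = {
        "subject_id": np.repeat(record.subject_id, n),
        "age_months": np.repeat(record.age_months, n),
        "sex": np.repeat(record.sex, n),
        "start_ms": starts,
        "end_ms": ends,
        "label": labels,
        "resting": resting,
        "sigma_g": sigma,
    }
    df = pd.DataFrame({**meta, **{k: cols[k] for k in ft.FEATURE_NAMES}})
    return df


def featurize_cohort(
    cohort: Cohort, spec: WindowSpec = CLASSIFY_SPEC, buffer_s: int = 60
) -> pd.DataFrame:
    frames = [
        featurize_subject(preprocess_subject(rec), spec, buffer_s)
        for rec in cohort.subjects
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass
class DetectionExperiment:
    """Pooled cross-validation outcome for a cohort."""

    windows: pd.DataFrame  # scored window table
    report: DetectionReport
    auroc: float
    folds: dict[str, int]


def run_cohort_detection(
    cohort: Cohort,
    config: BoosterConfig | None = None,
    n_folds: int = 10,
    threshold: float = 0.5,
    seed: int = 0,
    windows: pd.DataFrame | None = None,
) -> DetectionExperiment:
    """Featurize a cohort, run patient-grouped CV, and evaluate events.

    Monitored hours per subject are total wear hours (buffer time included
    in the denominator).
    """
    config = config or BoosterConfig()
    if windows is None:
        windows = featurize_cohort(cohort)
    counts = {s.subject_id: len(s.events) for s in cohort.subjects}
    folds = assign_cv_folds(
        list(counts), [counts[k] for k in counts], n_folds=n_folds, seed=seed
    )
    scored = cross_validate(windows, ft.FEATURE_NAMES, folds, config, seed=seed)
    scored = scored[scored["label"] != Label.QC_EXCLUDED.value].copy()
    events_by_subject = {s.subject_id: list(s.events) for s in cohort.subjects}
    hours_by_subject = {
        s.subject_id: sum(b - a for a, b in s.wear_intervals) / 3.6e6
        for s in cohort.subjects
    }
    report = _evaluate_grouped(scored, events_by_subject, hours_by_subject, threshold)
    return DetectionExperiment(scored, report, window_auroc(scored), folds)


def streaming_monitor(
    record: SubjectRecord,
    model: EnsembleModel,
    threshold: float,
    cadence_s: int = 30,
    window_s: int = 60,
    merge_gap_s: int = MERGE_GAP_S,
) -> AlarmSeries:
    """Replay a subject's record, scoring the trailing 60-s window every 30 s.

    Ticks with less than a full trailing window are skipped.  Alarms are
    chained online with the 3-minute merge rule; on an identical window
    grid the result equals the batch path exactly, because each tick's
    features come from the same featurization code.
    """
    pre = preprocess_subject(record)
    spec = WindowSpec(window_s, cadence_s)
    table = featurize_subject(pre, spec)
    X = table[list(ft.FEATURE_NAMES)]
    alarms: list[tuple[int, int]] = []
    gap_ms = merge_gap_s * 1000
    from .model import predict_scores

    # One tick at a time: the monitor never looks ahead of the current window.
    for i in range(len(table)):
        row = table.iloc[[i]]
        if row["label"].iloc[0] in ("qc_excluded",):
            continue
        score = predict_scores(
            model, X.iloc[[i]], resting_mask=row["resting"].to_numpy()
        )[0]
        if row["label"].iloc[0] in ("resting_excluded", "buffer_excluded"):
            continue
        if score >= threshold:
            s, e = int(row["start_ms"].iloc[0]), int(row["end_ms"].iloc[0])
            if alarms and s - alarms[-1][1] <= gap_ms:
                alarms[-1] = (alarms[-1][0], max(alarms[-1][1], e))
            else:
                alarms.append((s, e))
    return AlarmSeries(alarms, threshold)
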