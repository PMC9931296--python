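"""Cohort physiome profiling: developmental baselines outside seizure time.

Per subject, seizure intervals are excluded and the ten summary statistics
of seven variables (HR, SDNN, the three ACC axes, ACC magnitude, GSR) are
computed over all retained time, giving an n x 70 subject feature matrix.
SDNN is computed per 5-minute epoch (80% overlap) and then summarized.

Day is [08:00, 20:00) local clock, night [21:00, 07:00); the two unassigned
hours are excluded from both periods.  Day/night contrasts use two-sided
Wilcoxon rank-sum tests within age bands (0-1, 1-3, 3-5, >5 years), and a
multiple linear regression of each variable's period mean on age (months),
sex (0 = male, 1 = female) and period (0 = night, 1 = day) quantifies the
developmental effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import ranksums

from . import features as ft
from .preprocess import PreprocessedSubject, preprocess_subject
from .segment import EPOCH_SPEC, make_windows
from .streams import Cohort

__all__ = [
    "PHYSIOME_VARS",
    "AGE_BANDS",
    "MlrModel",
    "PcaModel",
    "subject_variable_series",
    "build_subject_matrix",
    "fit_mlr_daynight",
    "fit_mlr_by_period",
    "pca_project",
    "daynight_tests",
]

PHYSIOME_VARS: tuple[str, ...] = ("HR", "SDNN", "ACC_X", "ACC_Y", "ACC_Z", "ACC_MAG", "GSR")

#: Age bands in months: 0-1, 1-3, 3-5, >5 years.
AGE_BANDS: tuple[tuple[float, float, str], ...] = (
    (0, 12, "0-1y"),
    (12, 36, "1-3y"),
    (36, 60, "3-5y"),
    (60, np.inf, ">5y"),
)

DAY_HOURS = (8.0, 20.0)
NIGHT_HOURS = (21.0, 7.0)  # wraps midnight


def _clock_hours(ts_ms: np.ndarray) -> np.ndarray:
    # Unix ms -> local clock hour; UTC by construction of the simulator.
    return (ts_ms / 3.6e6) % 24.0


def _period_mask(ts_ms: np.ndarray, period: str) -> np.ndarray:
    h = _clock_hours(ts_ms)
    if period == "day":
        return (h >= DAY_HOURS[0]) & (h < DAY_HOURS[1])
    return (h >= NIGHT_HOURS[0]) | (h < NIGHT_HOURS[1])


def subject_variable_series(
    pre: PreprocessedSubject, use_residuals: bool = False
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Variable -> (timestamps_ms, values) outside seizure time.

    HR/ACC/GSR are sample series (raw scale by default, so age trends
    survive); SDNN is one value per 5-min epoch of the pseudo-RRI.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    events = [(e.onset_ms, e.offset_ms) for e in pre.record.events]

    def drop_seizure(ts: np.ndarray, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        keep = np.isfinite(vals)
        for a, b in events:
            keep &= ~((ts >= a) & (ts < b))
        return ts[keep], vals[keep]

    grids: dict[str, tuple[np.ndarray, int, int]] = {}
    for name, ch in pre.channels.items():
        arr = ch.residuals if use_residuals else ch.values
        grids[name] = (arr, ch.grid_t0_ms, ch.period_ms)
    if "ACC_MAG" not in grids and all(f"ACC_{a}" in grids for a in "XYZ"):
        ax, t0, p = grids["ACC_X"]
        ay, _, _ = grids["ACC_Y"]
        az, _, _ = grids["ACC_Z"]
        grids["ACC_MAG"] = (np.sqrt(ax**2 + ay**2 + az**2), t0, p)

    for var in ("HR", "GSR", "ACC_X", "ACC_Y", "ACC_Z", "ACC_MAG"):
        if var in grids:
            arr, t0, p = grids[var]
            ts = t0 + p * np.arange(len(arr), dtype=np.int64)
            out[var] = drop_seizure(ts, arr)

    if "RRI" in grids:
        arr, t0, p = grids["RRI"]
        rate = 1000.0 / p
        starts = make_windows((t0, t0 + p * len(arr)), EPOCH_SPEC)
        if len(starts):
            win_n = int(round(EPOCH_SPEC.length_s * rate))
            step_n = int(round(EPOCH_SPEC.step_s * rate))
            from numpy.lib.stride_tricks import sliding_window_view

            rows = sliding_window_view(arr, win_n)[::step_n][: len(starts)]
            sdnn = ft.hrv_time_matrix(rows)["sdnn"]
            mids = starts + EPOCH_SPEC.length_s * 500
            out["SDNN"] = drop_seizure(mids, sdnn)
    return out


def build_subject_matrix(cohort: Cohort) -> pd.DataFrame:
    """The n x 70 subject feature matrix (10 statistics x 7 variables).

    Subjects with no retained data for some variable get NaN there and are
    dropped with a warning by downstream consumers; the returned frame also
    carries ``age_months`` and ``sex`` as metadata columns.
    """
    rows = []
    for rec in cohort.subjects:
        pre = preprocess_subject(rec)
        series = subject_variable_series(pre)
        row: dict[str, float] = {
            "subject_id": rec.subject_id,
            "age_months": rec.age_months,
            "sex": rec.sex,
        }
        for var in PHYSIOME_VARS:
            ts, vals = series.get(var, (np.zeros(0), np.zeros(0)))
            st = ft.summary_stats(vals)
            row.update({f"{var}_{k}": v for k, v in st.items()})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("subject_id")
    return df


@dataclass
class MlrModel:
    """OLS fit of a variable's day/night means on age, sex and period."""

    response: str
    params: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    nobs: int
    rsquared: float


def fit_mlr_daynight(cohort: Cohort, response: str) -> MlrModel:
    """Stacked day/night regression: one day row and one night row per
    subject, response = period mean of the variable, regressors age
    (months), sex (female = 1) and period (day = 1), intercept included."""
    rows = []
    for rec in cohort.subjects:
        pre = preprocess_subject(rec)
        series = subject_variable_series(pre)
        if response not in series:
            continue
        ts, vals = series[response]
        for period, flag in (("day", 1), ("night", 0)):
            m = _period_mask(ts, period)
            if m.sum() == 0:
                continue
            rows.append(
                {
                    "y": float(np.mean(vals[m])),
                    "age": rec.age_months,
                    "sex": 1.0 if rec.sex == "female" else 0.0,
                    "period": float(flag),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty or df["sex"].nunique() < 2 or df["age"].nunique() < 2:
        raise ValueError("need both sexes and age variation to fit the regression")
    X = sm.add_constant(df[["age", "sex", "period"]])
    fit = sm.OLS(df["y"], X).fit()
    return MlrModel(response, fit.params, fit.pvalues, fit.bse, int(fit.nobs), fit.rsquared)


def fit_mlr_by_period(cohort: Cohort, response: str) -> dict[str, MlrModel]:
    """Separate day and night regressions of the period means on age and
    sex (the stacked fit above is the primary report; these are the
    per-period companions)."""
    rows = {"day": [], "night": []}
    for rec in cohort.subjects:
        pre = preprocess_subject(rec)
        series = subject_variable_series(pre)
        if response not in series:
            continue
        ts, vals = series[response]
        for period in ("day", "night"):
            m = _period_mask(ts, period)
            if m.sum() == 0:
                continue
            rows[period].append(
                {
                    "y": float(np.mean(vals[m])),
                    "age": rec.age_months,
                    "sex": 1.0 if rec.sex == "female" else 0.0,
                }
            )
    out: dict[str, MlrModel] = {}
    for period, recs in rows.items():
        df = pd.DataFrame(recs)
        if df.empty or df["sex"].nunique() < 2 or df["age"].nunique() < 2:
            continue
        fit = sm.OLS(df["y"], sm.add_constant(df[["age", "sex"]])).fit()
        out[period] = MlrModel(
            f"{response}:{period}", fit.params, fit.pvalues, fit.bse,
            int(fit.nobs), fit.rsquared,
        )
    return out


@dataclass
class PcaModel:
    components: np.ndarray  # (m_kept, d) orthonormal loading matrix W
    explained_variance_ratio: np.ndarray
    coordinates: pd.DataFrame  # (n, d) projections
    kept_columns: list[str]


def pca_project(matrix: pd.DataFrame, d: int = 3) -> PcaModel:
    """Project the subject matrix onto its top-``d`` principal axes.

    Each feature column is min-max scaled to [0, 1] and then mean-centered
    before the eigendecomposition; constant columns are dropped.  Rows with
    any NaN are dropped (subjects lacking a channel).
    """
    feat_cols = [c for c in matrix.columns if c not in ("age_months", "sex")]
    X = matrix[feat_cols].astype(float)
    X = X.dropna(axis=0)
    if len(X) <= d:
        raise ValueError(f"need more than d={d} complete subjects, got {len(X)}")
    rng_ = X.max() - X.min()
    kept = list(X.columns[rng_ > 0])
    Xs = (X[kept] - X[kept].min()) / (X[kept].max() - X[kept].min())
    Xc = Xs - Xs.mean()
    u, s, vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
    var = s**2
    W = vt[:d].T
    coords = pd.DataFrame(
        Xc.to_numpy() @ W, index=X.index, columns=[f"PC{i+1}" for i in range(d)]
    )
    return PcaModel(W, var[:d] / var.sum(), coords, kept)


def age_band(age_months: float) -> str:
    for lo, hi, name in AGE_BANDS:
        if lo <= age_months < hi:
            return name
    return AGE_BANDS[-1][2]


def daynight_tests(cohort: Cohort, variable: str) -> pd.DataFrame:
    """Per age band, two-sided Wilcoxon rank-sum test of the subjects' day
    means against their night means for ``variable``.

    Bands with fewer than 3 subjects observed in both periods are marked
    not testable (NaN p-value).
    """
    recs = []
    for rec in cohort.subjects:
        pre = preprocess_subject(rec)
        series = subject_variable_series(pre)
        if variable not in series:
            continue
        ts, vals = series[variable]
        day_m = _period_mask(ts, "day")
        night_m = _period_mask(ts, "night")
        if day_m.sum() == 0 or night_m.sum() == 0:
            continue
        recs.append(
            {
                "band": age_band(rec.age_months),
                "day_mean": float(np.mean(vals[day_m])),
                "night_mean": float(np.mean(vals[night_m])),
            }
        )
    df = pd.DataFrame(recs)
    rows = []
    for _, _, name in AGE_BANDS:
        g = df[df["band"] == name] if len(df) else df
        if len(g) < 3:
            rows.append({"band": name, "n": len(g), "statistic": np.nan, "pvalue": np.nan,
                         "day_mean": np.nan, "night_mean": np.nan})
            continue
        stat, p = ranksums(g["day_mean"], g["night_mean"])
        rows.append(
            {
                "band": name,
                "n": len(g),
                "statistic": float(stat),
                "pvalue": float(p),
                "day_mean": float(g["day_mean"].mean()),
                "night_mean": float(g["night_mean"].mean()),
            }
        )
    return pd.DataFrame(rows)
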