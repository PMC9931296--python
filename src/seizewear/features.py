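"""Feature extraction: summary statistics, HRV parameters, and the
120-feature vector computed from each 60-s window.

Block structure (names and order are frozen):

* HR statistics (10), pseudo-RRI statistics (10),
* HRV parameters (10 = SDNN, RMSSD, SDSD, NN50, pNN50, VLF, LF, HF, LF/HF, TP),
* GSR statistics (10),
* ACC x/y/z/magnitude statistics (40), GYR x/y/z/magnitude statistics (40).

The ten summary statistics are max, min, mean, median, sample standard
deviation, Q1, Q3, the 10th and 90th percentiles, and the peak difference
(max - min).  Features that cannot be computed from an empty or too-short
slice are NaN (explicit not-available markers), never silent zeros.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import welch

__all__ = [
    "SUMMARY_STAT_NAMES",
    "HRV_NAMES",
    "FEATURE_NAMES",
    "VLF_BAND",
    "LF_BAND",
    "HF_BAND",
    "summary_stats",
    "hrv_time_domain",
    "hrv_freq_domain",
    "aggregate_epoch_hrv",
    "extract_features",
    "summary_stats_matrix",
    "hrv_time_matrix",
    "hrv_freq_matrix",
]

SUMMARY_STAT_NAMES: tuple[str, ...] = (
    "max", "min", "mean", "median", "std", "q1", "q3", "p10", "p90", "peak_diff",
)

HRV_NAMES: tuple[str, ...] = (
    "sdnn", "rmssd", "sdsd", "nn50", "pnn50", "vlf", "lf", "hf", "lf_hf", "tp",
)

#: RRI spectral bands in Hz.
VLF_BAND = (0.001, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

_STAT_VARS: tuple[str, ...] = (
    "HR", "RRI", "GSR",
    "ACC_X", "ACC_Y", "ACC_Z", "ACC_MAG",
    "GYR_X", "GYR_Y", "GYR_Z", "GYR_MAG",
)


def _build_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    for var in ("HR", "RRI"):
        names += [f"{var}_{s}" for s in SUMMARY_STAT_NAMES]
    names += [f"HRV_{s}" for s in HRV_NAMES]
    names += [f"GSR_{s}" for s in SUMMARY_STAT_NAMES]
    for var in ("ACC_X", "ACC_Y", "ACC_Z", "ACC_MAG"):
        names += [f"{var}_{s}" for s in SUMMARY_STAT_NAMES]
    for var in ("GYR_X", "GYR_Y", "GYR_Z", "GYR_MAG"):
        names += [f"{var}_{s}" for s in SUMMARY_STAT_NAMES]
    return tuple(names)


#: The frozen 120-name feature schema.
FEATURE_NAMES: tuple[str, ...] = _build_feature_names()
assert len(FEATURE_NAMES) == 120


def summary_stats(values: np.ndarray) -> dict[str, float]:
    """The ten summary statistics of a value slice (NaN-aware).

    Quantiles use linear interpolation; std uses the N-1 denominator (0 for
    a single sample).  An empty slice yields all-NaN markers.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {s: np.nan for s in SUMMARY_STAT_NAMES}
    q1, q3, p10, p90 = np.percentile(v, [25, 75, 10, 90])
    vmax, vmin = float(np.max(v)), float(np.min(v))
    return {
        "max": vmax,
        "min": vmin,
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "std": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "q1": float(q1),
        "q3": float(q3),
        "p10": float(p10),
        "p90": float(p90),
        "peak_diff": vmax - vmin,
    }


def hrv_time_domain(rri_ms: np.ndarray) -> dict[str, float]:
    """Time-domain HRV of one window's RRI series (ms).

    SDNN is the sample standard deviation of the intervals; the remaining
    measures derive from successive differences d_i: RMSSD = sqrt(mean d^2),
    SDSD = sample std of d, NN50 = #{|d| > 50 ms}, pNN50 = NN50 / #pairs.
    Fewer than two valid samples yields NaN markers.
    """
    v = np.asarray(rri_ms, dtype=float)
    d = np.diff(v)
    d = d[np.isfinite(d)]  # differences across gaps are dropped
    vv = v[np.isfinite(v)]
    out = {s: np.nan for s in ("sdnn", "rmssd", "sdsd", "nn50", "pnn50")}
    if vv.size >= 2:
        out["sdnn"] = float(np.std(vv, ddof=1))
    if d.size >= 1:
        out["rmssd"] = float(np.sqrt(np.mean(d**2)))
        out["sdsd"] = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
        nn50 = int(np.sum(np.abs(d) > 50.0))
        out["nn50"] = float(nn50)
        out["pnn50"] = nn50 / d.size
    return out


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    m = (freqs >= lo) & (freqs <= hi)
    if m.sum() < 2:
        return np.zeros(psd.shape[:-1])
    return np.trapezoid(psd[..., m], freqs[m], axis=-1)


def hrv_freq_domain(rri_ms: np.ndarray, fs_hz: float = 1.0) -> dict[str, float]:
    """Frequency-domain HRV from a uniformly sampled RRI series.

    The mean-subtracted series is taken through Welch's method (Hann taper,
    a single full-length segment for 60-s windows); VLF/LF/HF powers are
    trapezoidal integrals of the density over 0.001-0.04, 0.04-0.15 and
    0.15-0.4 Hz, total power over 0.001-0.4 Hz, and LF/HF their ratio
    (NaN when HF is zero).
    """
    v = np.asarray(rri_ms, dtype=float)
    v = v[np.isfinite(v)]
    out = {s: np.nan for s in ("vlf", "lf", "hf", "lf_hf", "tp")}
    if v.size < 16:
        return out
    freqs, psd = welch(v - v.mean(), fs=fs_hz, nperseg=len(v), window="hann", detrend="linear")
    out["vlf"] = float(_band_power(freqs, psd, VLF_BAND))
    out["lf"] = float(_band_power(freqs, psd, LF_BAND))
    out["hf"] = float(_band_power(freqs, psd, HF_BAND))
    out["tp"] = float(_band_power(freqs, psd, (VLF_BAND[0], HF_BAND[1])))
    out["lf_hf"] = out["lf"] / out["hf"] if out["hf"] > 0 else np.nan
    return out


def aggregate_epoch_hrv(groups: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Element-wise arithmetic mean of the HRV parameter groups from the (at
    most five) sliding positions covering one 5-min epoch."""
    if len(groups) == 0:
        raise ValueError("need at least one HRV group to aggregate")
    keys = list(groups[0].keys())
    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in keys:
            out[k] = float(np.nanmean([g[k] for g in groups]))
    return out


def extract_features(slices: Mapping[str, np.ndarray], fs_rri_hz: float = 1.0) -> dict[str, float]:
    """Assemble the 120-feature vector for one 60-s window.

    ``slices`` maps variable names ("HR", "RRI", "GSR", "ACC_X", ...,
    "GYR_Z") to that window's sample arrays; the ACC/GYR magnitudes are
    derived here when the three axes are present.  A variable absent or
    empty contributes NaN markers for its block.
    """
    slices = dict(slices)
    for fam in ("ACC", "GYR"):
        axes = [slices.get(f"{fam}_{a}") for a in "XYZ"]
        if f"{fam}_MAG" not in slices and all(a is not None for a in axes):
            x, y, z = (np.asarray(a, dtype=float) for a in axes)
            slices[f"{fam}_MAG"] = np.sqrt(x**2 + y**2 + z**2)
    out: dict[str, float] = {}
    empty = np.zeros(0)
    for var in ("HR", "RRI"):
        st = summary_stats(slices.get(var, empty))
        out.update({f"{var}_{k}": v for k, v in st.items()})
    rri = slices.get("RRI", empty)
    hrv = hrv_time_domain(rri)
    hrv.update(hrv_freq_domain(rri, fs_rri_hz))
    out.update({f"HRV_{k}": hrv[k] for k in HRV_NAMES})
    st = summary_stats(slices.get("GSR", empty))
    out.update({f"GSR_{k}": v for k, v in st.items()})
    for var in ("ACC_X", "ACC_Y", "ACC_Z", "ACC_MAG", "GYR_X", "GYR_Y", "GYR_Z", "GYR_MAG"):
        st = summary_stats(slices.get(var, empty))
        out.update({f"{var}_{k}": v for k, v in st.items()})
    assert len(out) == 120
    return out


# ---------------------------------------------------------------------------
# Vectorized (windows x samples) versions used by the batch pipeline; each
# agrees exactly with the per-window operation above.
# ---------------------------------------------------------------------------


def summary_stats_matrix(rows: np.ndarray) -> dict[str, np.ndarray]:
    """The ten summary statistics along the last axis of ``rows`` (NaN-aware;
    all-NaN rows yield NaN)."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n_rows = rows.shape[0]
    finite = np.isfinite(rows)
    counts = finite.sum(axis=-1)
    clean = finite.all(axis=-1) & (rows.shape[-1] > 0)
    out = {s: np.full(n_rows, np.nan) for s in SUMMARY_STAT_NAMES}
    if clean.any():  # fast vectorized path for gap-free rows
        sub = rows[clean]
        q1, q3, p10, p90 = np.percentile(sub, [25, 75, 10, 90], axis=-1)
        vmax, vmin = sub.max(axis=-1), sub.min(axis=-1)
        std = np.std(sub, axis=-1, ddof=1) if sub.shape[-1] > 1 else np.zeros(len(sub))
        for key, val in (
            ("max", vmax), ("min", vmin), ("mean", sub.mean(axis=-1)),
            ("median", np.median(sub, axis=-1)), ("std", std),
            ("q1", q1), ("q3", q3), ("p10", p10), ("p90", p90),
            ("peak_diff", vmax - vmin),
        ):
            out[key][clean] = val
    for i in np.nonzero(~clean & (counts > 0))[0]:  # NaN-gapped rows
        st = summary_stats(rows[i])
        for key in SUMMARY_STAT_NAMES:
            out[key][i] = st[key]
    return out


def hrv_time_matrix(rri_rows: np.ndarray) -> dict[str, np.ndarray]:
    rows = np.asarray(rri_rows, dtype=float)
    d = np.diff(rows, axis=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_v = np.sum(np.isfinite(rows), axis=-1)
        n_d = np.sum(np.isfinite(d), axis=-1)
        sdnn = np.where(n_v >= 2, np.nanstd(rows, axis=-1, ddof=1), np.nan)
        rmssd = np.where(n_d >= 1, np.sqrt(np.nanmean(d**2, axis=-1)), np.nan)
        sdsd = np.full(rows.shape[:-1], np.nan)
        sdsd[n_d > 1] = np.nanstd(d, axis=-1, ddof=1)[n_d > 1]
        sdsd[n_d == 1] = 0.0
        nn50 = np.where(n_d >= 1, np.nansum(np.abs(d) > 50.0, axis=-1).astype(float), np.nan)
        pnn50 = np.where(n_d >= 1, nn50 / np.maximum(n_d, 1), np.nan)
    return {"sdnn": sdnn, "rmssd": rmssd, "sdsd": sdsd, "nn50": nn50, "pnn50": pnn50}


def hrv_freq_matrix(rri_rows: np.ndarray, fs_hz: float = 1.0) -> dict[str, np.ndarray]:
    """Welch band powers per row.  Rows with interior NaNs are linearly
    interpolated first; rows with fewer than 16 valid samples (or under half
    valid) are NaN."""
    rows = np.asarray(rri_rows, dtype=float).copy()
    n = rows.shape[-1]
    finite = np.isfinite(rows)
    counts = finite.sum(axis=-1)
    usable = (counts >= max(16, n // 2))
    idx = np.arange(n)
    for i in np.nonzero(usable & (counts < n))[0]:
        m = finite[i]
        rows[i] = np.interp(idx, idx[m], rows[i][m])
    out = {k: np.full(rows.shape[:-1], np.nan) for k in ("vlf", "lf", "hf", "lf_hf", "tp")}
    if not usable.any():
        return out
    sub = rows[usable]
    sub = sub - sub.mean(axis=-1, keepdims=True)
    freqs, psd = welch(sub, fs=fs_hz, nperseg=n, window="hann", detrend="linear", axis=-1)
    vlf = _band_power(freqs, psd, VLF_BAND)
    lf = _band_power(freqs, psd, LF_BAND)
    hf = _band_power(freqs, psd, HF_BAND)
    tp = _band_power(freqs, psd, (VLF_BAND[0], HF_BAND[1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        lf_hf = np.where(hf > 0, lf / hf, np.nan)
    for key, arr in (("vlf", vlf), ("lf", lf), ("hf", hf), ("lf_hf", lf_hf), ("tp", tp)):
        out[key][usable] = arr
    return out
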