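"""Signal pre-processing: quality identification, wavelet denoising,
smoothing/trimming, and personal-baseline residualization.

Order of operations per channel: SQI -> denoise -> trim + smooth -> baseline
adjust.  The heart-rate channel is first converted to a pseudo R-R interval
series (RRI_ms = 60000 / HR_bpm at the 1-Hz sample clock); true beat times
are not available from an optical wrist sensor, so every HRV quantity in
this package is defined on that uniformly sampled pseudo-RRI.

Denoising is a multilevel discrete wavelet transform (Daubechies-6,
symmetric padding) with VisuShrink hard thresholding of the detail
coefficients; for motion channels the fifth detail level (0.125-0.25 Hz at
8 Hz sampling) is zeroed outright, since seizure-relevant limb movement
energy sits in the 0.25-4 Hz range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

from .streams import Channel, SensorStream, SubjectRecord, period_ms

__all__ = [
    "QcMask",
    "WaveletPlan",
    "DenoiseDiagnostics",
    "ACC_PLAN",
    "RRI_PLAN",
    "sqi_mask",
    "hard_threshold",
    "visushrink_mu",
    "wavelet_denoise",
    "denoise_gapped",
    "smooth_and_trim",
    "baseline_adjust",
    "hr_to_rri",
    "PreprocessedChannel",
    "preprocess_subject",
]

MAX_MISSING_FRACTION = 0.60  # strict "more than 60% missing" removal rule
QC_WINDOW_S = 60


@dataclass
class QcMask:
    """Per 60-s non-overlapping window: keep flag + missing fraction."""

    window_length_s: int
    window_starts_ms: np.ndarray  # int64
    keep: np.ndarray  # bool
    missing_fraction: np.ndarray  # float in [0, 1]


@dataclass(frozen=True)
class WaveletPlan:
    """Decomposition settings for one channel family."""

    basis: str = "db6"
    levels: int = 5
    zeroed_detail_levels: frozenset[int] = frozenset()
    threshold_rule: str = "visushrink_hard"

    def __post_init__(self) -> None:
        if not set(self.zeroed_detail_levels) <= set(range(1, self.levels + 1)):
            raise ValueError("zeroed_detail_levels must be within 1..levels")


#: 8-Hz motion channels: 5 levels, fifth detail level zeroed.
ACC_PLAN = WaveletPlan(levels=5, zeroed_detail_levels=frozenset({5}))
#: 1-Hz pseudo-RRI: 4 levels, no zeroing (0.03-0.5 Hz detail band retained).
RRI_PLAN = WaveletPlan(levels=4)


@dataclass
class DenoiseDiagnostics:
    mu: float
    noise_sigma_hat: float
    energy_in: float
    energy_out: float


def sqi_mask(
    stream: SensorStream,
    wear_intervals: Sequence[tuple[int, int]] | None = None,
    span_ms: tuple[int, int] | None = None,
) -> QcMask:
    """Flag 60-s non-overlapping windows to keep or drop.

    A window is dropped when more than 60% of its expected samples are
    missing (strictly more; exactly 60% is kept), or when it is not fully
    inside a wear interval (non-wear time is dropped regardless of data).
    """
    if span_ms is None:
        if len(stream) == 0:
            return QcMask(QC_WINDOW_S, np.zeros(0, np.int64), np.zeros(0, bool), np.zeros(0))
        t0 = int(stream.timestamps_ms[0])
        t1 = int(stream.timestamps_ms[-1]) + stream.period_ms
    else:
        t0, t1 = span_ms
    win_ms = QC_WINDOW_S * 1000
    n_win = max((t1 - t0) // win_ms, 0)
    starts = t0 + win_ms * np.arange(n_win, dtype=np.int64)
    expected = QC_WINDOW_S * stream.rate_hz
    # observed samples per window via searchsorted on the sorted timestamps
    lo = np.searchsorted(stream.timestamps_ms, starts, side="left")
    hi = np.searchsorted(stream.timestamps_ms, starts + win_ms, side="left")
    observed = (hi - lo).astype(float)
    missing = 1.0 - observed / expected
    missing = np.clip(missing, 0.0, 1.0)
    keep = missing <= MAX_MISSING_FRACTION
    if wear_intervals is not None:
        worn = np.zeros(n_win, dtype=bool)
        for a, b in wear_intervals:
            worn |= (starts >= a) & (starts + win_ms <= b)
        keep &= worn
    return QcMask(QC_WINDOW_S, starts, keep, missing)


def hard_threshold(coeffs: np.ndarray, mu: float) -> np.ndarray:
    """Keep coefficients with ``|w| >= mu`` unchanged, zero the rest."""
    if mu < 0:
        raise ValueError("threshold mu must be >= 0")
    coeffs = np.asarray(coeffs, dtype=float)
    return np.where(np.abs(coeffs) >= mu, coeffs, 0.0)


def visushrink_mu(detail_level1: np.ndarray, n: float) -> float:
    """Universal threshold mu = sigma_hat * sqrt(2 ln n), with the noise
    scale estimated as median(|D1|) / 0.6745 from the finest detail level."""
    d1 = np.asarray(detail_level1, dtype=float)
    if d1.size == 0:
        raise ValueError("level-1 detail coefficients must be non-empty")
    if n < 2:
        raise ValueError("signal length n must be >= 2")
    sigma_hat = float(np.median(np.abs(d1))) / 0.6745
    return sigma_hat * np.sqrt(2.0 * np.log(n))


def wavelet_denoise(
    signal: np.ndarray,
    plan: WaveletPlan,
    force_mu: float | None = None,
) -> tuple[np.ndarray, DenoiseDiagnostics]:
    """Multilevel DWT denoising: decompose, zero the configured detail
    levels, hard-threshold the rest at a single global VisuShrink threshold
    estimated from the level-1 details, reconstruct to the input length.

    ``force_mu`` overrides the estimated threshold (0 disables thresholding,
    giving perfect reconstruction when no levels are zeroed).
    """
    x = np.asarray(signal, dtype=float)
    min_len = 2**plan.levels
    if len(x) < min_len:
        raise ValueError(
            f"signal of length {len(x)} too short for {plan.levels}-level "
            f"decomposition; need >= {min_len}"
        )
    import warnings as _warnings

    with _warnings.catch_warnings():
        # decomposing short runs at the full level count is intentional
        _warnings.filterwarnings("ignore", message="Level value of .* is too high")
        coeffs = pywt.wavedec(x, plan.basis, mode="symmetric", level=plan.levels)
    # coeffs[0] = approximation; coeffs[i] = detail level (levels - i + 1)
    d1 = coeffs[-1]
    if force_mu is not None:
        mu = float(force_mu)
        sigma_hat = np.nan
    else:
        if np.allclose(d1, 0.0):
            mu, sigma_hat = 0.0, 0.0
        else:
            sigma_hat = float(np.median(np.abs(d1))) / 0.6745
            mu = sigma_hat * np.sqrt(2.0 * np.log(len(x)))
    energy_in = float(sum(np.sum(c**2) for c in coeffs[1:]))
    new_coeffs = [coeffs[0]]
    for i, det in enumerate(coeffs[1:], start=1):
        level = plan.levels - i + 1
        if level in plan.zeroed_detail_levels:
            new_coeffs.append(np.zeros_like(det))
        else:
            new_coeffs.append(hard_threshold(det, mu))
    energy_out = float(sum(np.sum(c**2) for c in new_coeffs[1:]))
    rec = pywt.waverec(new_coeffs, plan.basis, mode="symmetric")
    return rec[: len(x)], DenoiseDiagnostics(mu, sigma_hat, energy_in, energy_out)


def denoise_gapped(
    values: np.ndarray, gap_starts: np.ndarray, plan: WaveletPlan
) -> np.ndarray:
    """Denoise a sample array split into contiguous runs at gap boundaries.

    ``gap_starts`` marks indices that begin a new run (index 0 implied).
    Runs shorter than ``2**plan.levels`` samples pass through untouched.
    """
    out = np.array(values, dtype=float)
    bounds = np.concatenate(([0], np.asarray(gap_starts, dtype=int), [len(values)]))
    bounds = np.unique(bounds)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= 2**plan.levels:
            out[a:b], _ = wavelet_denoise(out[a:b], plan)
    return out


def smooth_and_trim(
    values: np.ndarray, trim_percentile: float = 5.0, ma_width: int = 5
) -> np.ndarray:
    """Remove extreme points, then smooth with a centered moving average.

    Points strictly below the lower or strictly above the upper percentile
    become NaN (removed, not clipped); the moving average is taken over the
    surviving values with the window shrinking at edges and around gaps.
    NaNs already present in ``values`` are treated as missing throughout.
    Percentiles use linear interpolation over the finite values, so a
    constant signal survives untouched.  ``ma_width=1`` trims only.
    """
    if ma_width < 1 or ma_width % 2 == 0:
        raise ValueError("ma_width must be an odd integer >= 1")
    v = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(v)
    if not finite.any():
        return v
    lo = np.percentile(v[finite], trim_percentile)
    hi = np.percentile(v[finite], 100.0 - trim_percentile)
    v[finite & ((v < lo) | (v > hi))] = np.nan
    if ma_width == 1 or len(v) == 0:
        return v
    if len(v) < ma_width:  # window shrinks to the available span
        ma_width = len(v) - (1 - len(v) % 2)
        if ma_width <= 1:
            return v
    # centered moving nanmean via cumulative sums of values and counts
    mask = np.isfinite(v)
    filled = np.where(mask, v, 0.0)
    kernel = np.ones(ma_width)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(mask.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = sums / counts
    smoothed[~mask] = np.nan  # removed/missing points stay missing
    return smoothed


def baseline_adjust(values: np.ndarray) -> np.ndarray:
    """Subtract the subject-channel median of the retained (finite) values;
    the output has median exactly 0 over the retained samples."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("baseline_adjust requires at least one retained sample")
    return v - np.median(v[finite])


def hr_to_rri(hr_bpm: np.ndarray) -> np.ndarray:
    """Pseudo R-R interval in ms from 1-Hz heart rate: 60000 / HR.

    NaNs (missing samples) pass through; non-positive HR values are errors.
    """
    hr = np.asarray(hr_bpm, dtype=float)
    finite = np.isfinite(hr)
    if np.any(hr[finite] <= 0):
        raise ValueError("heart rate must be positive to derive RRI")
    out = np.full_like(hr, np.nan)
    out[finite] = 60000.0 / hr[finite]
    return out


# ---------------------------------------------------------------------------
# Subject-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class PreprocessedChannel:
    """One channel resampled onto its full nominal grid with NaN gaps.

    ``values`` holds the processed signal; ``residuals`` the same after
    personal-baseline (median) subtraction.  ``grid_t0_ms`` is the grid
    origin and ``period_ms`` the nominal sampling period.
    """

    channel: Channel
    grid_t0_ms: int
    period_ms: int
    values: np.ndarray
    residuals: np.ndarray
    #: raw-sample presence on the grid (True where the device delivered a
    #: sample, regardless of later trimming) — the basis for missing-rate QC
    observed: np.ndarray = None  # type: ignore[assignment]
    #: for derived magnitude channels: the denoised, pre-trim series the
    #: motion-state sigma threshold is calibrated against
    pretrim: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.observed is None:
            self.observed = np.isfinite(self.values)

    def index_of(self, t_ms: int) -> int:
        return int((t_ms - self.grid_t0_ms) // self.period_ms)


@dataclass
class PreprocessedSubject:
    record: SubjectRecord
    t0_ms: int
    t1_ms: int
    channels: dict[str, PreprocessedChannel]
    qc: dict[str, QcMask] = field(default_factory=dict)


def _to_grid(stream: SensorStream, t0: int, t1: int) -> tuple[np.ndarray, np.ndarray]:
    """Place samples onto the nominal grid [t0, t1); NaN where absent.
    Returns (values_on_grid, indices_of_observed_samples)."""
    p = stream.period_ms
    n = max((t1 - t0) // p, 0)
    grid = np.full(n, np.nan)
    if len(stream) == 0:
        return grid, np.zeros(0, dtype=int)
    idx = ((stream.timestamps_ms - t0) // p).astype(int)
    ok = (idx >= 0) & (idx < n)
    grid[idx[ok]] = stream.values[ok]
    return grid, idx[ok]


def _run_starts(observed_idx: np.ndarray) -> np.ndarray:
    """Indices (into the observed-sample order) where a new contiguous run
    begins, i.e. where the grid index jumps by more than one."""
    if len(observed_idx) == 0:
        return np.zeros(0, dtype=int)
    jumps = np.where(np.diff(observed_idx) > 1)[0] + 1
    return jumps


def preprocess_subject(
    record: SubjectRecord,
    qc_on: tuple[Channel, ...] = (Channel.HR, Channel.ACC_X),
) -> PreprocessedSubject:
    """Run the full per-channel pipeline and return grid-aligned residuals.

    HR additionally yields a pseudo-RRI channel (key ``"RRI"``) denoised
    with the 4-level plan; the cleaned HR is recovered as 60000/RRI so the
    two series stay consistent.  Motion channels are denoised with the
    5-level plan; GSR (0.2 Hz, 12 samples per minute) is trimmed and
    smoothed without wavelet denoising.
    """
    t0, t1 = record.span_ms()
    out: dict[str, PreprocessedChannel] = {}
    pretrim: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    qc: dict[str, QcMask] = {}
    for ch in qc_on:
        if ch in record.streams:
            qc[ch.value] = sqi_mask(record.streams[ch], record.wear_intervals, (t0, t1))

    for ch, stream in record.streams.items():
        grid, obs_idx = _to_grid(stream, t0, t1)
        obs_vals = grid[obs_idx] if len(obs_idx) else np.zeros(0)
        runs = _run_starts(obs_idx)
        if ch == Channel.HR:
            rri = hr_to_rri(obs_vals)
            rri = denoise_gapped(rri, runs, RRI_PLAN)
            rri = np.maximum(rri, 1.0)
            rri_grid = np.full_like(grid, np.nan)
            rri_grid[obs_idx] = rri
            rri_grid = smooth_and_trim(rri_grid)
            hr_grid = np.full_like(grid, np.nan)
            ok = np.isfinite(rri_grid)
            hr_grid[ok] = 60000.0 / rri_grid[ok]
            obs = np.zeros(len(grid), dtype=bool)
            obs[obs_idx] = True
            out["RRI"] = PreprocessedChannel(
                ch, t0, stream.period_ms, rri_grid, _safe_residual(rri_grid), obs
            )
            out[ch.value] = PreprocessedChannel(
                ch, t0, stream.period_ms, hr_grid, _safe_residual(hr_grid), obs.copy()
            )
            continue
        if ch in (Channel.GSR,):
            vals = np.full_like(grid, np.nan)
            vals[obs_idx] = obs_vals
        else:  # motion channels
            den = denoise_gapped(obs_vals, runs, ACC_PLAN)
            vals = np.full_like(grid, np.nan)
            vals[obs_idx] = den
        vals = smooth_and_trim(vals)
        obs = np.zeros(len(grid), dtype=bool)
        obs[obs_idx] = True
        out[ch.value] = PreprocessedChannel(
            ch, t0, stream.period_ms, vals, _safe_residual(vals), obs
        )
        if ch in (Channel.ACC_X, Channel.ACC_Y, Channel.ACC_Z,
                  Channel.GYR_X, Channel.GYR_Y, Channel.GYR_Z):
            den_grid = np.full_like(grid, np.nan)
            den_grid[obs_idx] = den
            pretrim[ch.value] = (den_grid, obs)

    # ACC/GYR magnitude are themselves tracked variables: derive each from
    # the denoised (pre-trim) axes, then trim, smooth and residualize the
    # magnitude series in its own right.
    for fam in ("ACC", "GYR"):
        keys = [f"{fam}_{a}" for a in "XYZ"]
        if all(k in pretrim for k in keys):
            mag_pre = np.sqrt(sum(pretrim[k][0] ** 2 for k in keys))
            obs = pretrim[keys[0]][1] & pretrim[keys[1]][1] & pretrim[keys[2]][1]
            mag = smooth_and_trim(mag_pre)
            ch0 = record.streams[Channel(keys[0])]
            out[f"{fam}_MAG"] = PreprocessedChannel(
                Channel(keys[0]), t0, ch0.period_ms, mag, _safe_residual(mag),
                obs, pretrim=mag_pre,
            )
    return PreprocessedSubject(record, t0, t1, out, qc)


def _safe_residual(vals: np.ndarray) -> np.ndarray:
    if np.isfinite(vals).any():
        return baseline_adjust(vals)
    return vals.copy()
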