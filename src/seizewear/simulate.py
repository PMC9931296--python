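"""Synthetic cohort generator for pediatric wearable recordings.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without patient data:

* age-dependent resting heart rate (infants ~115 bpm falling to ~80 bpm by
  age five and beyond);
* a day/night heart-rate contrast that is absent in infants (age <= 12
  months) and present in older children;
* galvanic skin response decreasing with age, higher by day than by night,
  slightly higher in females;
* beat-interval variability built from an AR(1) component plus sinusoidal
  modulations at 0.1 Hz and 0.25 Hz so that LF and HF band powers of the
  derived R-R interval series are controllable;
* seizures placed by a homogeneous Poisson process, with durations drawn
  from a six-bin categorical distribution (81.3 / 10.3 / 3.2 / 2.3 / 1.1 /
  1.8 % for <1, 1-2, 2-3, 3-4, 4-5 and >5 minutes) and a signature of
  elevated HR/GSR/motion, suppressed beat-to-beat variability, and an
  LF/HF shift injected within each event;
* contiguous missing-data spans and non-wear intervals.

Everything is deterministic under ``(seed, subject_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .streams import Channel, Cohort, SeizureEvent, SensorStream, SubjectRecord, period_ms

__all__ = [
    "DURATION_BINS",
    "EffectSizes",
    "SimConfig",
    "GroundTruth",
    "default_config_path",
    "sample_seizure_duration",
    "sample_seizure_durations",
    "generate_subject",
    "inject_seizure_signature",
    "generate_cohort",
]

#: Seizure-duration bins in seconds with their cohort-level probabilities
#: (fraction of recorded events per duration band).  The open-ended >5 min
#: band is capped by ``SimConfig.max_seizure_duration_s``.
DURATION_BINS: tuple[tuple[float, float, float], ...] = (
    (1.0, 60.0, 0.813),
    (60.0, 120.0, 0.103),
    (120.0, 180.0, 0.032),
    (180.0, 240.0, 0.023),
    (240.0, 300.0, 0.011),
    (300.0, 600.0, 0.018),
)


@dataclass(frozen=True)
class EffectSizes:
    """Seizure-time departures from personal baseline.

    ``hrv_suppression_factor`` multiplies the beat-to-beat variability inside
    the event (1 = unchanged); ``lfhf_gain`` multiplies the 0.1-Hz (LF band)
    modulation relative to the suppressed level, shifting LF/HF upward.
    """

    hr_delta_bpm: float = 25.0
    gsr_delta_us: float = 1.0
    acc_burst_g: float = 0.5
    gyr_burst_dps: float = 30.0
    hrv_suppression_factor: float = 0.4
    lfhf_gain: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    Ages are uniform over 1-161 months (the observed cohort range); the
    seizure rate of 5.6 events per 24 monitored hours matches the reported
    cohort aggregate (1,290 events over 5,543 hours).
    """

    n_subjects: int = 66
    age_min_months: int = 1
    age_max_months: int = 161
    sex_ratio_female: float = 0.5
    duration_hours: float = 24.0
    start_unix_ms: int = 1514764800000  # 2018-01-01T00:00:00Z; midnight origin

    # Heart-rate baseline: 115 bpm through 12 months, linearly falling to
    # 80 bpm at 60 months and flat beyond.
    hr_infant_bpm: float = 115.0
    hr_child_bpm: float = 80.0
    hr_infant_knot_months: float = 12.0
    hr_child_knot_months: float = 60.0
    circadian_hr_amplitude_bpm: float = 5.0  # zero for age <= 12 months
    circadian_peak_hour: float = 14.0

    hr_ar_sd_bpm: float = 2.0
    hr_ar_phi: float = 0.95
    hr_slow_sd_bpm: float = 8.0  # slow (tens of minutes) wandering of tone
    hr_lf_amp_bpm: float = 3.0  # 0.1-Hz modulation
    hr_hf_amp_bpm: float = 2.0  # 0.25-Hz modulation

    gsr_base_us: float = 8.0
    gsr_age_slope_us_per_month: float = -0.03
    gsr_floor_us: float = 1.0
    gsr_day_delta_us: float = 0.5
    gsr_sex_female_delta_us: float = 0.3
    gsr_noise_sd_us: float = 0.6

    acc_noise_sd_g: float = 0.02
    gyr_noise_sd_dps: float = 2.0
    activity_bouts_per_hour: float = 4.0
    activity_bout_mean_s: float = 120.0
    activity_amp_g: float = 0.25
    activity_amp_dps: float = 25.0

    seizures_per_day: float = 5.6
    duration_probs: tuple[float, ...] = tuple(p for _, _, p in DURATION_BINS)
    max_seizure_duration_s: float = 600.0
    min_event_gap_s: float = 180.0

    effects: EffectSizes = field(default_factory=EffectSizes)

    missing_rate: float = 0.05
    missing_span_mean_s: float = 120.0
    nonwear_rate: float = 0.05
    nonwear_span_mean_s: float = 1800.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not np.isclose(sum(self.duration_probs), 1.0):
            raise ValueError("duration_probs must sum to 1")
        if not (0.0 < self.effects.hrv_suppression_factor <= 1.0):
            raise ValueError("hrv_suppression_factor must be in (0, 1]")
        for name in ("seizures_per_day", "missing_rate", "nonwear_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def hr_baseline_bpm(self, age_months: float) -> float:
        """Piecewise-linear age->resting-HR curve."""
        a0, a1 = self.hr_infant_knot_months, self.hr_child_knot_months
        if age_months <= a0:
            return self.hr_infant_bpm
        if age_months >= a1:
            return self.hr_child_bpm
        w = (age_months - a0) / (a1 - a0)
        return (1 - w) * self.hr_infant_bpm + w * self.hr_child_bpm


@dataclass
class GroundTruth:
    """Latent quantities behind one generated subject."""

    events: list[SeizureEvent]
    hr_baseline_bpm: float
    gsr_baseline_us: float
    circadian_amplitude_bpm: float


def default_config_path():
    """Path of the packaged JSON file holding the default SimConfig."""
    from importlib import resources

    return resources.files("seizewear").joinpath("data/sim_defaults.json")


def sample_seizure_durations(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` seizure durations (seconds) from the six-bin categorical
    distribution, uniform within each bin; the >5-min bin is capped at
    ``config.max_seizure_duration_s``."""
    config.validate()
    bins = np.array([(lo, hi) for lo, hi, _ in DURATION_BINS], dtype=float)
    bins[-1, 1] = max(config.max_seizure_duration_s, bins[-1, 0] + 1.0)
    idx = rng.choice(len(bins), size=n, p=np.asarray(config.duration_probs))
    u = rng.random(n)
    lo, hi = bins[idx, 0], bins[idx, 1]
    return lo + u * (hi - lo)


def sample_seizure_duration(config: SimConfig, rng: np.random.Generator) -> float:
    """Single-draw convenience wrapper around :func:`sample_seizure_durations`."""
    return float(sample_seizure_durations(config, rng, 1)[0])


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------


def _subject_rng(config: SimConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, subject_index])


def _draw_spans(
    rng: np.random.Generator, total_s: float, rate_fraction: float, mean_len_s: float
) -> list[tuple[float, float]]:
    """Contiguous spans with exponential lengths covering ~rate_fraction of
    [0, total_s), non-overlapping, sorted."""
    if rate_fraction <= 0 or total_s <= 0:
        return []
    target = rate_fraction * total_s
    spans: list[tuple[float, float]] = []
    covered = 0.0
    for _ in range(10000):
        if covered >= target:
            break
        # exponential span length, truncated to the remaining coverage
        # budget so short recordings keep the configured rate
        length = min(rng.exponential(mean_len_s) + 1.0, target - covered + 1.0, total_s)
        start = rng.uniform(0, max(total_s - length, 1e-9))
        cand = (start, start + length)
        if any(not (cand[1] <= a or cand[0] >= b) for a, b in spans):
            continue
        spans.append(cand)
        covered += length
    return sorted(spans)


def _complement(spans: Sequence[tuple[float, float]], total_s: float) -> list[tuple[float, float]]:
    out = []
    cur = 0.0
    for a, b in spans:
        if a > cur:
            out.append((cur, a))
        cur = max(cur, b)
    if cur < total_s:
        out.append((cur, total_s))
    return [(a, b) for a, b in out if b - a > 1.0]


def _place_events(
    config: SimConfig,
    rng: np.random.Generator,
    wear: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Homogeneous Poisson placement of seizures inside wear time, rejecting
    overlaps and enforcing a minimum inter-event gap so buffer zones stay
    interpretable."""
    wear_total = sum(b - a for a, b in wear)
    n = rng.poisson(config.seizures_per_day * wear_total / 86400.0)
    if n == 0 or not wear:
        return []
    durations = sample_seizure_durations(config, rng, n)
    lengths = np.array([b - a for a, b in wear])
    placed: list[tuple[float, float]] = []
    for dur in durations:
        for _ in range(50):  # rejection sampling
            i = rng.choice(len(wear), p=lengths / lengths.sum())
            a, b = wear[i]
            if b - a <= dur:
                continue
            onset = rng.uniform(a, b - dur)
            cand = (onset, onset + dur)
            gap = config.min_event_gap_s
            if any(not (cand[1] + gap <= p or cand[0] >= q + gap) for p, q in placed):
                continue
            placed.append(cand)
            break
    return sorted(placed)


def _grid_s(duration_s: float, rate_hz: float) -> np.ndarray:
    n = int(round(duration_s * rate_hz))
    return np.arange(n) / rate_hz


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    from scipy.signal import lfilter

    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -phi], eps)


def _delete_spans(t_s: np.ndarray, spans: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean keep-mask for samples outside every span."""
    keep = np.ones(len(t_s), dtype=bool)
    for a, b in spans:
        keep &= ~((t_s >= a) & (t_s < b))
    return keep


def generate_subject(
    config: SimConfig, subject_index: int
) -> tuple[SubjectRecord, GroundTruth]:
    """Generate one subject's full multichannel record plus its ground truth.

    ``duration_hours == 0`` yields a record with empty streams and no events.
    """
    config.validate()
    rng = _subject_rng(config, subject_index)
    age = int(rng.integers(config.age_min_months, config.age_max_months + 1))
    sex = "female" if rng.random() < config.sex_ratio_female else "male"
    total_s = config.duration_hours * 3600.0
    sid = f"sim{subject_index:03d}"

    hr_base = config.hr_baseline_bpm(age)
    gsr_base = max(
        config.gsr_floor_us,
        config.gsr_base_us + config.gsr_age_slope_us_per_month * age,
    ) + (config.gsr_sex_female_delta_us if sex == "female" else 0.0)
    circ_amp = 0.0 if age <= 12 else config.circadian_hr_amplitude_bpm

    if total_s <= 0:
        record = SubjectRecord(sid, age, sex, streams={}, events=[], wear_intervals=[])
        return record, GroundTruth([], hr_base, gsr_base, circ_amp)

    nonwear = _draw_spans(rng, total_s, config.nonwear_rate, config.nonwear_span_mean_s)
    wear = _complement(nonwear, total_s)
    events_s = _place_events(config, rng, wear)

    t0 = config.start_unix_ms

    def clock_hours(t_s: np.ndarray) -> np.ndarray:
        return (((t0 / 1000.0) + t_s) / 3600.0) % 24.0

    def day_factor(t_s: np.ndarray) -> np.ndarray:
        return np.cos(2 * np.pi * (clock_hours(t_s) - config.circadian_peak_hour) / 24.0)

    streams: dict[Channel, SensorStream] = {}

    # Activity bouts: intervals of physical movement affecting the motion
    # channels; heart rate follows its own baseline + circadian + two-scale
    # AR model with LF/HF sinusoidal modulations.
    n_bouts = rng.poisson(config.activity_bouts_per_hour * total_s / 3600.0)
    bouts = []
    for _ in range(n_bouts):
        start = rng.uniform(0, total_s)
        length = rng.exponential(config.activity_bout_mean_s) + 10.0
        bouts.append((start, start + length))

    def bout_envelope(t_s: np.ndarray) -> np.ndarray:
        env = np.zeros(len(t_s))
        for a, b in bouts:
            env[(t_s >= a) & (t_s < b)] = 1.0
        return env

    # --- heart rate (1 Hz) --------------------------------------------------
    t_hr = _grid_s(total_s, 1.0)
    phase_lf, phase_hf = rng.uniform(0, 2 * np.pi, size=2)
    hr = (
        hr_base
        + circ_amp * day_factor(t_hr)
        + _ar1(rng, len(t_hr), config.hr_ar_phi, config.hr_ar_sd_bpm)
        + _ar1(rng, len(t_hr), 0.9995, config.hr_slow_sd_bpm)
        + config.hr_lf_amp_bpm * np.sin(2 * np.pi * 0.10 * t_hr + phase_lf)
        + config.hr_hf_amp_bpm * np.sin(2 * np.pi * 0.25 * t_hr + phase_hf)
    )
    streams[Channel.HR] = _to_stream(Channel.HR, t0, t_hr, np.clip(hr, 40.0, 220.0))

    # --- galvanic skin response (0.2 Hz) ------------------------------------
    t_gsr = _grid_s(total_s, 0.2)
    hours = clock_hours(t_gsr)
    is_day = (hours >= 8.0) & (hours < 20.0)
    gsr = (
        gsr_base
        + config.gsr_day_delta_us * is_day
        + _ar1(rng, len(t_gsr), 0.98, config.gsr_noise_sd_us)
    )
    streams[Channel.GSR] = _to_stream(Channel.GSR, t0, t_gsr, np.maximum(gsr, 0.05))

    # --- accelerometer / gyrometer (8 Hz) -----------------------------------
    # Each ACC axis reads the slowly drifting gravity projection (unit-norm
    # orientation vector) plus dynamic acceleration; at rest the magnitude
    # sits near 1 g, and activity bouts add zero-mean dynamic components.
    t_motion = _grid_s(total_s, 8.0)
    n_m = len(t_motion)
    bout_env = bout_envelope(t_motion)
    # orientation: heavily smoothed 3-D random walk, renormalized to |g| = 1
    raw = np.stack([_ar1(rng, n_m, 0.9999, 1.0) for _ in range(3)])
    raw += 0.2  # bias away from the origin so normalization is stable
    g_vec = raw / np.maximum(np.linalg.norm(raw, axis=0), 1e-6)
    for axis, ch_acc, ch_gyr in (
        (0, Channel.ACC_X, Channel.GYR_X),
        (1, Channel.ACC_Y, Channel.GYR_Y),
        (2, Channel.ACC_Z, Channel.GYR_Z),
    ):
        acc = g_vec[axis] + rng.normal(0.0, config.acc_noise_sd_g, n_m)
        acc += bout_env * rng.normal(0.0, config.activity_amp_g, n_m)
        gyr = rng.normal(0.0, config.gyr_noise_sd_dps, n_m)
        gyr += bout_env * rng.normal(0.0, config.activity_amp_dps, n_m)
        streams[ch_acc] = _to_stream(ch_acc, t0, t_motion, acc)
        streams[ch_gyr] = _to_stream(ch_gyr, t0, t_motion, gyr)

    wear_ms = [(t0 + int(round(a * 1000)), t0 + int(round(b * 1000))) for a, b in wear]
    events = [
        SeizureEvent(t0 + int(round(a * 1000)), t0 + int(round(b * 1000)), "simulated")
        for a, b in events_s
    ]
    record = SubjectRecord(sid, age, sex, streams, events, wear_ms)

    for event in events:
        record = inject_seizure_signature(record, event, config.effects, rng, config)

    # Missingness: contiguous transmission dropouts hit the whole device, so
    # one set of deleted spans is shared by all channels; non-wear samples
    # are removed everywhere as well.
    miss = _draw_spans(rng, total_s, config.missing_rate, config.missing_span_mean_s)
    for ch, stream in list(record.streams.items()):
        t_s = (stream.timestamps_ms - t0) / 1000.0
        keep = _delete_spans(t_s, miss) & _delete_spans(t_s, nonwear)
        record.streams[ch] = SensorStream(ch, stream.timestamps_ms[keep], stream.values[keep])

    return record, GroundTruth(events, hr_base, gsr_base, circ_amp)


def _to_stream(ch: Channel, t0: int, t_s: np.ndarray, values: np.ndarray) -> SensorStream:
    p = period_ms(ch)
    ts = t0 + np.round(t_s * 1000.0 / p).astype(np.int64) * p
    return SensorStream(ch, ts, values)


def inject_seizure_signature(
    record: SubjectRecord,
    event: SeizureEvent,
    effects: EffectSizes,
    rng: np.random.Generator,
    config: SimConfig | None = None,
) -> SubjectRecord:
    """Overlay the seizure-time signature on ``record`` within
    ``[event.onset_ms, event.offset_ms)`` and return the modified record.

    HR is raised by ``hr_delta_bpm`` with its deviation from the local median
    shrunk by ``hrv_suppression_factor``; an extra 0.1-Hz modulation realizes
    the LF/HF gain.  GSR is raised by ``gsr_delta_us``; ACC/GYR receive a
    jerky noise burst.  Signals outside the event are untouched.  With all
    effects at their identity values the record is returned unchanged.
    """
    lo, hi = record.span_ms()
    if not (lo <= event.onset_ms and event.offset_ms <= hi):
        raise ValueError(
            f"event [{event.onset_ms},{event.offset_ms}) outside record span [{lo},{hi})"
        )
    cfg = config or SimConfig()
    s = effects.hrv_suppression_factor

    def in_event(stream: SensorStream) -> np.ndarray:
        return (stream.timestamps_ms >= event.onset_ms) & (
            stream.timestamps_ms < event.offset_ms
        )

    hr = record.streams.get(Channel.HR)
    if hr is not None:
        m = in_event(hr)
        if m.any():
            seg = hr.values[m]
            center = np.median(seg)
            t_rel = (hr.timestamps_ms[m] - event.onset_ms) / 1000.0
            extra_lf = (effects.lfhf_gain - 1.0) * s * cfg.hr_lf_amp_bpm
            hr.values[m] = (
                center
                + (seg - center) * s
                + effects.hr_delta_bpm
                + extra_lf * np.sin(2 * np.pi * 0.10 * t_rel)
            )

    gsr = record.streams.get(Channel.GSR)
    if gsr is not None:
        m = in_event(gsr)
        gsr.values[m] += effects.gsr_delta_us

    for ch in (Channel.ACC_X, Channel.ACC_Y, Channel.ACC_Z):
        st = record.streams.get(ch)
        if st is not None and effects.acc_burst_g > 0:
            m = in_event(st)
            st.values[m] += rng.normal(0.0, effects.acc_burst_g, int(m.sum()))
    for ch in (Channel.GYR_X, Channel.GYR_Y, Channel.GYR_Z):
        st = record.streams.get(ch)
        if st is not None and effects.gyr_burst_dps > 0:
            m = in_event(st)
            st.values[m] += rng.normal(0.0, effects.gyr_burst_dps, int(m.sum()))
    return record


def generate_cohort(config: SimConfig, role: str = "discovery") -> Cohort:
    """Generate ``config.n_subjects`` records, reproducible from the seed."""
    config.validate()
    subjects = [generate_subject(config, i)[0] for i in range(config.n_subjects)]
    return Cohort(subjects, role=role)
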