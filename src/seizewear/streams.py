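"""Domain types and file I/O for wearable sensor streams.

A recording session produces one uniformly-clocked stream per sensor channel
(heart rate at 1 Hz, galvanic skin response at 0.2 Hz, tri-axial accelerometer
and gyrometer at 8 Hz).  Timestamps are integer Unix milliseconds; missing
samples are absent rows, never NaN sentinels.  All intervals in the package
are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "CHANNEL_RATE_HZ",
    "SensorStream",
    "SeizureEvent",
    "SubjectRecord",
    "Cohort",
    "StreamValidationError",
    "read_stream",
    "write_stream",
    "read_events",
    "write_events",
    "read_subject",
    "write_subject",
    "validate_subject",
]


class Channel(str, Enum):
    HR = "HR"
    GSR = "GSR"
    ACC_X = "ACC_X"
    ACC_Y = "ACC_Y"
    ACC_Z = "ACC_Z"
    GYR_X = "GYR_X"
    GYR_Y = "GYR_Y"
    GYR_Z = "GYR_Z"


#: Nominal acquisition rates of the wristband sensors.
CHANNEL_RATE_HZ: dict[Channel, float] = {
    Channel.HR: 1.0,
    Channel.GSR: 0.2,
    Channel.ACC_X: 8.0,
    Channel.ACC_Y: 8.0,
    Channel.ACC_Z: 8.0,
    Channel.GYR_X: 8.0,
    Channel.GYR_Y: 8.0,
    Channel.GYR_Z: 8.0,
}

#: Units per channel (bpm, microsiemens, g, deg/s).
CHANNEL_UNITS: dict[Channel, str] = {
    Channel.HR: "bpm",
    Channel.GSR: "uS",
    Channel.ACC_X: "g",
    Channel.ACC_Y: "g",
    Channel.ACC_Z: "g",
    Channel.GYR_X: "deg/s",
    Channel.GYR_Y: "deg/s",
    Channel.GYR_Z: "deg/s",
}


def period_ms(channel: Channel) -> int:
    """Nominal sampling period of ``channel`` in integer milliseconds."""
    return int(round(1000.0 / CHANNEL_RATE_HZ[channel]))


class StreamValidationError(ValueError):
    """An input file or in-memory record violates a stream invariant."""


@dataclass
class SensorStream:
    """One channel's samples on the channel's nominal clock.

    Attributes
    ----------
    channel : Channel
    timestamps_ms : int64 array, strictly increasing; consecutive gaps are
        integer multiples of the nominal period (absent rows encode missing
        data).
    values : float64 array, all finite.
    """

    channel: Channel
    timestamps_ms: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def rate_hz(self) -> float:
        return CHANNEL_RATE_HZ[self.channel]

    @property
    def period_ms(self) -> int:
        return period_ms(self.channel)

    def __len__(self) -> int:
        return len(self.timestamps_ms)

    def expected_count(self) -> int:
        """floor((t_last - t_first)/period) + 1, or 0 for an empty stream."""
        if len(self) == 0:
            return 0
        span = int(self.timestamps_ms[-1] - self.timestamps_ms[0])
        return span // self.period_ms + 1

    def missing_count(self) -> int:
        return self.expected_count() - len(self)

    def violations(self) -> list[str]:
        out: list[str] = []
        if len(self.timestamps_ms) != len(self.values):
            out.append(f"{self.channel.value}: timestamp/value length mismatch")
            return out
        if len(self) == 0:
            return out
        diffs = np.diff(self.timestamps_ms)
        if np.any(diffs <= 0):
            out.append(f"{self.channel.value}: timestamps not strictly increasing")
        p = self.period_ms
        bad = diffs[(diffs > 0) & (diffs % p != 0)]
        if bad.size:
            out.append(
                f"{self.channel.value}: {bad.size} gap(s) not a multiple of the "
                f"{p} ms nominal period (e.g. {int(bad[0])} ms)"
            )
        if not np.all(np.isfinite(self.values)):
            out.append(f"{self.channel.value}: non-finite values present")
        return out

    def validate(self) -> None:
        v = self.violations()
        if v:
            raise StreamValidationError("; ".join(v))


@dataclass(frozen=True)
class SeizureEvent:
    """A caregiver-annotated (or simulated) seizure interval [onset, offset)."""

    onset_ms: int
    offset_ms: int
    source: str = "caregiver"

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise StreamValidationError(
                f"seizure offset ({self.offset_ms}) must exceed onset ({self.onset_ms})"
            )

    @property
    def duration_s(self) -> float:
        return (self.offset_ms - self.onset_ms) / 1000.0


@dataclass
class SubjectRecord:
    """Demographics, channel streams, seizure annotations and wear intervals."""

    subject_id: str
    age_months: int
    sex: str  # "male" | "female"
    streams: dict[Channel, SensorStream] = field(default_factory=dict)
    events: list[SeizureEvent] = field(default_factory=list)
    wear_intervals: list[tuple[int, int]] = field(default_factory=list)

    def span_ms(self) -> tuple[int, int]:
        """Earliest and latest wall-clock extent covered by any stream."""
        starts = [int(s.timestamps_ms[0]) for s in self.streams.values() if len(s)]
        ends = [
            int(s.timestamps_ms[-1]) + s.period_ms
            for s in self.streams.values()
            if len(s)
        ]
        if not starts:
            return (0, 0)
        return (min(starts), max(ends))


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    role: str = "discovery"  # "discovery" | "replication"

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise StreamValidationError("cohort subject_ids are not unique")

    def __len__(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# File formats: stream CSV, events JSON, subject manifest JSON
# ---------------------------------------------------------------------------

_STREAM_HEADER = ["timestamp_ms", "value"]


def read_stream(path: str | Path, channel: Channel) -> SensorStream:
    """Read one channel's ``timestamp_ms,value`` CSV into a SensorStream.

    Raises
    ------
    StreamValidationError
        on malformed rows (naming the offending line) or non-monotonic /
        off-grid timestamps.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"timestamp_ms": np.int64, "value": np.float64})
    except (ValueError, pd.errors.ParserError) as exc:
        raise StreamValidationError(f"{path}: malformed stream CSV: {exc}") from exc
    if list(df.columns) != _STREAM_HEADER:
        raise StreamValidationError(
            f"{path}: expected header {_STREAM_HEADER}, got {list(df.columns)}"
        )
    bad = df.index[~np.isfinite(df["value"].to_numpy())]
    if len(bad):
        raise StreamValidationError(f"{path}: non-finite value at line {bad[0] + 2}")
    stream = SensorStream(channel, df["timestamp_ms"].to_numpy(), df["value"].to_numpy())
    stream.validate()
    return stream


def write_stream(stream: SensorStream, path: str | Path) -> None:
    """Write a stream as CSV with values printed at 6 significant digits.

    Gaps are preserved simply because absent samples have no row to write;
    ``read_stream`` recovers the identical sample set.
    """
    stream.validate()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(_STREAM_HEADER) + "\n")
        for t, v in zip(stream.timestamps_ms, stream.values):
            fh.write(f"{int(t)},{v:.6g}\n")


def read_events(path: str | Path) -> list[SeizureEvent]:
    """Read a JSON list of ``{onset_ms, offset_ms, source}`` annotations.

    Events are returned sorted by onset; overlapping events are rejected.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    events = [
        SeizureEvent(int(e["onset_ms"]), int(e["offset_ms"]), e.get("source", "caregiver"))
        for e in raw
    ]
    events.sort(key=lambda e: e.onset_ms)
    for a, b in zip(events, events[1:]):
        if b.onset_ms < a.offset_ms:
            raise StreamValidationError(
                f"overlapping seizure events: [{a.onset_ms},{a.offset_ms}) and "
                f"[{b.onset_ms},{b.offset_ms})"
            )
    return events


def write_events(events: Sequence[SeizureEvent], path: str | Path) -> None:
    payload = [
        {"onset_ms": e.onset_ms, "offset_ms": e.offset_ms, "source": e.source}
        for e in events
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def write_subject(record: SubjectRecord, out_dir: str | Path) -> Path:
    """Write one file per channel plus events JSON and a manifest; return the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    channels = {}
    for ch, stream in record.streams.items():
        rel = f"{sid}_{ch.value}.csv"
        write_stream(stream, out_dir / rel)
        channels[ch.value] = rel
    events_rel = f"{sid}_events.json"
    write_events(record.events, out_dir / events_rel)
    manifest = {
        "subject_id": sid,
        "age_months": record.age_months,
        "sex": record.sex,
        "channels": channels,
        "events_path": events_rel,
        "wear_intervals": [[int(a), int(b)] for a, b in record.wear_intervals],
    }
    mpath = out_dir / f"{sid}_manifest.json"
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return mpath


def read_subject(manifest_path: str | Path) -> SubjectRecord:
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        m = json.load(fh)
    base = manifest_path.parent
    streams = {
        Channel(name): read_stream(base / rel, Channel(name))
        for name, rel in m["channels"].items()
    }
    events = read_events(base / m["events_path"])
    return SubjectRecord(
        subject_id=m["subject_id"],
        age_months=int(m["age_months"]),
        sex=m["sex"],
        streams=streams,
        events=events,
        wear_intervals=[(int(a), int(b)) for a, b in m["wear_intervals"]],
    )


def _interval_contains(intervals: Iterable[tuple[int, int]], lo: int, hi: int) -> bool:
    return any(a <= lo and hi <= b for a, b in intervals)


def validate_subject(record: SubjectRecord) -> list[str]:
    """Report every invariant violation in ``record`` (empty list iff valid)."""
    out: list[str] = []
    if record.age_months < 0:
        out.append("age_months: must be >= 0")
    if record.sex not in ("male", "female"):
        out.append(f"sex: unknown value {record.sex!r}")
    for ch, stream in record.streams.items():
        if stream.channel != ch:
            out.append(f"streams[{ch.value}]: channel tag mismatch")
        out.extend(stream.violations())
    for a, b in record.wear_intervals:
        if b <= a:
            out.append(f"wear_intervals: empty or inverted interval [{a},{b})")
    ev = sorted(record.events, key=lambda e: e.onset_ms)
    for e1, e2 in zip(ev, ev[1:]):
        if e2.onset_ms < e1.offset_ms:
            out.append(
                f"events: overlap between [{e1.onset_ms},{e1.offset_ms}) and "
                f"[{e2.onset_ms},{e2.offset_ms})"
            )
    for e in ev:
        if not _interval_contains(record.wear_intervals, e.onset_ms, e.offset_ms):
            out.append(
                f"events: [{e.onset_ms},{e.offset_ms}) lies outside all wear intervals"
            )
    return out
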