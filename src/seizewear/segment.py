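"""Sliding-window segmentation, window labeling, and motion state.

Three window resolutions are used: 60 s / 30 s step for classification,
300 s / 60 s step (80% overlap) for the HRV/motion epochs, and 60 s
non-overlapping for quality control.  Windows are half-open ``[start,
start+length)`` and only windows fitting entirely inside the span are
emitted.

Labels: a window overlapping a seizure interval is *positive*; windows
overlapping only the 60-s buffer zones flanking an event are
*buffer_excluded*; quality-failed windows are *qc_excluded* (takes
precedence over everything); low-motion windows (ACC-magnitude standard
deviation below 0.1 g) are *resting_excluded* — the monitor treats rest as
non-seizure by construction; everything else is *negative*.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .streams import SeizureEvent

__all__ = [
    "WindowSpec",
    "Label",
    "CLASSIFY_SPEC",
    "EPOCH_SPEC",
    "QC_SPEC",
    "RESTING_SIGMA_G",
    "make_windows",
    "label_windows",
    "acc_magnitude",
    "motion_sigma",
    "epoch_motion_state",
]

RESTING_SIGMA_G = 0.1  # strict: sigma < 0.1 g is resting, exactly 0.1 g is active


@dataclass(frozen=True)
class WindowSpec:
    length_s: int
    step_s: int

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.length_s):
            raise ValueError("require 0 < step_s <= length_s")


CLASSIFY_SPEC = WindowSpec(60, 30)
EPOCH_SPEC = WindowSpec(300, 60)
QC_SPEC = WindowSpec(60, 60)


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    BUFFER_EXCLUDED = "buffer_excluded"
    QC_EXCLUDED = "qc_excluded"
    RESTING_EXCLUDED = "resting_excluded"


def make_windows(span_ms: tuple[int, int], spec: WindowSpec) -> np.ndarray:
    """Window start times (int64 ms) for ``[t0 + k*step, ... + length)``
    while the window fits inside the span; count = floor((T - length)/step)+1."""
    t0, t1 = span_ms
    if t1 <= t0:
        raise ValueError("span must satisfy t1 > t0")
    length = spec.length_s * 1000
    step = spec.step_s * 1000
    span = t1 - t0
    if span < length:
        return np.zeros(0, dtype=np.int64)
    n = (span - length) // step + 1
    return t0 + step * np.arange(n, dtype=np.int64)


def _overlaps(starts: np.ndarray, ends: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Half-open interval overlap of [starts, ends) with [lo, hi)."""
    return (starts < hi) & (ends > lo)


def label_windows(
    window_starts_ms: np.ndarray,
    length_s: int,
    events: Sequence[SeizureEvent],
    buffer_s: int = 60,
) -> np.ndarray:
    """Assign positive / buffer_excluded / negative per window.

    Any overlap with a seizure interval makes a window positive (most events
    last under a minute, so containment would starve the positive class);
    otherwise any overlap with the flanking buffers excludes it.
    """
    starts = np.asarray(window_starts_ms, dtype=np.int64)
    ends = starts + length_s * 1000
    labels = np.full(len(starts), Label.NEGATIVE.value, dtype=object)
    buf = buffer_s * 1000
    for e in events:
        in_buf = _overlaps(starts, ends, e.onset_ms - buf, e.onset_ms) | _overlaps(
            starts, ends, e.offset_ms, e.offset_ms + buf
        )
        labels[in_buf & (labels == Label.NEGATIVE.value)] = Label.BUFFER_EXCLUDED.value
    for e in events:  # positive wins over buffer from a neighboring event
        pos = _overlaps(starts, ends, e.onset_ms, e.offset_ms)
        labels[pos] = Label.POSITIVE.value
    return labels


def acc_magnitude(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Per-sample net acceleration sqrt(ax^2 + ay^2 + az^2), in g."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (len(ax) == len(ay) == len(az)):
        raise ValueError("axis arrays must have equal length")
    return np.sqrt(ax**2 + ay**2 + az**2)


def motion_sigma(acc_mag: np.ndarray) -> float:
    """Sample standard deviation (N-1 denominator) of an acceleration epoch."""
    a = np.asarray(acc_mag, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) < 2:
        raise ValueError("motion_sigma needs at least 2 samples")
    return float(np.std(a, ddof=1))


def epoch_motion_state(position_sigmas_g: Sequence[float]) -> str:
    """Majority vote over the (at most five) sliding positions covering a
    5-min epoch: 'resting' iff strictly more positions have sigma < 0.1 g
    than not; ties resolve to 'active' so potentially seizure-bearing epochs
    are never discarded on a tie."""
    sig = np.asarray(list(position_sigmas_g), dtype=float)
    if sig.size == 0:
        raise ValueError("need at least one position sigma")
    n_rest = int(np.sum(sig < RESTING_SIGMA_G))
    return "resting" if n_rest > sig.size - n_rest else "active"
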