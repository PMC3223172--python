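"""Temporal calibration of the image and tracking streams.

Images of a water-bath floor are acquired while the transducer is moved
up and down.  The transducer-to-floor distance is read from each frame
(threshold, then count pixels from the centre row down to the bright
floor line) giving an image-derived motion signal; the tracked sensor
height gives a second signal.  The lag between the streams is the offset
maximising their normalized cross-correlation.

Lags are integer samples: at typical 10 fps capture, subsample precision
is not meaningful.  Positive lag means the image stream trails the
sensor stream, i.e. image(t) matches sensor(t - lag).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SignalSeries",
    "LagEstimate",
    "extract_floor_distance",
    "estimate_lag",
    "read_signal_csv",
    "write_signal_csv",
    "NoFloorDetectedError",
    "UndefinedLagError",
]

_MIN_SAMPLES = 16


class NoFloorDetectedError(ValueError):
    """No supra-threshold pixel below the centre row."""


class UndefinedLagError(ValueError):
    """A flat signal carries no timing information."""


@dataclass(frozen=True)
class SignalSeries:
    """Uniformly sampled scalar signal (mm or px)."""

    timestamps: np.ndarray  # seconds, strictly increasing, uniform
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("timestamps and values must be equal-length 1-D")
        dt = np.diff(t)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise ValueError("timestamps must be strictly increasing and uniform")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)

    @property
    def rate(self) -> float:
        """Samples per second."""
        return 1.0 / float(self.timestamps[1] - self.timestamps[0])


@dataclass(frozen=True)
class LagEstimate:
    lag_seconds: float
    lag_samples: int
    peak_correlation: float


def extract_floor_distance(frame: np.ndarray, threshold: float) -> int:
    """Distance in pixels from the centre row down to the bath floor.

    Scans the centre column downward from the centre row and returns the
    offset of the first pixel at or above ``threshold``; when several
    bright lines are present the nearest one wins.
    """
    img = np.asarray(frame)
    if img.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale image")
    center_row = img.shape[0] // 2
    center_col = img.shape[1] // 2
    column = img[center_row:, center_col]
    hits = np.flatnonzero(column >= threshold)
    if hits.size == 0:
        raise NoFloorDetectedError(
            "no supra-threshold pixel below the centre row"
        )
    return int(hits[0])


def estimate_lag(
    image_signal: SignalSeries, sensor_signal: SignalSeries
) -> LagEstimate:
    """Lag of the image stream relative to the sensor stream.

    Both signals are mean-removed; the returned integer-sample lag
    maximises the Pearson correlation of the overlapping segments, with
    ties broken toward smaller |lag|.  Positive lag: image trails sensor.
    """
    a = np.asarray(image_signal.values, dtype=float)
    b = np.asarray(sensor_signal.values, dtype=float)
    if len(a) < _MIN_SAMPLES or len(b) < _MIN_SAMPLES:
        raise ValueError(f"need at least {_MIN_SAMPLES} samples per signal")
    ra, rb = image_signal.rate, sensor_signal.rate
    if abs(ra - rb) > 1e-9 * max(ra, rb):
        raise ValueError("signals must share one sampling rate")
    a = a - a.mean()
    b = b - b.mean()
    if np.max(np.abs(a)) == 0 or np.max(np.abs(b)) == 0:
        raise UndefinedLagError("flat signal: lag is undefined")

    n = min(len(a), len(b))
    max_lag = n - _MIN_SAMPLES  # keep a minimal overlap

    def segments(lag: int) -> tuple[np.ndarray, np.ndarray]:
        # positive lag: image trails sensor -> a[i] aligns with b[i - lag]
        if lag >= 0:
            return a[lag:n], b[: n - lag]
        return a[: n + lag], b[-lag:n]

    # lag selection uses the globally normalized cross-correlation: the
    # overlap sum shrinks with |lag|, which suppresses the spurious
    # period-multiple peaks a per-lag Pearson score would admit on
    # oscillatory signals
    global_denom = np.linalg.norm(a[:n]) * np.linalg.norm(b[:n])
    best_lag, best_score = 0, -np.inf
    # ordered by |lag| so ties resolve toward zero deterministically
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        seg_a, seg_b = segments(lag)
        score = float(seg_a @ seg_b) / global_denom
        if score > best_score + 1e-12:
            best_score, best_lag = score, lag

    seg_a, seg_b = segments(best_lag)
    sa = seg_a - seg_a.mean()
    sb = seg_b - seg_b.mean()
    denom = np.linalg.norm(sa) * np.linalg.norm(sb)
    if denom == 0 or not np.isfinite(best_score):
        raise UndefinedLagError("correlation undefined at the selected lag")
    return LagEstimate(
        lag_seconds=best_lag / ra,
        lag_samples=best_lag,
        peak_correlation=float(sa @ sb / denom),
    )


def write_signal_csv(path: str | Path, signal: SignalSeries) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp", "value"])
        for t, v in zip(signal.timestamps, signal.values):
            writer.writerow([repr(float(t)), repr(float(v))])


def read_signal_csv(path: str | Path) -> SignalSeries:
    ts, vals = [], []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            ts.append(float(rec["timestamp"]))
            vals.append(float(rec["value"]))
    return SignalSeries(np.array(ts), np.array(vals))
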