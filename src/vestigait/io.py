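"""Trial recordings: reading, writing, multi-rate resampling and yaw cleanup.

A walking trial is captured by five independently clocked sensors — three
IMUs (head, chest, pelvis; yaw angle, nominal 125 Hz), one camera tracking
the horizontal pixel offset of an abdominal marker (nominal 40 Hz), and one
ultrasonic range sensor measuring subject-platform distance (nominal
20 Hz).  This module parses the on-disk CSV/JSON trial format, aligns the
streams onto one uniform timeline, and converts raw yaw channels into
unwrapped, baseline-free signed series (rightward positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SensorStream",
    "TrialRecording",
    "UniformSeries",
    "YawSeries",
    "STREAM_CHANNELS",
    "STREAM_RATES",
    "DEFAULT_ANALYSIS_RATE",
    "read_trial",
    "write_trial",
    "resample_uniform",
    "to_yaw_series",
    "yaw_from_uniform",
    "unwrap_degrees",
    "wrap_degrees",
]

#: canonical channel name carried by each stream
STREAM_CHANNELS = {
    "head": "yaw_deg",
    "chest": "yaw_deg",
    "pelvis": "yaw_deg",
    "camera": "pixel_offset",
    "ultrasonic": "distance_cm",
}

#: nominal native sampling rates (Hz)
STREAM_RATES = {
    "head": 125.0,
    "chest": 125.0,
    "pelvis": 125.0,
    "camera": 40.0,
    "ultrasonic": 20.0,
}

#: common analysis rate: above the Nyquist content of the 40/20 Hz streams,
#: below the IMU rate, keeps arrays small.
DEFAULT_ANALYSIS_RATE = 100.0

SEGMENTS = ("head", "chest", "pelvis")
DIRECTIONS = ("FW", "BW")


@dataclass
class SensorStream:
    """One sensor's raw recording: a monotone timeline plus named channels."""

    name: str
    nominal_rate: float
    timestamps: np.ndarray
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.nominal_rate <= 0:
            raise ValueError(f"stream {self.name!r}: nominal_rate must be > 0")
        if self.timestamps.ndim != 1 or self.timestamps.size == 0:
            raise ValueError(f"stream {self.name!r}: bad timeline (empty)")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(f"stream {self.name!r}: bad timeline (timestamps not strictly increasing)")
        for ch, vals in self.channels.items():
            if vals.shape != self.timestamps.shape:
                raise ValueError(f"stream {self.name!r}: channel {ch!r} length mismatch")

    @property
    def t0(self) -> float:
        return float(self.timestamps[0])

    @property
    def t_end(self) -> float:
        return float(self.timestamps[-1])

    @property
    def duration(self) -> float:
        return self.t_end - self.t0

    def single_channel(self) -> tuple[str, np.ndarray]:
        """Name and values of the stream's only channel."""
        if len(self.channels) != 1:
            raise ValueError(f"stream {self.name!r} carries {len(self.channels)} channels, expected 1")
        ((name, values),) = self.channels.items()
        return name, values


@dataclass
class TrialRecording:
    """One walking trial: five sensor streams plus subject metadata."""

    subject_id: str
    height_cm: float
    direction: str
    head: SensorStream
    chest: SensorStream
    pelvis: SensorStream
    camera: SensorStream
    ultrasonic: SensorStream

    def __post_init__(self) -> None:
        if not 100.0 < self.height_cm < 220.0:
            raise ValueError(f"missing metadata: height_cm {self.height_cm} outside (100, 220)")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be FW or BW, got {self.direction!r}")
        t0 = max(s.t0 for s in self.streams.values())
        t1 = min(s.t_end for s in self.streams.values())
        if t1 - t0 < 1.0:
            raise ValueError("streams share a common interval shorter than 1 s")

    @property
    def streams(self) -> dict[str, SensorStream]:
        return {
            "head": self.head,
            "chest": self.chest,
            "pelvis": self.pelvis,
            "camera": self.camera,
            "ultrasonic": self.ultrasonic,
        }


@dataclass
class UniformSeries:
    """Values on a uniform time grid t0 + k / rate."""

    rate: float
    t0: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate


@dataclass
class YawSeries:
    """Unwrapped, baseline-removed signed yaw of one body segment (deg, right +)."""

    rate: float
    yaw_deg: np.ndarray
    segment: str

    def __post_init__(self) -> None:
        self.yaw_deg = np.asarray(self.yaw_deg, dtype=float)
        if self.segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}, got {self.segment!r}")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not np.all(np.isfinite(self.yaw_deg)):
            raise ValueError("yaw must be finite")

    @property
    def n(self) -> int:
        return int(self.yaw_deg.size)


# ----------------------------------------------------------------------------
# angle helpers


def unwrap_degrees(yaw_deg: np.ndarray) -> np.ndarray:
    """Unwrap a degree series across +-180 deg jumps."""
    return np.unwrap(np.asarray(yaw_deg, dtype=float), period=360.0)


def wrap_degrees(yaw_deg: np.ndarray) -> np.ndarray:
    """Wrap degrees into (-180, 180]."""
    wrapped = (np.asarray(yaw_deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


# ----------------------------------------------------------------------------
# trial I/O


def _read_stream_csv(path: Path, name: str, channel: str, rate: float) -> SensorStream:
    if not path.exists():
        raise FileNotFoundError(f"missing stream: {name} ({path})")
    frame = pd.read_csv(path)
    for col in ("time_s", channel):
        if col not in frame.columns:
            raise ValueError(f"stream {name!r}: missing channel {col!r} in {path}")
    t = frame["time_s"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"stream {name!r}: bad timeline in {path}")
    return SensorStream(name=name, nominal_rate=rate,
                        timestamps=t, channels={channel: frame[channel].to_numpy(dtype=float)})


def read_trial(manifest_path: str | Path) -> TrialRecording:
    """Load a trial from its JSON manifest.

    The manifest names the subject, height (cm), walking direction and one
    CSV per stream (paths relative to the manifest).  CSV columns are parsed
    by header name, never by position.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    for key in ("subject_id", "height_cm", "direction"):
        if key not in manifest or manifest[key] is None:
            raise ValueError(f"missing metadata: {key!r} absent from manifest")
    stream_paths = manifest.get("streams", {})
    streams: dict[str, SensorStream] = {}
    for name, channel in STREAM_CHANNELS.items():
        if name not in stream_paths:
            raise ValueError(f"missing stream: {name!r} not referenced in manifest")
        path = manifest_path.parent / stream_paths[name]
        streams[name] = _read_stream_csv(path, name, channel, STREAM_RATES[name])

    return TrialRecording(
        subject_id=str(manifest["subject_id"]),
        height_cm=float(manifest["height_cm"]),
        direction=str(manifest["direction"]),
        **streams,
    )


def write_trial(trial: TrialRecording, out_dir: str | Path) -> Path:
    """Write a trial as manifest JSON plus one CSV per stream; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stream_files = {}
    for name, stream in trial.streams.items():
        channel, values = stream.single_channel()
        fname = f"{name}.csv"
        pd.DataFrame({"time_s": stream.timestamps, channel: values}).to_csv(
            out_dir / fname, index=False, float_format="%.9g"
        )
        stream_files[name] = fname
    manifest = {
        "subject_id": trial.subject_id,
        "height_cm": trial.height_cm,
        "direction": trial.direction,
        "streams": stream_files,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


# ----------------------------------------------------------------------------
# resampling


def resample_uniform(
    streams: Iterable[SensorStream] | Mapping[str, SensorStream],
    target_rate: float = DEFAULT_ANALYSIS_RATE,
) -> dict[str, UniformSeries]:
    """Linearly interpolate every stream onto one uniform grid.

    The grid spans the streams' common overlap [max t0, min t_end] at
    ``target_rate``; all outputs share the same t0 and length.  Linear
    interpolation is exact on affine signals and idempotent when the source
    grid is a subset of the target grid.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if isinstance(streams, Mapping):
        streams = list(streams.values())
    else:
        streams = list(streams)
    if not streams:
        raise ValueError("no streams to resample")
    t0 = max(s.t0 for s in streams)
    t1 = min(s.t_end for s in streams)
    if t1 <= t0:
        raise ValueError("no common interval across streams")
    # round sample count so an exact-length overlap keeps its final sample
    n = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / target_rate
    out: dict[str, UniformSeries] = {}
    for stream in streams:
        _, values = stream.single_channel()
        out[stream.name] = UniformSeries(
            rate=target_rate, t0=t0, values=np.interp(grid, stream.timestamps, values)
        )
    return out


# ----------------------------------------------------------------------------
# yaw cleanup


def _remove_baseline(values: np.ndarray, rate: float, baseline_window_s: float | None) -> np.ndarray:
    """Subtract the yaw baseline.

    By default the baseline is the median of the whole series: for periodic
    locomotor yaw this is a robust zero even when the recording starts
    mid-oscillation.  Passing ``baseline_window_s`` uses the median of the
    initial window instead (appropriate when trials begin with quiet stance).
    """
    if baseline_window_s is None:
        baseline = float(np.median(values))
    else:
        k = max(1, int(round(baseline_window_s * rate)))
        baseline = float(np.median(values[:k]))
    return values - baseline


def to_yaw_series(
    stream: SensorStream,
    segment: str,
    baseline_window_s: float | None = None,
) -> YawSeries:
    """Convert a raw IMU stream into an unwrapped, baseline-free YawSeries.

    The yaw channel is unwrapped across +-180 deg jumps, then the baseline
    (series median by default; see :func:`_remove_baseline`) is subtracted so
    rightward rotation is positive and leftward negative.
    """
    if "yaw_deg" not in stream.channels:
        raise ValueError(f"missing channel: stream {stream.name!r} has no 'yaw_deg'")
    unwrapped = unwrap_degrees(stream.channels["yaw_deg"])
    cleaned = _remove_baseline(unwrapped, stream.nominal_rate, baseline_window_s)
    return YawSeries(rate=stream.nominal_rate, yaw_deg=cleaned, segment=segment)


def yaw_from_uniform(
    series: UniformSeries,
    segment: str,
    baseline_window_s: float | None = None,
    unwrap: bool = False,
) -> YawSeries:
    """Build a YawSeries from an already-resampled uniform yaw series.

    Resampling should happen on unwrapped angles; set ``unwrap=True`` only if
    the series may still contain +-180 deg jumps.
    """
    values = series.values
    if unwrap:
        values = unwrap_degrees(values)
    cleaned = _remove_baseline(values, series.rate, baseline_window_s)
    return YawSeries(rate=series.rate, yaw_deg=cleaned, segment=segment)
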