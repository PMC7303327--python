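"""Walking-trajectory metrics: XCoB, RP/LP and medial-lateral width (MLW).

The camera reports the horizontal pixel offset of an abdominal marker; with
the concurrent ultrasonic subject-platform range and a pinhole small-angle
model this becomes a lateral position in cm.  The straight "virtual line"
from the walk's start point to its end point is subtracted, leaving a signed
lateral deviation series x_i (right positive) from which all trajectory
metrics derive:

* XCoB - mean |x_i|, normalized by half the subject's body height (%).
* RP / LP - mean magnitudes of the rightward peaks / leftward valleys (cm).
* MLW - maximal vertical distance between the upper and lower envelopes of
  the deviation trace (cm), the widest medial-lateral sway of the walk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import UniformSeries
from .peaks import DEFAULT_SMOOTH_S, local_extrema

__all__ = [
    "DeviationSeries",
    "TrajectoryMetrics",
    "reconstruct_lateral",
    "subtract_virtual_line",
    "compute_xcob",
    "compute_rp_lp",
    "compute_mlw",
    "trajectory_metrics",
]


@dataclass
class DeviationSeries:
    """Signed lateral deviation from the virtual start-to-end line (cm, right +)."""

    rate: float
    x_cm: np.ndarray

    def __post_init__(self) -> None:
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not np.all(np.isfinite(self.x_cm)):
            raise ValueError("deviation must be finite")

    @property
    def n(self) -> int:
        return int(self.x_cm.size)


@dataclass
class TrajectoryMetrics:
    xcob_pct: float
    rp_cm: float
    lp_cm: float
    mlw_cm: float


def reconstruct_lateral(
    camera: UniformSeries,
    distance: UniformSeries,
    focal_px: float = 1000.0,
) -> UniformSeries:
    """Lateral marker position in cm from pixel offset and range.

    Pinhole small-angle model: ``lateral_cm = pixel_offset * distance_cm /
    focal_px``.  Both inputs must already be aligned on the same grid.
    """
    if focal_px <= 0:
        raise ValueError("focal_px must be > 0")
    if camera.n != distance.n or camera.rate != distance.rate:
        raise ValueError("camera and distance series must be aligned (same rate and length)")
    if np.any(distance.values <= 0):
        raise ValueError("invalid range: nonpositive distance sample")
    lateral = camera.values * distance.values / focal_px
    return UniformSeries(rate=camera.rate, t0=camera.t0, values=lateral)


def subtract_virtual_line(lateral: UniformSeries) -> DeviationSeries:
    """Deviation from the straight line joining the first and last samples.

    The line absorbs any constant offset and linear drift, so the walk's
    start and end map exactly to zero deviation.
    """
    if lateral.n < 2:
        raise ValueError("too short: need at least 2 samples")
    line = np.linspace(lateral.values[0], lateral.values[-1], lateral.n)
    return DeviationSeries(rate=lateral.rate, x_cm=lateral.values - line)


def compute_xcob(dev: DeviationSeries, height_cm: float) -> float:
    """Mean absolute deviation as a percentage of half body height."""
    if dev.n < 1:
        raise ValueError("too short: need at least 1 sample")
    if height_cm <= 0:
        raise ValueError("height_cm must be > 0")
    return 100.0 * float(np.mean(np.abs(dev.x_cm))) / (height_cm / 2.0)


def compute_rp_lp(
    dev: DeviationSeries,
    window_s: float = DEFAULT_SMOOTH_S,
) -> tuple[float, float]:
    """Mean rightward-peak and leftward-valley magnitudes (cm).

    Only extrema on the correct side of the line count: positive local
    maxima for RP, negative local minima for LP.  A side with no qualifying
    extremum contributes 0.
    """
    if dev.n < 3:
        raise ValueError("too short: need at least 3 samples")
    maxima, minima = local_extrema(dev.x_cm, dev.rate, window_s)
    peaks = dev.x_cm[maxima]
    valleys = dev.x_cm[minima]
    peaks = peaks[peaks > 0]
    valleys = valleys[valleys < 0]
    rp = float(np.mean(peaks)) if peaks.size else 0.0
    lp = float(np.mean(np.abs(valleys))) if valleys.size else 0.0
    return rp, lp


def _envelope(x: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Piecewise-linear envelope through ``anchors`` plus both endpoints."""
    idx = np.unique(np.concatenate([[0], anchors, [x.size - 1]]))
    return np.interp(np.arange(x.size), idx, x[idx])


def compute_mlw(
    dev: DeviationSeries,
    window_s: float = DEFAULT_SMOOTH_S,
    mode: str = "envelope",
) -> float:
    """Maximal medial-lateral width of the deviation trace (cm).

    ``envelope`` (default): upper envelope through the local maxima and
    lower envelope through the local minima (endpoints included); MLW is the
    largest upper-lower gap at any sample.  ``range``: plain max - min of
    the deviation, a fallback that coincides with the envelope width for
    stationary oscillations.
    """
    if dev.n < 3:
        raise ValueError("too short: need at least 3 samples")
    if mode == "range":
        return float(np.max(dev.x_cm) - np.min(dev.x_cm))
    if mode != "envelope":
        raise ValueError(f"unknown MLW mode {mode!r}")
    maxima, minima = local_extrema(dev.x_cm, dev.rate, window_s)
    upper = _envelope(dev.x_cm, maxima)
    lower = _envelope(dev.x_cm, minima)
    return max(float(np.max(upper - lower)), 0.0)


def trajectory_metrics(
    dev: DeviationSeries,
    height_cm: float,
    window_s: float = DEFAULT_SMOOTH_S,
    mlw_mode: str = "envelope",
) -> TrajectoryMetrics:
    """All trajectory metrics of one deviation series."""
    rp, lp = compute_rp_lp(dev, window_s)
    return TrajectoryMetrics(
        xcob_pct=compute_xcob(dev, height_cm),
        rp_cm=rp,
        lp_cm=lp,
        mlw_cm=compute_mlw(dev, window_s, mlw_mode),
    )
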