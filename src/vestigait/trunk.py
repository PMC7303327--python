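"""Trunk and head rotation metrics: MRT, chest-pelvis ratio and MoH.

During walking with metronome-paced head yaw, the chest and pelvis rotate
about the vertical axis.  Healthy walkers counter-rotate them (reciprocal,
out-of-phase); vestibular-hypofunction patients tend to rotate them together
("en bloc").  The chest-pelvis (CP) ratio captures this: each segment's yaw
is normalized by its own maximal absolute rotation and the mean |C_i + P_i|
is taken — 0 for perfect anti-phase, up to 2 for perfect in-phase motion.

MRT is simply the maximal absolute yaw excursion of a segment over the
trial.  MoH summarizes head turning as the mean and SD of half-cycle
excursions (degree change between successive alternating yaw extrema),
pooled by the side the excursion departs from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import YawSeries
from .peaks import DEFAULT_SMOOTH_S, alternating_extrema

__all__ = [
    "TrunkHeadMetrics",
    "compute_mrt",
    "compute_cp_ratio",
    "compute_moh",
    "trunk_head_metrics",
]


@dataclass
class TrunkHeadMetrics:
    chest_mrt_deg: float
    pelvis_mrt_deg: float
    cp_ratio: float
    moh_left_deg: float
    moh_left_sd: float
    moh_right_deg: float
    moh_right_sd: float


def compute_mrt(yaw: YawSeries) -> float:
    """Maximal absolute rotation (deg) of a segment over the trial."""
    if yaw.n == 0:
        raise ValueError("empty yaw series")
    return float(np.max(np.abs(yaw.yaw_deg)))


def compute_cp_ratio(chest: YawSeries, pelvis: YawSeries) -> float:
    """Chest-pelvis coordination ratio, in [0, 2].

    Each segment is normalized by its own trial-maximal |yaw| (sign kept),
    then the mean |C_i + P_i| is taken over the aligned samples.  Anti-phase
    rotation cancels (ratio near 0); in-phase rotation adds (ratio near 2
    for identical waveforms).
    """
    if chest.n != pelvis.n or chest.rate != pelvis.rate:
        raise ValueError("chest and pelvis series must be aligned (same rate and length)")
    max_c = np.max(np.abs(chest.yaw_deg)) if chest.n else 0.0
    max_p = np.max(np.abs(pelvis.yaw_deg)) if pelvis.n else 0.0
    if max_c == 0.0 or max_p == 0.0:
        raise ValueError("degenerate normalization: a segment shows zero maximal rotation")
    c = chest.yaw_deg / max_c
    p = pelvis.yaw_deg / max_p
    return float(np.mean(np.abs(c + p)))


def compute_moh(
    head: YawSeries,
    window_s: float = DEFAULT_SMOOTH_S,
) -> tuple[float, float, float, float]:
    """Movement-of-head statistics: (left_mean, left_sd, right_mean, right_sd).

    A half-cycle excursion is the absolute yaw change between successive
    alternating extrema.  Excursions departing from a rightward (positive)
    extreme pool as "right rotation", those departing from a leftward
    extreme as "left rotation"; each pool reports its mean and population
    SD in degrees.  An empty pool reports (0, 0).
    """
    idx, kind = alternating_extrema(head.yaw_deg, head.rate, window_s)
    if idx.size < 2:
        raise ValueError("no head turns detected")
    values = head.yaw_deg[idx]
    excursions = np.abs(np.diff(values))
    start_kind = kind[:-1]  # extremum each excursion departs from
    right = excursions[start_kind == 1]
    left = excursions[start_kind == -1]

    def _stats(pool: np.ndarray) -> tuple[float, float]:
        if pool.size == 0:
            return 0.0, 0.0
        return float(np.mean(pool)), float(np.std(pool))

    left_mean, left_sd = _stats(left)
    right_mean, right_sd = _stats(right)
    return left_mean, left_sd, right_mean, right_sd


def trunk_head_metrics(
    head: YawSeries,
    chest: YawSeries,
    pelvis: YawSeries,
    window_s: float = DEFAULT_SMOOTH_S,
) -> TrunkHeadMetrics:
    """All trunk/head metrics of one trial's aligned yaw series."""
    left_mean, left_sd, right_mean, right_sd = compute_moh(head, window_s)
    return TrunkHeadMetrics(
        chest_mrt_deg=compute_mrt(chest),
        pelvis_mrt_deg=compute_mrt(pelvis),
        cp_ratio=compute_cp_ratio(chest, pelvis),
        moh_left_deg=left_mean,
        moh_left_sd=left_sd,
        moh_right_deg=right_mean,
        moh_right_sd=right_sd,
    )
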