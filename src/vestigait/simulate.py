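"""Synthetic walking trials, simulated observers and the platform controller.

The generator stands in for the hardware: it emits the same five multi-rate
sensor streams a real trial produces (IMUs at 125 Hz, camera at 40 Hz,
ultrasonic ranger at 20 Hz) for a 5 m walk with metronome-paced 2 Hz head
yaw.  Kinematics are sinusoidal with optional linear drift and Gaussian
sensor noise — the minimal structure that still admits closed-form ground
truths for every metric:

* lateral path   A_s sin(2 pi f_s t) + d t            (cm)
* head yaw       A_h sin(2 pi f_h t)                  (deg, f_h = 2 Hz)
* chest yaw      A_c sin(2 pi f_s t)                  (deg)
* pelvis yaw     A_p sin(2 pi f_s t + phi)            (deg)

where phi is the chest-pelvis phase offset: 180 deg is the healthy
reciprocal pattern, 0 deg the "en bloc" patient pattern.  Trunk rotation is
stride-locked, so it shares the sway frequency.

Observers answer tumbling-E presentations with a simple psychometric rule:
above their effective threshold (static threshold + dynamic penalty when
the head is moving) they respond correctly except for rare lapses; below
it they guess at the 4-AFC chance rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .dva import ORIENTATIONS, Observer
from .io import SensorStream, TrialRecording, UniformSeries

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "ground_truth",
    "simulate_trial",
    "make_observer",
    "simulate_platform",
    "healthy_config",
    "patient_config",
    "sample_cohort",
]


@dataclass
class SynthConfig:
    """Generative parameters of one simulated walking trial.

    Defaults describe a healthy adult's trial: a 5 m walk at a comfortable
    1 m/s, ~1 Hz stride-locked medial-lateral sway of a few cm, 2 Hz
    metronome-paced head yaw of +-40 deg, small reciprocal (anti-phase)
    chest/pelvis rotation, and sub-centimeter / sub-degree sensor noise.
    """

    subject_id: str = "synth"
    height_cm: float = 170.0
    direction: str = "FW"
    walk_length_m: float = 5.0
    speed_mps: float = 1.0
    duration_s: float | None = None  # defaults to walk_length / speed
    sway_amp_cm: float = 5.0
    sway_freq_hz: float = 1.0
    drift_cm_per_s: float = 0.0
    head_amp_deg: float = 40.0
    head_freq_hz: float = 2.0
    chest_amp_deg: float = 7.0
    pelvis_amp_deg: float = 6.0
    cp_phase_deg: float = 180.0  # 180 = reciprocal/healthy, 0 = en-bloc/patient
    noise_sd_cm: float = 0.2
    noise_sd_deg: float = 0.5
    mean_distance_cm: float = 150.0
    focal_px: float = 1000.0
    imu_rate_hz: float = 125.0
    camera_rate_hz: float = 40.0
    ultrasonic_rate_hz: float = 20.0
    timestamp_jitter_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sway_amp_cm, self.head_amp_deg, self.chest_amp_deg, self.pelvis_amp_deg) < 0:
            raise ValueError("amplitudes must be >= 0")
        if min(self.sway_freq_hz, self.head_freq_hz) <= 0:
            raise ValueError("frequencies must be > 0")
        if self.speed_mps <= 0:
            raise ValueError("speed_mps must be > 0")

    @property
    def duration(self) -> float:
        return self.duration_s if self.duration_s is not None else self.walk_length_m / self.speed_mps

    def noiseless(self) -> "SynthConfig":
        return replace(self, noise_sd_cm=0.0, noise_sd_deg=0.0, timestamp_jitter_ms=0.0)


@dataclass
class GroundTruth:
    """Closed-form metric values implied by a noiseless config (whole cycles)."""

    xcob_pct: float
    rp_cm: float
    lp_cm: float
    mlw_cm: float
    chest_mrt_deg: float
    pelvis_mrt_deg: float
    cp_ratio: float
    moh_excursion_deg: float


def ground_truth(config: SynthConfig) -> GroundTruth:
    """Analytic metric values for the sinusoidal kinematics of ``config``.

    mean |A sin| over whole cycles is 2A/pi; two equal-frequency unit
    sinusoids offset by phi sum to amplitude 2 cos(phi/2), so the CP ratio
    is (4/pi) |cos(phi/2)|.  Drift is absorbed by the virtual-line
    subtraction and contributes nothing.
    """
    half_height = config.height_cm / 2.0
    return GroundTruth(
        xcob_pct=100.0 * (2.0 * config.sway_amp_cm / math.pi) / half_height,
        rp_cm=config.sway_amp_cm,
        lp_cm=config.sway_amp_cm,
        mlw_cm=2.0 * config.sway_amp_cm,
        chest_mrt_deg=config.chest_amp_deg,
        pelvis_mrt_deg=config.pelvis_amp_deg,
        cp_ratio=(4.0 / math.pi) * abs(math.cos(math.radians(config.cp_phase_deg) / 2.0)),
        moh_excursion_deg=2.0 * config.head_amp_deg,
    )


def _times(duration: float, rate: float, jitter_s: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(int(np.floor(duration * rate + 1e-9)) + 1) / rate
    if jitter_s > 0 and t.size > 2:
        # jitter interior stamps, clipped to keep the timeline strictly monotone
        jitter = rng.uniform(-jitter_s, jitter_s, size=t.size - 2)
        limit = 0.45 / rate
        t[1:-1] += np.clip(jitter, -limit, limit)
    return t


def simulate_trial(config: SynthConfig) -> tuple[TrialRecording, GroundTruth]:
    """Generate one trial's five sensor streams plus its analytic ground truth.

    Streams are sampled at their native rates; the camera sees the lateral
    path projected through the pinhole model at the nominal subject-platform
    distance, and the ultrasonic ranger reports that distance with jitter of
    the same scale as the lateral sensor noise.  Bit-reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    T = config.duration
    jitter_s = config.timestamp_jitter_ms / 1000.0

    def lateral(t: np.ndarray) -> np.ndarray:
        return (
            config.sway_amp_cm * np.sin(2.0 * np.pi * config.sway_freq_hz * t)
            + config.drift_cm_per_s * t
        )

    def imu_stream(name: str, amp: float, freq: float, phase_rad: float) -> SensorStream:
        t = _times(T, config.imu_rate_hz, jitter_s, rng)
        yaw = amp * np.sin(2.0 * np.pi * freq * t + phase_rad)
        yaw = yaw + rng.normal(0.0, config.noise_sd_deg, size=t.size) if config.noise_sd_deg > 0 else yaw
        return SensorStream(name=name, nominal_rate=config.imu_rate_hz,
                            timestamps=t, channels={"yaw_deg": yaw})

    head = imu_stream("head", config.head_amp_deg, config.head_freq_hz, 0.0)
    chest = imu_stream("chest", config.chest_amp_deg, config.sway_freq_hz, 0.0)
    pelvis = imu_stream("pelvis", config.pelvis_amp_deg, config.sway_freq_hz,
                        math.radians(config.cp_phase_deg))

    t_cam = _times(T, config.camera_rate_hz, jitter_s, rng)
    lat_cam = lateral(t_cam)
    if config.noise_sd_cm > 0:
        lat_cam = lat_cam + rng.normal(0.0, config.noise_sd_cm, size=t_cam.size)
    pixel = lat_cam * config.focal_px / config.mean_distance_cm
    camera = SensorStream(name="camera", nominal_rate=config.camera_rate_hz,
                          timestamps=t_cam, channels={"pixel_offset": pixel})

    t_us = _times(T, config.ultrasonic_rate_hz, jitter_s, rng)
    dist = np.full(t_us.size, config.mean_distance_cm)
    if config.noise_sd_cm > 0:
        dist = dist + rng.normal(0.0, config.noise_sd_cm, size=t_us.size)
    ultrasonic = SensorStream(name="ultrasonic", nominal_rate=config.ultrasonic_rate_hz,
                              timestamps=t_us, channels={"distance_cm": dist})

    trial = TrialRecording(
        subject_id=config.subject_id,
        height_cm=config.height_cm,
        direction=config.direction,
        head=head, chest=chest, pelvis=pelvis, camera=camera, ultrasonic=ultrasonic,
    )
    return trial, ground_truth(config)


def true_lateral(config: SynthConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free lateral path of ``config`` evaluated at times ``t`` (cm)."""
    return (
        config.sway_amp_cm * np.sin(2.0 * np.pi * config.sway_freq_hz * np.asarray(t))
        + config.drift_cm_per_s * np.asarray(t)
    )


# ----------------------------------------------------------------------------
# observers


def make_observer(
    static_threshold_logmar: float,
    dynamic_penalty_logmar: float = 0.0,
    guess_rate: float = 0.25,
    lapse_rate: float = 0.02,
    seed: int = 0,
) -> Observer:
    """A simulated 4-AFC tumbling-E reader.

    The observer resolves letters at or above its effective threshold
    (static threshold, plus the dynamic penalty while the head moves) with
    probability 1 - lapse_rate, and guesses at ``guess_rate`` (chance = 1/4)
    below it.  With both rates 0 the observer is deterministic.  Larger
    logMAR means a larger letter, so "readable" is logmar >= threshold.
    """
    if not 0.0 <= guess_rate <= 1.0 or not 0.0 <= lapse_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    orientations = np.asarray(ORIENTATIONS)

    def respond(logmar: float, orientation: int, dynamic: bool) -> int:
        threshold = static_threshold_logmar + (dynamic_penalty_logmar if dynamic else 0.0)
        p_correct = (1.0 - lapse_rate) if logmar >= threshold - 1e-12 else guess_rate
        if p_correct >= 1.0 or rng.random() < p_correct:
            return orientation
        wrong = orientations[orientations != orientation]
        return int(wrong[rng.integers(wrong.size)])

    return respond


# ----------------------------------------------------------------------------
# platform controller


def simulate_platform(
    subject_forward_pos: UniformSeries,
    gain_step: float = 0.10,
    target_gap_cm: float = 150.0,
    initial_speed_cmps: float | None = None,
    min_speed_cmps: float = 5.0,
    hysteresis_cm: float = 10.0,
) -> tuple[UniformSeries, np.ndarray]:
    """Platform speed control against a walking subject.

    The platform starts ``target_gap_cm`` ahead of the subject.  Each
    control tick (the input's rate, nominally the 20 Hz ultrasonic rate) the
    gap is measured; whenever it falls below the target the warning flag is
    raised and the motor signal is increased by ``gain_step`` (a stopped
    platform is kicked to ``min_speed_cmps``); when the gap opens beyond
    target + hysteresis the signal is decreased by ``gain_step``.  By
    default the platform launches at the subject's own pace, estimated from
    the first second of positions — a stationary subject therefore leaves
    the platform parked.

    Returns the per-tick gap trace (cm) and the boolean warning flags.
    """
    pos = subject_forward_pos.values
    rate = subject_forward_pos.rate
    dt = 1.0 / rate
    if initial_speed_cmps is None:
        k = min(pos.size - 1, max(1, int(round(rate))))
        initial_speed_cmps = max(0.0, (pos[k] - pos[0]) / (k * dt)) if pos.size > 1 else 0.0

    platform = pos[0] + target_gap_cm
    speed = float(initial_speed_cmps)
    gaps = np.empty(pos.size)
    warnings = np.zeros(pos.size, dtype=bool)
    for i, s in enumerate(pos):
        gap = platform - s
        gaps[i] = gap
        if gap < target_gap_cm:
            warnings[i] = True
            speed = max(speed * (1.0 + gain_step), min_speed_cmps)
        elif gap > target_gap_cm + hysteresis_cm and speed > 0.0:
            speed *= 1.0 - gain_step
        platform += speed * dt
    return UniformSeries(rate=rate, t0=subject_forward_pos.t0, values=gaps), warnings


# ----------------------------------------------------------------------------
# cohorts


def healthy_config(seed: int, **overrides) -> SynthConfig:
    """One healthy-subject trial config: small sway, reciprocal trunk rotation."""
    rng = np.random.default_rng(seed)
    params = dict(
        subject_id=f"H{seed:03d}",
        height_cm=float(np.clip(rng.normal(167.0, 8.0), 150.0, 195.0)),
        sway_amp_cm=float(max(1.0, rng.normal(5.0, 1.0))),
        cp_phase_deg=float(np.clip(rng.normal(180.0, 15.0), 90.0, 270.0)),
        chest_amp_deg=float(max(2.0, rng.normal(7.0, 1.5))),
        pelvis_amp_deg=float(max(2.0, rng.normal(6.0, 1.5))),
        head_amp_deg=float(max(20.0, rng.normal(42.0, 6.0))),
        seed=seed,
    )
    params.update(overrides)
    return SynthConfig(**params)


def patient_config(seed: int, **overrides) -> SynthConfig:
    """One bilateral-hypofunction trial config: large sway, en-bloc trunk rotation."""
    rng = np.random.default_rng(seed)
    params = dict(
        subject_id=f"P{seed:03d}",
        height_cm=float(np.clip(rng.normal(166.0, 8.0), 150.0, 195.0)),
        sway_amp_cm=float(max(2.0, rng.normal(12.0, 3.0))),
        cp_phase_deg=float(np.clip(rng.normal(20.0, 10.0), 0.0, 90.0)),
        chest_amp_deg=float(max(4.0, rng.normal(18.0, 3.0))),
        pelvis_amp_deg=float(max(4.0, rng.normal(16.0, 3.0))),
        head_amp_deg=float(max(20.0, rng.normal(40.0, 8.0))),
        seed=seed,
    )
    params.update(overrides)
    return SynthConfig(**params)


def sample_cohort(kind: str, n: int, seed: int = 0) -> list[SynthConfig]:
    """``n`` subject configs of one cohort, reproducible from ``seed``."""
    maker = {"healthy": healthy_config, "patient": patient_config}.get(kind)
    if maker is None:
        raise ValueError(f"unknown cohort kind {kind!r}")
    root = np.random.default_rng(seed)
    return [maker(int(root.integers(2**31 - 1))) for _ in range(n)]
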