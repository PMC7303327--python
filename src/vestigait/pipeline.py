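"""Per-subject analysis pipeline, group comparison and reporting.

A subject walks each direction twice; ``analyze_subject`` runs the full
signal chain (resample -> lateral reconstruction -> virtual-line deviation
-> trajectory metrics; yaw cleanup -> trunk/head metrics) on every trial
and averages the metrics arithmetically.  ``render_report`` writes the
machine-readable JSON and a human-readable Markdown table with the group
summary / U / Z / p row structure used for cohort contrasts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dva import DEFAULT_ABNORMAL_THRESHOLD, DEFAULT_DISPLAY_MS, DEFAULT_GATE_DPS, DVAResult
from .io import (
    DEFAULT_ANALYSIS_RATE,
    SensorStream,
    TrialRecording,
    resample_uniform,
    unwrap_degrees,
    yaw_from_uniform,
)
from .peaks import DEFAULT_SMOOTH_S
from .stats import GroupComparison, compare_groups
from .trajectory import TrajectoryMetrics, reconstruct_lateral, subtract_virtual_line, trajectory_metrics
from .trunk import TrunkHeadMetrics, trunk_head_metrics

__all__ = [
    "AnalysisConfig",
    "SubjectReport",
    "analyze_trial",
    "analyze_subject",
    "render_report",
    "report_to_dict",
    "report_from_dict",
]

METRIC_FIELDS = (
    "xcob_pct",
    "rp_cm",
    "lp_cm",
    "mlw_cm",
    "chest_mrt_deg",
    "pelvis_mrt_deg",
    "cp_ratio",
    "moh_left_deg",
    "moh_left_sd",
    "moh_right_deg",
    "moh_right_sd",
)


@dataclass
class AnalysisConfig:
    """Tunable analysis defaults; all overridable from a YAML file."""

    analysis_rate_hz: float = DEFAULT_ANALYSIS_RATE
    focal_px: float = 1000.0
    smoothing_s: float = DEFAULT_SMOOTH_S
    mlw_mode: str = "envelope"
    baseline_window_s: float | None = None
    gate_dps: float = DEFAULT_GATE_DPS
    display_ms: float = DEFAULT_DISPLAY_MS
    abnormal_threshold: float = DEFAULT_ABNORMAL_THRESHOLD

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SubjectReport:
    """Per-direction metric means for one subject (plus optional DVA results)."""

    subject_id: str
    direction: str
    n_trials: int
    trajectory: TrajectoryMetrics
    trunk_head: TrunkHeadMetrics
    dva: dict[str, DVAResult] = field(default_factory=dict)

    def metric(self, name: str) -> float:
        for block in (self.trajectory, self.trunk_head):
            if hasattr(block, name):
                return float(getattr(block, name))
        raise KeyError(name)


def _unwrapped(stream: SensorStream) -> SensorStream:
    """Copy of an IMU stream with its yaw channel unwrapped (pre-resampling)."""
    return SensorStream(
        name=stream.name,
        nominal_rate=stream.nominal_rate,
        timestamps=stream.timestamps,
        channels={"yaw_deg": unwrap_degrees(stream.channels["yaw_deg"])},
    )


def analyze_trial(
    trial: TrialRecording,
    config: AnalysisConfig | None = None,
) -> tuple[TrajectoryMetrics, TrunkHeadMetrics]:
    """Full signal chain for one trial."""
    config = config or AnalysisConfig()
    streams = dict(trial.streams)
    for seg in ("head", "chest", "pelvis"):
        streams[seg] = _unwrapped(streams[seg])
    uniform = resample_uniform(streams, config.analysis_rate_hz)

    lateral = reconstruct_lateral(uniform["camera"], uniform["ultrasonic"], config.focal_px)
    dev = subtract_virtual_line(lateral)
    traj = trajectory_metrics(dev, trial.height_cm, config.smoothing_s, config.mlw_mode)

    yaws = {
        seg: yaw_from_uniform(uniform[seg], seg, config.baseline_window_s)
        for seg in ("head", "chest", "pelvis")
    }
    trunk = trunk_head_metrics(yaws["head"], yaws["chest"], yaws["pelvis"], config.smoothing_s)
    return traj, trunk


def analyze_subject(
    trials: Sequence[TrialRecording],
    config: AnalysisConfig | None = None,
    dva_results: Mapping[str, DVAResult] | None = None,
) -> SubjectReport:
    """Analyze a subject's repeated trials of one direction and average the metrics."""
    if not trials:
        raise ValueError("need at least one trial")
    subject_ids = {t.subject_id for t in trials}
    directions = {t.direction for t in trials}
    if len(subject_ids) > 1 or len(directions) > 1:
        raise ValueError("inconsistent trials: mixed subjects or directions")

    per_trial = [analyze_trial(t, config) for t in trials]
    means: dict[str, float] = {}
    for name in METRIC_FIELDS:
        values = []
        for traj, trunk in per_trial:
            block = traj if hasattr(traj, name) else trunk
            values.append(getattr(block, name))
        means[name] = float(np.mean(values))

    traj_mean = TrajectoryMetrics(
        xcob_pct=means["xcob_pct"], rp_cm=means["rp_cm"],
        lp_cm=means["lp_cm"], mlw_cm=means["mlw_cm"],
    )
    trunk_mean = TrunkHeadMetrics(
        chest_mrt_deg=means["chest_mrt_deg"],
        pelvis_mrt_deg=means["pelvis_mrt_deg"],
        cp_ratio=means["cp_ratio"],
        moh_left_deg=means["moh_left_deg"],
        moh_left_sd=means["moh_left_sd"],
        moh_right_deg=means["moh_right_deg"],
        moh_right_sd=means["moh_right_sd"],
    )
    return SubjectReport(
        subject_id=trials[0].subject_id,
        direction=trials[0].direction,
        n_trials=len(trials),
        trajectory=traj_mean,
        trunk_head=trunk_mean,
        dva=dict(dva_results or {}),
    )


# ----------------------------------------------------------------------------
# serialization and rendering


def report_to_dict(report: SubjectReport) -> dict:
    return {
        "subject_id": report.subject_id,
        "direction": report.direction,
        "n_trials": report.n_trials,
        "trajectory": dataclasses.asdict(report.trajectory),
        "trunk_head": dataclasses.asdict(report.trunk_head),
        "dva": {mode: dataclasses.asdict(res) for mode, res in report.dva.items()},
    }


def report_from_dict(data: Mapping) -> SubjectReport:
    from .trajectory import TrajectoryMetrics
    from .trunk import TrunkHeadMetrics

    return SubjectReport(
        subject_id=data["subject_id"],
        direction=data["direction"],
        n_trials=int(data["n_trials"]),
        trajectory=TrajectoryMetrics(**data["trajectory"]),
        trunk_head=TrunkHeadMetrics(**data["trunk_head"]),
        dva={mode: DVAResult(**res) for mode, res in data.get("dva", {}).items()},
    )


def _comparison_to_dict(comp: GroupComparison) -> dict:
    return dataclasses.asdict(comp)


def _fmt(x: float) -> str:
    return f"{x:.3g}"


def _markdown_table(comparisons: Sequence[GroupComparison]) -> str:
    lines = [
        "| Metric | Group A mean ± SD | A median (IQR) | Group B mean ± SD | B median (IQR) | U | Z | p |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for c in comparisons:
        a, b = c.group_a, c.group_b
        lines.append(
            f"| {c.metric} "
            f"| {_fmt(a.mean)} ± {_fmt(a.sd)} | {_fmt(a.median)} ({_fmt(a.iqr_low)}–{_fmt(a.iqr_high)}) "
            f"| {_fmt(b.mean)} ± {_fmt(b.sd)} | {_fmt(b.median)} ({_fmt(b.iqr_low)}–{_fmt(b.iqr_high)}) "
            f"| {_fmt(c.u)} | {_fmt(c.z)} | {_fmt(c.p)} |"
        )
    return "\n".join(lines) + "\n"


def render_report(
    reports: Sequence[SubjectReport],
    comparisons: Sequence[GroupComparison],
    out_path: str | Path,
) -> tuple[Path, Path]:
    """Write the JSON report and its Markdown companion; returns both paths."""
    out_path = Path(out_path)
    try:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "subjects": [report_to_dict(r) for r in reports],
            "comparisons": [_comparison_to_dict(c) for c in comparisons],
        }
        with open(out_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        md_path = out_path.with_suffix(".md")
        with open(md_path, "w") as fh:
            fh.write("# Subject metrics\n\n")
            for r in reports:
                fh.write(
                    f"- {r.subject_id} ({r.direction}, n={r.n_trials}): "
                    f"XCoB {_fmt(r.trajectory.xcob_pct)} %, MLW {_fmt(r.trajectory.mlw_cm)} cm, "
                    f"CP ratio {_fmt(r.trunk_head.cp_ratio)}\n"
                )
            if comparisons:
                fh.write("\n# Group comparison\n\n")
                fh.write(_markdown_table(comparisons))
    except OSError as exc:
        raise OSError(f"io error: cannot write report to {out_path}") from exc
    return out_path, md_path
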