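"""Dynamic visual acuity (DVA) test engine: chart, sessions and scoring.

The optotype chart is a tumbling-"E" chart with 11 sizes in equal 0.1 logMAR
steps from 20/200 (logMAR 1.0) down to 20/20 (logMAR 0.0); a letter's detail
subtends 10^logMAR arcmin, so its 5-detail height is 5 * 10^logMAR arcmin.

A session presents 5 randomly oriented optotypes (0/90/180/270 deg) per
size, descending one size at a time, for 75 ms each.  In dynamic modes a
presentation is emitted only while the head turns fast enough: the signed
head yaw velocity must exceed +gate (right modes) or fall below -gate (left
modes), gate default 120 deg/s.  The session ends when all 5 optotypes of a
size are missed, when the chart is exhausted (all 55 answered), or — during
locomotion — when the walk ends.

Scoring is letter-by-letter: each correct optotype is worth 0.02 logMAR
(5 per 0.1 line), all letters on sizes larger than the start size are
credited, and the threshold is 1.1 - 0.02 * total correct.  The DVA result
is the dynamic-minus-static threshold difference; a decrement strictly
greater than the configured limit (default 0.2 logMAR) flags abnormality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import YawSeries
from .peaks import smooth

__all__ = [
    "ORIENTATIONS",
    "MODES",
    "ChartLevel",
    "OptotypeChart",
    "Presentation",
    "AcuitySession",
    "DVAResult",
    "build_chart",
    "yaw_velocity",
    "run_session",
    "score_session",
    "dva_decrement",
    "session_to_frame",
]

ORIENTATIONS = (0, 90, 180, 270)

MODES = (
    "SVA",
    "sDVA_left",
    "sDVA_right",
    "loDVA_FW_left",
    "loDVA_FW_right",
    "loDVA_BW_left",
    "loDVA_BW_right",
)

#: standard ETDRS-style Snellen labels for logMAR 1.0 .. 0.0
_SNELLEN = (
    "20/200", "20/160", "20/125", "20/100", "20/80",
    "20/63", "20/50", "20/40", "20/32", "20/25", "20/20",
)

PRESENTATIONS_PER_LEVEL = 5
DEFAULT_GATE_DPS = 120.0
DEFAULT_DISPLAY_MS = 75.0
DEFAULT_ABNORMAL_THRESHOLD = 0.2
#: minimum spacing between presentations (subject answers between letters)
DEFAULT_MIN_INTERVAL_S = 1.0
#: logMAR credit per correctly read optotype (one 5-letter 0.1 line)
LETTER_LOGMAR = 0.02

#: response generator contract: (logmar, orientation_deg, dynamic) -> response_deg
Observer = Callable[[float, int, bool], int]


@dataclass(frozen=True)
class ChartLevel:
    index: int
    logmar: float
    snellen: str
    size_arcmin: float


@dataclass(frozen=True)
class OptotypeChart:
    levels: tuple[ChartLevel, ...]

    def __len__(self) -> int:
        return len(self.levels)


@dataclass
class Presentation:
    level_index: int
    logmar: float
    orientation: int
    trigger_velocity_dps: float  # NaN in static mode
    display_ms: float
    response: int | None
    correct: bool


@dataclass
class AcuitySession:
    mode: str
    presentations: list[Presentation]
    start_level: int
    termination: str  # all_missed_at_level | all_55_presented | walk_complete
    threshold_logmar: float = field(default=float("nan"))

    @property
    def n_correct(self) -> int:
        return sum(p.correct for p in self.presentations)


@dataclass
class DVAResult:
    mode: str
    static_logmar: float
    dynamic_logmar: float
    decrement_logmar: float
    abnormal: bool


def build_chart() -> OptotypeChart:
    """The 11-level tumbling-E chart, largest (20/200) to smallest (20/20)."""
    levels = []
    for i in range(11):
        logmar = round(1.0 - 0.1 * i, 10)
        levels.append(
            ChartLevel(index=i, logmar=logmar, snellen=_SNELLEN[i],
                       size_arcmin=5.0 * 10.0 ** logmar)
        )
    return OptotypeChart(levels=tuple(levels))


def yaw_velocity(yaw: YawSeries, smooth_s: float = 0.02) -> np.ndarray:
    """Signed head yaw velocity (deg/s): central difference after 20 ms smoothing."""
    ys = smooth(yaw.yaw_deg, yaw.rate, smooth_s)
    return np.gradient(ys) * yaw.rate


class _TriggerSource:
    """Streams trigger velocities from one or more head-yaw passes.

    ``loop=True`` (standing modes) recycles the trace indefinitely — the
    subject keeps turning until the protocol terminates.  Without looping
    (locomotion modes) the source is exhausted when every pass has been
    walked through, which terminates the session as ``walk_complete``.
    """

    def __init__(
        self,
        passes: Sequence[YawSeries],
        sign: int,
        gate_dps: float,
        min_interval_s: float,
        loop: bool,
    ) -> None:
        self._eligible: list[tuple[np.ndarray, np.ndarray, int]] = []
        any_eligible = False
        for p in passes:
            v = yaw_velocity(p)
            mask = sign * v > gate_dps
            idx = np.nonzero(mask)[0]
            any_eligible = any_eligible or idx.size > 0
            self._eligible.append((idx, v, max(1, int(round(min_interval_s * p.rate)))))
        if not any_eligible:
            raise ValueError("no trigger events: head velocity never exceeds the gate")
        self._loop = loop
        self._pass = 0
        self._cursor = 0

    def next(self) -> float | None:
        """Velocity of the next trigger, or None when the walk is over."""
        while True:
            if self._pass >= len(self._eligible):
                if not self._loop:
                    return None
                self._pass, self._cursor = 0, 0
            idx, v, refractory = self._eligible[self._pass]
            pos = np.searchsorted(idx, self._cursor)
            if pos < idx.size:
                i = int(idx[pos])
                self._cursor = i + refractory
                return float(v[i])
            self._pass += 1
            self._cursor = 0


def _mode_traits(mode: str) -> tuple[bool, int, bool]:
    """(dynamic, gate sign, loop) for a session mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "SVA":
        return False, 0, False
    sign = 1 if mode.endswith("right") else -1
    loop = mode.startswith("sDVA")
    return True, sign, loop


def start_level_for(mode: str, sva_smallest_level: int | None, chart: OptotypeChart) -> int:
    """Protocol start size: chart top for SVA, else 4 sizes above the SVA result."""
    if mode == "SVA":
        return 0
    if sva_smallest_level is None:
        raise ValueError("missing baseline: dynamic modes need sva_smallest_level")
    if not 0 <= sva_smallest_level < len(chart):
        raise ValueError(f"sva_smallest_level {sva_smallest_level} outside chart")
    return max(0, sva_smallest_level - 4)


def run_session(
    mode: str,
    chart: OptotypeChart,
    observer: Observer,
    head_yaw: YawSeries | Sequence[YawSeries] | None = None,
    sva_smallest_level: int | None = None,
    rng_seed: int = 0,
    gate_dps: float = DEFAULT_GATE_DPS,
    display_ms: float = DEFAULT_DISPLAY_MS,
    min_interval_s: float = DEFAULT_MIN_INTERVAL_S,
) -> AcuitySession:
    """Run one acuity session and score it.

    ``observer`` answers each presentation; see :data:`Observer`.  Dynamic
    modes need ``head_yaw`` (one YawSeries, or a list of walk passes for
    locomotion modes) and ``sva_smallest_level`` (the SVA result's chart
    index).  The orientation sequence is reproducible from ``rng_seed``.
    """
    dynamic, sign, loop = _mode_traits(mode)
    start = start_level_for(mode, sva_smallest_level, chart)

    triggers: _TriggerSource | None = None
    if dynamic:
        if head_yaw is None:
            raise ValueError(f"mode {mode!r} requires a head yaw trace")
        passes = head_yaw if isinstance(head_yaw, (list, tuple)) else [head_yaw]
        triggers = _TriggerSource(passes, sign, gate_dps, min_interval_s, loop)

    rng = np.random.default_rng(rng_seed)
    presentations: list[Presentation] = []
    termination = "all_55_presented"

    for level in chart.levels[start:]:
        level_correct = 0
        level_presented = 0
        walk_over = False
        for _ in range(PRESENTATIONS_PER_LEVEL):
            velocity = float("nan")
            if triggers is not None:
                nxt = triggers.next()
                if nxt is None:
                    walk_over = True
                    break
                velocity = nxt
            orientation = int(rng.choice(ORIENTATIONS))
            response = int(observer(level.logmar, orientation, dynamic))
            correct = response == orientation
            presentations.append(
                Presentation(
                    level_index=level.index,
                    logmar=level.logmar,
                    orientation=orientation,
                    trigger_velocity_dps=velocity,
                    display_ms=display_ms,
                    response=response,
                    correct=correct,
                )
            )
            level_presented += 1
            level_correct += correct
        if walk_over:
            termination = "walk_complete"
            break
        if level_presented == PRESENTATIONS_PER_LEVEL and level_correct == 0:
            termination = "all_missed_at_level"
            break

    session = AcuitySession(
        mode=mode, presentations=presentations, start_level=start, termination=termination
    )
    session.threshold_logmar = score_session(session, chart)
    return session


def score_session(session: AcuitySession, chart: OptotypeChart) -> float:
    """Letter-by-letter threshold: 1.1 - 0.02 x total correct.

    All 5 letters at every size larger than the start size are credited as
    correct (the subject skipped them from a known-good baseline).  A
    session with no correct responses from the chart top scores 1.1, one
    line worse than the largest size.
    """
    credited = PRESENTATIONS_PER_LEVEL * session.start_level
    total_correct = credited + session.n_correct
    return round(1.1 - LETTER_LOGMAR * total_correct, 10)


def dva_decrement(
    static_logmar: float,
    dynamic_logmar: float,
    abnormal_threshold: float = DEFAULT_ABNORMAL_THRESHOLD,
    mode: str = "",
) -> DVAResult:
    """Dynamic-minus-static acuity loss with the abnormality flag.

    The flag raises only for a decrement *strictly* greater than the
    threshold (default 0.2 logMAR; 0.3 is the conservative alternative).
    """
    if not (np.isfinite(static_logmar) and np.isfinite(dynamic_logmar)):
        raise ValueError("scores must be finite")
    decrement = round(dynamic_logmar - static_logmar, 10)
    return DVAResult(
        mode=mode,
        static_logmar=static_logmar,
        dynamic_logmar=dynamic_logmar,
        decrement_logmar=decrement,
        abnormal=bool(decrement > abnormal_threshold + 1e-9),
    )


def session_to_frame(session: AcuitySession) -> pd.DataFrame:
    """Session log: one row per presentation, ready for CSV export."""
    return pd.DataFrame(
        {
            "mode": session.mode,
            "level_index": [p.level_index for p in session.presentations],
            "logmar": [p.logmar for p in session.presentations],
            "orientation_deg": [p.orientation for p in session.presentations],
            "trigger_velocity_dps": [p.trigger_velocity_dps for p in session.presentations],
            "response_deg": [p.response for p in session.presentations],
            "correct": [p.correct for p in session.presentations],
        }
    )
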