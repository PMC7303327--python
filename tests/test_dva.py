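"""DVA engine: chart, session protocol, triggering and scoring."""

import numpy as np
import pytest

from vestigait.dva import (
    build_chart,
    dva_decrement,
    run_session,
    session_to_frame,
    start_level_for,
)
from vestigait.io import YawSeries
from vestigait.simulate import make_observer


def head_trace(amp_deg, freq_hz, duration=5.0, rate=125.0):
    t = np.arange(int(round(duration * rate)) + 1) / rate
    return YawSeries(rate=rate, yaw_deg=amp_deg * np.sin(2 * np.pi * freq_hz * t), segment="head")


def perfect_observer():
    return make_observer(0.0, guess_rate=0.0, lapse_rate=0.0)


def threshold_observer(logmar):
    return make_observer(logmar, guess_rate=0.0, lapse_rate=0.0)


class TestChart:
    def test_eleven_levels_in_tenth_logmar_steps(self, chart):
        assert len(chart.levels) == 11
        logmars = [lvl.logmar for lvl in chart.levels]
        assert logmars[0] == 1.0 and logmars[-1] == 0.0
        steps = np.diff(logmars)
        np.testing.assert_allclose(steps, -0.1, atol=1e-12)

    def test_logmar_zero_is_20_20_at_5_arcmin(self, chart):
        smallest = chart.levels[-1]
        assert smallest.snellen == "20/20"
        assert smallest.size_arcmin == pytest.approx(5.0)

    def test_letter_size_follows_mar(self, chart):
        for lvl in chart.levels:
            assert lvl.size_arcmin == pytest.approx(5.0 * 10.0 ** lvl.logmar)


class TestSessionProtocol:
    def test_perfect_observer_reads_all_55(self, chart):
        s = run_session("SVA", chart, perfect_observer(), rng_seed=1)
        assert len(s.presentations) == 55
        assert s.termination == "all_55_presented"
        assert s.threshold_logmar == pytest.approx(0.0)

    def test_deterministic_04_observer(self, chart):
        s = run_session("SVA", chart, threshold_observer(0.4), rng_seed=1)
        assert s.n_correct == 35  # 7 readable lines of 5
        assert len(s.presentations) == 40  # plus the all-missed 0.3 line
        assert s.termination == "all_missed_at_level"
        assert s.threshold_logmar == pytest.approx(0.40)

    def test_blind_observer_scores_floor(self, chart):
        s = run_session("SVA", chart, threshold_observer(99.0), rng_seed=1)
        assert s.n_correct == 0
        assert s.threshold_logmar == pytest.approx(1.1)

    def test_reproducible_from_seed(self, chart):
        obs = make_observer(0.3, seed=5)
        a = run_session("sDVA_right", chart, obs, head_yaw=head_trace(30, 2),
                        sva_smallest_level=8, rng_seed=42)
        obs = make_observer(0.3, seed=5)
        b = run_session("sDVA_right", chart, obs, head_yaw=head_trace(30, 2),
                        sva_smallest_level=8, rng_seed=42)
        assert session_to_frame(a).equals(session_to_frame(b))

    @pytest.mark.parametrize(
        "sva_level, expected_start",
        [(10, 6), (8, 4), (4, 0), (2, 0), (0, 0)],
    )
    def test_start_level_four_sizes_above_sva(self, chart, sva_level, expected_start):
        assert start_level_for("sDVA_left", sva_level, chart) == expected_start

    def test_dynamic_mode_requires_baseline(self, chart):
        with pytest.raises(ValueError, match="missing baseline"):
            run_session("sDVA_right", chart, perfect_observer(), head_yaw=head_trace(30, 2))

    def test_staircase_exact_at_every_level(self, chart):
        for lvl in chart.levels:
            s = run_session("SVA", chart, threshold_observer(lvl.logmar), rng_seed=7)
            assert s.threshold_logmar == pytest.approx(lvl.logmar, abs=1e-12)


class TestTriggering:
    def test_fast_head_triggers_with_correct_sign(self, chart):
        for mode, sign in [("sDVA_right", 1), ("sDVA_left", -1)]:
            s = run_session(mode, chart, perfect_observer(),
                            head_yaw=head_trace(30, 2), sva_smallest_level=10, rng_seed=2)
            assert s.presentations
            for p in s.presentations:
                assert sign * p.trigger_velocity_dps > 120.0

    def test_slow_head_never_triggers(self, chart):
        # peak velocity 5 * 2 pi * 1 ~ 31 deg/s, below the 120 deg/s gate
        with pytest.raises(ValueError, match="no trigger events"):
            run_session("sDVA_right", chart, perfect_observer(),
                        head_yaw=head_trace(5, 1), sva_smallest_level=10, rng_seed=2)

    def test_walk_end_terminates_locomotion_session(self, chart):
        s = run_session("loDVA_FW_right", chart, perfect_observer(),
                        head_yaw=head_trace(30, 2, duration=5.0),
                        sva_smallest_level=0, rng_seed=2)
        assert s.termination == "walk_complete"
        # 5 m pass at 2 Hz yields roughly 3-6 answered letters
        assert 3 <= len(s.presentations) <= 6

    def test_multi_pass_accumulates_presentations(self, chart):
        single = run_session("loDVA_FW_right", chart, perfect_observer(),
                             head_yaw=head_trace(30, 2), sva_smallest_level=10, rng_seed=2)
        multi = run_session("loDVA_FW_right", chart, perfect_observer(),
                            head_yaw=[head_trace(30, 2)] * 12,
                            sva_smallest_level=10, rng_seed=2)
        assert len(multi.presentations) > len(single.presentations)
        assert multi.termination == "all_55_presented"
        assert multi.threshold_logmar == pytest.approx(0.0)


class TestScoring:
    @pytest.mark.parametrize(
        "static, dynamic, expect_dec, expect_abnormal",
        [
            (0.2, 0.4, 0.2, False),  # boundary: not strictly greater
            (0.0, 0.3, 0.3, True),
            (0.1, 0.1, 0.0, False),
        ],
    )
    def test_decrement_and_abnormality(self, static, dynamic, expect_dec, expect_abnormal):
        res = dva_decrement(static, dynamic)
        assert res.decrement_logmar == pytest.approx(expect_dec)
        assert res.abnormal is expect_abnormal

    def test_raising_dynamic_penalty_never_improves_dva(self, chart):
        medians = []
        for penalty in (0.0, 0.2, 0.4):
            scores = []
            for seed in range(30):
                obs = make_observer(0.1, dynamic_penalty_logmar=penalty, seed=seed)
                s = run_session("sDVA_right", chart, obs, head_yaw=head_trace(40, 2),
                                sva_smallest_level=9, rng_seed=100 + seed)
                scores.append(s.threshold_logmar)
            medians.append(float(np.median(scores)))
        assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9
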