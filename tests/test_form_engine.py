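"""Misalignment detection, form accuracy, rep counting and recommendations."""

import numpy as np
import pytest

from poseform.catalog import load_exercise
from poseform.form_engine import (
    RepSegment,
    assess_session,
    associated_muscles,
    count_repetitions,
    detect_misalignment,
    find_descent_attempts,
    form_accuracy,
    recommend_corrective,
)
from poseform.kinematics import AngleFrame, JointSpec, RepFSMConfig, extract_angles
from poseform.synth import SquatSimParams, simulate_squat_stream

SQUAT_SPECS = [
    JointSpec(joint_name="hip", proximal="shoulder", vertex="hip", distal="knee",
              reference_deg=90, tolerance_deg=10),
    JointSpec(joint_name="knee", proximal="hip", vertex="knee", distal="ankle",
              reference_deg=90, tolerance_deg=10),
    JointSpec(joint_name="ankle", proximal="knee", vertex="ankle", distal="foot_index",
              reference_deg=75, tolerance_deg=10),
]


def _frame(**angles):
    return AngleFrame(frame_index=0, angles=angles)


class TestMisalignment:
    def test_large_hip_deviation_is_red(self):
        report = detect_misalignment(_frame(hip=133.58), SQUAT_SPECS[:1])
        a = report.joints["hip"]
        assert a.status == "red"
        assert a.deviation_deg == pytest.approx(43.58)

    def test_measured_equals_reference_is_green_with_zero_deviation(self):
        a = detect_misalignment(_frame(knee=90.0), SQUAT_SPECS[1:2]).joints["knee"]
        assert a.status == "green" and a.deviation_deg == 0.0

    def test_knee_outside_band_is_red(self):
        a = detect_misalignment(_frame(knee=122.95), SQUAT_SPECS[1:2]).joints["knee"]
        assert a.status == "red"

    def test_status_is_pure_in_the_tolerance_boundary(self):
        for measured, expected in [(100.0, "green"), (100.01, "red"), (80.0, "green")]:
            a = detect_misalignment(_frame(knee=measured), SQUAT_SPECS[1:2]).joints["knee"]
            assert a.status == expected

    def test_missing_joint_reported_unassessed(self):
        report = detect_misalignment(_frame(knee=90.0), SQUAT_SPECS)
        assert report.unassessed == {"hip", "ankle"}


class TestFormAccuracy:
    def test_all_joints_at_reference_scores_100(self):
        report = detect_misalignment(_frame(hip=90, knee=90, ankle=75), SQUAT_SPECS)
        assert form_accuracy(report, SQUAT_SPECS) == 100.0

    def test_one_joint_at_twice_tolerance_among_three(self):
        report = detect_misalignment(_frame(hip=110, knee=90, ankle=75), SQUAT_SPECS)
        assert form_accuracy(report, SQUAT_SPECS) == pytest.approx(200 / 3, abs=0.01)

    def test_everything_beyond_twice_tolerance_floors_at_zero(self):
        report = detect_misalignment(_frame(hip=140, knee=140, ankle=125), SQUAT_SPECS)
        assert form_accuracy(report, SQUAT_SPECS) == 0.0

    def test_accuracy_100_iff_all_within_tolerance(self):
        inside = detect_misalignment(_frame(hip=99, knee=81, ankle=75), SQUAT_SPECS)
        assert form_accuracy(inside, SQUAT_SPECS) == 100.0
        outside = detect_misalignment(_frame(hip=101, knee=81, ankle=75), SQUAT_SPECS)
        assert form_accuracy(outside, SQUAT_SPECS) < 100.0

    def test_strictly_decreasing_beyond_tolerance(self):
        scores = [
            form_accuracy(
                detect_misalignment(_frame(hip=90 + dev, knee=90, ankle=75), SQUAT_SPECS),
                SQUAT_SPECS,
            )
            for dev in (12, 15, 18)
        ]
        assert scores[0] > scores[1] > scores[2]

    def test_no_assessed_joints_is_an_error(self):
        with pytest.raises(ValueError):
            form_accuracy(detect_misalignment(_frame(), SQUAT_SPECS), SQUAT_SPECS)


FSM = RepFSMConfig(descent_threshold=150, bottom_threshold=100, hysteresis=5)


def oracle_rep_count(theta, fsm):
    """Independent crossing-based count: a rep is a dip below the bottom
    threshold followed by a recovery above descent + hysteresis."""
    count = 0
    seen_bottom = False
    for a in np.asarray(theta, dtype=float):
        if not np.isfinite(a):
            continue
        if a < fsm.bottom_threshold:
            seen_bottom = True
        elif a > fsm.descent_threshold + fsm.hysteresis and seen_bottom:
            count += 1
            seen_bottom = False
    return count


class TestRepCounting:
    def test_constant_standing_angle_counts_zero(self):
        assert count_repetitions(np.full(100, 175.0), FSM) == []

    def test_five_cycle_sinusoid_counts_five(self):
        t = np.linspace(0, 5, 1000)
        theta = 125 + 45 * np.cos(2 * np.pi * t)  # 170 <-> 80, 5 cycles
        reps = count_repetitions(theta, FSM)
        assert len(reps) == 5
        for r in reps:
            assert r.start < r.bottom < r.end
            assert r.bottom_angle_deg == pytest.approx(80, abs=0.1)

    def test_jitter_around_standing_rejected_by_hysteresis(self, rng):
        theta = 170 + rng.uniform(-3, 3, size=500)
        assert count_repetitions(theta, FSM) == []

    def test_shallow_partial_reps_not_counted(self):
        t = np.linspace(0, 3, 600)
        theta = 135 + 35 * np.cos(2 * np.pi * t)  # dips to 100, never below
        assert count_repetitions(theta, FSM) == []
        assert len(find_descent_attempts(theta, FSM)) == 3

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            RepFSMConfig(descent_threshold=100, bottom_threshold=150)

    def test_matches_oracle_on_500_random_piecewise_linear_series(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n_knots = rng.integers(4, 15)
            knots = rng.uniform(60, 180, size=n_knots)
            knots[0] = 175.0  # start standing
            theta = np.concatenate(
                [
                    np.linspace(a, b, rng.integers(3, 12), endpoint=False)
                    for a, b in zip(knots, knots[1:])
                ]
            )
            reps = count_repetitions(theta, FSM)
            assert len(reps) == oracle_rep_count(theta, FSM)
            for r in reps:
                assert r.start < r.bottom < r.end

    @pytest.mark.parametrize("k", range(0, 11))
    def test_generator_rep_count_recovered_exactly(self, k, squat_config):
        stream, _ = simulate_squat_stream(SquatSimParams(n_reps=k))
        frames = extract_angles(stream, squat_config)
        theta = np.array([f.angles["knee"] for f in frames])
        assert len(count_repetitions(theta, squat_config.fsm)) == k

    def test_segments_are_ordered_and_non_overlapping(self, clean_squat, squat_config):
        stream, _ = clean_squat
        frames = extract_angles(stream, squat_config)
        theta = np.array([f.angles["knee"] for f in frames])
        reps = count_repetitions(theta, squat_config.fsm)
        for a, b in zip(reps, reps[1:]):
            assert a.end < b.start

    def test_rep_segment_ordering_enforced(self):
        with pytest.raises(ValueError):
            RepSegment(start=5, bottom=5, end=9, bottom_angle_deg=90.0)


class TestMusclesAndRecommendations:
    def test_catalog_muscle_lists(self):
        assert associated_muscles("barbell_squat") == [
            "quadriceps", "gluteus maximus", "hamstrings",
        ]
        assert associated_muscles("pull_up") == [
            "latissimus dorsi", "biceps brachii", "teres major",
        ]

    def test_every_catalog_exercise_lists_2_to_3_muscles(self):
        from poseform.catalog import list_exercises

        assert len(list_exercises()) == 7
        for name in list_exercises():
            assert 2 <= len(associated_muscles(name)) <= 3

    def test_unknown_exercise_rejected(self):
        with pytest.raises(KeyError):
            associated_muscles("yoga")

    def test_empty_deficiency_list_yields_no_recommendations(self):
        assert recommend_corrective([]) == []

    def test_demo_durations_within_contract(self):
        for level in ("beginner", "intermediate", "advanced"):
            for code in ("insufficient_depth", "knee_valgus", "trunk_lean", "heel_rise"):
                (rec,) = recommend_corrective([code], level)
                assert 10 <= rec.demo_duration_s <= 15
                assert rec.level == level
                assert rec.deficiency_code == code

    def test_order_is_stable_and_deterministic(self):
        recs = recommend_corrective(["insufficient_depth", "knee_valgus"], "advanced")
        assert [r.deficiency_code for r in recs] == ["insufficient_depth", "knee_valgus"]
        again = recommend_corrective(["insufficient_depth", "knee_valgus"], "advanced")
        assert recs == again

    def test_unknown_code_rejected(self):
        with pytest.raises(KeyError):
            recommend_corrective(["slouching"])


class TestSessionAssessment:
    def test_clean_squat_end_to_end(self, clean_squat, squat_config):
        stream, _ = clean_squat
        frames = extract_angles(stream, squat_config)
        session = assess_session(frames, squat_config)
        assert session.n_reps == 5
        assert session.session_accuracy == pytest.approx(100.0, abs=1e-6)
        assert session.deficiencies == []
        assert session.recommendations == []

    @pytest.mark.parametrize(
        "mode, magnitude, expected",
        [
            ("insufficient_depth", 25.0, "insufficient_depth"),
            ("trunk_lean", 20.0, "trunk_lean"),
            ("heel_rise", 20.0, "heel_rise"),
            ("knee_valgus", 0.06, "knee_valgus"),
        ],
    )
    def test_error_modes_diagnosed(self, mode, magnitude, expected, squat_config):
        from poseform.kinematics import knee_valgus_offset

        stream, _ = simulate_squat_stream(
            SquatSimParams(n_reps=3, error_modes={mode: magnitude})
        )
        frames = extract_angles(stream, squat_config)
        session = assess_session(
            frames, squat_config, valgus_offsets=knee_valgus_offset(stream)
        )
        assert expected in session.deficiencies
        assert any(r.deficiency_code == expected for r in session.recommendations)
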