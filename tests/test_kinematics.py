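"""Kinematic scoring against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from cmipipe.kinematics import (
    ErrorCode,
    MovementMarks,
    classify_direction_reversal,
    classify_error,
    compute_composites,
    compute_velocity_profile,
    cronbach_alpha,
    score_marks,
    score_trial,
    summarize_session,
    TrialOutcomes,
)
from cmipipe.synthetic import (
    PC_FR,
    STANDARD,
    CohortSpec,
    TaskGeometry,
    TrialRecord,
    generate_session,
    generate_trial,
    minimum_jerk_position,
)


def make_trial(t_ms, xy, go_cue_ms=0.0, target="right", condition="standard"):
    xy = np.asarray(xy, dtype=float)
    return TrialRecord(
        participant="p000",
        condition=condition,
        trial=0,
        target=target,
        t_ms=np.asarray(t_ms, dtype=float),
        x_mm=xy[:, 0],
        y_mm=xy[:, 1],
        finger_x_mm=xy[:, 0],
        finger_y_mm=xy[:, 1],
        go_cue_ms=go_cue_ms,
    )


class TestVelocityProfile:
    def test_constant_velocity_flat_profile(self):
        t = np.arange(0, 500, 5.0)
        xy = np.column_stack([0.2 * t, np.zeros_like(t)])
        prof = compute_velocity_profile(make_trial(t, xy), smoothing=1)
        assert prof.pv == pytest.approx(0.2)
        np.testing.assert_allclose(prof.speed, 0.2, atol=1e-12)

    def test_stationary_trial_zero_pv(self):
        t = np.arange(0, 500, 5.0)
        prof = compute_velocity_profile(make_trial(t, np.zeros((t.size, 2))))
        assert prof.pv == 0.0

    def test_minimum_jerk_peak_matches_closed_form(self):
        # D = 55 mm over T = 500 ms: PV = 1.875*55/500 = 0.206 mm/ms
        t = np.arange(0, 500.001, 1.0)
        x = 55.0 * minimum_jerk_position(t / 500.0)
        prof = compute_velocity_profile(
            make_trial(t, np.column_stack([x, np.zeros_like(x)])), smoothing=1
        )
        assert prof.pv == pytest.approx(0.20625, rel=1e-3)

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            compute_velocity_profile(
                make_trial([0, 5, 5, 10], np.zeros((4, 2)))
            )


def brute_force_crossings(speed, thr):
    """Exhaustive scan for upward and downward threshold crossings."""
    up = [i for i in range(len(speed) - 1) if speed[i] < thr <= speed[i + 1]]
    down = [i for i in range(len(speed) - 1) if speed[i] >= thr > speed[i + 1]]
    return up, down


class TestMarks:
    def test_single_peak_full_equals_ballistic(self, clean_spec, geometry, rng):
        tr = generate_trial("up", STANDARD, geometry, clean_spec, rng)
        prof = compute_velocity_profile(tr)
        marks = score_marks(prof, tr, geometry)
        assert marks.full_offset_idx == marks.ballistic_offset_idx
        assert marks.onset_idx <= marks.ballistic_offset_idx

    def test_corrective_submovement_extends_full_offset(self, geometry, rng):
        spec = CohortSpec(
            seed=1, error_probability=0.0, endpoint_noise_sd=0.0,
            endpoint_bias_sd=0.0, position_noise_sd=0.0,
            dr_probability={"standard": 0.0, "pc_fr": 0.0},
            correction_probability={"standard": 1.0, "pc_fr": 1.0},
        )
        tr = generate_trial("right", STANDARD, geometry, spec, rng)
        prof = compute_velocity_profile(tr)
        marks = score_marks(prof, tr, geometry)
        assert marks.full_offset_idx > marks.ballistic_offset_idx

    def test_crossings_match_brute_force_scan(self, clean_spec, geometry):
        # randomized instances vs an exhaustive-scan oracle
        rng = np.random.default_rng(7)
        for _ in range(25):
            d = rng.choice(["up", "down", "left", "right"])
            spec = CohortSpec(
                seed=int(rng.integers(1e6)), error_probability=0.0,
                endpoint_noise_sd=1.0, endpoint_bias_sd=0.0,
                position_noise_sd=0.05,
                dr_probability={"standard": 0.3, "pc_fr": 0.3},
                correction_probability={"standard": 0.5, "pc_fr": 0.5},
            )
            tr = generate_trial(d, STANDARD, geometry, spec, rng)
            prof = compute_velocity_profile(tr)
            marks = score_marks(prof, tr, geometry)
            thr = 0.1 * prof.pv
            start = int(np.searchsorted(prof.t, tr.go_cue_ms))
            up, down = brute_force_crossings(prof.speed[start:], thr)
            assert marks.onset_idx == start + up[0] + 1
            after_onset = [i for i in down if i + start >= marks.onset_idx]
            assert marks.ballistic_offset_idx == start + after_onset[0] + 1
            assert marks.full_offset_idx in [start + i + 1 for i in down]


class TestErrorClassification:
    def mk_marks(self, onset_ms, full_ms):
        return MovementMarks(0, 0, 0, onset_ms, full_ms, full_ms)

    def trial_stub(self, go=2000.0):
        t = np.arange(0, 3000, 5.0)
        return make_trial(t, np.zeros((t.size, 2)), go_cue_ms=go)

    def test_rt_too_short(self):
        marks = MovementMarks(0, 0, 0, 2100.0, 2500.0, 2500.0)
        assert classify_error(self.trial_stub(), marks) is ErrorCode.RT_TOO_SHORT

    def test_rt_boundary_exactly_150_passes(self):
        marks = MovementMarks(0, 0, 0, 2150.0, 2500.0, 2500.0)
        assert classify_error(self.trial_stub(), marks) is ErrorCode.NONE

    def test_rt_too_long(self):
        marks = MovementMarks(0, 0, 0, 2000.0 + 8500.0, 11000.0, 11000.0)
        assert classify_error(self.trial_stub(), marks) is ErrorCode.RT_TOO_LONG

    def test_mt_too_long(self):
        marks = MovementMarks(0, 0, 0, 2300.0, 2300.0 + 10500.0, 2300.0 + 10500.0)
        assert classify_error(self.trial_stub(), marks) is ErrorCode.MT_TOO_LONG

    def test_mt_boundary_exactly_10000_passes(self):
        marks = MovementMarks(0, 0, 0, 2300.0, 12300.0, 12300.0)
        assert classify_error(self.trial_stub(), marks) is ErrorCode.NONE

    def test_left_home_early(self):
        t = np.arange(0, 3000, 5.0)
        xy = np.zeros((t.size, 2))
        xy[t < 2000, 0] = np.linspace(0, 30, (t < 2000).sum())
        marks = MovementMarks(0, 0, 0, 2300.0, 2800.0, 2800.0)
        trial = make_trial(t, xy, go_cue_ms=2000.0)
        assert classify_error(trial, marks) is ErrorCode.LEFT_HOME_EARLY

    @pytest.mark.parametrize(
        "code", ["left_home_early", "rt_too_short", "rt_too_long", "mt_too_long"]
    )
    def test_injected_errors_recovered(self, code, clean_spec, geometry, rng):
        tr = generate_trial(
            "right", STANDARD, geometry, clean_spec, rng, force_error=code
        )
        out = score_trial(tr, geometry)
        assert out.is_error and out.error_code.value == code


class TestDirectionReversal:
    def straight_trial(self, direction_vec, geometry):
        # 300 ms hold then straight-line motion along direction_vec
        t = np.arange(0, 800, 5.0)
        xy = np.zeros((t.size, 2))
        move = t >= 300
        frac = np.linspace(0, 1, move.sum())
        xy[move] = np.outer(frac, np.asarray(direction_vec, float) * 55.0)
        return make_trial(t, xy, go_cue_ms=100.0)

    def marks_for(self, trial, geometry):
        prof = compute_velocity_profile(trial, smoothing=1)
        return score_marks(prof, trial, geometry)

    def test_opposite_exit_is_dr(self, geometry):
        tr = self.straight_trial([-1.0, 0.0], geometry)
        marks = self.marks_for(tr, geometry)
        assert classify_direction_reversal(tr, marks, geometry) is True

    def test_26_degree_exit_not_dr(self, geometry):
        tr = self.straight_trial([1.0, 0.5], geometry)  # arctan(0.5) = 26.57 deg
        marks = self.marks_for(tr, geometry)
        assert classify_direction_reversal(tr, marks, geometry) is False

    def test_exact_45_degrees_not_dr(self, geometry):
        tr = self.straight_trial([1.0, 1.0], geometry)  # exactly 45 deg
        marks = self.marks_for(tr, geometry)
        assert classify_direction_reversal(tr, marks, geometry) is False

    def test_never_exiting_center_flagged(self, geometry):
        t = np.arange(0, 500, 5.0)
        xy = np.full((t.size, 2), 0.1)
        xy[t.size // 2 :] += 0.5  # tiny jiggle, stays inside the center
        tr = make_trial(t, xy, go_cue_ms=0.0)
        prof = compute_velocity_profile(tr, smoothing=1)
        with pytest.raises(ValueError):
            classify_direction_reversal(tr, MovementMarks(1, 2, 3, 0, 0, 0), geometry)


class TestScoreTrial:
    def test_path_length_matches_polyline_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(20, 60))
            t = np.arange(n) * 5.0
            xy = np.cumsum(rng.normal(0, 2.0, size=(n, 2)), axis=0)
            trial = make_trial(t, xy)
            prof = compute_velocity_profile(trial, smoothing=1)
            # oracle: naive segment-length summation over the full record
            naive = sum(
                float(np.hypot(*(xy[i + 1] - xy[i]))) for i in range(n - 1)
            )
            from cmipipe.kinematics import _path_length

            assert _path_length(xy, 0, n - 1) == pytest.approx(naive, rel=1e-12)

    def test_overshoot_adds_twice_the_excursion(self, geometry):
        t = np.arange(0, 1200, 5.0)
        n = t.size
        x = np.zeros(n)
        seg = np.linspace(0, 60, 80)  # overshoot to 60
        back = np.linspace(60, 55, 40)  # return 5 mm
        x[40 : 40 + 80] = seg
        x[120 : 120 + 40] = back
        x[160:] = 55.0
        trial = make_trial(t, np.column_stack([x, np.zeros(n)]), go_cue_ms=0.0)
        out = score_trial(trial, geometry, smoothing=1)
        assert not out.is_error
        # path additivity: 5 mm overshoot-and-return adds 10 mm over the
        # straight 55 mm path; the ballistic burst ends at the turn point
        assert out.PLf == pytest.approx(55.0 + 10.0, abs=1.5)
        assert out.PLb == pytest.approx(60.0, abs=1.5)

    def test_dr_trial_scored_with_excursion_in_ballistic_path(
        self, clean_spec, geometry, rng
    ):
        tr = generate_trial(
            "right", PC_FR, geometry, clean_spec, rng, force_dr=True
        )
        out = score_trial(tr, geometry)
        assert out.is_dr
        excursion = clean_spec.dr_excursion_frac * geometry.target_distance
        assert out.PLb == pytest.approx(excursion, abs=2.5)
        assert out.PLf > geometry.target_distance


class TestSessionSummary:
    def outcomes_from_endpoints(self, endpoints, target="right"):
        return [
            TrialOutcomes(
                participant="p0", condition="standard", trial=i, target=target,
                is_error=False, error_code=ErrorCode.NONE, is_dr=False,
                RT=300.0, MTf=500.0, PV=0.2, PLb=55.0, PLf=55.0,
                endpoint_x=e[0], endpoint_y=e[1],
            )
            for i, e in enumerate(endpoints)
        ]

    def test_on_target_endpoints_zero_error(self, geometry):
        outs = self.outcomes_from_endpoints([(55.0, 0.0)] * 4)
        s = summarize_session(outs, geometry)
        assert s.AE == 0.0 and s.VE == 0.0

    def test_hand_computed_ae_ve(self, geometry):
        # mean endpoint (55, 0) on target -> AE = 0; dispersion 1 mm -> VE = 1
        outs = self.outcomes_from_endpoints(
            [(54.0, 0.0), (56.0, 0.0), (55.0, 1.0), (55.0, -1.0)]
        )
        s = summarize_session(outs, geometry)
        assert s.AE == pytest.approx(0.0, abs=1e-12)
        assert s.VE == pytest.approx(1.0, abs=1e-12)

    def test_pct_dr(self, geometry):
        outs = self.outcomes_from_endpoints([(55.0, 0.0)] * 20)
        for o in outs[:5]:
            o.is_dr = True
        s = summarize_session(outs, geometry)
        assert s.pct_DR == 25.0

    def test_trimming_never_removes_identical_trials(self, geometry):
        outs = self.outcomes_from_endpoints([(55.0, 0.0)] * 6)
        s = summarize_session(outs, geometry)
        assert s.n_trimmed == 0

    def test_outlier_trial_trimmed(self, geometry):
        outs = self.outcomes_from_endpoints([(55.0, 0.0)] * 10)
        outs[0].RT = 5000.0  # way past 2 SD of the others once it is included
        for i, o in enumerate(outs[1:], 1):
            o.RT = 300.0 + i  # small spread so the SD is finite
        s = summarize_session(outs, geometry)
        assert s.n_trimmed == 1
        assert s.means["RT"] == pytest.approx(np.mean([300.0 + i for i in range(1, 10)]))

    def test_degenerate_sessions_raise(self, geometry):
        with pytest.raises(ValueError):
            summarize_session([], geometry)
        outs = self.outcomes_from_endpoints([(55.0, 0.0)])
        with pytest.raises(ValueError):
            summarize_session(outs, geometry)


class TestComposites:
    def session_frame(self, rng, n=12):
        rows = []
        for cond in ("standard", "pc_fr"):
            for i in range(n):
                rows.append(
                    {"participant": f"p{i:03d}", "condition": cond,
                     "RT": rng.normal(350, 40), "MTf": rng.normal(600, 60),
                     "PV": rng.normal(0.2, 0.03), "PLf": rng.normal(60, 5),
                     "AE": abs(rng.normal(2, 1)), "VE": abs(rng.normal(2, 1))}
                )
        return pd.DataFrame(rows)

    def test_matches_brute_force_oracle(self, rng):
        df = self.session_frame(rng)
        comp = compute_composites(df)
        # oracle: standardize pooled, negate PV, average
        def z(v):
            return (v - v.mean()) / v.std(ddof=1)

        timing = (z(df["RT"]) + z(df["MTf"]) - z(df["PV"])) / 3
        traj = (z(df["PLf"]) + z(df["AE"]) + z(df["VE"])) / 3
        np.testing.assert_allclose(comp["timing_score"], timing, atol=1e-12)
        np.testing.assert_allclose(comp["trajectory_score"], traj, atol=1e-12)

    def test_cohort_mean_is_zero(self, rng):
        comp = compute_composites(self.session_frame(rng))
        assert abs(comp["timing_score"].mean()) < 1e-10
        assert abs(comp["trajectory_score"].mean()) < 1e-10

    def test_affine_invariance(self, rng):
        df = self.session_frame(rng)
        ref = compute_composites(df)
        df2 = df.copy()
        df2["RT"] = df2["RT"] * 1000.0 + 7.0  # change units
        df2["PV"] = df2["PV"] * 60.0
        again = compute_composites(df2)
        np.testing.assert_allclose(
            ref["timing_score"], again["timing_score"], atol=1e-10
        )

    def test_plus_one_sd_participant_scores_plus_one(self):
        # three participants at z = -1, 0, +1 on every timing component
        df = pd.DataFrame(
            {
                "participant": ["a", "b", "c"],
                "condition": "standard",
                "RT": [300.0, 350.0, 400.0],
                "MTf": [500.0, 600.0, 700.0],
                "PV": [0.25, 0.2, 0.15],  # fastest is lowest z -> inverted
                "PLf": [55.0, 56.0, 57.0],
                "AE": [1.0, 2.0, 3.0],
                "VE": [1.0, 2.0, 3.0],
            }
        )
        comp = compute_composites(df)
        assert comp.loc[2, "timing_score"] == pytest.approx(1.0)
        assert comp.loc[1, "timing_score"] == pytest.approx(0.0)


class TestCronbach:
    def test_identical_items_alpha_one(self):
        x = np.tile(np.random.default_rng(0).normal(size=(20, 1)), (1, 3))
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_worked_matrix_matches_formula_oracle(self):
        X = np.array([[1, 2, 3], [2, 3, 3], [3, 4, 5], [4, 4, 6]], dtype=float)
        k = 3
        oracle = k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum() / X.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(X) == pytest.approx(oracle, abs=1e-12)

    def test_independent_items_alpha_near_zero(self):
        # alpha has a small negative finite-sample bias, so the check on
        # the expectation uses a reasonably large cohort per replicate
        rng = np.random.default_rng(2)
        alphas = [
            cronbach_alpha(rng.normal(size=(100, 2))) for _ in range(500)
        ]
        assert abs(np.mean(alphas)) < 0.05

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((5, 3)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.zeros((2, 1)))


class TestGeneratorScorerIdentity:
    def test_noiseless_session_identity(self, clean_spec, geometry):
        trials = generate_session("p000", 0, STANDARD, geometry, clean_spec)
        outs = [score_trial(t, geometry) for t in trials]
        assert not any(o.is_error for o in outs)
        s = summarize_session(outs, geometry)
        assert s.pct_DR == 0.0
        assert s.AE == pytest.approx(0.0, abs=0.05)
        assert s.VE == pytest.approx(0.0, abs=0.05)
        dt = 1000.0 / clean_spec.sampling_rate
        for t, o in zip(trials, outs):
            assert abs(o.RT - (t.nominal_rt_ms - 0.0)) <= dt

    def test_path_length_bounds(self, geometry):
        # PLf >= PLb >= straight-line onset-to-offset distance
        spec = CohortSpec(
            seed=21, error_probability=0.0,
            dr_probability={"standard": 0.3, "pc_fr": 0.3},
            correction_probability={"standard": 0.5, "pc_fr": 0.5},
        )
        trials = generate_session("p000", 0, PC_FR, geometry, spec)
        checked = 0
        for tr in trials:
            o = score_trial(tr, geometry)
            if o.is_error:
                continue
            assert o.PLf >= o.PLb - 1e-9
            checked += 1
        assert checked >= 15
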