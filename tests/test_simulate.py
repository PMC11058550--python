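"""Synthetic user/cohort generator: thermal drift, skill mapping, attendance."""

import numpy as np
import pytest
from scipy import stats

from myotrain import (
    BreathingTaskConfig,
    CohortConfig,
    ThermalModel,
    TrackingTaskConfig,
    UserModel,
    generate_user_trace,
    score_breathing_task,
    score_tracking_task,
    simulate_attendance,
    simulate_cohort,
    simulate_participant,
    spearman,
    thermal_offset,
)
from myotrain.calibration import compute_zero_offset
from myotrain.simulate import SimulatedUser, generate_covariates, prescribed_days, sigma_for_skill


class TestThermalModel:
    def test_closed_form_points(self):
        m = ThermalModel(b_inf_kpa=0.4, tau_s=20.0)
        assert thermal_offset(0.0, m) == 0.0
        assert thermal_offset(1e6, m) == pytest.approx(0.4)
        assert thermal_offset(20.0, m) == pytest.approx(0.4 * (1 - np.exp(-1)))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            thermal_offset(-1.0, ThermalModel())

    def test_pre_warmup_zero_cal_is_worse_than_post(self):
        """A zero calibration taken on insertion mis-estimates the steady-state
        baseline by more than one taken after the 2-minute warm-up game —
        the rationale for the device's two-stage zero calibration."""
        user = SimulatedUser(UserModel(rest_noise_frac=0.0))
        b_inf = user.model.thermal.b_inf_kpa
        assert b_inf > 0
        rng = np.random.default_rng(0)
        pre = compute_zero_offset(user.zero_trace("tongue", 10.0, 0.0, 50.0, rng))
        post = compute_zero_offset(user.zero_trace("tongue", 10.0, 130.0, 50.0, rng))
        assert abs(pre.offset_kpa - b_inf) > abs(post.offset_kpa - b_inf)


class TestSkillMapping:
    def test_sigma_inversion_formula(self):
        # P(|N(0, sigma)| <= h) recovers the requested skill
        for skill in (0.3, 0.7, 0.95):
            sigma = sigma_for_skill(skill, half_width_kpa=0.4)
            recovered = 2 * stats.norm.cdf(0.4 / sigma) - 1
            assert recovered == pytest.approx(skill)
        assert sigma_for_skill(1.0, 0.4) == 0.0

    def test_perfect_skill_scores_100(self):
        user = UserModel(skill_0=1.0, skill_inf=1.0, rest_noise_frac=0.0)
        cfg = TrackingTaskConfig()
        trace = generate_user_trace(user, cfg, day=1, seed=0)
        assert score_tracking_task(trace, cfg, user.pmax_tongue_kpa).score_pct == 100.0

    def test_zero_skill_scores_0(self):
        user = UserModel(skill_0=0.0, skill_inf=0.0, rest_noise_frac=0.0)
        cfg = TrackingTaskConfig()
        trace = generate_user_trace(user, cfg, day=1, seed=0)
        assert score_tracking_task(trace, cfg, user.pmax_tongue_kpa).score_pct == 0.0

    def test_learning_curve_is_monotone_and_bounded(self):
        user = UserModel()
        skills = [user.skill(d) for d in range(1, 29)]
        assert all(s2 >= s1 for s1, s2 in zip(skills, skills[1:]))
        assert user.skill_0 <= skills[0] <= skills[-1] <= user.skill_inf

    def test_breathing_skill_maps_to_score(self):
        user = UserModel(skill_0=0.8, skill_inf=0.8)
        cfg = BreathingTaskConfig()
        scores = [
            score_breathing_task(
                generate_user_trace(user, cfg, day=1, seed=s), cfg, user.pmax_lip_kpa
            ).score_pct
            for s in range(10)
        ]
        assert np.mean(scores) == pytest.approx(80.0, abs=2.0)


class TestAttendance:
    def test_full_adherence_attends_all_24(self):
        user = UserModel(adherence=1.0, dropout_hazard=0.0)
        assert simulate_attendance(user, seed=0) == prescribed_days()

    def test_zero_adherence_attends_none(self):
        user = UserModel(adherence=0.0, dropout_hazard=0.0)
        assert simulate_attendance(user, seed=0) == []

    def test_immediate_dropout_mirrors_early_leavers(self):
        # certain dropout on day 1: at most the very first days are attended
        user = UserModel(adherence=1.0, dropout_hazard=1.0)
        assert simulate_attendance(user, seed=0) == []

    def test_attendance_is_subset_of_prescription(self):
        user = UserModel(adherence=0.7, dropout_hazard=0.05)
        for seed in range(10):
            attended = simulate_attendance(user, seed=seed)
            assert set(attended) <= set(prescribed_days())
            assert attended == sorted(attended)

    def test_default_hazard_gives_about_20pct_dropout(self):
        # (1 - h)^28 ~ 0.8 for the default daily hazard
        user = UserModel()
        survival = (1 - user.dropout_hazard) ** 28
        assert survival == pytest.approx(0.8, abs=0.02)


class TestWholeStudy:
    def test_participant_simulation_is_seed_deterministic(self):
        user = UserModel(adherence=0.9)
        log1 = simulate_participant(user, weeks=1, seed=42)
        log2 = simulate_participant(user, weeks=1, seed=42)
        assert log1 == log2

    def test_sessions_land_on_attended_days(self):
        user = UserModel(adherence=0.8, dropout_hazard=0.01)
        log = simulate_participant(user, weeks=2, seed=3)
        days = [s.day_index for s in log.sessions]
        assert set(days) <= set(prescribed_days(weeks=2))

    def test_scores_improve_from_first_to_last_week(self):
        user = UserModel(adherence=1.0, dropout_hazard=0.0, skill_0=0.5, skill_inf=0.9)
        log = simulate_participant(user, weeks=4, seed=11)
        first = np.mean([t.score_pct for t in log.sessions[0].task_results])
        last = np.mean([t.score_pct for t in log.sessions[-1].task_results])
        assert last > first + 10


class TestCohortCovariates:
    def test_perfect_negative_association_gives_spearman_minus_1(self):
        cfg = CohortConfig(association_rho=-1.0)
        rng = np.random.default_rng(5)
        lip_changes = rng.normal(10, 5, 8)
        cov = generate_covariates(cfg, lip_changes, rng)
        delta = (cov["ahi_supine_post"] - cov["ahi_supine_pre"]).to_numpy()
        assert spearman(lip_changes, delta) == pytest.approx(-1.0)

    def test_zero_association_is_null_at_large_n(self):
        cfg = CohortConfig(association_rho=0.0)
        rng = np.random.default_rng(6)
        lip_changes = rng.normal(10, 5, 2000)
        cov = generate_covariates(cfg, lip_changes, rng)
        delta = (cov["ahi_supine_post"] - cov["ahi_supine_pre"]).to_numpy()
        assert abs(spearman(lip_changes, delta)) < 0.06

    def test_programmed_rho_recovered_at_large_n(self):
        cfg = CohortConfig(association_rho=-0.76)
        rng = np.random.default_rng(7)
        lip_changes = rng.normal(10, 5, 3000)
        cov = generate_covariates(cfg, lip_changes, rng)
        delta = (cov["ahi_supine_post"] - cov["ahi_supine_pre"]).to_numpy()
        assert spearman(lip_changes, delta) == pytest.approx(-0.76, abs=0.05)

    def test_cohort_seed_determinism_and_log_structure(self):
        cfg = CohortConfig(n=2, weeks=1, seed=9)
        logs1, cov1 = simulate_cohort(cfg)
        logs2, cov2 = simulate_cohort(cfg)
        assert logs1 == logs2
        assert cov1.equals(cov2)
        assert [log.participant_id for log in logs1] == ["P01", "P02"]
        assert set(logs1[0].covariates) == {"ahi_pre", "ahi_post", "ahi_supine_pre", "ahi_supine_post"}
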