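"""Compliance, success summaries, rank statistics and the report table."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from myotrain import (
    TaskKind,
    UserModel,
    build_report,
    compliance_from_counts,
    compute_compliance,
    paired_permutation_test,
    permutation_pvalue,
    simulate_participant,
    spearman,
    summarize_success,
)
from myotrain.analytics import round_half_up, success_summary_from_scores
from myotrain.clinical_tables import load_ahi_pre_post, load_success_rates, session_counts


class TestCompliance:
    def test_fixture_counts(self):
        counts = session_counts()
        assert counts["1"] == 24 and counts["7"] == 18
        summary = compliance_from_counts(counts)
        assert summary.per_participant["1"][1] == 1.0
        assert summary.per_participant["7"][1] == pytest.approx(18 / 24)
        assert summary.overall_completed == 175
        assert summary.overall_prescribed == 192
        assert summary.overall_pct == 91

    def test_pooled_equals_participant_mean_at_equal_denominators(self):
        counts = {"a": 20, "b": 24, "c": 12}
        summary = compliance_from_counts(counts)
        mean_of_fracs = np.mean([f for _, f in summary.per_participant.values()])
        assert summary.overall_fraction == pytest.approx(mean_of_fracs)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compliance_from_counts({})
        with pytest.raises(ValueError):
            compute_compliance([])

    def test_compliance_from_simulated_logs(self):
        log = simulate_participant(UserModel(adherence=1.0, dropout_hazard=0.0), weeks=1, seed=0)
        summary = compute_compliance([log])
        assert summary.overall_fraction == 1.0


class TestSuccessSummary:
    def test_identical_values_collapse_the_band(self):
        s = success_summary_from_scores([70, 70, 70], [90, 90, 90], TaskKind.TONGUE)
        assert s.first_mean == 70 and s.first_sd == 0
        assert s.ci96_last == (90, 90)

    def test_fixture_tongue_and_lip_columns(self):
        df = load_success_rates()
        tongue = success_summary_from_scores(
            df["tongue_baseline"], df["tongue_post"], TaskKind.TONGUE
        )
        assert tongue.first_mean == pytest.approx(65.875)
        assert tongue.first_pct == 66 and tongue.last_pct == 85
        assert round(tongue.first_sd) == 18 and round(tongue.last_sd) == 17
        lip = success_summary_from_scores(df["lip_baseline"], df["lip_post"], TaskKind.LIP)
        assert lip.first_pct == 78 and lip.last_pct == 87

    def test_first_and_last_completed_sessions_define_the_trajectory(self):
        user = UserModel(adherence=1.0, dropout_hazard=0.0, skill_0=0.5, skill_inf=0.9)
        log = simulate_participant(user, weeks=4, seed=21)
        s = summarize_success([log], TaskKind.TONGUE)
        first_session = [t.score_pct for t in log.sessions[0].task_results if t.task_kind == TaskKind.TONGUE]
        assert s.first_mean == pytest.approx(np.mean(first_session))
        assert s.n == 1 and s.first_sd == 0.0


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 4.0, 4.5, 10.0]) == pytest.approx(1.0)
        assert spearman(x, [5.0, 1.0, 0.0, -2.0]) == pytest.approx(-1.0)

    def test_tied_pair_matches_hand_midrank_oracle(self):
        # y = (1,1,3,4): midranks (1.5, 1.5, 3, 4); Pearson with (1,2,3,4)
        # = 4.5 / sqrt(5 * 4.5) = 0.9486832980505138
        assert spearman([1, 2, 3, 4], [1, 1, 3, 4]) == pytest.approx(4.5 / np.sqrt(22.5))

    def test_constant_vector_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            spearman([1, 2, 3], [5, 5, 5])

    @settings(deadline=None, max_examples=40)
    @given(
        xy=st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=4,
            max_size=12,
            unique_by=lambda t: t[0],
        )
    )
    def test_invariant_under_strictly_monotone_transforms(self, xy):
        x = np.array([a for a, _ in xy], dtype=float)
        y = np.array([b for _, b in xy], dtype=float)
        if np.ptp(y) == 0:
            return
        base = spearman(x, y)
        assert spearman(np.exp(x / 50.0), y) == pytest.approx(base)
        assert spearman(x, y**3 + 2 * y) == pytest.approx(base)


class TestPermutationPvalue:
    def test_perfect_monotone_n5_is_2_over_120(self):
        res = permutation_pvalue([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 120)

    def test_exact_mode_is_seed_independent(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8]
        y = [2.7, 1.8, 2.8, 1.2, 8.2, 8.4, 5.9, 0.4]
        results = {permutation_pvalue(x, y, seed=s).p_value for s in (0, 1, 2)}
        assert len(results) == 1

    def test_p_at_least_one_over_n_factorial(self):
        res = permutation_pvalue([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.p_value >= 1 / 24

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            ps.append(permutation_pvalue(x, y).p_value)
        ps = np.array(ps)
        assert 0 < ps.min() and ps.max() <= 1
        assert abs(ps.mean() - 0.5) < 0.08

    def test_matches_scipy_permutation_test(self):
        x = np.array([1.0, 4.0, 2.5, 7.0, 5.0, 3.2])
        y = np.array([2.0, 3.5, 1.0, 8.0, 4.5, 7.7])
        ours = permutation_pvalue(x, y)
        # permute y only (single sample) so scipy enumerates n! pairings
        ref = stats.permutation_test(
            (y,),
            lambda b: stats.spearmanr(x, b).statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        assert ours.rs == pytest.approx(float(stats.spearmanr(x, y).statistic))
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_monte_carlo_branch_for_larger_n(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = x + rng.normal(size=12) * 0.2
        res = permutation_pvalue(x, y, seed=3, n_mc=2000)
        assert not res.exact
        assert res.p_value <= 0.01


class TestPairedPermutation:
    def test_identical_pre_post_gives_p_1(self):
        assert paired_permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_all_positive_differences_n8(self):
        pre = np.zeros(8)
        post = np.arange(1.0, 9.0)
        assert paired_permutation_test(pre, post) == pytest.approx(2 / 256)

    def test_n3_matches_full_enumeration_oracle(self):
        pre = np.array([1.0, 2.0, 3.0])
        post = np.array([2.5, 1.8, 4.0])
        d = post - pre
        obs = abs(d.mean())
        count = sum(
            1
            for signs in itertools.product([-1, 1], repeat=3)
            if abs(np.mean(np.array(signs) * d)) >= obs - 1e-12
        )
        assert paired_permutation_test(pre, post) == pytest.approx(count / 8)

    def test_fixture_ahi_change(self):
        df = load_ahi_pre_post()
        p = paired_permutation_test(df["ahi_pre"], df["ahi_post"])
        assert 0 < p <= 1


class TestRoundingAndReport:
    def test_round_half_up_matches_table_style(self):
        assert round_half_up(65.875) == 66
        assert round_half_up(84.875) == 85
        assert round_half_up(0.5) == 1
        assert round_half_up(20.7125, 1) == 20.7
        assert round_half_up(-2.5) == -3

    def test_report_covariate_means_match_fixture(self):
        log = simulate_participant(UserModel(adherence=1.0, dropout_hazard=0.0), weeks=1, seed=5)
        df = load_ahi_pre_post()
        report = build_report([log], df)
        get = lambda sec, met: float(
            report.query("section == @sec and metric == @met")["value"].iloc[0]
        )
        assert get("covariate_ahi", "pre_mean") == 20.7
        assert get("covariate_ahi", "post_mean") == 17.7
        assert get("compliance", "overall_pct") == 100

    def test_report_without_covariates_has_no_covariate_rows(self):
        log = simulate_participant(UserModel(adherence=1.0, dropout_hazard=0.0), weeks=1, seed=5)
        report = build_report([log], None)
        assert not report["section"].str.startswith("covariate").any()
        assert "association" not in set(report["section"])
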