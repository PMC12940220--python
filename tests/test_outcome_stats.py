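"""Paired pre/post testing, effect sizes, ICC and cohort accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from poseform.outcome_stats import (
    choose_test,
    cohort_accounting,
    d_from_ci,
    icc_agreement,
    paired_analysis,
    summarize_outcomes,
    wilcoxon_z,
)


def exact_wilcoxon_p(diffs):
    """Exact two-sided signed-rank p by enumeration over all sign flips."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))  # midranks for tied magnitudes
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


class TestChooseTest:
    def test_normal_differences_choose_paired_t(self):
        hits = 0
        for seed in range(100):
            d = np.random.default_rng(seed).normal(1.0, 2.0, size=100)
            hits += choose_test(d) == "paired_t"
        assert hits >= 90

    def test_skewed_differences_choose_wilcoxon(self):
        hits = 0
        for seed in range(100):
            d = np.random.default_rng(seed).exponential(2.0, size=100) - 1.0
            hits += choose_test(d) == "wilcoxon"
        assert hits >= 90

    def test_fewer_than_three_diffs_rejected(self):
        with pytest.raises(ValueError):
            choose_test([1.0, 2.0])


class TestPairedAnalysis:
    def test_identical_pre_post_gives_null_effects(self, rng):
        pre = rng.normal(10, 2, size=30)
        res = paired_analysis(pre, pre.copy())
        assert res.mean_diff == 0.0
        assert res.cohens_d_pooled == 0.0
        assert res.cohens_d_diff == 0.0

    def test_wilcoxon_p_matches_enumeration_on_hand_set(self):
        diffs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -1.0])
        pre = np.zeros(6)
        res = paired_analysis(pre, diffs, force_test="wilcoxon")
        assert res.p_two_sided == pytest.approx(exact_wilcoxon_p(diffs), abs=1e-12)

    def test_wilcoxon_exact_matches_enumeration_up_to_n10(self, rng):
        """Exact signed-rank p equals full sign-flip enumeration, n <= 10."""
        for n in range(4, 11):
            for _ in range(10):
                # continuous magnitudes: no ties, exact path applies
                diffs = rng.normal(0.5, 1.0, size=n)
                diffs = diffs[diffs != 0]
                if diffs.size < 3:
                    continue
                res = paired_analysis(
                    np.zeros(diffs.size), diffs, force_test="wilcoxon"
                )
                assert res.p_two_sided == pytest.approx(
                    exact_wilcoxon_p(diffs), abs=1e-12
                )

    def test_scipy_exact_path_matches_enumeration_at_n15(self, rng):
        diffs = rng.normal(0.8, 1.0, size=15)  # continuous: tie-free
        res = paired_analysis(np.zeros(15), diffs, force_test="wilcoxon")
        assert res.p_two_sided == pytest.approx(exact_wilcoxon_p(diffs), abs=1e-10)

    def test_effect_r_uses_root_n(self, rng):
        pre = rng.normal(30, 5, size=50)
        post = pre + rng.exponential(2.0, size=50)
        res = paired_analysis(pre, post, force_test="wilcoxon")
        z = wilcoxon_z(post - pre)
        assert res.effect_r == pytest.approx(abs(z) / np.sqrt(50))
        assert 0 <= res.effect_r <= 1

    def test_parameter_recovery_of_trial_sized_effect(self):
        """The generating mean change (4.39, SD 3.85, n=146) falls inside
        the estimated 95% CI in at least 93 of 100 replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pre = rng.normal(34.67, 11.34, size=146)
            post = pre + rng.normal(4.39, 3.85, size=146)
            res = paired_analysis(pre, post)
            hits += res.ci95[0] <= 4.39 <= res.ci95[1]
        assert hits >= 93

    def test_pairwise_deletion_ignores_injected_missingness(self, rng):
        pre = rng.normal(20, 4, size=40)
        post = pre + rng.normal(1, 1, size=40)
        base = paired_analysis(pre, post)
        pre2 = np.concatenate([pre, [np.nan, 15.0]])
        post2 = np.concatenate([post, [22.0, np.nan]])
        withmiss = paired_analysis(pre2, post2)
        assert withmiss.n_used == base.n_used == 40
        assert withmiss.mean_diff == pytest.approx(base.mean_diff)
        assert withmiss.p_two_sided == pytest.approx(base.p_two_sided)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            paired_analysis([np.nan] * 5, [1, 2, 3, 4, 5])

    def test_printed_summary_consistency_d_diff(self):
        """Difference-SD Cohen's d back-computed from the published mean
        change 4.39 kg and 95% CI [3.76, 5.01] (n=146) approximates the
        published d = 1.148 within rounding."""
        assert d_from_ci(4.39, 3.76, 5.01, 146) == pytest.approx(1.148, abs=0.02)


class TestTypeIError:
    def test_null_pipeline_rejection_rate_near_alpha(self):
        """choose_test -> paired_analysis on pure-noise changes rejects
        at close to the nominal 5% level (2,000 replicates)."""
        rejections = 0
        n_rep = 2000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            pre = rng.normal(50, 10, size=30)
            post = pre + rng.normal(0, 3, size=30)
            res = paired_analysis(pre, post)
            rejections += res.p_two_sided < 0.05
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07


class TestICC:
    def test_perfect_agreement_is_one(self):
        assert icc_agreement([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        assert abs(icc_agreement(a, b)) < 0.2

    def test_constant_offset_penalized_under_absolute_agreement(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        icc = icc_agreement(a, a + 1.0)
        assert icc < 1.0
        assert icc == pytest.approx(10 / 12)  # ANOVA decomposition by hand

    def test_matches_pingouin_two_way_absolute_single(self, rng):
        import pingouin as pg

        a = rng.normal(size=40)
        b = a + rng.normal(scale=0.4, size=40)
        ours = icc_agreement(a, b)
        df = pd.DataFrame(
            {
                "t": np.tile(np.arange(40), 2),
                "r": np.repeat(["a", "b"], 40),
                "s": np.concatenate([a, b]),
            }
        )
        table = pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
        ref = float(table.loc[table["Type"].str.contains("A,1"), "ICC"].iloc[0])
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_agreement([2, 2, 2], [2, 2, 2])


class TestCohortAccounting:
    @staticmethod
    def trial_log():
        statuses = (
            ["completed"] * 146
            + ["voluntary_withdrawal"] * 39
            + ["military_conscription"] * 23
            + ["academic_status_change"] * 8
        )
        return {f"S{i:03d}": s for i, s in enumerate(statuses)}

    def test_trial_retention_and_dropout_percentages(self):
        acc = cohort_accounting(self.trial_log())
        assert acc.enrolled == 216
        assert acc.completers == 146
        assert acc.retention_pct == 67.6
        assert acc.dropout_pct["voluntary_withdrawal"] == 18.1
        assert acc.dropout_pct["military_conscription"] == 10.6
        assert acc.dropout_pct["academic_status_change"] == 3.7

    def test_zero_dropouts_is_full_retention(self):
        acc = cohort_accounting({"a": "completed", "b": "completed"})
        assert acc.retention_pct == 100.0
        assert acc.dropouts == {}

    def test_adherence_percent_of_prescription(self):
        log = self.trial_log()
        sessions = {sid: 42.3 for sid, s in log.items() if s == "completed"}
        acc = cohort_accounting(log, sessions_completed=sessions)
        assert acc.adherence_mean_sessions == 42.3
        assert acc.adherence_pct_of_prescribed == 88.1

    def test_missing_status_rejected(self):
        with pytest.raises(ValueError):
            cohort_accounting({"a": "completed", "b": None})


def test_summarize_outcomes_shape(rng):
    rows = []
    for outcome in ("a", "b"):
        pre = rng.normal(10, 2, size=25)
        post = pre + rng.normal(1, 1, size=25)
        for i, (x, y) in enumerate(zip(pre, post)):
            rows.append({"subject_id": i, "outcome": outcome, "pre": x, "post": y})
    out = summarize_outcomes(pd.DataFrame(rows))
    assert list(out["outcome"]) == ["a", "b"]
    assert {"p", "test", "cohens_d_diff", "pre_median"} <= set(out.columns)
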