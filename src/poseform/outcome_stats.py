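"""Pre/post trial statistics: normality-gated paired tests, effect sizes,
rater agreement, and cohort attrition/adherence accounting.

The analysis pipeline mirrors a standard single-arm pre/post design:
Shapiro-Wilk on the paired differences decides between a paired t-test
(normal) and a Wilcoxon signed-rank test (non-normal), two-tailed at
alpha = 0.05.  Effect sizes are reported as Cohen's d in two variants —
pooled-SD ``mean_diff / sqrt((sd_pre^2 + sd_post^2) / 2)`` and
difference-SD ``mean_diff / sd(diffs)`` — and, on the Wilcoxon path, as
``r = |Z| / sqrt(N)`` from the normal-approximation Z of the signed-rank
statistic.  Missing values are handled by pairwise deletion.

Rater agreement uses the two-way random-effects, absolute-agreement,
single-measure intraclass correlation (ICC2,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

TestName = Literal["paired_t", "wilcoxon"]

OUTCOME_NAMES = (
    "1RM squat (kg)",
    "body fat (%)",
    "skeletal muscle mass (%)",
    "FMS (score)",
    "VO2max (mL/kg/min)",
)


@dataclass
class PairedResult:
    test_used: TestName
    statistic: float
    p_two_sided: float
    n_used: int
    mean_diff: float
    ci95: tuple[float, float]
    cohens_d_pooled: float
    cohens_d_diff: float
    effect_r: float | None = None
    shapiro_p: float | None = None


def _complete_pairs(pre, post) -> tuple[np.ndarray, np.ndarray]:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be aligned, equal-length arrays")
    keep = np.isfinite(pre) & np.isfinite(post)
    return pre[keep], post[keep]


def choose_test(diffs, alpha_norm: float = 0.05) -> TestName:
    """Shapiro-Wilk gate: paired t-test if differences look normal."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 3:
        raise ValueError("need at least 3 paired differences")
    if np.ptp(d) == 0:
        # constant differences: Shapiro is undefined; a t-test is moot too
        return "wilcoxon"
    p = stats.shapiro(d).pvalue
    return "paired_t" if p >= alpha_norm else "wilcoxon"


def wilcoxon_z(diffs) -> float:
    """Normal-approximation Z of the signed-rank statistic.

    Zero differences are dropped (Wilcoxon convention); ties share
    midranks with the usual variance correction; a 0.5 continuity
    correction is applied toward the null mean.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d) & (d != 0)]
    n = d.size
    if n == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    sigma2 -= (counts**3 - counts).sum() / 48.0
    if sigma2 <= 0:
        return 0.0
    delta = w_plus - mu
    cc = min(0.5, abs(delta))
    return (delta - math.copysign(cc, delta)) / math.sqrt(sigma2)


def _signed_rank_exact(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank (statistic W+, p) by sign-flip enumeration.

    Midranks handle tied magnitudes; feasible for the small n where ties
    make scipy's exact null distribution inapplicable.
    """
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for mask in range(2**n):
        w = sum(ranks[j] for j in range(n) if mask >> j & 1)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return float(w_obs), count / 2**n


def paired_analysis(
    pre,
    post,
    alpha_norm: float = 0.05,
    force_test: TestName | None = None,
) -> PairedResult:
    """Full paired pre/post analysis of one outcome.

    Runs the normality-gated test on ``post - pre`` and reports the mean
    difference with a t-based 95% CI (df = n - 1), both Cohen's d
    variants, and the Wilcoxon effect size r when that path is taken.
    The Wilcoxon p-value is exact for small samples (full sign-flip
    enumeration with midranks up to n = 12, scipy's exact distribution
    up to n = 25 without ties), normal approximation with continuity
    correction otherwise.
    """
    pre, post = _complete_pairs(pre, post)
    n = pre.size
    if n < 3:
        raise ValueError("need at least 3 complete pre/post pairs")
    diffs = post - pre
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    sd_pre = float(pre.std(ddof=1))
    sd_post = float(post.std(ddof=1))

    se = sd_diff / math.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
    pooled = math.sqrt((sd_pre**2 + sd_post**2) / 2.0)
    d_pooled = mean_diff / pooled if pooled > 0 else 0.0
    d_diff = mean_diff / sd_diff if sd_diff > 0 else 0.0

    test = force_test or choose_test(diffs, alpha_norm)
    shapiro_p = None
    if np.ptp(diffs) > 0:
        shapiro_p = float(stats.shapiro(diffs).pvalue)

    if test == "paired_t":
        res = stats.ttest_rel(post, pre)
        statistic, p = float(res.statistic), float(res.pvalue)
        effect_r = None
    else:
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            statistic, p = 0.0, 1.0
        elif nonzero.size <= 12:
            statistic, p = _signed_rank_exact(nonzero)
        else:
            has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
            method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
            res = stats.wilcoxon(nonzero, method=method, correction=True)
            statistic, p = float(res.statistic), float(res.pvalue)
        effect_r = abs(wilcoxon_z(diffs)) / math.sqrt(n)

    return PairedResult(
        test_used=test,
        statistic=statistic,
        p_two_sided=p,
        n_used=int(n),
        mean_diff=mean_diff,
        ci95=ci,
        cohens_d_pooled=d_pooled,
        cohens_d_diff=d_diff,
        effect_r=effect_r,
        shapiro_p=shapiro_p,
    )


def d_from_ci(mean_diff: float, ci_low: float, ci_high: float, n: int) -> float:
    """Difference-SD Cohen's d back-computed from a printed mean and t-CI.

    The half-width of a t-based CI is ``t_{0.975, n-1} * sd / sqrt(n)``,
    so ``sd = half_width * sqrt(n) / t`` and ``d = mean / sd``.  Useful
    as a consistency check on published summaries.
    """
    half = (ci_high - ci_low) / 2.0
    tcrit = stats.t.ppf(0.975, df=n - 1)
    sd = half * math.sqrt(n) / tcrit
    return mean_diff / sd


def icc_agreement(ratings_a, ratings_b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA decomposition
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` with k = 2
    raters, which stays well defined for degenerate but legitimate
    inputs such as perfect agreement (both error terms zero -> 1.0).
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D arrays")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired ratings")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("ICC undefined: zero variance in both raters")
    X = np.column_stack([a, b])
    k = 2
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((X - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: no variance components")
    return float((msr - mse) / denom)


@dataclass
class CohortAccounting:
    enrolled: int
    completers: int
    dropouts: dict[str, int]
    dropout_pct: dict[str, float]
    retention_pct: float
    adherence_mean_sessions: float | None = None
    adherence_sd_sessions: float | None = None
    adherence_pct_of_prescribed: float | None = None


def cohort_accounting(
    enrollment: Mapping[str, str] | pd.DataFrame,
    sessions_completed: Mapping[str, float] | None = None,
    prescribed_sessions: int = 48,
) -> CohortAccounting:
    """Attrition and adherence arithmetic from an enrollment log.

    ``enrollment`` maps subject id to terminal status (``completed`` or
    a dropout category), or is a DataFrame with ``subject_id`` and
    ``status`` columns.  Percentages are reported to 1 decimal;
    adherence is summarized over completers as mean +/- SD sessions and
    percent of the prescription.
    """
    if isinstance(enrollment, pd.DataFrame):
        if enrollment["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids in enrollment log")
        statuses = dict(zip(enrollment["subject_id"], enrollment["status"]))
    else:
        statuses = dict(enrollment)
    if any(s is None or (isinstance(s, float) and math.isnan(s)) for s in statuses.values()):
        raise ValueError("every subject needs a terminal status")
    enrolled = len(statuses)
    if enrolled == 0:
        raise ValueError("empty enrollment log")
    completer_ids = [sid for sid, s in statuses.items() if s == "completed"]
    completers = len(completer_ids)
    dropouts: dict[str, int] = {}
    for s in statuses.values():
        if s != "completed":
            dropouts[s] = dropouts.get(s, 0) + 1
    acc = CohortAccounting(
        enrolled=enrolled,
        completers=completers,
        dropouts=dropouts,
        dropout_pct={k: round(100.0 * v / enrolled, 1) for k, v in dropouts.items()},
        retention_pct=round(100.0 * completers / enrolled, 1),
    )
    if sessions_completed is not None:
        done = np.array([float(sessions_completed[sid]) for sid in completer_ids])
        acc.adherence_mean_sessions = round(float(done.mean()), 1)
        acc.adherence_sd_sessions = round(float(done.std(ddof=1)), 1)
        acc.adherence_pct_of_prescribed = round(
            100.0 * float(done.mean()) / prescribed_sessions, 1
        )
    return acc


def summarize_outcomes(
    table: pd.DataFrame,
    alpha_norm: float = 0.05,
) -> pd.DataFrame:
    """Tidy per-outcome summary of a paired cohort table.

    ``table`` holds columns ``subject_id``, ``outcome``, ``pre``,
    ``post``.  Returns one row per outcome with medians [IQR], the
    chosen test, p-value, effect sizes and n after pairwise deletion.
    """
    rows = []
    for outcome, grp in table.groupby("outcome", sort=False):
        pre, post = _complete_pairs(grp["pre"], grp["post"])
        res = paired_analysis(pre, post, alpha_norm=alpha_norm)
        q = lambda x, p: float(np.percentile(x, p))  # noqa: E731
        rows.append(
            {
                "outcome": outcome,
                "n": res.n_used,
                "pre_median": q(pre, 50),
                "pre_iqr_low": q(pre, 25),
                "pre_iqr_high": q(pre, 75),
                "post_median": q(post, 50),
                "post_iqr_low": q(post, 25),
                "post_iqr_high": q(post, 75),
                "pre_mean": float(pre.mean()),
                "pre_sd": float(pre.std(ddof=1)),
                "post_mean": float(post.mean()),
                "post_sd": float(post.std(ddof=1)),
                "mean_diff": res.mean_diff,
                "ci95_low": res.ci95[0],
                "ci95_high": res.ci95[1],
                "test": res.test_used,
                "statistic": res.statistic,
                "p": res.p_two_sided,
                "cohens_d_pooled": res.cohens_d_pooled,
                "cohens_d_diff": res.cohens_d_diff,
                "effect_r": res.effect_r,
            }
        )
    return pd.DataFrame(rows)
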