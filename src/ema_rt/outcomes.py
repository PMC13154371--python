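"""Symptom-change outcomes: change scores, responder labels, paired tests.

Change is the simple difference Δ = post − pre on each scale, so
improvement is negative.  Responders are participants whose GDS-15 change
meets the minimal-detectable-change (MDC) criterion Δ ≤ −3.81, the change
magnitude with only a 5% probability of arising from measurement error on
that scale (meta-analytically derived constant).

Pre/post comparisons use a Shapiro–Wilk gate on the differences: normal
differences get a paired t test with Cohen's d = mean(diff)/SD(diff);
non-normal differences get a Wilcoxon signed-rank test with the
matched-pairs rank-biserial correlation (W⁻ − W⁺)/(W⁻ + W⁺), zero
differences dropped before ranking.  All tests are one-tailed in the
a-priori direction of improvement (post < pre); effect sizes are signed so
that improvement is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MDC_GDS15 = -3.81
SCALES = ("gds15", "cesdr", "phq9", "bai")


@dataclass(frozen=True)
class PairedTestResult:
    scale: str
    test: str                     # "t" | "wilcoxon"
    statistic: float
    p_one_tailed: float
    effect_size_name: str         # "cohen_d" | "rank_biserial"
    effect_size: float
    mean_diff: float
    sd_diff: float
    se_diff: float
    shapiro_p: float
    degenerate: bool = False


def change_scores(scales: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Δ = post − pre per subject and scale.

    Subjects missing either timepoint are excluded and listed in the audit.
    """
    pre = scales[scales["timepoint"] == "pre"].set_index("subject_id")
    post = scales[scales["timepoint"] == "post"].set_index("subject_id")
    common = pre.index.intersection(post.index)
    excluded = sorted(set(pre.index).symmetric_difference(post.index))
    rows = {"subject_id": list(common)}
    for s in SCALES:
        rows[f"d_{s}"] = (post.loc[common, s] - pre.loc[common, s]).to_numpy()
    return pd.DataFrame(rows), {"excluded_subjects": excluded}


def classify_responder(changes: pd.DataFrame,
                       threshold: float = MDC_GDS15) -> pd.DataFrame:
    """Responder iff d_gds15 ≤ threshold (the boundary value counts)."""
    out = changes[["subject_id"]].copy()
    out["is_responder"] = (changes["d_gds15"] <= threshold).astype(int)
    return out


def cohen_d_from_summary(mean_diff: float, sd_diff: float) -> float:
    """Paired Cohen's d from a printed change summary."""
    return mean_diff / sd_diff


def se_from_summary(sd_diff: float, n: int) -> float:
    """Standard error of the mean change from its SD and sample size."""
    return sd_diff / np.sqrt(n)


def _rank_biserial(diff: np.ndarray) -> tuple[float, float, float]:
    """Matched-pairs rank-biserial on nonzero diffs; improvement positive.

    Returns (r_rb, W_plus, W_minus) with W± the signed-rank sums;
    r = (W⁻ − W⁺) / (W⁻ + W⁺) so that mostly-negative differences
    (post < pre) give r near +1.
    """
    nz = diff[diff != 0]
    if nz.size == 0:
        return np.nan, 0.0, 0.0
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    return (w_minus - w_plus) / (w_minus + w_plus), w_plus, w_minus


def paired_test(pre, post, scale: str = "",
                alpha_normality: float = 0.05) -> PairedTestResult:
    """Shapiro-gated one-tailed paired comparison of pre vs post scores."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = pre.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = post - pre
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    se_diff = float(sd_diff / np.sqrt(n))

    if np.all(diff == 0):
        return PairedTestResult(
            scale=scale, test="wilcoxon", statistic=np.nan, p_one_tailed=1.0,
            effect_size_name="rank_biserial", effect_size=np.nan,
            mean_diff=0.0, sd_diff=0.0, se_diff=0.0, shapiro_p=np.nan,
            degenerate=True)

    shapiro_p = float(stats.shapiro(diff).pvalue)
    if shapiro_p >= alpha_normality:
        t_res = stats.ttest_rel(post, pre, alternative="less")
        d = cohen_d_from_summary(mean_diff, sd_diff)
        return PairedTestResult(
            scale=scale, test="t", statistic=float(t_res.statistic),
            p_one_tailed=float(t_res.pvalue), effect_size_name="cohen_d",
            effect_size=-d,  # improvement (negative diff) reported positive
            mean_diff=mean_diff, sd_diff=sd_diff, se_diff=se_diff,
            shapiro_p=shapiro_p)

    rb, w_plus, w_minus = _rank_biserial(diff)
    w_res = stats.wilcoxon(diff, alternative="less", zero_method="wilcox",
                           method="auto")
    return PairedTestResult(
        scale=scale, test="wilcoxon", statistic=float(max(w_plus, w_minus)),
        p_one_tailed=float(w_res.pvalue), effect_size_name="rank_biserial",
        effect_size=float(rb), mean_diff=mean_diff, sd_diff=sd_diff,
        se_diff=se_diff, shapiro_p=shapiro_p)


def paired_test_suite(scales: pd.DataFrame,
                      alpha_normality: float = 0.05) -> list[PairedTestResult]:
    """Run the gated paired test on every scale of a pre/post battery."""
    pre = scales[scales["timepoint"] == "pre"].set_index("subject_id")
    post = scales[scales["timepoint"] == "post"].set_index("subject_id")
    common = pre.index.intersection(post.index)
    return [paired_test(pre.loc[common, s], post.loc[common, s], scale=s,
                        alpha_normality=alpha_normality)
            for s in SCALES]
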