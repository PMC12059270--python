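"""Screening stable features for association with FIGO stage group.

Pipeline (applied to the analysis sequence, default S2): restrict to stable
features; per feature a normality-routed two-group test (Shapiro-Wilk on each
group; Welch t-test if both normal, Mann-Whitney U otherwise); survivors
(p < 0.05) are gated on inter-observer agreement ICC(2,1) > 0.75 computed
between the primary features and features re-extracted from perturbed masks
(the second-reader emulation); survivors get a ROC AUC with high stage as the
positive class. No multiple-testing correction is applied (reported as a
caveat in the run report).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StagingRecord",
    "group_compare",
    "icc_two_rater",
    "roc_auc",
    "staging_screen",
]

P_THRESHOLD = 0.05
ICC_THRESHOLD = 0.75


def group_compare(values, labels, alpha_normality: float = 0.05,
                  force_test: str | None = None):
    """Two-sided two-group comparison with a normality-routed test choice.

    Shapiro-Wilk per group at ``alpha_normality``; if both groups are
    compatible with normality a Welch t-test is used, otherwise a
    Mann-Whitney U test (exact when min group size <= 8 and there are no
    ties). ``force_test`` ("t_test" / "mann_whitney") bypasses the routing.
    Returns (p_value, test_used).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in ("low", "high")]
    if any(len(g) < 3 for g in groups):
        raise ValueError("need >= 3 observations per group")
    a, b = groups
    if np.ptp(values) == 0:
        return 1.0, "degenerate_constant"
    if force_test is None:
        normal = []
        for g in groups:
            if np.ptp(g) == 0:
                normal.append(False)
                continue
            normal.append(stats.shapiro(g).pvalue > alpha_normality)
        use_t = all(normal)
    else:
        if force_test not in ("t_test", "mann_whitney"):
            raise ValueError("force_test must be 't_test' or 'mann_whitney'")
        use_t = force_test == "t_test"
    if use_t:
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue), "t_test"
    ties = len(np.unique(values)) < len(values)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), "mann_whitney"


def icc_two_rater(ratings_a, ratings_b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Variance components come from the two-way ANOVA decomposition over
    n subjects x 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Zero between-subject variance makes the ICC degenerate (NaN).
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1D rating vectors required")
    n = a.size
    if n < 3:
        raise ValueError("need n >= 3 subjects")
    k = 2
    x = np.column_stack([a, b])
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 0 or denom == 0:
        return np.nan
    return float((msr - mse) / denom)


def roc_auc(scores, labels) -> float:
    """AUC = P(score_high > score_low) + 0.5 P(tie), high stage positive.

    Computed through the rank-sum (Mann-Whitney U) identity; the direction is
    fixed (no flipping), so AUC < 0.5 means the feature is lower in the high
    stage group.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == "high"]
    neg = scores[labels == "low"]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _group_summary(values: np.ndarray, test_used: str) -> str:
    """Group descriptive: mean +/- SD when the t-test route was taken,
    median (25th-75th percentile) otherwise."""
    if values.size == 0:
        return ""
    if test_used == "t_test":
        return f"{values.mean():.4g} ± {values.std(ddof=1):.4g}"
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return f"{q50:.4g} ({q25:.4g}, {q75:.4g})"


@dataclass(frozen=True)
class StagingRecord:
    """Per-feature stage-association result for one (map, ROI mode)."""

    feature_id: str
    family: str
    map_label: str
    roi_mode: str
    low_summary: str
    high_summary: str
    p_value: float
    test_used: str
    icc: float
    auc: float
    selected: bool


def staging_screen(
    features: pd.DataFrame,
    stable_set: pd.DataFrame,
    rater_b_features: pd.DataFrame | None,
    labels: pd.DataFrame,
) -> pd.DataFrame:
    """Screen stable features of one sequence for stage association.

    Parameters
    ----------
    features : tidy feature table (subject_id, map, roi_mode, feature_id,
        value) restricted to the analysis sequence.
    stable_set : stability records (columns map, roi_mode, feature_id,
        stable); only rows with stable=True are screened.
    rater_b_features : same layout as ``features``, extracted from the
        perturbed (second-reader) masks; if None the ICC stage is skipped
        with a warning column and selection is undefined (NaN icc, selected
        False).
    labels : DataFrame (subject_id, stage) with stage in {low, high}.

    Returns a DataFrame of StagingRecord rows. Gates short-circuit: ICC is
    only computed for p < 0.05 survivors, AUC for ICC survivors (NaN
    otherwise). No multiple-testing correction (reported as-is).
    """
    stable = stable_set[stable_set["stable"]] if "stable" in stable_set else stable_set
    lab = labels.set_index("subject_id")["stage"]
    rows = []
    for _, srow in stable.iterrows():
        key = (srow["map"], srow["roi_mode"], srow["feature_id"])
        sub = features[
            (features["map"] == key[0])
            & (features["roi_mode"] == key[1])
            & (features["feature_id"] == key[2])
        ]
        if sub.empty:
            continue
        sub = sub.set_index("subject_id")["value"]
        common = sub.index.intersection(lab.index)
        vals = sub.loc[common].to_numpy()
        labs = lab.loc[common].to_numpy()
        if min((labs == "low").sum(), (labs == "high").sum()) < 3:
            p, test_used = np.nan, "insufficient_n"
        else:
            p, test_used = group_compare(vals, labs)
        summaries = {
            g: _group_summary(vals[labs == g], test_used) for g in ("low", "high")
        }
        icc_val = np.nan
        auc_val = np.nan
        if p < P_THRESHOLD:
            if rater_b_features is not None:
                sub_b = rater_b_features[
                    (rater_b_features["map"] == key[0])
                    & (rater_b_features["roi_mode"] == key[1])
                    & (rater_b_features["feature_id"] == key[2])
                ].set_index("subject_id")["value"]
                paired = common.intersection(sub_b.index)
                if len(paired) >= 3:
                    icc_val = icc_two_rater(
                        sub.loc[paired].to_numpy(), sub_b.loc[paired].to_numpy()
                    )
            if np.isfinite(icc_val) and icc_val > ICC_THRESHOLD:
                auc_val = roc_auc(vals, labs)
        selected = bool(
            p < P_THRESHOLD and np.isfinite(icc_val) and icc_val > ICC_THRESHOLD
        )
        rows.append(
            {
                "feature_id": key[2],
                "family": key[2].split("_")[0],
                "map": key[0],
                "roi_mode": key[1],
                "low_summary": summaries["low"],
                "high_summary": summaries["high"],
                "p_value": p,
                "test_used": test_used,
                "icc": icc_val,
                "auc": auc_val,
                "selected": selected,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "family", "map", "roi_mode", "low_summary",
            "high_summary", "p_value", "test_used", "icc", "auc", "selected",
        ],
    )
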