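"""Feature stability across SMS accelerations: CCC, COV, categories, summaries.

For every (feature, map, ROI mode) the concordance correlation coefficient
(Lin) is computed across subjects between the reference sequence S1 and each
accelerated sequence (S1-S2, S1-S3), and the coefficient of variation is
computed per subject across the three sequences and then averaged over
subjects. A feature is stable when both CCCs exceed 0.9 and the mean COV is
at most 0.1.

CCC uses population (1/n) moments — Lin's original estimator:
    CCC = 2 rho sx sy / (sx^2 + sy^2 + (mx - my)^2)

COV uses the sample (n-1) standard deviation over the three repeated
acquisitions divided by the absolute mean; a near-zero mean makes it
undefined (flagged and excluded from averages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StabilityRecord",
    "ccc",
    "cov",
    "categorize",
    "stability_table",
    "summarize",
]

CCC_STABLE_THRESHOLD = 0.9
COV_STABLE_THRESHOLD = 0.1


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population moments.

    Conventions for degenerate input: two identical constant vectors have
    perfect concordance (1.0); if exactly one vector is constant, concordance
    is 0 (no covariation can be established).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n)
    if vx == 0 and vy == 0:
        return 1.0 if mx == my else 0.0
    if vx == 0 or vy == 0:
        return 0.0
    sxy = ((x - mx) * (y - my)).mean()
    return float(2.0 * sxy / (vx + vy + (mx - my) ** 2))


def cov(values, eps_scale: float = 1e-12) -> float:
    """Coefficient of variation of repeated measurements: sample SD / |mean|.

    Returns NaN (undefined) when |mean| < eps_scale * max|values| — a
    ratio-scale dispersion is meaningless about a zero mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    mean = v.mean()
    scale = np.max(np.abs(v))
    if scale == 0:
        return 0.0  # all-zero: no variation at all
    if abs(mean) < eps_scale * scale:
        return np.nan
    return float(v.std(ddof=1) / abs(mean))


def categorize(value: float, metric: str) -> str:
    """Four-tier category for a CCC or COV value.

    CCC: excellent > 0.9, good (0.75, 0.9], moderate (0.5, 0.75], poor <= 0.5.
    COV: excellent < 0.05, good [0.05, 0.1], moderate (0.1, 0.2], poor > 0.2.
    The half-open boundaries keep the stable rule (CCC > 0.9, COV <= 0.1)
    aligned with the good/excellent tiers.
    """
    if not np.isfinite(value):
        return "undefined"
    if metric == "ccc":
        if value > 0.9:
            return "excellent"
        if value > 0.75:
            return "good"
        if value > 0.5:
            return "moderate"
        return "poor"
    if metric == "cov":
        if value < 0.05:
            return "excellent"
        if value <= 0.1:
            return "good"
        if value <= 0.2:
            return "moderate"
        return "poor"
    raise ValueError("metric must be 'ccc' or 'cov'")


@dataclass(frozen=True)
class StabilityRecord:
    """Per-(feature, map, ROI mode) stability summary across sequences."""

    feature_id: str
    map_label: str
    roi_mode: str
    ccc_s1s2: float
    ccc_s1s3: float
    cov: float
    ccc_category: str
    cov_category: str
    stable: bool
    n_subjects: int


def stability_table(
    features: pd.DataFrame,
    stable_rule: str = "both",
) -> pd.DataFrame:
    """Stability records for every (feature, map, roi_mode) in a feature table.

    ``features`` is the tidy long table (subject_id, sequence, map, roi_mode,
    feature_id, value) covering sequences S1-S3. Subjects missing any of the
    three sequences are dropped per record. ``stable_rule`` is ``"both"``
    (conservative: CCC > 0.9 in S1-S2 AND S1-S3) or ``"s1s2"``.

    Returns a DataFrame with one row per record; the categorized CCC is the
    minimum of the two pairwise CCCs under the "both" rule, the S1-S2 CCC
    otherwise.
    """
    if stable_rule not in ("both", "s1s2"):
        raise ValueError("stable_rule must be 'both' or 's1s2'")
    needed = {"subject_id", "sequence", "map", "roi_mode", "feature_id", "value"}
    if not needed.issubset(features.columns):
        raise ValueError(f"feature table must have columns {sorted(needed)}")

    wide = features.pivot_table(
        index=["map", "roi_mode", "feature_id", "subject_id"],
        columns="sequence", values="value", aggfunc="first",
    )
    if not {"S1", "S2", "S3"}.issubset(wide.columns):
        return pd.DataFrame()
    wide = wide[["S1", "S2", "S3"]].dropna()  # drop subjects missing a sequence

    # per-subject COV across the three sequences (sample SD / |mean|)
    x = wide.to_numpy(dtype=float)
    row_mean = x.mean(axis=1)
    row_sd = x.std(axis=1, ddof=1)
    row_scale = np.abs(x).max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        row_cov = row_sd / np.abs(row_mean)
    row_cov = np.where(row_scale == 0, 0.0,
                       np.where(np.abs(row_mean) < 1e-12 * row_scale, np.nan, row_cov))
    aux = pd.DataFrame(
        {
            "s1": x[:, 0], "s2": x[:, 1], "s3": x[:, 2],
            "s1s1": x[:, 0] ** 2, "s2s2": x[:, 1] ** 2, "s3s3": x[:, 2] ** 2,
            "s1s2": x[:, 0] * x[:, 1], "s1s3": x[:, 0] * x[:, 2],
            "cov": row_cov,
        },
        index=wide.index,
    )
    g = aux.groupby(level=["map", "roi_mode", "feature_id"], sort=True)
    n = g.size()
    m = g.mean()  # NaN-aware for the cov column
    keep = n >= 3
    m, n = m[keep], n[keep]

    v1 = m["s1s1"] - m["s1"] ** 2  # population variances
    v2 = m["s2s2"] - m["s2"] ** 2
    v3 = m["s3s3"] - m["s3"] ** 2
    c12_num = 2.0 * (m["s1s2"] - m["s1"] * m["s2"])
    c13_num = 2.0 * (m["s1s3"] - m["s1"] * m["s3"])

    def _ccc_vec(num, va, vb, ma, mb):
        denom = va + vb + (ma - mb) ** 2
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
        # identical constants -> 1; one-sided constant -> 0
        both_const = (va == 0) & (vb == 0)
        out = np.where(both_const & (ma == mb), 1.0, out)
        out = np.where(both_const & (ma != mb), 0.0, out)
        out = np.where(~both_const & ((va == 0) | (vb == 0)), 0.0, out)
        return out

    c12 = _ccc_vec(c12_num, v1, v2, m["s1"], m["s2"])
    c13 = _ccc_vec(c13_num, v1, v3, m["s1"], m["s3"])
    mean_cov = m["cov"].to_numpy()

    ccc_for_rule = np.minimum(c12, c13) if stable_rule == "both" else c12
    stable = (
        np.isfinite(mean_cov)
        & (ccc_for_rule > CCC_STABLE_THRESHOLD)
        & (mean_cov <= COV_STABLE_THRESHOLD)
    )
    idx = m.index
    return pd.DataFrame(
        {
            "feature_id": idx.get_level_values("feature_id"),
            "map": idx.get_level_values("map"),
            "roi_mode": idx.get_level_values("roi_mode"),
            "ccc_s1s2": c12,
            "ccc_s1s3": c13,
            "cov": mean_cov,
            "ccc_category": [categorize(v, "ccc") for v in ccc_for_rule],
            "cov_category": [categorize(v, "cov") for v in mean_cov],
            "stable": stable,
            "n_subjects": n.to_numpy(),
        }
    ).reset_index(drop=True)


def summarize(records: pd.DataFrame) -> dict:
    """Category-proportion and stable-proportion tables from stability records.

    Returns a dict of DataFrames: ``category_proportions`` per (roi_mode,
    metric) over all features; ``per_map_category_proportions`` per (map,
    roi_mode, metric); ``stable_proportions`` per (map, roi_mode) plus
    overall rows. All proportion vectors sum to 1 (up to 1e-12).
    """
    if records.empty:
        raise ValueError("no stability records to summarize")
    cats = ["excellent", "good", "moderate", "poor", "undefined"]

    def cat_props(df, col):
        p = df[col].value_counts(normalize=True)
        return {c: float(p.get(c, 0.0)) for c in cats}

    rows = []
    for mode, grp in records.groupby("roi_mode"):
        for metric, col in (("ccc", "ccc_category"), ("cov", "cov_category")):
            rows.append({"roi_mode": mode, "metric": metric,
                         "n_features": len(grp), **cat_props(grp, col)})
    category_proportions = pd.DataFrame(rows)

    rows = []
    for (map_label, mode), grp in records.groupby(["map", "roi_mode"]):
        for metric, col in (("ccc", "ccc_category"), ("cov", "cov_category")):
            rows.append({"map": map_label, "roi_mode": mode, "metric": metric,
                         "n_features": len(grp), **cat_props(grp, col)})
    per_map = pd.DataFrame(rows)

    rows = []
    for (map_label, mode), grp in records.groupby(["map", "roi_mode"]):
        rows.append({"map": map_label, "roi_mode": mode,
                     "n_features": len(grp),
                     "stable_proportion": float(grp["stable"].mean())})
    for mode, grp in records.groupby("roi_mode"):
        rows.append({"map": "all", "roi_mode": mode, "n_features": len(grp),
                     "stable_proportion": float(grp["stable"].mean())})
    stable_proportions = pd.DataFrame(rows)

    return {
        "category_proportions": category_proportions,
        "per_map_category_proportions": per_map,
        "stable_proportions": stable_proportions,
    }
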