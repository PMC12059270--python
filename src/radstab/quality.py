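"""Objective image quality: SNR/CNR on the b = 800 s/mm^2 volume.

SNR = SI_tumor / SD_tumor and CNR = (SI_tumor - SI_muscle) /
sqrt(SD_tumor^2 + SD_muscle^2), where SI/SD are the mean and standard
deviation within the ROI drawn on the slice with the largest tumor extent.
Note the convention: SD is the within-ROI standard deviation of the lesion
itself (which mixes tissue heterogeneity with noise), not a background-air
noise estimate.

The triplicate manual measurement of the ROI is emulated by jittered copies
of the mask (integer translations); sequence comparison uses the Friedman
test with Dunn-Bonferroni post hoc pairwise z-tests computed from rank sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = ["RoiStats", "snr", "cnr", "measure_roi_stats", "compare_quality"]


@dataclass(frozen=True)
class RoiStats:
    """Mean signal intensity and standard deviation within one ROI."""

    si: float
    sd: float
    n_voxels: int
    label: str = "tumor"

    def __post_init__(self):
        if self.sd < 0 or self.n_voxels < 1:
            raise ValueError("invalid ROI statistics")


def snr(tumor: RoiStats) -> float:
    """Signal-to-noise ratio SI/SD of the tumor ROI."""
    if tumor.sd <= 0:
        raise ZeroDivisionError("SNR undefined for zero within-ROI SD")
    return tumor.si / tumor.sd


def cnr(tumor: RoiStats, muscle: RoiStats) -> float:
    """Contrast-to-noise ratio between tumor and reference muscle ROI."""
    denom = np.hypot(tumor.sd, muscle.sd)
    if denom == 0:
        raise ZeroDivisionError("CNR undefined: both ROI SDs are zero")
    return (tumor.si - muscle.si) / denom


def measure_roi_stats(
    volume: np.ndarray,
    roi_mask: np.ndarray,
    repeats: int = 3,
    jitter: int = 0,
    seed: int = 0,
    label: str = "tumor",
) -> RoiStats:
    """Triplicate ROI measurement, averaged.

    Each repeat translates the mask by a random integer offset drawn
    uniformly from [-jitter, jitter] per in-plane axis (jitter = 0 reproduces
    a single exact measurement); SI and SD are averaged over repeats.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    sis, sds, ns = [], [], []
    for _ in range(repeats):
        if jitter > 0:
            shift = [int(s) for s in rng.integers(-jitter, jitter + 1, size=2)] + [0]
            m = ndimage.shift(roi_mask.astype(np.uint8), shift, order=0) > 0
            if not m.any():
                raise ValueError("ROI empty after jitter")
        else:
            m = roi_mask
        vals = volume[m]
        sis.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        ns.append(int(vals.size))
    return RoiStats(si=float(np.mean(sis)), sd=float(np.mean(sds)),
                    n_voxels=int(np.round(np.mean(ns))), label=label)


def _dunn_bonferroni(ranks: np.ndarray, pairs) -> dict:
    """Dunn pairwise z-tests on mean within-subject ranks, Bonferroni-adjusted.

    ``ranks`` is (n_subjects, k) of within-subject ranks (average ranks for
    ties). The standard error of a mean-rank difference is
    sqrt(k (k + 1) / (6 n)); the Bonferroni factor is the number of pairs.
    """
    n, k = ranks.shape
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    out = {}
    m = len(pairs)
    for a, b_ in pairs:
        z = (mean_ranks[a] - mean_ranks[b_]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b_)] = {"z": float(z), "p_adjusted": float(min(1.0, m * p))}
    return out


def compare_quality(table: pd.DataFrame, metric: str = "snr") -> dict:
    """Friedman test + Dunn-Bonferroni post hoc across S1/S2/S3.

    ``table`` is long format with columns (subject_id, sequence, <metric>)
    or wide with columns S1, S2, S3. Subjects with missing cells are dropped
    (logged in the result). Returns the Friedman statistic/p and adjusted
    pairwise p-values for (S1,S2), (S2,S3), (S1,S3).
    """
    if {"S1", "S2", "S3"}.issubset(table.columns):
        wide = table[["S1", "S2", "S3"]].copy()
    else:
        wide = table.pivot(index="subject_id", columns="sequence", values=metric)
        wide = wide[["S1", "S2", "S3"]]
    n_total = len(wide)
    wide = wide.dropna()
    dropped = n_total - len(wide)
    if len(wide) < 3:
        raise ValueError("need >= 3 complete subjects")
    x = wide.to_numpy(dtype=float)

    if np.allclose(x, x[:, [0]]):
        # identical conditions: no evidence of any difference
        friedman_stat, friedman_p = 0.0, 1.0
    else:
        friedman_stat, friedman_p = stats.friedmanchisquare(x[:, 0], x[:, 1], x[:, 2])
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    labels = ("S1", "S2", "S3")
    pair_idx = [(0, 1), (1, 2), (0, 2)]
    dunn = _dunn_bonferroni(ranks, pair_idx)
    return {
        "friedman_statistic": float(friedman_stat),
        "friedman_p": float(friedman_p),
        "n_subjects": int(len(wide)),
        "n_dropped": int(dropped),
        "pairwise": {
            (labels[a], labels[b]): v for (a, b), v in dunn.items()
        },
    }
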