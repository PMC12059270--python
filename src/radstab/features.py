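"""Radiomics feature extraction: 93 features per parametric map per ROI mode.

Families and counts: first-order (18), GLCM (24), GLRLM (16), GLSZM (16),
NGTDM (5), GLDM (14). The ROI is either the full tumor volume (3D mode,
13 texture directions / 26-connectivity) or the single axial slice with the
largest in-slice tumor area (2D mode, 4 in-plane directions /
8-connectivity). Intensities are discretized per map within the ROI
(fixed bin count by default — the six maps live on heterogeneous physical
scales, so a single bin width would be inappropriate).

Degenerate features (undefined on the given ROI, e.g. any texture feature of
a single-voxel region) are returned as 0 with an explicit flag, never as a
silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _texture as tx
from .fitting import MAP_NAMES, ParametricMapSet

__all__ = [
    "RoiMask",
    "DiscretizationConfig",
    "FeatureVector",
    "FAMILY_COUNTS",
    "feature_manifest",
    "select_2d_slice",
    "discretize",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "extract_features",
    "feature_frame",
]

FAMILY_COUNTS = {
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
    "gldm": 14,
}

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def feature_manifest() -> tuple[str, ...]:
    """The 93 stable feature ids, as ``family_Name``."""
    names = [f"firstorder_{n}" for n in FIRSTORDER_NAMES]
    names += [f"glcm_{n}" for n in tx.GLCM_NAMES]
    names += [f"glrlm_{n}" for n in tx.GLRLM_NAMES]
    names += [f"glszm_{n}" for n in tx.GLSZM_NAMES]
    names += [f"ngtdm_{n}" for n in tx.NGTDM_NAMES]
    names += [f"gldm_{n}" for n in tx.GLDM_NAMES]
    return tuple(names)


@dataclass(frozen=True)
class RoiMask:
    """Binary ROI aligned to the map grid, in 2D or 3D mode.

    In 2D mode all true voxels lie on ``slice_index`` — the axial slice
    maximizing the in-slice ROI area (ties broken by the lowest index).
    """

    mask: np.ndarray
    mode: str = "3D"
    slice_index: int | None = None

    def __post_init__(self):
        if self.mode not in ("2D", "3D"):
            raise ValueError("mode must be '2D' or '3D'")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        if self.mode == "2D":
            if self.slice_index is None:
                raise ValueError("2D mode requires slice_index")
            off_slice = self.mask.copy()
            off_slice[:, :, self.slice_index] = False
            if off_slice.any():
                raise ValueError("2D mask has voxels off the selected slice")


def select_2d_slice(mask_3d: np.ndarray) -> RoiMask:
    """2D ROI: the axial (z) slice with maximal tumor area."""
    mask_3d = np.asarray(mask_3d, dtype=bool)
    if not mask_3d.any():
        raise ValueError("mask is empty")
    areas = mask_3d.sum(axis=(0, 1))
    idx = int(np.argmax(areas))  # argmax returns the first maximal slice
    out = np.zeros_like(mask_3d)
    out[:, :, idx] = mask_3d[:, :, idx]
    return RoiMask(mask=out, mode="2D", slice_index=idx)


@dataclass(frozen=True)
class DiscretizationConfig:
    """Gray-level discretization applied to masked voxels of one map."""

    method: str = "fixed_bin_count"
    n_bins: int = 32
    bin_width: float | None = None

    def __post_init__(self):
        if self.method not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError("unknown discretization method")
        if self.method == "fixed_bin_count" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.method == "fixed_bin_width" and not (self.bin_width and self.bin_width > 0):
            raise ValueError("bin_width must be > 0")


def discretize(values, config: DiscretizationConfig | None = None):
    """Map continuous values to integer gray levels 1..Ng.

    fixed_bin_count: uniform bins over [min, max]; the maximum maps to Ng;
    a constant region maps to a single level (Ng = 1). fixed_bin_width:
    levels anchored at floor(min / width).
    """
    config = config or DiscretizationConfig()
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no voxels to discretize")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    vmin, vmax = v.min(), v.max()
    if config.method == "fixed_bin_count":
        if vmax == vmin:
            return np.ones(v.shape, dtype=int), 1
        ng = config.n_bins
        lv = np.floor((v - vmin) / (vmax - vmin) * ng).astype(int) + 1
        lv = np.minimum(lv, ng)
        return lv, ng
    w = config.bin_width
    lv = np.floor(v / w).astype(int) - int(np.floor(vmin / w)) + 1
    return lv, int(lv.max())


def first_order_features(values, levels=None, voxel_volume: float = 1.0,
                         config: DiscretizationConfig | None = None) -> dict:
    """The standard 18 first-order statistics of the masked intensities.

    Entropy and Uniformity are computed on discretized levels (``levels`` if
    given, else discretized here with ``config``); percentiles use linear
    interpolation. Zero-variance Skewness/Kurtosis are degenerate (NaN here;
    mapped to 0 + flag at extraction).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    if levels is None:
        levels, _ = discretize(v, config)
    counts = np.bincount(np.asarray(levels).ravel())[1:]
    p = counts[counts > 0] / counts.sum()
    mean = float(v.mean())
    var = float(v.var())  # population variance
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else np.nan
    if var > 0:
        m = v - mean
        skew = float(np.mean(m**3) / var**1.5)
        kurt = float(np.mean(m**4) / var**2)  # Fisher-uncorrected (not excess)
    else:
        skew = np.nan
        kurt = np.nan
    energy = float((v**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }


def _as_plane(levels, mask, mode, slice_index):
    if mode == "2D":
        return levels[:, :, slice_index], mask[:, :, slice_index]
    return levels, mask


def glcm_features(levels, mask, mode: str = "3D", slice_index: int | None = None) -> dict:
    lv, m = _as_plane(levels, mask, mode, slice_index)
    return tx.glcm_features(lv, m, int(lv.max()) if m.any() else 1)


def glrlm_features(levels, mask, mode: str = "3D", slice_index: int | None = None) -> dict:
    lv, m = _as_plane(levels, mask, mode, slice_index)
    return tx.glrlm_features(lv, m, int(lv.max()) if m.any() else 1)


def glszm_features(levels, mask, mode: str = "3D", slice_index: int | None = None) -> dict:
    lv, m = _as_plane(levels, mask, mode, slice_index)
    return tx.glszm_features(lv, m, int(lv.max()) if m.any() else 1)


def ngtdm_features(levels, mask, mode: str = "3D", slice_index: int | None = None) -> dict:
    lv, m = _as_plane(levels, mask, mode, slice_index)
    return tx.ngtdm_features(lv, m, int(lv.max()) if m.any() else 1)


def gldm_features(levels, mask, mode: str = "3D", slice_index: int | None = None,
                  alpha: int = 0) -> dict:
    lv, m = _as_plane(levels, mask, mode, slice_index)
    return tx.gldm_features(lv, m, int(lv.max()) if m.any() else 1, alpha=alpha)


@dataclass(frozen=True)
class FeatureVector:
    """93 named feature values for one (subject, sequence, map, ROI mode)."""

    values: dict
    map_label: str
    roi_mode: str
    subject_id: str = ""
    sequence: str = ""
    flags: dict = field(default_factory=dict)
    missing: bool = False

    def __post_init__(self):
        if not self.missing and len(self.values) != 93:
            raise ValueError(f"expected 93 features, got {len(self.values)}")


def _extract_single(map_values, mask, mode, slice_index, voxel_volume, config):
    """93 features for one map; returns (values, flags)."""
    vals = map_values[mask]
    bbox = tuple(
        slice(int(c.min()), int(c.max()) + 1) for c in np.nonzero(mask)
    )
    m = mask[bbox]
    lv = np.zeros(m.shape, dtype=int)
    lv[m], ng = discretize(vals, config)
    if mode == "2D":
        z0 = bbox[2].start
        lv2, m2 = lv[:, :, slice_index - z0], m[:, :, slice_index - z0]
    else:
        lv2, m2 = lv, m

    out = {}
    fo = first_order_features(vals, levels=lv[m], voxel_volume=voxel_volume)
    out.update({f"firstorder_{k}": v for k, v in fo.items()})
    out.update({f"glcm_{k}": v for k, v in tx.glcm_features(lv2, m2, ng).items()})
    out.update({f"glrlm_{k}": v for k, v in tx.glrlm_features(lv2, m2, ng).items()})
    out.update({f"glszm_{k}": v for k, v in tx.glszm_features(lv2, m2, ng).items()})
    out.update({f"ngtdm_{k}": v for k, v in tx.ngtdm_features(lv2, m2, ng).items()})
    out.update({f"gldm_{k}": v for k, v in tx.gldm_features(lv2, m2, ng).items()})

    flags = {}
    for k, v in out.items():
        if not np.isfinite(v):
            out[k] = 0.0  # degenerate-by-convention, explicitly flagged
            flags[k] = True
    return out, flags


def extract_features(
    map_set: ParametricMapSet,
    roi: RoiMask,
    config: DiscretizationConfig | None = None,
    subject_id: str = "",
    sequence: str = "",
    respect_fit_mask: bool = True,
    voxel_volume: float = 1.0,
) -> dict[str, FeatureVector]:
    """Extract all 93 features from each of the six maps within the ROI.

    The effective mask intersects the ROI with the map set's fit mask; a map
    whose effective mask is empty yields a vector flagged ``missing``.
    ``voxel_volume`` (e.g. mm^3) only affects TotalEnergy.
    """
    config = config or DiscretizationConfig()
    maps = map_set.as_dict()
    out = {}
    base = roi.mask & map_set.fit_mask if respect_fit_mask else roi.mask
    for name in MAP_NAMES:
        arr = maps[name]
        eff = base & np.isfinite(arr)
        if not eff.any() or (roi.mode == "2D" and not eff[:, :, roi.slice_index].any()):
            out[name] = FeatureVector(
                values={}, map_label=name, roi_mode=roi.mode,
                subject_id=subject_id, sequence=sequence, missing=True,
            )
            continue
        values, flags = _extract_single(
            arr, eff, roi.mode, roi.slice_index, voxel_volume, config
        )
        out[name] = FeatureVector(
            values=values, map_label=name, roi_mode=roi.mode,
            subject_id=subject_id, sequence=sequence, flags=flags,
        )
    return out


def feature_frame(vectors) -> pd.DataFrame:
    """Tidy long-format feature table from FeatureVectors.

    Columns: subject_id, sequence, map, roi_mode, feature_id, value,
    degenerate_flag.
    """
    rows = []
    for fv in vectors:
        if fv.missing:
            continue
        for fid, val in fv.values.items():
            rows.append(
                {
                    "subject_id": fv.subject_id,
                    "sequence": fv.sequence,
                    "map": fv.map_label,
                    "roi_mode": fv.roi_mode,
                    "feature_id": fid,
                    "value": val,
                    "degenerate_flag": bool(fv.flags.get(fid, False)),
                }
            )
    return pd.DataFrame(rows)
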