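"""Texture-matrix construction and feature formulas (GLCM/GLRLM/GLSZM/NGTDM/GLDM).

All functions operate on an integer level array (values 1..Ng inside the ROI,
0 outside) and a boolean mask of the same shape, either 2D (single axial
slice, 4 unique in-plane directions / 8-connectivity) or 3D (13 unique
directions / 26-connectivity). Gray-level indices are 1-based and distances
are in voxels. Matrices are computed per direction where applicable,
normalized per direction, and features averaged over directions with equal
weight. Degenerate quantities are returned as NaN; the extraction layer maps
them to 0 with an explicit flag.

Definitions follow the IBSI/pyradiomics formulations; the GLDM dependence
size counts the center voxel plus its dependent neighbors.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

EPS_GUARD = 1e-6  # documented guard for undefined ratio denominators

DIRECTIONS_2D = ((1, 0), (0, 1), (1, 1), (1, -1))
DIRECTIONS_3D = tuple(
    d
    for d in (
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    )
    if d != (0, 0, 0) and d > tuple(-c for c in d)
)  # 13 unique half-space directions


def directions(ndim: int):
    if ndim == 2:
        return DIRECTIONS_2D
    if ndim == 3:
        return DIRECTIONS_3D
    raise ValueError("levels must be 2D or 3D")


def _offset_pairs(levels, mask, d):
    """Gray-level index pairs (i, j) for co-occurrences along offset d."""
    src = [slice(max(-o, 0), None) if o <= 0 else slice(None, -o) for o in d]
    dst = [slice(max(o, 0), None) if o >= 0 else slice(None, o) for o in d]
    src, dst = tuple(src), tuple(dst)
    ok = mask[src] & mask[dst]
    return levels[src][ok], levels[dst][ok]


def glcm_matrix(levels, mask, d, ng):
    """Symmetric, normalized co-occurrence matrix for one offset."""
    a, b = _offset_pairs(levels, mask, d)
    if a.size == 0:
        return None
    counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T
    return counts / counts.sum()


_GLCM_IDX_CACHE: dict = {}


def _glcm_indices(ng):
    """Cached index arrays for an ng x ng co-occurrence matrix."""
    if ng not in _GLCM_IDX_CACHE:
        i = np.arange(1, ng + 1)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        _GLCM_IDX_CACHE[ng] = (i, ii, jj, np.abs(ii - jj), ii + jj)
    return _GLCM_IDX_CACHE[ng]


def glcm_features_single(P):
    """The 24 co-occurrence features from one normalized symmetric matrix."""
    ng = P.shape[0]
    i, ii, jj, absdiff_idx, sum_idx = _glcm_indices(ng)
    px = P.sum(axis=1)  # == py by symmetry
    mu_x = float((i * px).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    # diagonal/cross-diagonal probabilities
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.bincount(sum_idx.ravel(), weights=P.ravel(), minlength=2 * ng + 1)[2:]
    k_diff = np.arange(0, ng)
    p_diff = np.bincount(absdiff_idx.ravel(), weights=P.ravel(), minlength=ng)

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum()) if p.size else 0.0

    Pp = P[P > 0]
    joint_entropy = float(-(Pp * np.log2(Pp)).sum())
    hx = ent(px)
    # information measures of correlation
    with np.errstate(divide="ignore"):
        outer = px[:, None] * px[None, :]
    nz = (P > 0) & (outer > 0)
    hxy1 = float(-(P[nz] * np.log2(outer[nz])).sum())
    onz = outer > 0
    hxy2 = float(-(outer[onz] * np.log2(outer[onz])).sum())
    if hx > 0:
        imc1 = (joint_entropy - hxy1) / hx
    else:
        imc1 = np.nan
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    diff_avg = float((k_diff * p_diff).sum())
    contrast = float((((ii - jj) ** 2) * P).sum())
    autocorr = float(((ii * jj) * P).sum())
    cluster = ii + jj - 2.0 * mu_x
    if sigma_x > 0:
        correlation = (autocorr - mu_x * mu_x) / (sigma_x * sigma_x)
    else:
        correlation = 1.0  # constant region: perfect (degenerate) correlation

    # maximal correlation coefficient
    if ng == 1:
        mcc = 1.0
    else:
        # Q(a, c) = sum_k P(a,k) P(c,k) / (px(a) py(k)); empty levels drop out
        A = np.where(px[:, None] > 0, P / np.where(px[:, None] > 0, px[:, None], 1.0), 0.0)
        B = np.where(px[None, :] > 0, P / np.where(px[None, :] > 0, px[None, :], 1.0), 0.0)
        Q = np.einsum("ak,ck->ac", A, B)
        eigs = np.sort(np.abs(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(0.0, eigs[1].real if eigs.size > 1 else 0.0)))

    absdiff = absdiff_idx
    off = absdiff > 0
    inverse_variance = float((P[off] / (absdiff[off] ** 2)).sum())

    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu_x,
        "ClusterProminence": float((cluster**4 * P).sum()),
        "ClusterShade": float((cluster**3 * P).sum()),
        "ClusterTendency": float((cluster**2 * P).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float((((k_diff - diff_avg) ** 2) * p_diff).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": joint_entropy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((P / (1.0 + absdiff**2)).sum()),
        "Idmn": float((P / (1.0 + (absdiff / ng) ** 2)).sum()),
        "Id": float((P / (1.0 + absdiff)).sum()),
        "Idn": float((P / (1.0 + absdiff / ng)).sum()),
        "InverseVariance": inverse_variance,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float((((ii - mu_x) ** 2) * P).sum()),
        "MCC": mcc,
    }


def glcm_features(levels, mask, ng):
    """Direction-averaged 24-feature GLCM set (4 directions in 2D, 13 in 3D)."""
    per_dir = []
    for d in directions(levels.ndim):
        P = glcm_matrix(levels, mask, d, ng)
        if P is not None:
            per_dir.append(glcm_features_single(P))
    if not per_dir:
        return {k: np.nan for k in GLCM_NAMES}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


def run_lengths(levels, mask, d):
    """(gray level, run length) pairs of the maximal runs along direction d."""
    shape = levels.shape
    coords = np.argwhere(mask)
    if coords.size == 0:
        return np.empty(0, int), np.empty(0, int)
    d = np.asarray(d)

    # a voxel starts a run if its predecessor along d is outside the mask or
    # carries a different level
    prev = coords - d
    prev_ok = np.zeros(len(coords), dtype=bool)
    ins = np.all((prev >= 0) & (prev < shape), axis=1)
    if ins.any():
        pin = prev[ins]
        pm = mask[tuple(pin.T)]
        same = levels[tuple(pin.T)] == levels[tuple(coords[ins].T)]
        prev_ok[ins] = pm & same
    starts = coords[~prev_ok]
    run_levels = levels[tuple(starts.T)]
    lengths = np.ones(len(starts), dtype=int)
    pos = starts.copy()
    active = np.arange(len(starts))
    while active.size:
        nxt = pos[active] + d
        ins = np.all((nxt >= 0) & (nxt < shape), axis=1)
        good = np.zeros(len(active), dtype=bool)
        if ins.any():
            nin = nxt[ins]
            ok = mask[tuple(nin.T)] & (levels[tuple(nin.T)] == run_levels[active[ins]])
            good[ins] = ok
        lengths[active[good]] += 1
        pos[active[good]] += d
        active = active[good]
    return run_levels, lengths


def glrlm_matrix(levels, mask, d, ng):
    lv, ln = run_lengths(levels, mask, d)
    if lv.size == 0:
        return None
    nr_max = int(ln.max())
    M = np.zeros((ng, nr_max))
    np.add.at(M, (lv - 1, ln - 1), 1.0)
    return M


def _rlm_style_features(M, n_voxels, prefix_short, prefix_long, names):
    """Shared emphasis/nonuniformity formulas for GLRLM-shaped matrices.

    ``M[i-1, j-1]`` counts runs (or zones, or dependencies) of gray level i
    and size j; ``n_voxels`` is the voxel count for the percentage feature.
    """
    nr = M.sum()
    if nr == 0:
        return {k: np.nan for k in names}
    i = np.arange(1, M.shape[0] + 1, dtype=float)
    j = np.arange(1, M.shape[1] + 1, dtype=float)
    pg = M.sum(axis=1)  # per gray level
    pr = M.sum(axis=0)  # per size
    p = M / nr
    ii, jj = np.meshgrid(i, j, indexing="ij")
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    pos = p[p > 0]
    out = {
        f"{prefix_short}Emphasis": float((pr / j**2).sum() / nr),
        f"{prefix_long}Emphasis": float((pr * j**2).sum() / nr),
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        names["size_nonuniformity"]: float((pr**2).sum() / nr),
        names["size_nonuniformity_norm"]: float((pr**2).sum() / nr**2),
        names["percentage"]: float(nr / n_voxels),
        "GrayLevelVariance": float((((ii - mu_i) ** 2) * p).sum()),
        names["size_variance"]: float((((jj - mu_j) ** 2) * p).sum()),
        names["entropy"]: float(-(pos * np.log2(pos)).sum()),
        "LowGrayLevelEmphasis": float((pg / i**2).sum() / nr),
        "HighGrayLevelEmphasis": float((pg * i**2).sum() / nr),
        f"{prefix_short}LowGrayLevelEmphasis": float((p / (ii**2 * jj**2)).sum()),
        f"{prefix_short}HighGrayLevelEmphasis": float((p * ii**2 / jj**2).sum()),
        f"{prefix_long}LowGrayLevelEmphasis": float((p * jj**2 / ii**2).sum()),
        f"{prefix_long}HighGrayLevelEmphasis": float((p * ii**2 * jj**2).sum()),
    }
    return out


_GLRLM_MAP = {
    "size_nonuniformity": "RunLengthNonUniformity",
    "size_nonuniformity_norm": "RunLengthNonUniformityNormalized",
    "percentage": "RunPercentage",
    "size_variance": "RunVariance",
    "entropy": "RunEntropy",
}


def glrlm_features(levels, mask, ng):
    """Direction-averaged 16-feature run-length set."""
    n_vox = int(mask.sum())
    per_dir = []
    for d in directions(levels.ndim):
        M = glrlm_matrix(levels, mask, d, ng)
        if M is None:
            continue
        f = _rlm_style_features(M, n_vox, "ShortRun", "LongRun", _GLRLM_MAP)
        f = {_glrlm_rename(k): v for k, v in f.items()}
        per_dir.append(f)
    if not per_dir:
        return {k: np.nan for k in GLRLM_NAMES}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


def _glrlm_rename(key):
    # emphasis keys come out as e.g. "ShortRunEmphasis" already; low/high gray
    # aliases need the run-specific names
    return {
        "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
        "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
    }.get(key, key)


def glszm_matrix(levels, mask, ng, connectivity=None):
    """Zone matrix: connected regions (8/26-connectivity) of equal level."""
    if connectivity is None:
        connectivity = np.ones((3,) * levels.ndim, dtype=int)
    zones = []  # (level, size)
    for g in range(1, ng + 1):
        binary = (levels == g) & mask
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=connectivity)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    if not zones:
        return None
    zl = np.array([z[0] for z in zones])
    zs = np.array([z[1] for z in zones])
    M = np.zeros((ng, int(zs.max())))
    np.add.at(M, (zl - 1, zs - 1), 1.0)
    return M


_GLSZM_MAP = {
    "size_nonuniformity": "SizeZoneNonUniformity",
    "size_nonuniformity_norm": "SizeZoneNonUniformityNormalized",
    "percentage": "ZonePercentage",
    "size_variance": "ZoneVariance",
    "entropy": "ZoneEntropy",
}


def glszm_features(levels, mask, ng):
    """16-feature size-zone set (no directions: single matrix)."""
    M = glszm_matrix(levels, mask, ng)
    if M is None:
        return {k: np.nan for k in GLSZM_NAMES}
    f = _rlm_style_features(M, int(mask.sum()), "SmallArea", "LargeArea", _GLSZM_MAP)
    f = {
        {
            "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
            "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
        }.get(k, k): v
        for k, v in f.items()
    }
    return {k: f[k] for k in GLSZM_NAMES}


def _neighbor_sums(levels, mask):
    """Sum and count of masked neighbor levels (full 8/26 neighborhood)."""
    kernel = np.ones((3,) * levels.ndim)
    kernel[(1,) * levels.ndim] = 0
    vals = np.where(mask, levels, 0).astype(float)
    nsum = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    ncnt = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    return nsum, ncnt


def ngtdm_features(levels, mask, ng):
    """Coarseness, Contrast, Busyness, Complexity, Strength.

    s_i sums |i - A_i| over valid voxels of level i, where A_i is the average
    level of the masked neighbors; voxels without masked neighbors are
    excluded.
    """
    nsum, ncnt = _neighbor_sums(levels, mask)
    valid = mask & (ncnt > 0)
    nvp = int(valid.sum())
    if nvp == 0:
        return {k: np.nan for k in NGTDM_NAMES}
    lv = levels[valid].astype(float)
    abar = nsum[valid] / ncnt[valid]
    diff = np.abs(lv - abar)
    n_i = np.bincount(levels[valid] - 1, minlength=ng).astype(float)
    s_i = np.bincount(levels[valid] - 1, weights=diff, minlength=ng)
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1, dtype=float)

    sum_ps = float((p_i * s_i).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1.0 / EPS_GUARD

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        ii_, jj_ = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float((pi_ * pj_ * (ii_ - jj_) ** 2).sum()) / (ngp * (ngp - 1))
        contrast *= float(s_i.sum()) / nvp
        denom = float(np.abs(ii_ * pi_ - jj_ * pj_).sum())
        busyness = sum_ps / denom if denom > 0 else np.nan
        si_, sj_ = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = float(
            (np.abs(ii_ - jj_) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum()
        ) / nvp
        s_sum = float(s_i.sum())
        strength = (
            float(((pi_ + pj_) * (ii_ - jj_) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def gldm_matrix(levels, mask, ng, alpha=0):
    """Dependence matrix: P[i-1, d-1] counts voxels of level i whose
    dependence size is d = 1 + (number of neighbors within alpha of i)."""
    shape = levels.shape
    dep = np.zeros(shape, dtype=int)
    for d in directions(levels.ndim):
        for sign in (1, -1):
            off = tuple(sign * o for o in d)
            src = tuple(
                slice(max(-o, 0), None) if o <= 0 else slice(None, -o) for o in off
            )
            dst = tuple(
                slice(max(o, 0), None) if o >= 0 else slice(None, o) for o in off
            )
            both = mask[src] & mask[dst]
            close = np.abs(levels[src] - levels[dst]) <= alpha
            contrib = np.zeros(mask[src].shape, dtype=int)
            contrib[both & close] = 1
            dep[src] += contrib
    if not mask.any():
        return None
    lv = levels[mask]
    dp = dep[mask] + 1  # dependence size includes the center voxel
    M = np.zeros((ng, int(dp.max())))
    np.add.at(M, (lv - 1, dp - 1), 1.0)
    return M


_GLDM_MAP = {
    "size_nonuniformity": "DependenceNonUniformity",
    "size_nonuniformity_norm": "DependenceNonUniformityNormalized",
    "percentage": "DependencePercentage",
    "size_variance": "DependenceVariance",
    "entropy": "DependenceEntropy",
}


def gldm_features(levels, mask, ng, alpha=0):
    """14-feature dependence set (the normalized GLNU and the percentage,
    both constant 1 here, are not part of the 14 and are dropped)."""
    M = gldm_matrix(levels, mask, ng, alpha=alpha)
    if M is None:
        return {k: np.nan for k in GLDM_NAMES}
    f = _rlm_style_features(M, int(mask.sum()), "SmallDependence", "LargeDependence", _GLDM_MAP)
    return {k: f[k] for k in GLDM_NAMES}


GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis", "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
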