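"""Independent brute-force texture oracles for the matrix-based families.

Everything here is written as naive explicit loops straight from the textbook
definitions (pair enumeration, line walking, flood fill, neighborhood scans),
deliberately sharing no code with the package implementation. Fine for the
tiny (4x4 and 4x4x3) arrays used in the oracle tests.
"""

from __future__ import annotations

import numpy as np

DIRS_2D = [(1, 0), (0, 1), (1, 1), (1, -1)]
DIRS_3D = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _dirs(ndim):
    return DIRS_2D if ndim == 2 else DIRS_3D


def _neighbors(shape, p, ndim):
    """All distance-1 Chebyshev neighbors of p inside the array bounds."""
    deltas = []
    rng = (-1, 0, 1)
    if ndim == 2:
        cand = [(a, b) for a in rng for b in rng if (a, b) != (0, 0)]
    else:
        cand = [
            (a, b, c) for a in rng for b in rng for c in rng if (a, b, c) != (0, 0, 0)
        ]
    for d in cand:
        q = tuple(pi + di for pi, di in zip(p, d))
        if all(0 <= qi < si for qi, si in zip(q, shape)):
            deltas.append(q)
    return deltas


def _log2(x):
    return np.log2(x)


# ---------------------------------------------------------------- GLCM ----
def brute_glcm_matrix(levels, mask, d, ng):
    C = np.zeros((ng, ng))
    for p in np.argwhere(mask):
        q = tuple(p + np.asarray(d))
        if all(0 <= qi < si for qi, si in zip(q, levels.shape)) and mask[q]:
            i, j = levels[tuple(p)], levels[q]
            C[i - 1, j - 1] += 1
            C[j - 1, i - 1] += 1
    return C / C.sum() if C.sum() else None


def brute_glcm_features(P):
    ng = P.shape[0]
    eps_free_sum = 0.0
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sig2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    sig = np.sqrt(sig2)

    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + P[i][j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + P[i][j]

    def entropy(d):
        return -sum(v * _log2(v) for v in d if v > 0)

    joint_ent = entropy(P.ravel())
    hx = entropy(px)
    hxy1 = -sum(
        P[i][j] * _log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if P[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * _log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if px[i] * px[j] > 0
    )
    da = sum(k * v for k, v in pdiff.items())
    autoc = sum((i + 1) * (j + 1) * P[i][j] for i in range(ng) for j in range(ng))

    if ng == 1:
        mcc = 1.0
    else:
        Q = np.zeros((ng, ng))
        for a in range(ng):
            for c in range(ng):
                s = 0.0
                for k in range(ng):
                    if px[a] > 0 and px[k] > 0:
                        s += P[a][k] * P[c][k] / (px[a] * px[k])
                Q[a, c] = s
        ev = sorted(np.abs(np.linalg.eigvals(Q)), reverse=True)
        mcc = float(np.sqrt(max(0.0, ev[1].real))) if len(ev) > 1 else 1.0

    out = {
        "Autocorrelation": autoc,
        "JointAverage": mu,
        "ClusterProminence": sum(
            (i + j + 2 - 2 * mu) ** 4 * P[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            (i + j + 2 - 2 * mu) ** 3 * P[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            (i + j + 2 - 2 * mu) ** 2 * P[i][j] for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum(
            (i - j) ** 2 * P[i][j] for i in range(ng) for j in range(ng)
        ),
        "Correlation": (autoc - mu * mu) / sig2 if sig2 > 0 else 1.0,
        "DifferenceAverage": da,
        "DifferenceEntropy": entropy(pdiff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "JointEnergy": sum(P[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": joint_ent,
        "Imc1": (joint_ent - hxy1) / hx if hx > 0 else np.nan,
        "Imc2": np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_ent)))),
        "Idm": sum(
            P[i][j] / (1.0 + (i - j) ** 2) for i in range(ng) for j in range(ng)
        ),
        "Idmn": sum(
            P[i][j] / (1.0 + ((i - j) / ng) ** 2)
            for i in range(ng) for j in range(ng)
        ),
        "Id": sum(
            P[i][j] / (1.0 + abs(i - j)) for i in range(ng) for j in range(ng)
        ),
        "Idn": sum(
            P[i][j] / (1.0 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        ),
        "InverseVariance": sum(
            P[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "MaximumProbability": P.max(),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": entropy(psum.values()),
        "SumSquares": sum(
            (i + 1 - mu) ** 2 * P[i][j] for i in range(ng) for j in range(ng)
        ),
        "MCC": mcc,
    }
    return {k: float(v) for k, v in out.items()}


def brute_glcm(levels, mask, ng):
    per_dir = []
    for d in _dirs(levels.ndim):
        P = brute_glcm_matrix(levels, mask, d, ng)
        if P is not None:
            per_dir.append(brute_glcm_features(P))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------- GLRLM ----
def brute_runs(levels, mask, d):
    """Enumerate maximal runs by walking every line in direction d."""
    runs = []
    seen = set()
    for p in map(tuple, np.argwhere(mask)):
        prev = tuple(pi - di for pi, di in zip(p, d))
        inside = all(0 <= qi < si for qi, si in zip(prev, levels.shape))
        if inside and mask[prev] and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        q = p
        while True:
            nxt = tuple(qi + di for qi, di in zip(q, d))
            if (
                all(0 <= vi < si for vi, si in zip(nxt, levels.shape))
                and mask[nxt]
                and levels[nxt] == levels[p]
            ):
                length += 1
                q = nxt
            else:
                break
        assert p not in seen
        seen.add(p)
        runs.append((int(levels[p]), length))
    return runs


def _size_matrix_features(entries, n_voxels, ng, names):
    """Features of a (level, size)-count matrix from a plain entry list."""
    if not entries:
        return None
    nr = len(entries)
    max_s = max(s for _, s in entries)
    M = np.zeros((ng, max_s))
    for g, s in entries:
        M[g - 1, s - 1] += 1
    p = M / nr
    pg = M.sum(axis=1)
    ps = M.sum(axis=0)
    i = np.arange(1, ng + 1)
    j = np.arange(1, max_s + 1)
    mu_i = sum(i[a] * p[a, b] for a in range(ng) for b in range(max_s))
    mu_j = sum(j[b] * p[a, b] for a in range(ng) for b in range(max_s))
    out = {
        names[0]: sum(ps[b] / j[b] ** 2 for b in range(max_s)) / nr,
        names[1]: sum(ps[b] * j[b] ** 2 for b in range(max_s)) / nr,
        "GrayLevelNonUniformity": sum(pg[a] ** 2 for a in range(ng)) / nr,
        "GrayLevelNonUniformityNormalized": sum(pg[a] ** 2 for a in range(ng)) / nr**2,
        names[2]: sum(ps[b] ** 2 for b in range(max_s)) / nr,
        names[3]: sum(ps[b] ** 2 for b in range(max_s)) / nr**2,
        names[4]: nr / n_voxels,
        "GrayLevelVariance": sum(
            (i[a] - mu_i) ** 2 * p[a, b] for a in range(ng) for b in range(max_s)
        ),
        names[5]: sum(
            (j[b] - mu_j) ** 2 * p[a, b] for a in range(ng) for b in range(max_s)
        ),
        names[6]: -sum(
            p[a, b] * _log2(p[a, b])
            for a in range(ng) for b in range(max_s) if p[a, b] > 0
        ),
        names[7]: sum(pg[a] / i[a] ** 2 for a in range(ng)) / nr,
        names[8]: sum(pg[a] * i[a] ** 2 for a in range(ng)) / nr,
        names[9]: sum(
            p[a, b] / (i[a] ** 2 * j[b] ** 2)
            for a in range(ng) for b in range(max_s)
        ),
        names[10]: sum(
            p[a, b] * i[a] ** 2 / j[b] ** 2
            for a in range(ng) for b in range(max_s)
        ),
        names[11]: sum(
            p[a, b] * j[b] ** 2 / i[a] ** 2
            for a in range(ng) for b in range(max_s)
        ),
        names[12]: sum(
            p[a, b] * i[a] ** 2 * j[b] ** 2
            for a in range(ng) for b in range(max_s)
        ),
    }
    return {k: float(v) for k, v in out.items()}


_GLRLM_ORDER = (
    "ShortRunEmphasis", "LongRunEmphasis", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "RunEntropy", "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)


def brute_glrlm(levels, mask, ng):
    n_vox = int(mask.sum())
    per_dir = []
    for d in _dirs(levels.ndim):
        runs = brute_runs(levels, mask, d)
        f = _size_matrix_features(runs, n_vox, ng, _GLRLM_ORDER)
        if f is not None:
            per_dir.append(f)
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------- GLSZM ----
def brute_zones(levels, mask):
    """Connected equal-level zones by breadth-first flood fill."""
    visited = np.zeros_like(mask, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        g = levels[start]
        queue = [start]
        visited[start] = True
        size = 0
        while queue:
            p = queue.pop()
            size += 1
            for q in _neighbors(mask.shape, p, mask.ndim):
                if mask[q] and not visited[q] and levels[q] == g:
                    visited[q] = True
                    queue.append(q)
        zones.append((int(g), size))
    return zones


_GLSZM_ORDER = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "ZoneVariance",
    "ZoneEntropy", "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)


def brute_glszm(levels, mask, ng):
    zones = brute_zones(levels, mask)
    return _size_matrix_features(zones, int(mask.sum()), ng, _GLSZM_ORDER)


# --------------------------------------------------------------- NGTDM ----
def brute_ngtdm(levels, mask, ng):
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for p in map(tuple, np.argwhere(mask)):
        nb = [levels[q] for q in _neighbors(mask.shape, p, mask.ndim) if mask[q]]
        if not nb:
            continue
        g = levels[p]
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - float(np.mean(nb)))
    nvp = n_i.sum()
    p_i = n_i / nvp
    present = [a for a in range(ng) if p_i[a] > 0]
    ngp = len(present)
    i = np.arange(1, ng + 1, dtype=float)
    sum_ps = float(sum(p_i[a] * s_i[a] for a in range(ng)))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(
                p_i[a] * p_i[b] * (i[a] - i[b]) ** 2
                for a in present for b in present
            )
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
        denom = sum(
            abs(i[a] * p_i[a] - i[b] * p_i[b]) for a in present for b in present
        )
        busyness = sum_ps / denom if denom > 0 else np.nan
        complexity = (
            sum(
                abs(i[a] - i[b]) * (p_i[a] * s_i[a] + p_i[b] * s_i[b])
                / (p_i[a] + p_i[b])
                for a in present for b in present
            )
            / nvp
        )
        strength = (
            sum(
                (p_i[a] + p_i[b]) * (i[a] - i[b]) ** 2
                for a in present for b in present
            )
            / s_i.sum()
            if s_i.sum() > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------- GLDM ----
_GLDM_ORDER = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "DependencePercentage", "DependenceVariance", "DependenceEntropy",
    "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

GLDM_KEEP = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def brute_gldm(levels, mask, ng, alpha=0):
    entries = []
    for p in map(tuple, np.argwhere(mask)):
        dep = sum(
            1
            for q in _neighbors(mask.shape, p, mask.ndim)
            if mask[q] and abs(int(levels[q]) - int(levels[p])) <= alpha
        )
        entries.append((int(levels[p]), dep + 1))  # size includes the center
    f = _size_matrix_features(entries, int(mask.sum()), ng, _GLDM_ORDER)
    return {k: f[k] for k in GLDM_KEEP}
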