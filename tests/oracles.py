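"""Independent brute-force oracles for the texture and first-order features.

Everything here is written as plain per-voxel / per-matrix-entry loops,
deliberately sharing no code with the package implementation, so the two
routes can be compared on random volumes.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRECTIONS_13 = [d for d in NEIGHBORS_26 if d > (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def _entropy2(values):
    return -sum(v * math.log2(v) for v in values if v > 0)


# --------------------------------------------------------------------------
# GLCM

def glcm_matrix_oracle(levels, mask, ng, offset, symmetric=True):
    shape = levels.shape
    m = np.zeros((ng, ng))
    for p in np.argwhere(mask):
        q = tuple(p + offset)
        if _inside(shape, q) and mask[q]:
            m[levels[tuple(p)] - 1, levels[q] - 1] += 1
    if symmetric:
        m = m + m.T
    return m / m.sum() if m.sum() > 0 else None


def glcm_features_oracle(p):
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))
    pdiff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            pdiff[abs(i - j)] += p[i, j]
    da = sum(k * pdiff[k] for k in range(ng))
    f = {}
    f["JointAverage"] = mux
    f["SumAverage"] = sum((i + j + 2) * p[i, j] for i in range(ng) for j in range(ng))
    for name, power in [("ClusterTendency", 2), ("ClusterShade", 3), ("ClusterProminence", 4)]:
        f[name] = sum((i + j + 2 - mux - muy) ** power * p[i, j] for i in range(ng) for j in range(ng))
    f["Contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    autoc = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    f["Autocorrelation"] = autoc
    f["JointEnergy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["Idm"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng))
    f["Idn"] = sum(p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    f["InverseVariance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _entropy2(pdiff)
    f["DifferenceVariance"] = sum((k - da) ** 2 * pdiff[k] for k in range(ng))
    f["SumSquares"] = sum((i + 1 - mux) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    f["Correlation"] = (
        (autoc - mux * muy) / (sigx * sigy) if sigx > 0 and sigy > 0 else 1.0
    )
    return f


def glcm_oracle(levels, mask, ng):
    per = []
    for off in DIRECTIONS_13:
        m = glcm_matrix_oracle(levels, mask, ng, off)
        if m is not None:
            per.append(glcm_features_oracle(m))
    if not per:
        return None
    return {k: float(np.mean([f[k] for f in per])) for k in per[0]}


# --------------------------------------------------------------------------
# generic (level x size) feature forms shared by GLRLM / GLSZM / GLDM oracles

def _size_features_oracle(mat, n_voxels):
    ni, ns = mat.shape
    nr = mat.sum()
    p = mat / nr
    f = {}
    f["SmallEmphasis"] = sum(p[i, s] / (s + 1) ** 2 for i in range(ni) for s in range(ns))
    f["LargeEmphasis"] = sum(p[i, s] * (s + 1) ** 2 for i in range(ni) for s in range(ns))
    f["GrayLevelNonUniformity"] = sum(mat[i, :].sum() ** 2 for i in range(ni)) / nr
    f["GrayLevelNonUniformityNormalized"] = sum(p[i, :].sum() ** 2 for i in range(ni))
    f["SizeNonUniformity"] = sum(mat[:, s].sum() ** 2 for s in range(ns)) / nr
    f["SizeNonUniformityNormalized"] = sum(p[:, s].sum() ** 2 for s in range(ns))
    f["Percentage"] = nr / n_voxels
    mu_i = sum((i + 1) * p[i, s] for i in range(ni) for s in range(ns))
    mu_s = sum((s + 1) * p[i, s] for i in range(ni) for s in range(ns))
    f["GrayLevelVariance"] = sum((i + 1 - mu_i) ** 2 * p[i, s] for i in range(ni) for s in range(ns))
    f["SizeVariance"] = sum((s + 1 - mu_s) ** 2 * p[i, s] for i in range(ni) for s in range(ns))
    f["LowGrayLevelEmphasis"] = sum(p[i, s] / (i + 1) ** 2 for i in range(ni) for s in range(ns))
    f["HighGrayLevelEmphasis"] = sum(p[i, s] * (i + 1) ** 2 for i in range(ni) for s in range(ns))
    f["SmallLowGrayLevelEmphasis"] = sum(
        p[i, s] / ((i + 1) ** 2 * (s + 1) ** 2) for i in range(ni) for s in range(ns)
    )
    f["SmallHighGrayLevelEmphasis"] = sum(
        p[i, s] * (i + 1) ** 2 / (s + 1) ** 2 for i in range(ni) for s in range(ns)
    )
    f["LargeLowGrayLevelEmphasis"] = sum(
        p[i, s] * (s + 1) ** 2 / (i + 1) ** 2 for i in range(ni) for s in range(ns)
    )
    f["LargeHighGrayLevelEmphasis"] = sum(
        p[i, s] * (i + 1) ** 2 * (s + 1) ** 2 for i in range(ni) for s in range(ns)
    )
    f["Entropy"] = _entropy2(p.ravel())
    return f


# --------------------------------------------------------------------------
# GLRLM

def glrlm_runs_oracle(levels, mask, direction):
    """Naive run scanning: start at voxels with no same-level predecessor."""
    shape = levels.shape
    runs = []
    d = np.asarray(direction)
    for p in np.argwhere(mask):
        prev = tuple(p - d)
        if _inside(shape, prev) and mask[prev] and levels[prev] == levels[tuple(p)]:
            continue  # not a run start
        length = 1
        q = p + d
        while _inside(shape, tuple(q)) and mask[tuple(q)] and levels[tuple(q)] == levels[tuple(p)]:
            length += 1
            q = q + d
        runs.append((int(levels[tuple(p)]), length))
    return runs


def glrlm_oracle(levels, mask, ng):
    n_vox = int(mask.sum())
    per = []
    for d in DIRECTIONS_13:
        runs = glrlm_runs_oracle(levels, mask, d)
        if not runs:
            continue
        max_len = max(r for _, r in runs)
        mat = np.zeros((ng, max_len))
        for g, r in runs:
            mat[g - 1, r - 1] += 1
        per.append(_size_features_oracle(mat, n_vox))
    if not per:
        return None
    return {k: float(np.mean([f[k] for f in per])) for k in per[0]}


# --------------------------------------------------------------------------
# GLSZM

def glszm_zones_oracle(levels, mask):
    """Flood-fill (BFS) 26-connected equal-level zones."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        g = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for off in NEIGHBORS_26:
                q = tuple(np.add(p, off))
                if _inside(shape, q) and mask[q] and not seen[q] and levels[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((int(g), size))
    return zones


def glszm_oracle(levels, mask, ng):
    zones = glszm_zones_oracle(levels, mask)
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return _size_features_oracle(mat, int(mask.sum()))


# --------------------------------------------------------------------------
# GLDM

def gldm_oracle(levels, mask, ng, alpha=0):
    shape = levels.shape
    counts = defaultdict(float)
    max_j = 1
    for p in np.argwhere(mask):
        p = tuple(p)
        dep = 0
        for off in NEIGHBORS_26:
            q = tuple(np.add(p, off))
            if _inside(shape, q) and mask[q] and abs(int(levels[q]) - int(levels[p])) <= alpha:
                dep += 1
        j = dep + 1
        max_j = max(max_j, j)
        counts[(int(levels[p]), j)] += 1
    mat = np.zeros((ng, max_j))
    for (g, j), c in counts.items():
        mat[g - 1, j - 1] += c
    return _size_features_oracle(mat, int(mask.sum()))


# --------------------------------------------------------------------------
# NGTDM

def ngtdm_oracle(levels, mask, ng, coarseness_cap=1.0e6):
    shape = levels.shape
    s = [0.0] * ng
    n = [0] * ng
    n_valid = 0
    for p in np.argwhere(mask):
        p = tuple(p)
        nb = [
            int(levels[tuple(np.add(p, off))])
            for off in NEIGHBORS_26
            if _inside(shape, tuple(np.add(p, off))) and mask[tuple(np.add(p, off))]
        ]
        if not nb:
            continue
        n_valid += 1
        g = int(levels[p])
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(nb) / len(nb))
    if n_valid == 0:
        return None
    prob = [c / n_valid for c in n]
    present = [i for i in range(ng) if prob[i] > 0]
    ngp = len(present)
    ps = sum(prob[i] * s[i] for i in range(ng))
    f = {}
    f["Coarseness"] = 1.0 / ps if ps > 0 else coarseness_cap
    if ngp > 1:
        c1 = sum(
            prob[i] * prob[j] * (i - j) ** 2 for i in present for j in present
        ) / (ngp * (ngp - 1))
        f["Contrast"] = c1 * sum(s) / n_valid
    else:
        f["Contrast"] = 0.0
    denom = sum(
        abs((i + 1) * prob[i] - (j + 1) * prob[j]) for i in present for j in present
    )
    f["Busyness"] = ps / denom if denom > 0 else 0.0
    f["Complexity"] = sum(
        abs(i - j) * (prob[i] * s[i] + prob[j] * s[j]) / (prob[i] + prob[j])
        for i in present
        for j in present
    ) / n_valid
    ssum = sum(s)
    f["Strength"] = (
        sum((prob[i] + prob[j]) * (i - j) ** 2 for i in present for j in present) / ssum
        if ssum > 0
        else 0.0
    )
    return f


# --------------------------------------------------------------------------
# first order

def first_order_oracle(x, levels=None):
    x = sorted(float(v) for v in x)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    f = {"Mean": mean, "Minimum": x[0], "Maximum": x[-1], "Range": x[-1] - x[0], "Variance": var}
    f["Median"] = float(np.median(x))
    if var > 0:
        f["Skewness"] = (sum((v - mean) ** 3 for v in x) / n) / var**1.5
        f["Kurtosis"] = (sum((v - mean) ** 4 for v in x) / n) / var**2
    else:
        f["Skewness"] = 0.0
        f["Kurtosis"] = 0.0
    f["Energy"] = sum(v**2 for v in x)
    f["RootMeanSquared"] = math.sqrt(sum(v**2 for v in x) / n)
    f["MeanAbsoluteDeviation"] = sum(abs(v - mean) for v in x) / n
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    if robust:
        rmean = sum(robust) / len(robust)
        f["RobustMeanAbsoluteDeviation"] = sum(abs(v - rmean) for v in robust) / len(robust)
    else:
        f["RobustMeanAbsoluteDeviation"] = 0.0
    f["InterquartileRange"] = p75 - p25
    f["10Percentile"] = p10
    f["90Percentile"] = p90
    if levels is not None:
        lv = list(int(v) for v in levels)
        f["Uniformity"] = sum((lv.count(g) / len(lv)) ** 2 for g in set(lv))
    return f
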