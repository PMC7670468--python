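"""Gray-level texture matrices and their scalar features.

Five families over a discretized VOI:

* GLCM  — co-occurrence of level pairs at distance 1, 13 unique 3D
  directions, symmetrized, normalized per direction; features averaged
  over directions.
* GLRLM — run lengths of equal levels along the same 13 directions;
  features averaged over directions.
* GLSZM — sizes of 26-connected equal-level zones.
* GLDM  — per-voxel count of 26-neighbours within a level tolerance
  ``alpha`` (default 0); the matrix is indexed by (level, d+1) so an
  isolated voxel contributes dependence size 1.
* NGTDM — per-level summed absolute difference between a voxel's level
  and the mean level of its valid 26-neighbours.

Distances are measured in voxels (no isotropic resampling by default).
Degenerate inputs (no co-occurring pairs, a single voxel, zero texture)
return documented sentinels rather than NaN: division guards yield 0,
NGTDM Coarseness caps at 1e6, and the affected feature ids are reported
so callers can flag them.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..prep import DiscretizedVolume

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrices",
    "glcm_features",
    "glrlm_matrices",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "ngtdm_table",
    "ngtdm_features",
]

COARSENESS_CAP = 1.0e6

#: the 13 unique direction offsets of the 26-neighbourhood (first
#: non-zero component positive); their negations complete the 26.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_ALL_26 = DIRECTIONS_13 + tuple((-a, -b, -c) for a, b, c in DIRECTIONS_13)


def _crop(dvol: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """Crop levels/mask to the mask bounding box (pure speed-up)."""
    idx = np.argwhere(dvol.mask)
    if idx.size == 0:
        raise ValueError("empty VOI")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    mask = dvol.mask[sl]
    levels = np.where(mask, dvol.levels[sl], 0)
    return levels, mask


def _offset_slices(offset):
    src, dst = [], []
    for d in offset:
        if d >= 0:
            src.append(slice(None, None if d == 0 else -d))
            dst.append(slice(d, None))
        else:
            src.append(slice(-d, None))
            dst.append(slice(None, d))
    return tuple(src), tuple(dst)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# --------------------------------------------------------------------------
# GLCM

def glcm_matrices(dvol: DiscretizedVolume, offsets=DIRECTIONS_13, symmetric: bool = True):
    """Normalized co-occurrence matrix per offset (offsets with no valid
    voxel pair are omitted)."""
    levels, mask = _crop(dvol)
    ng = dvol.n_levels
    out = []
    for off in offsets:
        s, d = _offset_slices(off)
        a, b = levels[s], levels[d]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        counts = np.bincount((a[valid] - 1) * ng + (b[valid] - 1), minlength=ng * ng)
        m = counts.reshape(ng, ng).astype(np.float64)
        if symmetric:
            m = m + m.T
        out.append(m / m.sum())
    return out


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(i @ px)
    muy = float(i @ py)
    sigx = float(np.sqrt(((i - mux) ** 2) @ px))
    sigy = float(np.sqrt(((i - muy) ** 2) @ py))
    ii = i[:, None]
    jj = i[None, :]
    diff = np.abs(ii - jj)
    # difference distribution p_{x-y}
    k = np.arange(ng)
    pxy_diff = np.bincount(diff.ravel().astype(np.int64), weights=p.ravel(), minlength=ng)[:ng]
    da = float(k @ pxy_diff)
    autoc = float(np.sum(ii * jj * p))
    feats = {
        "JointAverage": mux,
        "SumAverage": float(np.sum((ii + jj) * p)),
        "ClusterShade": float(np.sum((ii + jj - mux - muy) ** 3 * p)),
        "ClusterProminence": float(np.sum((ii + jj - mux - muy) ** 4 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mux - muy) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Autocorrelation": autoc,
        "JointEnergy": float(np.sum(p * p)),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) ** 2) / ng**2))),
        "Idn": float(np.sum(p / (1.0 + diff / ng))),
        "InverseVariance": float(np.sum(p[diff > 0] / (diff[diff > 0] ** 2.0))),
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(pxy_diff),
        "DifferenceVariance": float(((k - da) ** 2) @ pxy_diff),
        "SumSquares": float(np.sum((ii - mux) ** 2 * p)),
    }
    if sigx > 0 and sigy > 0:
        feats["Correlation"] = (autoc - mux * muy) / (sigx * sigy)
    else:
        feats["Correlation"] = 1.0  # fully dependent degenerate case
    return feats


GLCM_NAMES = (
    "JointAverage", "SumAverage", "ClusterShade", "ClusterProminence",
    "ClusterTendency", "Contrast", "Autocorrelation", "JointEnergy",
    "Idm", "Idmn", "Idn", "InverseVariance", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "SumSquares", "Correlation",
)


def glcm_features(dvol: DiscretizedVolume, offsets=DIRECTIONS_13, symmetric: bool = True):
    """Per-offset GLCM features averaged over offsets.

    Returns (features, flags); if no offset produced a valid pair the
    features are all the 0 sentinel and every name is flagged.
    """
    mats = glcm_matrices(dvol, offsets, symmetric)
    if not mats:
        return {n: 0.0 for n in GLCM_NAMES}, list(GLCM_NAMES)
    per = [_glcm_features_single(m) for m in mats]
    return {n: float(np.mean([f[n] for f in per])) for n in GLCM_NAMES}, []


# --------------------------------------------------------------------------
# GLRLM

def glrlm_matrices(dvol: DiscretizedVolume, directions=DIRECTIONS_13):
    """Run-length count matrix (n_levels x max_run) per direction."""
    levels, mask = _crop(dvol)
    ng = dvol.n_levels
    coords = np.argwhere(mask)
    lev = levels[tuple(coords.T)]
    out = []
    for dvec in directions:
        d = np.asarray(dvec)
        dd = int(d @ d)
        t = coords @ d
        # line key: constant along the line through a voxel in direction d
        key = coords * dd - t[:, None] * d
        order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
        ks = key[order]
        ts = t[order]
        ls = lev[order]
        if ls.size == 0:
            out.append(np.zeros((ng, 1)))
            continue
        same_line = np.all(ks[1:] == ks[:-1], axis=1) & (ts[1:] - ts[:-1] == dd)
        new_run = np.empty(ls.size, dtype=bool)
        new_run[0] = True
        new_run[1:] = ~same_line | (ls[1:] != ls[:-1])
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, ls.size))
        run_levels = ls[starts]
        mat = np.zeros((ng, int(lengths.max())))
        np.add.at(mat, (run_levels - 1, lengths - 1), 1.0)
        out.append(mat)
    return out


GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)


def _size_indexed_features(mat: np.ndarray, n_voxels: int, prefix: dict[str, str]) -> dict[str, float]:
    """Shared feature forms for GLRLM/GLSZM-style (level x size) matrices.

    ``prefix`` maps generic names to family-specific feature ids.
    """
    nr = mat.sum()
    p = mat / nr
    i = np.arange(1, mat.shape[0] + 1)[:, None].astype(float)
    r = np.arange(1, mat.shape[1] + 1)[None, :].astype(float)
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    mu_i = float(np.sum(p * i))
    mu_r = float(np.sum(p * r))
    generic = {
        "SmallEmphasis": float(np.sum(p / r**2)),
        "LargeEmphasis": float(np.sum(p * r**2)),
        "GrayLevelNonUniformity": float(np.sum(mat.sum(axis=1) ** 2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2)),
        "SizeNonUniformity": float(np.sum(mat.sum(axis=0) ** 2) / nr),
        "SizeNonUniformityNormalized": float(np.sum(pr**2)),
        "Percentage": float(nr / n_voxels),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "SizeVariance": float(np.sum(p * (r - mu_r) ** 2)),
        "LowGrayLevelEmphasis": float(np.sum(p / i**2)),
        "HighGrayLevelEmphasis": float(np.sum(p * i**2)),
        "SmallLowGrayLevelEmphasis": float(np.sum(p / (i**2 * r**2))),
        "SmallHighGrayLevelEmphasis": float(np.sum(p * i**2 / r**2)),
        "LargeLowGrayLevelEmphasis": float(np.sum(p * r**2 / i**2)),
        "LargeHighGrayLevelEmphasis": float(np.sum(p * i**2 * r**2)),
        "Entropy": _entropy2(p.ravel()),
    }
    return {fam: generic[gen] for fam, gen in prefix.items()}


_GLRLM_MAP = {
    "ShortRunEmphasis": "SmallEmphasis",
    "LongRunEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity": "SizeNonUniformity",
    "RunLengthNonUniformityNormalized": "SizeNonUniformityNormalized",
    "RunPercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "RunVariance": "SizeVariance",
    "LowGrayLevelRunEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelRunEmphasis": "HighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}


def glrlm_features(dvol: DiscretizedVolume, directions=DIRECTIONS_13):
    mats = glrlm_matrices(dvol, directions)
    n_vox = int(dvol.mask.sum())
    per = [
        _size_indexed_features(m, n_vox, _GLRLM_MAP)
        for m in mats
        if m.sum() > 0
    ]
    if not per:
        return {n: 0.0 for n in GLRLM_NAMES}, list(GLRLM_NAMES)
    return {n: float(np.mean([f[n] for f in per])) for n in GLRLM_NAMES}, []


# --------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(dvol: DiscretizedVolume) -> np.ndarray:
    """Zone matrix: count of 26-connected equal-level components by
    (level, zone size)."""
    levels, mask = _crop(dvol)
    ng = dvol.n_levels
    zones: list[tuple[int, int]] = []
    for g in np.unique(levels[mask]):
        lab, n = ndimage.label(levels == g, structure=_STRUCT_26)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((int(g), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return mat


GLSZM_NAMES = (
    "SmallAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_GLSZM_MAP = {
    "SmallAreaEmphasis": "SmallEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity": "SizeNonUniformity",
    "SizeZoneNonUniformityNormalized": "SizeNonUniformityNormalized",
    "ZonePercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "ZoneVariance": "SizeVariance",
    "ZoneEntropy": "Entropy",
    "LowGrayLevelZoneEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelZoneEmphasis": "HighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}


def glszm_features(dvol: DiscretizedVolume):
    mat = glszm_matrix(dvol)
    feats = _size_indexed_features(mat, int(dvol.mask.sum()), _GLSZM_MAP)
    return {n: feats[n] for n in GLSZM_NAMES}, []


# --------------------------------------------------------------------------
# GLDM

def gldm_matrix(dvol: DiscretizedVolume, alpha: int = 0, delta: int = 1) -> np.ndarray:
    """Dependence matrix P(level, j) with j = dependent-neighbour count + 1.

    A neighbour (26-neighbourhood at Chebyshev distance ``delta``) is
    dependent when its level differs from the centre by at most ``alpha``.
    """
    if delta != 1:
        raise NotImplementedError("only delta=1 (26-neighbourhood) is implemented")
    levels, mask = _crop(dvol)
    ng = dvol.n_levels
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _ALL_26:
        s, d = _offset_slices(off)
        both = (levels[s] > 0) & (levels[d] > 0)
        close = np.abs(levels[s] - levels[d]) <= alpha
        contrib = np.zeros(levels.shape, dtype=np.int64)
        contrib[s] = (both & close).astype(np.int64)
        dep += contrib
    lev = levels[mask]
    j = dep[mask] + 1
    mat = np.zeros((ng, int(j.max())))
    np.add.at(mat, (lev - 1, j - 1), 1.0)
    return mat


GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

_GLDM_MAP = {
    "SmallDependenceEmphasis": "SmallEmphasis",
    "LargeDependenceEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "DependenceNonUniformity": "SizeNonUniformity",
    "DependenceNonUniformityNormalized": "SizeNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "DependenceVariance": "SizeVariance",
    "DependenceEntropy": "Entropy",
    "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}


def gldm_features(dvol: DiscretizedVolume, alpha: int = 0, delta: int = 1):
    mat = gldm_matrix(dvol, alpha=alpha, delta=delta)
    feats = _size_indexed_features(mat, int(dvol.mask.sum()), _GLDM_MAP)
    return {n: feats[n] for n in GLDM_NAMES}, []


# --------------------------------------------------------------------------
# NGTDM

def ngtdm_table(dvol: DiscretizedVolume, delta: int = 1):
    """Per-level occurrence probabilities p_i and summed gray-tone
    differences s_i over the 26-neighbourhood.

    Returns (p, s, n_valid) with p, s indexed 0..n_levels-1. Voxels with
    no in-mask neighbour are excluded.
    """
    if delta != 1:
        raise NotImplementedError("only delta=1 (26-neighbourhood) is implemented")
    levels, mask = _crop(dvol)
    ng = dvol.n_levels
    kern = np.ones((3, 3, 3))
    kern[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate((levels * mask).astype(float), kern, mode="constant")
    nb_cnt = ndimage.correlate(mask.astype(float), kern, mode="constant")
    valid = mask & (nb_cnt > 0)
    lev = levels[valid]
    abar = nb_sum[valid] / nb_cnt[valid]
    n_valid = int(valid.sum())
    p = np.bincount(lev - 1, minlength=ng).astype(float)
    s = np.zeros(ng)
    np.add.at(s, lev - 1, np.abs(lev - abar))
    if n_valid:
        p /= n_valid
    return p, s, n_valid


NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def ngtdm_features(dvol: DiscretizedVolume, delta: int = 1):
    p, s, n_valid = ngtdm_table(dvol, delta=delta)
    flags: list[str] = []
    if n_valid == 0:
        return {n: 0.0 for n in NGTDM_NAMES} | {"Coarseness": COARSENESS_CAP}, list(NGTDM_NAMES)
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, p.size + 1, dtype=float)
    ps = float(p @ s)

    if ps > 0:
        coarseness = 1.0 / ps
    else:
        coarseness = COARSENESS_CAP
        flags.append("Coarseness")

    if ngp > 1:
        pi = p[present]
        ii = i[present]
        dmat = (ii[:, None] - ii[None, :]) ** 2
        contrast = float(np.sum(pi[:, None] * pi[None, :] * dmat)) / (ngp * (ngp - 1))
        contrast *= float(s.sum()) / n_valid
    else:
        contrast = 0.0

    denom_busy = float(np.sum(np.abs((i * p)[present][:, None] - (i * p)[present][None, :])))
    busyness = ps / denom_busy if denom_busy > 0 else 0.0
    if denom_busy == 0:
        flags.append("Busyness")

    pi = p[present]
    ii = i[present]
    si = s[present]
    pair_w = np.abs(ii[:, None] - ii[None, :])
    num = (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]) / (pi[:, None] + pi[None, :])
    complexity = float(np.sum(pair_w * num)) / n_valid

    ssum = float(s.sum())
    if ssum > 0:
        strength = float(np.sum((pi[:, None] + pi[None, :]) * (ii[:, None] - ii[None, :]) ** 2)) / ssum
    else:
        strength = 0.0
        flags.append("Strength")

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }, flags
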