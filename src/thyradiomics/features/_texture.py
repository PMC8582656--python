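"""Gray-level texture-matrix families on a discretized ROI.

Five families are computed from a :class:`GrayLevelMap`:

* GLCM  — co-occurrence of level pairs at distance 1 over the 13 unique 3D
  direction classes; matrices are symmetrized and normalized per direction
  and every feature is the mean of its per-direction values.
* GLRLM — run lengths of equal-level voxels along the same 13 directions,
  features averaged over directions.
* GLSZM — sizes of 26-connected equal-level zones (direction free).
* NGTDM — per-level sums of absolute differences between a voxel's level
  and the mean level of its valid 26-neighbours.
* GLDM  — per-voxel dependence, the number of 26-neighbours sharing the
  voxel's level (tolerance alpha = 0); the dependence *size* recorded in the
  matrix counts the centre voxel, so a lone voxel has size 1.

Gray levels run 1..Ng over the full discretized range; levels absent from
the ROI simply contribute empty rows.  Entropies use log base 2 restricted
to positive probabilities.  A ROI too small to form any voxel pair yields
NaN for every GLCM feature (flagged, not dropped).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._discretize import GrayLevelMap

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "DIRECTIONS_13",
    "NGTDM_COARSENESS_CAP",
]

# the 13 offsets whose first nonzero component is positive; together with
# their negatives they cover the 26-neighbourhood at distance 1
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

NGTDM_COARSENESS_CAP = 1e6

GLCM_FEATURE_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_FEATURE_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_FEATURE_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_FEATURE_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
GLDM_FEATURE_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _pair_slices(shape, d):
    """Slices (a, b) such that b = a + d, both inside the grid."""
    a = tuple(slice(max(0, -di), n - max(0, di)) for n, di in zip(shape, d))
    b = tuple(slice(max(0, di), n - max(0, -di)) for n, di in zip(shape, d))
    return a, b


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrix(glmap: GrayLevelMap, d) -> np.ndarray:
    ng = glmap.n_levels
    a_sl, b_sl = _pair_slices(glmap.levels.shape, d)
    la, lb = glmap.levels[a_sl].ravel(), glmap.levels[b_sl].ravel()
    keep = (la > 0) & (lb > 0)
    la, lb = la[keep] - 1, lb[keep] - 1
    counts = np.bincount(la * ng + lb, minlength=ng * ng).reshape(ng, ng).astype(float)
    return counts + counts.T  # symmetric


def _glcm_features_one(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    # diagonal (i - j) and cross (i + j) marginals
    k_diff = np.arange(ng, dtype=float)                 # |i - j| = 0 .. ng-1
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)       # i + j = 2 .. 2 ng
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    hxy = _entropy2(p.ravel())
    hx, hy = _entropy2(px), _entropy2(py)
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxy[nz])))
    hxy2 = _entropy2(pxy.ravel())

    da = float(np.sum(k_diff * p_diff))

    if sig_x > 0 and sig_y > 0:
        corr = (float(np.sum(ii * jj * p)) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        corr = 1.0

    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))))

    # MCC via the transition-like matrix Q over levels present in p
    present = px > 0
    if present.sum() > 1:
        ps = p[np.ix_(present, present)]
        pxs, pys = px[present], py[present]
        q = (ps / pxs[:, None]) @ (ps / pys[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(max(ev[1], 0.0))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0

    off = ii != jj
    out = {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mu_x,
        "ClusterProminence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng**2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": float(np.sum(p[off] / (ii[off] - jj[off]) ** 2)),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * p)),
        "MCC": mcc,
    }
    return out


def glcm_features(glmap: GrayLevelMap) -> dict[str, float]:
    """24 co-occurrence features, averaged over the 13 direction classes."""
    ng = glmap.n_levels
    per_dir = []
    for d in DIRECTIONS_13:
        counts = _glcm_matrix(glmap, d)
        tot = counts.sum()
        if tot == 0:
            continue  # no pair along this direction (tiny ROI)
        per_dir.append(_glcm_features_one(counts / tot, ng))
    if not per_dir:
        return {k: float("nan") for k in GLCM_FEATURE_NAMES}
    out = {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURE_NAMES}
    return out


# ---------------------------------------------------------------------------
# GLRLM


def _runs_for_direction(levels: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Gray level and length of every maximal run along direction ``d``.

    The grid is decomposed into lattice lines parallel to ``d``; each line is
    scanned in order and split where the level changes.  Out-of-mask voxels
    (level 0) break runs and are discarded.
    """
    shape = levels.shape
    coords = np.indices(shape).reshape(3, -1)
    d_arr = np.asarray(d).reshape(3, 1)
    axis = next(i for i in range(3) if d[i] != 0)
    t = coords[axis] * d[axis]  # step count along the line (d components are ±1)
    line = coords - t * d_arr   # constant per line: the line's anchor point
    off = np.asarray(shape).reshape(3, 1) - 1
    span = [2 * n for n in shape]
    lp = line + off
    lid = (lp[0] * span[1] + lp[1]) * span[2] + lp[2]
    order = np.lexsort((t, lid))
    lv = levels.ravel()[order]
    lid_s = lid[order]
    new = np.empty(lv.size, dtype=bool)
    new[0] = True
    new[1:] = (lid_s[1:] != lid_s[:-1]) | (lv[1:] != lv[:-1])
    run_id = np.cumsum(new) - 1
    run_len = np.bincount(run_id)
    run_lv = lv[new]
    keep = run_lv > 0
    return run_lv[keep], run_len[keep]


def _rl_matrix(glmap: GrayLevelMap, d) -> np.ndarray:
    lv, ln = _runs_for_direction(glmap.levels, d)
    ng = glmap.n_levels
    max_len = int(ln.max()) if ln.size else 1
    mat = np.bincount(
        (lv - 1) * max_len + (ln - 1), minlength=ng * max_len
    ).reshape(ng, max_len)
    return mat.astype(float)


def _size_weighted_features(mat: np.ndarray, n_voxels: int, prefix: dict[str, str]) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas on a (level x size) count matrix.

    ``prefix`` maps the generic names onto family-specific ones
    (run/zone, ShortRun/SmallArea, ...).
    """
    ng, ns = mat.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, ns + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    n_s = mat.sum()  # number of runs / zones
    p = mat / n_s
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float(np.sum(i * pg))
    mu_j = float(np.sum(j * ps))

    gen = {
        "GrayLevelNonUniformity": float(np.sum(mat.sum(axis=1) ** 2) / n_s),
        "GrayLevelNonUniformityNormalized": float(np.sum(mat.sum(axis=1) ** 2) / n_s**2),
        "GrayLevelVariance": float(np.sum((ii - mu_i) ** 2 * p)),
        "HighGrayLevelEmphasis": float(np.sum(mat * ii**2) / n_s),
        "LowGrayLevelEmphasis": float(np.sum(mat / ii**2) / n_s),
        "LargeEmphasis": float(np.sum(mat * jj**2) / n_s),
        "SmallEmphasis": float(np.sum(mat / jj**2) / n_s),
        "LargeHigh": float(np.sum(mat * ii**2 * jj**2) / n_s),
        "LargeLow": float(np.sum(mat * jj**2 / ii**2) / n_s),
        "SmallHigh": float(np.sum(mat * ii**2 / jj**2) / n_s),
        "SmallLow": float(np.sum(mat / (ii**2 * jj**2)) / n_s),
        "SizeNonUniformity": float(np.sum(mat.sum(axis=0) ** 2) / n_s),
        "SizeNonUniformityNormalized": float(np.sum(mat.sum(axis=0) ** 2) / n_s**2),
        "SizeVariance": float(np.sum((jj - mu_j) ** 2 * p)),
        "Entropy": _entropy2(p.ravel()),
        "Percentage": float(n_s / n_voxels),
    }
    return {real: gen[g] for g, real in prefix.items()}


_GLRLM_MAP = {
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
    "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
    "LargeEmphasis": "LongRunEmphasis",
    "SmallEmphasis": "ShortRunEmphasis",
    "LargeHigh": "LongRunHighGrayLevelEmphasis",
    "LargeLow": "LongRunLowGrayLevelEmphasis",
    "SmallHigh": "ShortRunHighGrayLevelEmphasis",
    "SmallLow": "ShortRunLowGrayLevelEmphasis",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "SizeVariance": "RunVariance",
    "Entropy": "RunEntropy",
    "Percentage": "RunPercentage",
}

_GLSZM_MAP = {
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
    "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
    "LargeEmphasis": "LargeAreaEmphasis",
    "SmallEmphasis": "SmallAreaEmphasis",
    "LargeHigh": "LargeAreaHighGrayLevelEmphasis",
    "LargeLow": "LargeAreaLowGrayLevelEmphasis",
    "SmallHigh": "SmallAreaHighGrayLevelEmphasis",
    "SmallLow": "SmallAreaLowGrayLevelEmphasis",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "SizeVariance": "ZoneVariance",
    "Entropy": "ZoneEntropy",
    "Percentage": "ZonePercentage",
}


def glrlm_features(glmap: GrayLevelMap) -> dict[str, float]:
    """16 run-length features, averaged over the 13 direction classes."""
    per_dir = [
        _size_weighted_features(_rl_matrix(glmap, d), glmap.n_voxels, _GLRLM_MAP)
        for d in DIRECTIONS_13
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_features(glmap: GrayLevelMap) -> dict[str, float]:
    """16 size-zone features from 26-connected equal-level zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    lv_list, sz_list = [], []
    for lvl in range(1, glmap.n_levels + 1):
        lab, n_zones = ndimage.label(glmap.levels == lvl, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        lv_list.append(np.full(n_zones, lvl))
        sz_list.append(sizes)
    lv = np.concatenate(lv_list)
    sz = np.concatenate(sz_list)
    ng = glmap.n_levels
    max_sz = int(sz.max())
    mat = np.bincount((lv - 1) * max_sz + (sz - 1), minlength=ng * max_sz).reshape(
        ng, max_sz
    ).astype(float)
    return _size_weighted_features(mat, glmap.n_voxels, _GLSZM_MAP)


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(glmap: GrayLevelMap) -> dict[str, float]:
    """5 neighbourhood gray-tone difference features."""
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    lv = glmap.levels.astype(float)
    nbr_sum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(glmap.mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = glmap.mask & (nbr_cnt > 0.5)

    ng = glmap.n_levels
    levels_v = glmap.levels[valid]
    diffs = np.abs(levels_v - nbr_sum[valid] / nbr_cnt[valid])
    n_i = np.bincount(levels_v, minlength=ng + 1)[1:].astype(float)
    s_i = np.bincount(levels_v, weights=diffs, minlength=ng + 1)[1:]

    nvp = n_i.sum()
    if nvp == 0:  # isolated voxels only: no valid neighbourhood anywhere
        return {k: float("nan") for k in NGTDM_FEATURE_NAMES}
    p_i = n_i / nvp
    i = np.arange(1, ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    ip, pp, sp = i[present], p_i[present], s_i[present]
    ps_sum = float(np.sum(p_i * s_i))
    s_sum = float(s_i.sum())

    coarseness = min(1.0 / ps_sum, NGTDM_COARSENESS_CAP) if ps_sum > 0 else NGTDM_COARSENESS_CAP

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        contrast = (
            float(np.sum(pp[:, None] * pp[None, :] * di**2))
            / (ngp * (ngp - 1))
            * (s_sum / nvp)
        )
        ipi = ip * pp
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        busyness = ps_sum / busy_den if busy_den > 0 else 0.0
        pssum2 = pp * sp
        complexity = float(
            np.sum(
                np.abs(di) * (pssum2[:, None] + pssum2[None, :]) / (pp[:, None] + pp[None, :])
            )
        ) / nvp
        strength = (
            float(np.sum((pp[:, None] + pp[None, :]) * di**2)) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_features(glmap: GrayLevelMap) -> dict[str, float]:
    """14 gray-level dependence features (alpha = 0, distance 1)."""
    lv = glmap.levels
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        a_sl, b_sl = _pair_slices(lv.shape, d)
        eq = (lv[a_sl] == lv[b_sl]) & glmap.mask[a_sl] & glmap.mask[b_sl]
        dep[a_sl] += eq
        dep[b_sl] += eq

    ng = glmap.n_levels
    levels_m = lv[glmap.mask]
    size_m = dep[glmap.mask] + 1  # dependence size counts the centre voxel
    max_size = int(size_m.max())
    mat = np.bincount(
        (levels_m - 1) * max_size + (size_m - 1), minlength=ng * max_size
    ).reshape(ng, max_size).astype(float)

    nz = mat.sum()
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, max_size + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = mat / nz
    pg, pd = p.sum(axis=1), p.sum(axis=0)
    mu_i, mu_j = float(np.sum(i * pg)), float(np.sum(j * pd))

    return {
        "SmallDependenceEmphasis": float(np.sum(mat / jj**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(mat * jj**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(mat.sum(axis=1) ** 2) / nz),
        "DependenceNonUniformity": float(np.sum(mat.sum(axis=0) ** 2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(mat.sum(axis=0) ** 2) / nz**2),
        "GrayLevelVariance": float(np.sum((ii - mu_i) ** 2 * p)),
        "DependenceVariance": float(np.sum((jj - mu_j) ** 2 * p)),
        "DependenceEntropy": _entropy2(p.ravel()),
        "LowGrayLevelEmphasis": float(np.sum(mat / ii**2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(mat * ii**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(mat / (ii**2 * jj**2)) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(mat * ii**2 / jj**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(mat * jj**2 / ii**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(mat * ii**2 * jj**2) / nz),
    }
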