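"""Independent brute-force oracles for texture features and statistics.

Everything here is deliberately naive: explicit Python loops enumerating
voxel pairs, runs, zones and neighbourhoods, and feature formulas written
out term by term.  These implementations share no code with the package
and serve as ground truth on tiny level maps.
"""

from __future__ import annotations

import math

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
POS_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def _log2(x):
    return math.log2(x)


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels: np.ndarray, d, ng: int) -> np.ndarray:
    """Symmetric co-occurrence counts by exhaustive pair enumeration."""
    mat = np.zeros((ng, ng))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                nb = (x + d[0], y + d[1], z + d[2])
                if not _inside(shape, nb):
                    continue
                b = levels[nb]
                if b == 0:
                    continue
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    return mat


def glcm_features(p: np.ndarray, ng: int) -> dict:
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)  # k = i+j in [2, 2 ng]
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i][j]
            p_sum[i + j] += p[i][j]

    def ent(vals):
        return -sum(v * _log2(v) for v in vals if v > 0)

    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i][j] * _log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = ent([px[i] * py[j] for i in range(ng) for j in range(ng)])

    da = sum(k * p_diff[k] for k in range(ng))
    denom = max(hx, hy)

    present = [i for i in range(ng) if px[i] > 0]
    if len(present) > 1:
        q = np.zeros((len(present), len(present)))
        for ai, i in enumerate(present):
            for aj, j in enumerate(present):
                q[ai, aj] = sum(
                    p[i][k] * p[j][k] / (px[i] * py[k]) for k in present if py[k] > 0
                )
        ev = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
        mcc = math.sqrt(max(ev[1], 0.0))
    else:
        mcc = 1.0

    corr = 1.0
    if sig_x > 0 and sig_y > 0:
        corr = (
            sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / (sig_x * sig_y)

    return {
        "Autocorrelation": sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)),
        "JointAverage": mu_x,
        "ClusterProminence": sum(
            (i + j + 2 - mu_x - mu_y) ** 4 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            (i + j + 2 - mu_x - mu_y) ** 3 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            (i + j + 2 - mu_x - mu_y) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": sum((k - da) ** 2 * p_diff[k] for k in range(ng)),
        "JointEnergy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / denom if denom > 0 else 0.0,
        "Imc2": math.sqrt(1 - math.exp(-2 * max(hxy2 - hxy, 0.0))),
        "Idm": sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "Idmn": sum(
            p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
        ),
        "Id": sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "Idn": sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)),
        "InverseVariance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "MaximumProbability": max(p[i][j] for i in range(ng) for j in range(ng)),
        "SumAverage": sum((k + 2) * p_sum[k] for k in range(2 * ng - 1)),
        "SumEntropy": ent(p_sum),
        "SumSquares": sum(
            (i + 1 - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "MCC": mcc,
    }


def glcm_direction_averaged(levels: np.ndarray, ng: int) -> dict:
    per_dir = []
    for d in POS_13:
        mat = glcm_matrix(levels, d, ng)
        tot = mat.sum()
        if tot == 0:
            continue
        per_dir.append(glcm_features(mat / tot, ng))
    assert per_dir, "oracle: no pairs at all"
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# Runs (GLRLM)


def runs(levels: np.ndarray, d) -> list[tuple[int, int]]:
    """(level, length) of every maximal run along +/-d, by walking voxels."""
    shape = levels.shape
    out = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                lvl = levels[x, y, z]
                if lvl == 0:
                    continue
                prev = (x - d[0], y - d[1], z - d[2])
                if _inside(shape, prev) and levels[prev] == lvl:
                    continue  # not a run start
                length = 1
                cur = (x + d[0], y + d[1], z + d[2])
                while _inside(shape, cur) and levels[cur] == lvl:
                    length += 1
                    cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                out.append((int(lvl), length))
    return out


def rl_matrix(levels: np.ndarray, d, ng: int) -> np.ndarray:
    rs = runs(levels, d)
    max_len = max(l for _, l in rs)
    mat = np.zeros((ng, max_len))
    for lvl, length in rs:
        mat[lvl - 1, length - 1] += 1
    return mat


# ---------------------------------------------------------------------------
# Zones (GLSZM)


def zones(levels: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) of every 26-connected equal-level zone via flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    out = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                lvl = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for d in ALL_26:
                        nb = (cx + d[0], cy + d[1], cz + d[2])
                        if _inside(shape, nb) and not seen[nb] and levels[nb] == lvl:
                            seen[nb] = True
                            stack.append(nb)
                out.append((int(lvl), size))
    return out


def szm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    zs = zones(levels)
    max_sz = max(s for _, s in zs)
    mat = np.zeros((ng, max_sz))
    for lvl, size in zs:
        mat[lvl - 1, size - 1] += 1
    return mat


def size_features(mat: np.ndarray, n_voxels: int) -> dict:
    """Generic (level x size) features with explicit sums; generic names."""
    ng, ns = mat.shape
    n_s = mat.sum()
    mu_i = sum((i + 1) * mat[i, j] / n_s for i in range(ng) for j in range(ns))
    mu_j = sum((j + 1) * mat[i, j] / n_s for i in range(ng) for j in range(ns))
    ent = -sum(
        mat[i, j] / n_s * _log2(mat[i, j] / n_s)
        for i in range(ng)
        for j in range(ns)
        if mat[i, j] > 0
    )
    return {
        "GrayLevelNonUniformity": sum(mat[i, :].sum() ** 2 for i in range(ng)) / n_s,
        "GrayLevelNonUniformityNormalized": sum(mat[i, :].sum() ** 2 for i in range(ng)) / n_s**2,
        "GrayLevelVariance": sum(
            (i + 1 - mu_i) ** 2 * mat[i, j] / n_s for i in range(ng) for j in range(ns)
        ),
        "HighGrayLevelEmphasis": sum(
            (i + 1) ** 2 * mat[i, j] for i in range(ng) for j in range(ns)
        ) / n_s,
        "LowGrayLevelEmphasis": sum(
            mat[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)
        ) / n_s,
        "LargeEmphasis": sum((j + 1) ** 2 * mat[i, j] for i in range(ng) for j in range(ns)) / n_s,
        "SmallEmphasis": sum(mat[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)) / n_s,
        "LargeHigh": sum(
            (i + 1) ** 2 * (j + 1) ** 2 * mat[i, j] for i in range(ng) for j in range(ns)
        ) / n_s,
        "LargeLow": sum(
            (j + 1) ** 2 * mat[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)
        ) / n_s,
        "SmallHigh": sum(
            (i + 1) ** 2 * mat[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)
        ) / n_s,
        "SmallLow": sum(
            mat[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(ns)
        ) / n_s,
        "SizeNonUniformity": sum(mat[:, j].sum() ** 2 for j in range(ns)) / n_s,
        "SizeNonUniformityNormalized": sum(mat[:, j].sum() ** 2 for j in range(ns)) / n_s**2,
        "SizeVariance": sum(
            (j + 1 - mu_j) ** 2 * mat[i, j] / n_s for i in range(ng) for j in range(ns)
        ),
        "Entropy": ent,
        "Percentage": n_s / n_voxels,
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(levels: np.ndarray, ng: int):
    """(n_i, s_i) per gray level from per-voxel neighbourhood loops."""
    shape = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                lvl = levels[x, y, z]
                if lvl == 0:
                    continue
                nb_vals = []
                for d in ALL_26:
                    nb = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, nb) and levels[nb] != 0:
                        nb_vals.append(levels[nb])
                if not nb_vals:
                    continue
                n_i[lvl - 1] += 1
                s_i[lvl - 1] += abs(lvl - sum(nb_vals) / len(nb_vals))
    return n_i, s_i


def ngtdm_features(levels: np.ndarray, ng: int, cap: float = 1e6) -> dict:
    n_i, s_i = ngtdm_table(levels, ng)
    nvp = n_i.sum()
    p_i = n_i / nvp
    present = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(present)
    ps = sum(p_i[i] * s_i[i] for i in range(ng))
    coarseness = min(1.0 / ps, cap) if ps > 0 else cap
    if ngp > 1:
        contrast = (
            sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
        busy_den = sum(
            abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in present for j in present
        )
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j)
            * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
            / (p_i[i] + p_i[j])
            for i in present
            for j in present
        ) / nvp
        strength = (
            sum((p_i[i] + p_i[j]) * (i - j) ** 2 for i in present for j in present)
            / s_i.sum()
            if s_i.sum() > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Dependence matrix by per-voxel neighbour counting (alpha = 0)."""
    shape = levels.shape
    entries = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                lvl = levels[x, y, z]
                if lvl == 0:
                    continue
                dep = 0
                for d in ALL_26:
                    nb = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, nb) and levels[nb] == lvl:
                        dep += 1
                entries.append((int(lvl), dep + 1))  # size includes centre
    max_size = max(s for _, s in entries)
    mat = np.zeros((ng, max_size))
    for lvl, size in entries:
        mat[lvl - 1, size - 1] += 1
    return mat


def gldm_features(levels: np.ndarray, ng: int) -> dict:
    mat = gldm_matrix(levels, ng)
    _, ns = mat.shape
    nz = mat.sum()
    mu_i = sum((i + 1) * mat[i, j] / nz for i in range(ng) for j in range(ns))
    mu_j = sum((j + 1) * mat[i, j] / nz for i in range(ng) for j in range(ns))
    ent = -sum(
        mat[i, j] / nz * _log2(mat[i, j] / nz)
        for i in range(ng)
        for j in range(ns)
        if mat[i, j] > 0
    )
    return {
        "SmallDependenceEmphasis": sum(
            mat[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)
        ) / nz,
        "LargeDependenceEmphasis": sum(
            (j + 1) ** 2 * mat[i, j] for i in range(ng) for j in range(ns)
        ) / nz,
        "GrayLevelNonUniformity": sum(mat[i, :].sum() ** 2 for i in range(ng)) / nz,
        "DependenceNonUniformity": sum(mat[:, j].sum() ** 2 for j in range(ns)) / nz,
        "DependenceNonUniformityNormalized": sum(mat[:, j].sum() ** 2 for j in range(ns)) / nz**2,
        "GrayLevelVariance": sum(
            (i + 1 - mu_i) ** 2 * mat[i, j] / nz for i in range(ng) for j in range(ns)
        ),
        "DependenceVariance": sum(
            (j + 1 - mu_j) ** 2 * mat[i, j] / nz for i in range(ng) for j in range(ns)
        ),
        "DependenceEntropy": ent,
        "LowGrayLevelEmphasis": sum(
            mat[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)
        ) / nz,
        "HighGrayLevelEmphasis": sum(
            (i + 1) ** 2 * mat[i, j] for i in range(ng) for j in range(ns)
        ) / nz,
        "SmallDependenceLowGrayLevelEmphasis": sum(
            mat[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(ns)
        ) / nz,
        "SmallDependenceHighGrayLevelEmphasis": sum(
            (i + 1) ** 2 * mat[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)
        ) / nz,
        "LargeDependenceLowGrayLevelEmphasis": sum(
            (j + 1) ** 2 * mat[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)
        ) / nz,
        "LargeDependenceHighGrayLevelEmphasis": sum(
            (i + 1) ** 2 * (j + 1) ** 2 * mat[i, j] for i in range(ng) for j in range(ns)
        ) / nz,
    }


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up


def bh_stepup(pvals) -> np.ndarray:
    """Adjusted q-values by the literal step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = p[idx] * m / rank_from_top
        running_min = min(running_min, val)
        q[idx] = running_min
    return q
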