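"""Grey-level texture matrices and their features (GLCM, GLRLM, GLSZM, NGTDM).

All matrices operate on a discretised level array where 0 marks voxels
outside the VOI and 1..n are grey levels.  Co-occurrence and run-length
matrices are computed per 3-D direction (13 unique directions) and the
feature values averaged over directions; size-zone and neighbourhood
matrices use 26-connectivity.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# one representative per ± pair of the 26 neighbour offsets
DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

_EPS = np.finfo(float).eps


def _shifted_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Level values of all in-mask voxel pairs separated by ``offset``."""
    sl_a, sl_b = [], []
    for d in offset:
        if d >= 0:
            sl_a.append(slice(0, levels.shape[len(sl_a)] - d))
            sl_b.append(slice(d, levels.shape[len(sl_b)]))
        else:
            sl_a.append(slice(-d, levels.shape[len(sl_a)]))
            sl_b.append(slice(0, levels.shape[len(sl_b)] + d))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    ok = (a > 0) & (b > 0)
    return a[ok], b[ok]


def glcm_matrix(levels: np.ndarray, offset: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Symmetric, normalised grey-level co-occurrence matrix for one offset."""
    a, b = _shifted_pairs(levels, offset)
    if a.size == 0:
        return np.zeros((n_levels, n_levels))
    m = np.zeros((n_levels, n_levels))
    np.add.at(m, (a - 1, b - 1), 1.0)
    m = m + m.T  # symmetric co-occurrence
    return m / m.sum()


def glcm_features_from_matrix(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    diff = i - j
    px = p.sum(axis=1)
    mu_x = float((np.arange(1, n + 1) * px).sum())
    sd_x = float(np.sqrt(((np.arange(1, n + 1) - mu_x) ** 2 * px).sum()))
    pos = p > 0
    feats = {
        "contrast": float((p * diff**2).sum()),
        "dissimilarity": float((p * np.abs(diff)).sum()),
        "idm": float((p / (1 + diff**2)).sum()),
        "inverse_difference": float((p / (1 + np.abs(diff))).sum()),
        "energy": float((p**2).sum()),
        "joint_entropy": float(-(p[pos] * np.log2(p[pos])).sum()),
        "joint_maximum": float(p.max()),
        "sum_average": float((p * (i + j)).sum()),
        "cluster_shade": float((p * (i + j - 2 * mu_x) ** 3).sum()),
        "cluster_prominence": float((p * (i + j - 2 * mu_x) ** 4).sum()),
    }
    if sd_x > 0:
        feats["correlation"] = float(
            ((p * (i - mu_x) * (j - mu_x)).sum()) / sd_x**2
        )
    else:
        feats["correlation"] = 1.0
    return feats


def glcm_features(levels: np.ndarray, n_levels: int,
                  directions=DIRECTIONS_13) -> dict[str, float]:
    """GLCM features averaged over the 13 unique 3-D directions."""
    per_dir = []
    for d in directions:
        p = glcm_matrix(levels, d, n_levels)
        if p.sum() > 0:
            per_dir.append(glcm_features_from_matrix(p))
    if not per_dir:
        return {}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def glrlm_matrix(levels: np.ndarray, offset: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Grey-level run-length matrix for one direction.

    Entry (i, r-1) counts maximal runs of r consecutive voxels of level i
    along the direction; out-of-mask voxels break runs.
    """
    shape = levels.shape
    max_run = int(np.ceil(np.sqrt(sum((s * abs(d)) ** 2 for s, d in zip(shape, offset))))) + 1
    m = np.zeros((n_levels, max(max_run, 1)))
    d = np.asarray(offset)
    # run starts: in-mask voxels whose predecessor is outside bbox/mask or differs
    coords = np.argwhere(levels > 0)
    pred = coords - d
    in_bbox = np.all((pred >= 0) & (pred < shape), axis=1)
    start = ~in_bbox
    if in_bbox.any():
        pv = levels[tuple(pred[in_bbox].T)]
        cv = levels[tuple(coords[in_bbox].T)]
        sub = np.zeros(in_bbox.sum(), dtype=bool)
        sub |= pv != cv
        start[in_bbox] = sub
        start[in_bbox] |= pv == 0
    for c in coords[start]:
        lvl = levels[tuple(c)]
        r = 1
        nxt = c + d
        while np.all(nxt >= 0) and np.all(nxt < shape) and levels[tuple(nxt)] == lvl:
            r += 1
            nxt = nxt + d
        m[lvl - 1, r - 1] += 1
    # trim trailing all-zero run lengths
    used = np.nonzero(m.sum(axis=0))[0]
    return m[:, : used[-1] + 1] if used.size else m[:, :1]


def _rl_sz_features(m: np.ndarray, prefix_small: str, prefix_large: str,
                    n_sites: int) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas on a (level × size) matrix."""
    total = m.sum()
    if total == 0:
        return {}
    p = m / total
    n_lev, n_sz = m.shape
    i = np.arange(1, n_lev + 1)[:, None].astype(float)
    j = np.arange(1, n_sz + 1)[None, :].astype(float)
    pg = p.sum(axis=1)  # grey-level marginal
    ps = p.sum(axis=0)  # size/length marginal
    mu_sz = float((ps * j.ravel()).sum())
    mu_gl = float((pg * i.ravel()).sum())
    pos = p > 0
    return {
        prefix_small: float((p / j**2).sum()),
        prefix_large: float((p * j**2).sum()),
        "grey_level_nonuniformity": float((m.sum(axis=1) ** 2).sum() / total),
        "grey_level_nonuniformity_norm": float((pg**2).sum()),
        "size_nonuniformity": float((m.sum(axis=0) ** 2).sum() / total),
        "size_nonuniformity_norm": float((ps**2).sum()),
        "low_grey_emphasis": float((p / i**2).sum()),
        "high_grey_emphasis": float((p * i**2).sum()),
        "size_variance": float((p * (j - mu_sz) ** 2).sum()),
        "grey_level_variance": float((p * (i - mu_gl) ** 2).sum()),
        "entropy": float(-(p[pos] * np.log2(p[pos])).sum()),
        "percentage": float(total / n_sites),
    }


def glrlm_features(levels: np.ndarray, n_levels: int,
                   directions=DIRECTIONS_13) -> dict[str, float]:
    """GLRLM features averaged over the 13 unique 3-D directions."""
    n_sites = int((levels > 0).sum())
    per_dir = []
    for d in directions:
        m = glrlm_matrix(levels, d, n_levels)
        f = _rl_sz_features(m, "short_run_emphasis", "long_run_emphasis", n_sites)
        if f:
            per_dir.append(f)
    if not per_dir:
        return {}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def glszm_zones(levels: np.ndarray, n_levels: int) -> list[tuple[int, int]]:
    """All (grey level, zone size) pairs; a zone is a 26-connected set of equal level."""
    zones = []
    for lvl in range(1, n_levels + 1):
        lab, n = ndimage.label(levels == lvl, structure=STRUCT_26)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((lvl, int(s)) for s in sizes)
    return zones


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    zones = glszm_zones(levels, n_levels)
    if not zones:
        return np.zeros((n_levels, 1))
    max_size = max(s for _, s in zones)
    m = np.zeros((n_levels, max_size))
    for lvl, s in zones:
        m[lvl - 1, s - 1] += 1
    return m


def glszm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    n_sites = int((levels > 0).sum())
    m = glszm_matrix(levels, n_levels)
    return _rl_sz_features(m, "small_area_emphasis", "large_area_emphasis", n_sites)


def ngtdm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Neighbourhood grey-tone difference features (26-neighbourhood)."""
    in_mask = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nbr_sum = ndimage.convolve(np.where(in_mask, levels, 0).astype(float), kernel,
                               mode="constant")
    nbr_cnt = ndimage.convolve(in_mask.astype(float), kernel, mode="constant")
    valid = in_mask & (nbr_cnt > 0)
    if not valid.any():
        return {}
    abar = nbr_sum[valid] / nbr_cnt[valid]
    lv = levels[valid]
    n_total = int(valid.sum())
    s = np.zeros(n_levels)
    n_i = np.zeros(n_levels)
    np.add.at(s, lv - 1, np.abs(lv - abar))
    np.add.at(n_i, lv - 1, 1)
    p = n_i / n_total
    present = p > 0
    n_g = int(present.sum())
    ii = np.arange(1, n_levels + 1, dtype=float)

    coarseness = 1.0 / max((p * s).sum(), _EPS)
    if n_g > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        li, lj = np.meshgrid(ii, ii, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = float(
            (pi * pj * (li - lj) ** 2)[both].sum() / (n_g * (n_g - 1))
            * s.sum() / n_total
        )
        num = (pi * li - pj * lj)
        busyness = float(
            (p * s).sum() / max(np.abs(num[both]).sum(), _EPS)
        )
        si, sj = np.meshgrid(s, s, indexing="ij")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(both, (pi * si + pj * sj) / np.where(both, pi + pj, 1.0), 0.0)
        complexity = float((np.abs(li - lj)[both] * ratio[both]).sum() / n_total)
        strength = float(
            ((pi + pj) * (li - lj) ** 2)[both].sum() / max(s.sum(), _EPS)
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "coarseness": float(coarseness),
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
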