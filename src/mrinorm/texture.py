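"""Grey-level texture matrices and their features.

Implements the six matrix families of the standard radiomics taxonomy —
co-occurrence (GLCM), run length (GLRLM), size zone (GLSZM), distance zone
(GLDZM), neighbouring grey level dependence (NGLDM) and neighbourhood grey
tone difference (NGTDM) — on integer grey-level arrays produced by
fixed-bin-number discretization (level 0 marks voxels outside the mask).

Conventions: 26-connectivity for 3D zones and neighbourhoods, city-block
distance to the mask border for distance zones, and features per the IBSI
reference nomenclature. Feature values that are mathematically undefined on
an input (e.g. correlation of a single-level matrix) are returned as NaN;
the caller flags them, never drops them.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_3D",
    "DIRECTIONS_2D",
    "cooccurrence_matrix",
    "merged_cooccurrence",
    "run_length_matrix",
    "size_zone_matrix",
    "distance_zone_matrix",
    "dependence_matrix",
    "gray_tone_difference",
    "texture_matrices",
    "glcm_features",
    "szm_style_features",
    "ngldm_features",
    "ngtdm_features",
    "GLCM_FEATURE_NAMES",
    "SZM_SUFFIXES",
    "NGLDM_FEATURE_NAMES",
    "NGTDM_FEATURE_NAMES",
]


def _unique_directions_3d() -> list[tuple[int, int, int]]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                first = next(v for v in d if v != 0)
                if first > 0:
                    dirs.append(d)
    return dirs


#: 13 unique 3D directions (one per opposite pair of the 26-neighbourhood).
DIRECTIONS_3D: list[tuple[int, int, int]] = _unique_directions_3d()
#: 4 unique in-plane directions for per-slice (2D) aggregation.
DIRECTIONS_2D: list[tuple[int, int, int]] = [(1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0)]


def _pair_slices(shape, offset):
    sl_a, sl_b = [], []
    for n, d in zip(shape, offset):
        sl_a.append(slice(max(0, -d), n - max(0, d)))
        sl_b.append(slice(max(0, d), n - max(0, -d)))
    return tuple(sl_a), tuple(sl_b)


def _glcm_counts(levels: np.ndarray, n_levels: int, offset, symmetric: bool) -> np.ndarray:
    sl_a, sl_b = _pair_slices(levels.shape, offset)
    a, b = levels[sl_a], levels[sl_b]
    valid = (a > 0) & (b > 0)
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    if valid.any():
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    if symmetric:
        counts = counts + counts.T
    return counts


def cooccurrence_matrix(levels: np.ndarray, n_levels: int, offset,
                        symmetric: bool = True) -> np.ndarray:
    """Probability co-occurrence matrix at one offset.

    Counts ordered level pairs (x, x+offset) with both voxels inside the
    mask (level > 0); symmetric mode adds the transpose; normalized to
    sum 1. Raises if the offset yields no valid pair.
    """
    if not any(offset):
        raise ValueError("offset must be nonzero")
    counts = _glcm_counts(np.asarray(levels), n_levels, tuple(offset), symmetric)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no valid voxel pairs at offset {tuple(offset)}")
    return counts / total


def merged_cooccurrence(levels: np.ndarray, n_levels: int, offsets,
                        symmetric: bool = True) -> np.ndarray | None:
    """Merge counts over several offsets into one probability matrix;
    None when no offset yields a pair."""
    levels = np.asarray(levels)
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    for off in offsets:
        counts += _glcm_counts(levels, n_levels, tuple(off), symmetric)
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def _runs(levels: np.ndarray, direction) -> tuple[np.ndarray, np.ndarray]:
    """Run levels and lengths of equal-level runs along one direction.

    A run is a maximal sequence of mask voxels with identical level along
    the lattice line with step ``direction``; out-of-mask voxels break runs.
    """
    d = np.asarray(direction, dtype=np.int64)
    pts = np.argwhere(levels > 0)
    if pts.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lv = levels[pts[:, 0], pts[:, 1], pts[:, 2]].astype(np.int64)
    c = int(np.flatnonzero(d)[0])
    t = pts[:, c] * d[c]
    lid = pts - t[:, None] * d
    order = np.lexsort((t, lid[:, 2], lid[:, 1], lid[:, 0]))
    t_s, lid_s, lv_s = t[order], lid[order], lv[order]
    if len(t_s) == 1:
        cont = np.empty(0, dtype=bool)
    else:
        cont = ((np.diff(t_s) == 1)
                & np.all(np.diff(lid_s, axis=0) == 0, axis=1)
                & (np.diff(lv_s) == 0))
    starts = np.concatenate(([0], np.flatnonzero(~cont) + 1))
    bounds = np.concatenate((starts, [len(t_s)]))
    lengths = np.diff(bounds)
    return lv_s[starts], lengths


def run_length_matrix(levels: np.ndarray, n_levels: int, directions,
                      merge: bool = True) -> np.ndarray:
    """Count matrix M[level, run length] merged over ``directions``."""
    levels = np.asarray(levels)
    max_len = max(levels.shape)
    M = np.zeros((n_levels, max_len), dtype=np.float64)
    for d in directions:
        run_lv, run_len = _runs(levels, d)
        if run_lv.size:
            np.add.at(M, (run_lv - 1, run_len - 1), 1.0)
    return _trim_cols(M)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _zones(levels: np.ndarray, n_levels: int):
    """Yield (level, zone_sizes, zone_labels, labeled_array) per level with
    26-connected equal-level zones."""
    for g in range(1, n_levels + 1):
        binary = levels == g
        if not binary.any():
            continue
        lab, nlab = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        yield g, sizes, np.arange(1, nlab + 1), lab


def size_zone_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Count matrix M[level, zone size] of 26-connected equal-level zones."""
    levels = np.asarray(levels)
    M = np.zeros((n_levels, int(levels.size)), dtype=np.float64)
    for g, sizes, _, _ in _zones(levels, n_levels):
        np.add.at(M, (np.full(len(sizes), g - 1), sizes - 1), 1.0)
    return _trim_cols(M)


def border_distance_map(mask: np.ndarray) -> np.ndarray:
    """City-block distance from each mask voxel to the nearest voxel outside
    the mask (image border counts as outside); border voxels get 1."""
    padded = np.pad(np.asarray(mask) > 0, 1)
    d = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return np.asarray(d)[1:-1, 1:-1, 1:-1]


def distance_zone_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Count matrix M[level, zone distance] with zone distance the minimum
    city-block border distance over the zone's voxels."""
    levels = np.asarray(levels)
    dmap = border_distance_map(levels > 0)
    max_d = int(dmap.max()) if dmap.size else 1
    M = np.zeros((n_levels, max(max_d, 1)), dtype=np.float64)
    for g, sizes, idx, lab in _zones(levels, n_levels):
        dmin = ndimage.minimum(dmap, labels=lab, index=idx)
        dmin = np.atleast_1d(np.asarray(dmin, dtype=np.int64))
        np.add.at(M, (np.full(len(dmin), g - 1), dmin - 1), 1.0)
    return _trim_cols(M)


def _neighbor_shifts():
    return [d for d in _all_26()]


def _all_26():
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) != (0, 0, 0):
                    out.append((dx, dy, dz))
    return out


def dependence_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """NGLDM count matrix S[level, dependence count + 1].

    The dependence count of a mask voxel is the number of its 26-neighbours
    inside the mask whose level differs by at most ``alpha`` (default 0:
    identical level).
    """
    levels = np.asarray(levels)
    inmask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _all_26():
        sl_a, sl_b = _pair_slices(levels.shape, off)
        a, b = levels[sl_a], levels[sl_b]
        ok = inmask[sl_a] & inmask[sl_b] & (np.abs(a - b) <= alpha)
        dep[sl_a] += ok
    S = np.zeros((n_levels, 27), dtype=np.float64)
    np.add.at(S, (levels[inmask] - 1, dep[inmask]), 1.0)
    return _trim_cols(S)


def gray_tone_difference(levels: np.ndarray, n_levels: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """NGTDM vectors: per level g, ``s[g]`` the summed absolute difference
    between g and the mean level of each voxel's in-mask 26-neighbourhood,
    and ``n[g]`` the voxel count (voxels with no in-mask neighbour are
    excluded)."""
    levels = np.asarray(levels, dtype=np.float64)
    inmask = levels > 0
    nsum = np.zeros(levels.shape)
    ncnt = np.zeros(levels.shape)
    for off in _all_26():
        sl_a, sl_b = _pair_slices(levels.shape, off)
        contrib = np.where(inmask[sl_b], levels[sl_b], 0.0)
        nsum[sl_a] += contrib
        ncnt[sl_a] += inmask[sl_b]
    valid = inmask & (ncnt > 0)
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    g_here = levels[valid]
    avg = nsum[valid] / ncnt[valid]
    diff = np.abs(g_here - avg)
    np.add.at(s, g_here.astype(np.int64) - 1, diff)
    np.add.at(n, g_here.astype(np.int64) - 1, 1.0)
    return s, n


def texture_matrices(levels: np.ndarray, n_levels: int) -> dict:
    """All raw 3D texture matrices for one discretized region."""
    if not (np.asarray(levels) > 0).any():
        raise ValueError("empty mask: no in-mask levels")
    return {
        "GLRLM": run_length_matrix(levels, n_levels, DIRECTIONS_3D),
        "GLSZM": size_zone_matrix(levels, n_levels),
        "GLDZM": distance_zone_matrix(levels, n_levels),
        "NGLDM": dependence_matrix(levels, n_levels),
        "NGTDM": gray_tone_difference(levels, n_levels),
    }


def _trim_cols(M: np.ndarray) -> np.ndarray:
    """Drop trailing all-zero columns (keep at least one)."""
    nz = np.flatnonzero(M.sum(axis=0))
    last = int(nz[-1]) + 1 if nz.size else 1
    return M[:, :last]


# ---------------------------------------------------------------------------
# feature computation
# ---------------------------------------------------------------------------

GLCM_FEATURE_NAMES = [
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy",
    "angular_second_moment", "contrast", "dissimilarity",
    "inverse_difference", "inverse_difference_normalized",
    "inverse_difference_moment", "inverse_difference_moment_normalized",
    "inverse_variance", "correlation", "autocorrelation",
    "cluster_tendency", "cluster_shade", "cluster_prominence",
    "information_correlation_1", "information_correlation_2",
]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 25 co-occurrence features of a probability matrix (sum 1)."""
    N = P.shape[0]
    i = np.arange(1, N + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(0, N)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * N + 1)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])

    f: dict[str, float] = {}
    f["joint_maximum"] = float(P.max())
    mu = float((ii * P).sum())
    f["joint_average"] = mu
    f["joint_variance"] = float(((ii - mu) ** 2 * P).sum())
    f["joint_entropy"] = _entropy(P.ravel())
    da = float((k_diff * p_diff).sum())
    f["difference_average"] = da
    f["difference_variance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    f["difference_entropy"] = _entropy(p_diff)
    sa = float((k_sum * p_sum).sum())
    f["sum_average"] = sa
    f["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    f["sum_entropy"] = _entropy(p_sum)
    f["angular_second_moment"] = float((P ** 2).sum())
    f["contrast"] = float(((ii - jj) ** 2 * P).sum())
    f["dissimilarity"] = float((np.abs(ii - jj) * P).sum())
    f["inverse_difference"] = float((P / (1.0 + np.abs(ii - jj))).sum())
    f["inverse_difference_normalized"] = float((P / (1.0 + np.abs(ii - jj) / N)).sum())
    f["inverse_difference_moment"] = float((P / (1.0 + (ii - jj) ** 2)).sum())
    f["inverse_difference_moment_normalized"] = float(
        (P / (1.0 + (ii - jj) ** 2 / N ** 2)).sum())
    off = ii != jj
    f["inverse_variance"] = float((P[off] / (ii[off] - jj[off]) ** 2).sum())
    denom = np.sqrt(var_x * var_y)
    f["correlation"] = (float(((ii * jj * P).sum() - mu_x * mu_y) / denom)
                        if denom > 0 else float("nan"))
    f["autocorrelation"] = float((ii * jj * P).sum())
    cdev = ii + jj - mu_x - mu_y
    f["cluster_tendency"] = float((cdev ** 2 * P).sum())
    f["cluster_shade"] = float((cdev ** 3 * P).sum())
    f["cluster_prominence"] = float((cdev ** 4 * P).sum())
    hxy = f["joint_entropy"]
    hx = _entropy(px)
    pxpy = np.outer(px, py)
    pos = pxpy > 0
    hxy1 = float(-(P[pos] * np.log2(pxpy[pos])).sum())
    hxy2 = _entropy(pxpy.ravel())
    f["information_correlation_1"] = ((hxy - hxy1) / hx if hx > 0 else float("nan"))
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    f["information_correlation_2"] = float(np.sqrt(max(arg, 0.0)))
    return f


#: Generic size-zone-style feature suffixes; {ax} is the class's axis word
#: (run/zone) and {axlong} its long form (run_length/zone_size/zone_distance).
SZM_SUFFIXES = [
    "small_{ax}_emphasis", "large_{ax}_emphasis",
    "low_grey_level_emphasis", "high_grey_level_emphasis",
    "small_{ax}_low_grey_level_emphasis", "small_{ax}_high_grey_level_emphasis",
    "large_{ax}_low_grey_level_emphasis", "large_{ax}_high_grey_level_emphasis",
    "grey_level_non_uniformity", "grey_level_non_uniformity_normalized",
    "{axlong}_non_uniformity", "{axlong}_non_uniformity_normalized",
    "{ax}_percentage", "grey_level_variance", "{axlong}_variance",
    "{axlong}_entropy",
]


def szm_style_features(M: np.ndarray, n_voxels: int, ax: str, axlong: str
                       ) -> dict[str, float]:
    """The common 16-feature family shared by GLRLM / GLSZM / GLDZM.

    ``M`` is a count matrix (rows: grey level, columns: run length / zone
    size / zone distance, 1-based); ``n_voxels`` is the number of mask
    voxels for the percentage feature.
    """
    Ns = M.sum()
    if Ns == 0:
        return {s.format(ax=ax, axlong=axlong): float("nan") for s in SZM_SUFFIXES}
    Ng, Nj = M.shape
    i = np.arange(1, Ng + 1, dtype=np.float64)
    j = np.arange(1, Nj + 1, dtype=np.float64)
    r = M.sum(axis=1)
    c = M.sum(axis=0)
    p = M / Ns
    mu_i = float((i * r).sum() / Ns)
    mu_j = float((j * c).sum() / Ns)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    f = {
        f"small_{ax}_emphasis": float((c / j ** 2).sum() / Ns),
        f"large_{ax}_emphasis": float((c * j ** 2).sum() / Ns),
        "low_grey_level_emphasis": float((r / i ** 2).sum() / Ns),
        "high_grey_level_emphasis": float((r * i ** 2).sum() / Ns),
        f"small_{ax}_low_grey_level_emphasis": float((M / (ii ** 2 * jj ** 2)).sum() / Ns),
        f"small_{ax}_high_grey_level_emphasis": float((M * ii ** 2 / jj ** 2).sum() / Ns),
        f"large_{ax}_low_grey_level_emphasis": float((M * jj ** 2 / ii ** 2).sum() / Ns),
        f"large_{ax}_high_grey_level_emphasis": float((M * ii ** 2 * jj ** 2).sum() / Ns),
        "grey_level_non_uniformity": float((r ** 2).sum() / Ns),
        "grey_level_non_uniformity_normalized": float((r ** 2).sum() / Ns ** 2),
        f"{axlong}_non_uniformity": float((c ** 2).sum() / Ns),
        f"{axlong}_non_uniformity_normalized": float((c ** 2).sum() / Ns ** 2),
        f"{ax}_percentage": float(Ns / n_voxels),
        "grey_level_variance": float((p * (ii - mu_i) ** 2).sum()),
        f"{axlong}_variance": float((p * (jj - mu_j) ** 2).sum()),
        f"{axlong}_entropy": _entropy(p.ravel()),
    }
    return f


NGLDM_FEATURE_NAMES = [
    "low_dependence_emphasis", "high_dependence_emphasis",
    "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis",
    "grey_level_non_uniformity", "grey_level_non_uniformity_normalized",
    "dependence_count_non_uniformity", "dependence_count_non_uniformity_normalized",
    "dependence_count_percentage", "grey_level_variance",
    "dependence_count_variance", "dependence_count_entropy",
    "dependence_count_energy",
]


def ngldm_features(S: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 17 neighbouring-grey-level-dependence features.

    Column k of ``S`` holds dependence count k (axis value j = k + 1)."""
    base = szm_style_features(S, n_voxels, ax="dependence", axlong="dependence_count")
    p = S / S.sum() if S.sum() else S
    f = {
        "low_dependence_emphasis": base["small_dependence_emphasis"],
        "high_dependence_emphasis": base["large_dependence_emphasis"],
        "low_grey_level_count_emphasis": base["low_grey_level_emphasis"],
        "high_grey_level_count_emphasis": base["high_grey_level_emphasis"],
        "low_dependence_low_grey_level_emphasis":
            base["small_dependence_low_grey_level_emphasis"],
        "low_dependence_high_grey_level_emphasis":
            base["small_dependence_high_grey_level_emphasis"],
        "high_dependence_low_grey_level_emphasis":
            base["large_dependence_low_grey_level_emphasis"],
        "high_dependence_high_grey_level_emphasis":
            base["large_dependence_high_grey_level_emphasis"],
        "grey_level_non_uniformity": base["grey_level_non_uniformity"],
        "grey_level_non_uniformity_normalized":
            base["grey_level_non_uniformity_normalized"],
        "dependence_count_non_uniformity": base["dependence_count_non_uniformity"],
        "dependence_count_non_uniformity_normalized":
            base["dependence_count_non_uniformity_normalized"],
        "dependence_count_percentage": base["dependence_percentage"],
        "grey_level_variance": base["grey_level_variance"],
        "dependence_count_variance": base["dependence_count_variance"],
        "dependence_count_entropy": base["dependence_count_entropy"],
        "dependence_count_energy": float((p ** 2).sum()),
    }
    return f


NGTDM_FEATURE_NAMES = ["coarseness", "contrast", "busyness", "complexity", "strength"]


def ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    """The 5 neighbourhood-grey-tone-difference features."""
    nv = n.sum()
    if nv == 0:
        return {k: float("nan") for k in NGTDM_FEATURE_NAMES}
    p = n / nv
    present = p > 0
    g = np.arange(1, len(n) + 1, dtype=np.float64)
    ngp = int(present.sum())
    f: dict[str, float] = {}
    denom = float((p * s).sum())
    f["coarseness"] = 1.0 / denom if denom > 0 else float("nan")
    if ngp > 1:
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        gi, gj = np.meshgrid(g[present], g[present], indexing="ij")
        f["contrast"] = float((pi * pj * (gi - gj) ** 2).sum()
                              / (ngp * (ngp - 1)) * s.sum() / nv)
        bus_den = float(np.abs(gi * pi - gj * pj)[gi != gj].sum())
        f["busyness"] = denom / bus_den if bus_den > 0 else float("nan")
        si = s[present]
        si_i, si_j = np.meshgrid(si, si, indexing="ij")
        f["complexity"] = float((np.abs(gi - gj)
                                 * (pi * si_i + pj * si_j) / (pi + pj)).sum() / nv)
        str_num = float(((pi + pj) * (gi - gj) ** 2).sum())
        f["strength"] = str_num / s.sum() if s.sum() > 0 else float("nan")
    else:
        f["contrast"] = float("nan")
        f["busyness"] = float("nan")
        f["complexity"] = float("nan")
        f["strength"] = float("nan")
    return f
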