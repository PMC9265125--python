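"""Five 3D texture-matrix families on a quantized VOI.

All families use the 26-neighborhood at Chebyshev distance 1. Directed
families (GLCM, GLRLM) merge counts over the 13 unique 3D direction
vectors (both orientations for GLCM symmetry) into a single matrix before
normalization, rather than averaging per-direction features. The GLSZM
uses 26-connected equal-level zones; the NGLDM dependence threshold is
alpha = 0 (neighbors count only when their level is identical); the NGTDM
compares each voxel's level with the mean level of its in-VOI neighbors.

Feature rosters (11 GLCM / 13 GLRLM / 13 GLSZM / 16 NGLDM / 5 NGTDM) are
fixed by the registry in ``data/feature_registry.yaml``; features with a
variance denominator (e.g. GLCM correlation of a constant VOI) return 0
when that variance vanishes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import QuantizedVoi

#: the 13 unique direction vectors of the 26-neighborhood (one orientation each)
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_EPS = 1e-6  # NGTDM coarseness guard


def _pair_views(arr: np.ndarray, off) -> tuple[np.ndarray, np.ndarray]:
    """Views (a, b) with b displaced by ``off`` voxels relative to a."""
    sl_a, sl_b = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def _pair_slices(shape, off):
    sl_a, sl_b = [], []
    for o, n in zip(off, shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return tuple(sl_a), tuple(sl_b)


# ---------------------------------------------------------------- GLCM


def glcm_matrix(q: QuantizedVoi) -> np.ndarray:
    """Symmetric co-occurrence probabilities merged over the 13 directions."""
    if q.voxel_count < 2:
        raise ValueError("GLCM requires a VOI with at least 2 voxels")
    nb = q.n_bins
    counts = np.zeros((nb, nb))
    for off in DIRECTIONS_13:
        lv_a, lv_b = _pair_views(q.levels, off)
        m_a, m_b = _pair_views(q.mask, off)
        ok = m_a & m_b
        if ok.any():
            idx = (lv_a[ok] - 1) * nb + (lv_b[ok] - 1)
            counts += np.bincount(idx, minlength=nb * nb).reshape(nb, nb)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs in the VOI")
    return counts / total


def glcm_features(q: QuantizedVoi) -> dict[str, float]:
    p = glcm_matrix(q)
    nb = p.shape[0]
    i = np.arange(1, nb + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    diff2 = (I - J) ** 2
    absdiff = np.abs(I - J)
    p_sum = np.bincount((I + J).astype(int).ravel(), weights=p.ravel())
    p_diff = np.bincount(absdiff.astype(int).ravel(), weights=p.ravel())
    k_sum = np.arange(p_sum.size, dtype=np.float64)

    def _entropy(w):
        w = w[w > 0]
        return float(-(w * np.log2(w)).sum())

    correlation = 0.0
    if var > 0:
        correlation = float(((I * J * p).sum() - mu * mu) / var)
    return {
        "angular_second_moment": float((p**2).sum()),
        "contrast": float((diff2 * p).sum()),
        "correlation": correlation,
        "variance": var,
        "inverse_difference_moment": float((p / (1.0 + diff2)).sum()),
        "sum_average": float((k_sum * p_sum).sum()),
        "sum_entropy": _entropy(p_sum),
        "entropy": _entropy(p),
        "difference_entropy": _entropy(p_diff),
        "dissimilarity": float((absdiff * p).sum()),
        "inverse_difference": float((p / (1.0 + absdiff)).sum()),
    }


# ---------------------------------------------------------------- GLRLM


def glrlm_matrix(q: QuantizedVoi) -> np.ndarray:
    """Counts of maximal equal-level runs, merged over the 13 directions.

    Entry (g-1, l-1) is the number of runs of gray level g and length l.
    """
    shape = q.levels.shape
    nb = q.n_bins
    max_len = max(shape)
    counts = np.zeros((nb, max_len), dtype=np.int64)
    for off in DIRECTIONS_13:
        sl_a, sl_b = _pair_slices(shape, off)
        # fwd[v]: v and v+off are both VOI voxels with equal level
        fwd = np.zeros(shape, dtype=bool)
        fwd[sl_a] = (
            q.mask[sl_a] & q.mask[sl_b] & (q.levels[sl_a] == q.levels[sl_b])
        )
        # run starts: VOI voxels whose -off neighbor does not continue the run
        bwd = np.zeros(shape, dtype=bool)
        bwd[sl_b] = fwd[sl_a]
        starts = q.mask & ~bwd
        # forward extension length: ext[v] = fwd[v] * (1 + ext[v + off])
        ext = np.zeros(shape, dtype=np.int32)
        while True:
            nxt = np.zeros_like(ext)
            nxt[sl_a] = fwd[sl_a] * (1 + ext[sl_b])
            if np.array_equal(nxt, ext):
                break
            ext = nxt
        run_len = 1 + ext[starts]
        lv = q.levels[starts]
        idx = (lv.astype(np.int64) - 1) * max_len + (run_len - 1)
        counts += np.bincount(idx, minlength=nb * max_len).reshape(nb, max_len)
    return counts


def _run_zone_features(R: np.ndarray, prefix: str) -> dict[str, float]:
    """Shared run-length / size-zone statistics from a count matrix R."""
    n = float(R.sum())
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)  # gray level
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)  # run length / zone size
    I, J = np.meshgrid(i, j, indexing="ij")
    p = R / n
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float((i * p_i).sum())
    mu_j = float((j * p_j).sum())
    short_tag, long_tag = ("short_run", "long_run") if prefix == "run" else (
        "small_zone", "large_zone")
    unit = "run" if prefix == "run" else "zone_size"
    return {
        f"{short_tag}_emphasis": float((p / J**2).sum()),
        f"{long_tag}_emphasis": float((p * J**2).sum()),
        "gray_level_nonuniformity": float((R.sum(axis=1) ** 2).sum() / n),
        f"{unit}_nonuniformity": float((R.sum(axis=0) ** 2).sum() / n),
        "low_gray_level_emphasis": float((p / I**2).sum()),
        "high_gray_level_emphasis": float((p * I**2).sum()),
        f"{short_tag}_low_gray_level_emphasis": float((p / (I**2 * J**2)).sum()),
        f"{short_tag}_high_gray_level_emphasis": float((p * I**2 / J**2).sum()),
        f"{long_tag}_low_gray_level_emphasis": float((p * J**2 / I**2).sum()),
        f"{long_tag}_high_gray_level_emphasis": float((p * I**2 * J**2).sum()),
        "gray_level_variance": float((p * (I - mu_i) ** 2).sum()),
        f"{unit}_variance": float((p * (J - mu_j) ** 2).sum()),
    }


def glrlm_features(q: QuantizedVoi) -> dict[str, float]:
    R = glrlm_matrix(q)
    feats = _run_zone_features(R, "run")
    # run percentage: runs per voxel per direction, in (0, 1]
    feats["run_percentage"] = float(
        R.sum() / (q.voxel_count * len(DIRECTIONS_13))
    )
    order = (
        "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
        "run_nonuniformity", "run_percentage", "low_gray_level_emphasis",
        "high_gray_level_emphasis", "short_run_low_gray_level_emphasis",
        "short_run_high_gray_level_emphasis", "long_run_low_gray_level_emphasis",
        "long_run_high_gray_level_emphasis", "gray_level_variance",
        "run_variance",
    )
    return {k: feats[k] for k in order}


# ---------------------------------------------------------------- GLSZM


def glszm_matrix(q: QuantizedVoi) -> np.ndarray:
    """Counts of 26-connected equal-level zones by level and size."""
    nb = q.n_bins
    structure = np.ones((3, 3, 3), dtype=bool)
    per_level: dict[int, np.ndarray] = {}
    max_size = 1
    for g in np.unique(q.voi_levels):
        labeled, n_zones = ndimage.label(q.levels == g, structure=structure)
        if n_zones:
            sizes = np.bincount(labeled.ravel())[1:]
            per_level[int(g)] = sizes
            max_size = max(max_size, int(sizes.max()))
    counts = np.zeros((nb, max_size), dtype=np.int64)
    for g, sizes in per_level.items():
        counts[g - 1] += np.bincount(sizes - 1, minlength=max_size)
    return counts


def glszm_features(q: QuantizedVoi) -> dict[str, float]:
    Z = glszm_matrix(q)
    feats = _run_zone_features(Z, "zone")
    feats["zone_percentage"] = float(Z.sum() / q.voxel_count)
    order = (
        "small_zone_emphasis", "large_zone_emphasis", "gray_level_nonuniformity",
        "zone_size_nonuniformity", "zone_percentage", "low_gray_level_emphasis",
        "high_gray_level_emphasis", "small_zone_low_gray_level_emphasis",
        "small_zone_high_gray_level_emphasis", "large_zone_low_gray_level_emphasis",
        "large_zone_high_gray_level_emphasis", "gray_level_variance",
        "zone_size_variance",
    )
    return {k: feats[k] for k in order}


# ---------------------------------------------------------------- NGLDM


def ngldm_matrix(q: QuantizedVoi) -> np.ndarray:
    """Dependence counts: entry (g-1, k) is the number of VOI voxels of
    level g with exactly k identical-level neighbors (k = 0..26)."""
    shape = q.levels.shape
    dep = np.zeros(shape, dtype=np.int32)
    for off in DIRECTIONS_13:
        sl_a, sl_b = _pair_slices(shape, off)
        eq = q.mask[sl_a] & q.mask[sl_b] & (q.levels[sl_a] == q.levels[sl_b])
        dep[sl_a] += eq
        dep[sl_b] += eq
    nb = q.n_bins
    idx = (q.levels[q.mask].astype(np.int64) - 1) * 27 + dep[q.mask]
    return np.bincount(idx, minlength=nb * 27).reshape(nb, 27)


def ngldm_features(q: QuantizedVoi) -> dict[str, float]:
    M = ngldm_matrix(q).astype(np.float64)
    ns = M.sum()
    i = np.arange(1, M.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, M.shape[1] + 1, dtype=np.float64)  # dependence + 1
    I, J = np.meshgrid(i, j, indexing="ij")
    p = M / ns
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float((i * p_i).sum())
    mu_j = float((j * p_j).sum())
    pj_pos = p_j[p_j > 0]
    return {
        "low_dependence_emphasis": float((p / J**2).sum()),
        "high_dependence_emphasis": float((p * J**2).sum()),
        "gray_level_nonuniformity": float((M.sum(axis=1) ** 2).sum() / ns),
        "gray_level_nonuniformity_normalized": float(
            (M.sum(axis=1) ** 2).sum() / ns**2
        ),
        "dependence_count_nonuniformity": float((M.sum(axis=0) ** 2).sum() / ns),
        "dependence_count_nonuniformity_normalized": float(
            (M.sum(axis=0) ** 2).sum() / ns**2
        ),
        "low_gray_level_count_emphasis": float((p / I**2).sum()),
        "high_gray_level_count_emphasis": float((p * I**2).sum()),
        "low_dependence_low_gray_level_emphasis": float((p / (I**2 * J**2)).sum()),
        "low_dependence_high_gray_level_emphasis": float((p * I**2 / J**2).sum()),
        "high_dependence_low_gray_level_emphasis": float((p * J**2 / I**2).sum()),
        "high_dependence_high_gray_level_emphasis": float((p * I**2 * J**2).sum()),
        "gray_level_variance": float((p * (I - mu_i) ** 2).sum()),
        "dependence_count_variance": float((p * (J - mu_j) ** 2).sum()),
        "dependence_count_entropy": float(-(pj_pos * np.log2(pj_pos)).sum()),
        "dependence_count_energy": float((p_j**2).sum()),
    }


# ---------------------------------------------------------------- NGTDM


def ngtdm_table(q: QuantizedVoi) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) for i = 1..n_bins: per-level occurrence counts and sums of
    absolute differences from the neighborhood mean level. Only VOI voxels
    with at least one in-VOI neighbor contribute."""
    shape = q.levels.shape
    nbr_sum = np.zeros(shape, dtype=np.float64)
    nbr_cnt = np.zeros(shape, dtype=np.int32)
    for off in DIRECTIONS_13:
        sl_a, sl_b = _pair_slices(shape, off)
        both = q.mask[sl_a] & q.mask[sl_b]
        nbr_sum[sl_a] += q.levels[sl_b] * both
        nbr_sum[sl_b] += q.levels[sl_a] * both
        nbr_cnt[sl_a] += both
        nbr_cnt[sl_b] += both
    valid = q.mask & (nbr_cnt > 0)
    lv = q.levels[valid].astype(np.int64)
    diff = np.abs(lv - nbr_sum[valid] / nbr_cnt[valid])
    nb = q.n_bins
    n_i = np.bincount(lv - 1, minlength=nb).astype(np.float64)
    s_i = np.bincount(lv - 1, weights=diff, minlength=nb)
    return n_i, s_i


def ngtdm_features(q: QuantizedVoi) -> dict[str, float]:
    n_i, s_i = ngtdm_table(q)
    nvb = n_i.sum()
    p = n_i / nvb if nvb > 0 else n_i
    i = np.arange(1, q.n_bins + 1, dtype=np.float64)
    occ = p > 0
    ng_p = int(occ.sum())
    io, po, so = i[occ], p[occ], s_i[occ]
    ps = float((p * s_i).sum())

    coarseness = 1.0 / max(ps, _EPS)
    contrast = 0.0
    if ng_p > 1:
        contrast = float(
            (po[:, None] * po[None, :] * (io[:, None] - io[None, :]) ** 2).sum()
            / (ng_p * (ng_p - 1))
            * s_i.sum()
            / nvb
        )
    busy_den = float(np.abs(io[:, None] * po[:, None] - io[None, :] * po[None, :]).sum())
    busyness = ps / busy_den if busy_den > 0 else 0.0
    absdiff = np.abs(io[:, None] - io[None, :])
    complexity = float(
        (
            absdiff
            * (po[:, None] * so[:, None] + po[None, :] * so[None, :])
            / (po[:, None] + po[None, :])
        ).sum()
        / nvb
    )
    s_sum = float(s_i.sum())
    strength = (
        float(((po[:, None] + po[None, :]) * absdiff**2).sum()) / s_sum
        if s_sum > 0
        else 0.0
    )
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


TEXTURE_FAMILY_FUNCS = {
    "GLCM": glcm_features,
    "GLRLM": glrlm_features,
    "GLSZM": glszm_features,
    "NGLDM": ngldm_features,
    "NGTDM": ngtdm_features,
}


def texture_features(q: QuantizedVoi) -> dict[str, dict[str, float]]:
    """All five families' features for one quantized VOI."""
    return {fam: fn(q) for fam, fn in TEXTURE_FAMILY_FUNCS.items()}
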