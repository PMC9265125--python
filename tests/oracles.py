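"""Independent brute-force reference implementations.

Everything here is deliberately written as plain Python loops over voxels,
pairs, runs and zones — no shared code with the package's vectorized
implementations — so that agreement is a genuine cross-check and not a
tautology.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

NEIGHBOR_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

# one orientation per axis pair: keep an offset only if its negation is absent
DIRECTIONS_13: list[tuple[int, int, int]] = []
for off in NEIGHBOR_OFFSETS_26:
    if (-off[0], -off[1], -off[2]) not in DIRECTIONS_13:
        DIRECTIONS_13.append(off)


def _in_bounds(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


def _voi_voxels(mask):
    return [tuple(v) for v in np.argwhere(mask)]


# ------------------------------------------------------------- wavelet


def separable_convolve_oracle(volume: np.ndarray, taps_per_axis) -> np.ndarray:
    """Triple-loop separable convolution with symmetric padding.

    Convention: y[i] = sum_k w[k] * x_padded[i + len(w)//2 - k], matching a
    centered true convolution with mirror boundary.
    """
    out = np.asarray(volume, dtype=np.float64)
    for axis, taps in enumerate(taps_per_axis):
        w = list(taps)
        pad = len(w)
        c = len(w) // 2
        moved = np.moveaxis(out, axis, -1)
        res = np.zeros_like(moved)
        n = moved.shape[-1]
        for idx in np.ndindex(moved.shape[:-1]):
            line = moved[idx]
            padded = np.pad(line, pad, mode="symmetric")
            for i in range(n):
                acc = 0.0
                for k in range(len(w)):
                    acc += w[k] * padded[pad + i + c - k]
                res[idx][i] = acc
        out = np.moveaxis(res, -1, axis)
    return out


# ---------------------------------------------------------------- GLCM


def glcm_probabilities(levels, mask):
    counts = defaultdict(float)
    shape = mask.shape
    total = 0.0
    for v in _voi_voxels(mask):
        g = int(levels[v])
        for off in NEIGHBOR_OFFSETS_26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _in_bounds(w, shape) and mask[w]:
                counts[(g, int(levels[w]))] += 1.0
                total += 1.0
    return {k: c / total for k, c in counts.items()}


def glcm_features_oracle(levels, mask):
    p = glcm_probabilities(levels, mask)
    mu = sum(i * v for (i, _), v in p.items())
    var = sum((i - mu) ** 2 * v for (i, _), v in p.items())
    p_sum = defaultdict(float)
    p_diff = defaultdict(float)
    for (i, j), v in p.items():
        p_sum[i + j] += v
        p_diff[abs(i - j)] += v
    corr = 0.0
    if var > 0:
        corr = (sum(i * j * v for (i, j), v in p.items()) - mu * mu) / var
    ent = lambda d: -sum(v * math.log2(v) for v in d if v > 0)
    return {
        "angular_second_moment": sum(v * v for v in p.values()),
        "contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "correlation": corr,
        "variance": var,
        "inverse_difference_moment": sum(
            v / (1 + (i - j) ** 2) for (i, j), v in p.items()
        ),
        "sum_average": sum(k * v for k, v in p_sum.items()),
        "sum_entropy": ent(p_sum.values()),
        "entropy": ent(p.values()),
        "difference_entropy": ent(p_diff.values()),
        "dissimilarity": sum(abs(i - j) * v for (i, j), v in p.items()),
        "inverse_difference": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
    }


# --------------------------------------------------------------- GLRLM


def glrlm_counts(levels, mask):
    """Maximal-run counts {(gray level, run length): n} over 13 directions."""
    counts = defaultdict(int)
    shape = mask.shape
    for d in DIRECTIONS_13:
        for v in _voi_voxels(mask):
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if (
                _in_bounds(prev, shape)
                and mask[prev]
                and levels[prev] == levels[v]
            ):
                continue  # not a run start
            length = 1
            nxt = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            while _in_bounds(nxt, shape) and mask[nxt] and levels[nxt] == levels[v]:
                length += 1
                nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
            counts[(int(levels[v]), length)] += 1
    return counts


def _run_zone_features_oracle(counts, n_voxels, kind, n_dirs=13):
    n = sum(counts.values())
    f = {}
    short_tag, long_tag = (
        ("short_run", "long_run") if kind == "run" else ("small_zone", "large_zone")
    )
    unit = "run" if kind == "run" else "zone_size"
    f[f"{short_tag}_emphasis"] = sum(c / j**2 for (_, j), c in counts.items()) / n
    f[f"{long_tag}_emphasis"] = sum(c * j**2 for (_, j), c in counts.items()) / n
    by_i = defaultdict(float)
    by_j = defaultdict(float)
    for (i, j), c in counts.items():
        by_i[i] += c
        by_j[j] += c
    f["gray_level_nonuniformity"] = sum(c**2 for c in by_i.values()) / n
    f[f"{unit}_nonuniformity"] = sum(c**2 for c in by_j.values()) / n
    if kind == "run":
        f["run_percentage"] = n / (n_voxels * n_dirs)
    else:
        f["zone_percentage"] = n / n_voxels
    f["low_gray_level_emphasis"] = sum(c / i**2 for (i, _), c in counts.items()) / n
    f["high_gray_level_emphasis"] = sum(c * i**2 for (i, _), c in counts.items()) / n
    f[f"{short_tag}_low_gray_level_emphasis"] = (
        sum(c / (i**2 * j**2) for (i, j), c in counts.items()) / n
    )
    f[f"{short_tag}_high_gray_level_emphasis"] = (
        sum(c * i**2 / j**2 for (i, j), c in counts.items()) / n
    )
    f[f"{long_tag}_low_gray_level_emphasis"] = (
        sum(c * j**2 / i**2 for (i, j), c in counts.items()) / n
    )
    f[f"{long_tag}_high_gray_level_emphasis"] = (
        sum(c * i**2 * j**2 for (i, j), c in counts.items()) / n
    )
    mu_i = sum(i * c for i, c in by_i.items()) / n
    mu_j = sum(j * c for j, c in by_j.items()) / n
    f["gray_level_variance"] = sum((i - mu_i) ** 2 * c for i, c in by_i.items()) / n
    f[f"{unit}_variance"] = sum((j - mu_j) ** 2 * c for j, c in by_j.items()) / n
    return f


def glrlm_features_oracle(levels, mask):
    return _run_zone_features_oracle(
        glrlm_counts(levels, mask), int(mask.sum()), "run"
    )


# --------------------------------------------------------------- GLSZM


def glszm_counts(levels, mask):
    """Zone counts {(gray level, zone size): n} by flood fill, 26-connected."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    counts = defaultdict(int)
    for v in _voi_voxels(mask):
        if seen[v]:
            continue
        g = int(levels[v])
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for off in NEIGHBOR_OFFSETS_26:
                w = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
                if (
                    _in_bounds(w, shape)
                    and mask[w]
                    and not seen[w]
                    and levels[w] == g
                ):
                    seen[w] = True
                    stack.append(w)
        counts[(g, size)] += 1
    return counts


def glszm_features_oracle(levels, mask):
    return _run_zone_features_oracle(
        glszm_counts(levels, mask), int(mask.sum()), "zone"
    )


# --------------------------------------------------------------- NGLDM


def ngldm_counts(levels, mask):
    """{(gray level, dependence): n} with alpha = 0."""
    shape = mask.shape
    counts = defaultdict(int)
    for v in _voi_voxels(mask):
        dep = 0
        for off in NEIGHBOR_OFFSETS_26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _in_bounds(w, shape) and mask[w] and levels[w] == levels[v]:
                dep += 1
        counts[(int(levels[v]), dep)] += 1
    return counts


def ngldm_features_oracle(levels, mask):
    counts = ngldm_counts(levels, mask)
    ns = sum(counts.values())
    # j = dependence + 1 to keep the emphasis weights finite
    cj = {(i, k + 1): c for (i, k), c in counts.items()}
    by_i = defaultdict(float)
    by_j = defaultdict(float)
    for (i, j), c in cj.items():
        by_i[i] += c
        by_j[j] += c
    mu_i = sum(i * c for i, c in by_i.items()) / ns
    mu_j = sum(j * c for j, c in by_j.items()) / ns
    ent = -sum(
        (c / ns) * math.log2(c / ns) for c in by_j.values() if c > 0
    )
    return {
        "low_dependence_emphasis": sum(c / j**2 for (_, j), c in cj.items()) / ns,
        "high_dependence_emphasis": sum(c * j**2 for (_, j), c in cj.items()) / ns,
        "gray_level_nonuniformity": sum(c**2 for c in by_i.values()) / ns,
        "gray_level_nonuniformity_normalized": sum(c**2 for c in by_i.values())
        / ns**2,
        "dependence_count_nonuniformity": sum(c**2 for c in by_j.values()) / ns,
        "dependence_count_nonuniformity_normalized": sum(
            c**2 for c in by_j.values()
        )
        / ns**2,
        "low_gray_level_count_emphasis": sum(c / i**2 for (i, _), c in cj.items())
        / ns,
        "high_gray_level_count_emphasis": sum(c * i**2 for (i, _), c in cj.items())
        / ns,
        "low_dependence_low_gray_level_emphasis": sum(
            c / (i**2 * j**2) for (i, j), c in cj.items()
        )
        / ns,
        "low_dependence_high_gray_level_emphasis": sum(
            c * i**2 / j**2 for (i, j), c in cj.items()
        )
        / ns,
        "high_dependence_low_gray_level_emphasis": sum(
            c * j**2 / i**2 for (i, j), c in cj.items()
        )
        / ns,
        "high_dependence_high_gray_level_emphasis": sum(
            c * i**2 * j**2 for (i, j), c in cj.items()
        )
        / ns,
        "gray_level_variance": sum(
            (i - mu_i) ** 2 * c for i, c in by_i.items()
        )
        / ns,
        "dependence_count_variance": sum(
            (j - mu_j) ** 2 * c for j, c in by_j.items()
        )
        / ns,
        "dependence_count_entropy": ent,
        "dependence_count_energy": sum((c / ns) ** 2 for c in by_j.values()),
    }


# --------------------------------------------------------------- NGTDM


def ngtdm_table_oracle(levels, mask, n_bins):
    shape = mask.shape
    n_i = [0.0] * (n_bins + 1)
    s_i = [0.0] * (n_bins + 1)
    for v in _voi_voxels(mask):
        nbrs = []
        for off in NEIGHBOR_OFFSETS_26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _in_bounds(w, shape) and mask[w]:
                nbrs.append(int(levels[w]))
        if nbrs:
            g = int(levels[v])
            n_i[g] += 1
            s_i[g] += abs(g - sum(nbrs) / len(nbrs))
    return n_i, s_i


def ngtdm_features_oracle(levels, mask, n_bins, eps=1e-6):
    n_i, s_i = ngtdm_table_oracle(levels, mask, n_bins)
    nvb = sum(n_i)
    p = [c / nvb for c in n_i]
    occ = [g for g in range(1, n_bins + 1) if p[g] > 0]
    ps = sum(p[g] * s_i[g] for g in occ)
    s_total = sum(s_i)
    coarseness = 1.0 / max(ps, eps)
    ngp = len(occ)
    contrast = 0.0
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ)
            / (ngp * (ngp - 1))
            * s_total
            / nvb
        )
    busy_den = sum(abs(i * p[i] - j * p[j]) for i in occ for j in occ)
    busyness = ps / busy_den if busy_den > 0 else 0.0
    complexity = (
        sum(
            abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            for i in occ
            for j in occ
        )
        / nvb
    )
    strength = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ) / s_total
        if s_total > 0
        else 0.0
    )
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


TEXTURE_ORACLES = {
    "GLCM": lambda lv, m, nb: glcm_features_oracle(lv, m),
    "GLRLM": lambda lv, m, nb: glrlm_features_oracle(lv, m),
    "GLSZM": lambda lv, m, nb: glszm_features_oracle(lv, m),
    "NGLDM": lambda lv, m, nb: ngldm_features_oracle(lv, m),
    "NGTDM": ngtdm_features_oracle,
}
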