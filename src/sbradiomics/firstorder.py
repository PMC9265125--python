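"""Morphological, intensity and histogram features.

Morphology (8 features) is computed from the binary VOI mask alone, using a
marching-cubes iso-surface at level 0.5 with the header voxel spacing for
the mesh volume V and surface area A:

    sphericity   = (36 pi V^2)^(1/3) / A
    compactness1 = V / (sqrt(pi) A^(3/2))
    compactness2 = 36 pi V^2 / A^3    (= sphericity^3)

Intensity (18 features) uses population moments (divide by N); skewness and
excess kurtosis of a constant region are defined as 0. Histogram features
(20) are computed on the 64-level quantized VOI; percentiles use linear
interpolation, entropy is base 2, and mode ties break to the smallest level.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from .discretize import HISTOGRAM_BINS, QuantizedVoi
from .image_io import VoiMask, VolumeImage

MORPHOLOGY_FEATURES = (
    "mesh_volume",
    "voxel_volume",
    "surface_area",
    "surface_to_volume_ratio",
    "sphericity",
    "compactness_1",
    "compactness_2",
    "max_3d_diameter",
)

INTENSITY_FEATURES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "energy",
    "root_mean_square",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "interquartile_range",
    "percentile_10",
    "percentile_90",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
)

HISTOGRAM_FEATURES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "mode",
    "interquartile_range",
    "range",
    "percentile_10",
    "percentile_90",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
    "entropy",
    "uniformity",
    "max_gradient",
    "max_gradient_level",
)


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume of an oriented triangle mesh (divergence theorem)."""
    tri = verts[faces]
    return float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)


def _max_diameter(coords_mm: np.ndarray, spacing) -> float:
    """Largest pairwise distance between VOI voxel centers, floored at the
    largest voxel spacing so a single-voxel VOI still spans one voxel."""
    floor = float(max(spacing))
    if len(coords_mm) < 2:
        return floor
    pts = coords_mm
    if len(pts) > 4:
        try:
            pts = coords_mm[ConvexHull(coords_mm).vertices]
        except QhullError:  # degenerate (coplanar/collinear) point sets
            pass
    return max(float(pdist(pts).max()), floor)


#: Gaussian width (voxels) applied to the mask indicator before meshing;
#: suppresses the staircase area bias of meshing a raw binary grid
_MESH_SIGMA = 0.8


def morphology_features(mask: VoiMask) -> dict[str, float]:
    """The 8 shape features of a VOI mask; intensity-independent."""
    spacing = mask.spacing
    padded = np.pad(mask.values.astype(np.float64), 2)
    smoothed = gaussian_filter(padded, _MESH_SIGMA)
    # tiny masks can smooth entirely below the iso-level; mesh them raw
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=spacing)
    area = float(mesh_surface_area(verts, faces))
    volume = _mesh_volume(verts, faces)
    voxel_volume = mask.voxel_count * mask.voxel_volume
    coords = np.argwhere(mask.values) * np.asarray(spacing)
    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area
    return {
        "mesh_volume": volume,
        "voxel_volume": voxel_volume,
        "surface_area": area,
        "surface_to_volume_ratio": area / volume,
        "sphericity": sphericity,
        "compactness_1": volume / (np.sqrt(np.pi) * area**1.5),
        "compactness_2": 36.0 * np.pi * volume**2 / area**3,
        "max_3d_diameter": _max_diameter(coords, spacing),
    }


def _population_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, excess kurtosis) with the N convention;
    skewness/kurtosis of a constant sample are 0 by convention."""
    mu = float(x.mean())
    if x.max() == x.min():  # constant region: exact-zero convention
        return mu, 0.0, 0.0, 0.0
    var = float(((x - mu) ** 2).mean())
    if var <= 0:
        return mu, 0.0, 0.0, 0.0
    m3 = float(((x - mu) ** 3).mean())
    m4 = float(((x - mu) ** 4).mean())
    return mu, var, m3 / var**1.5, m4 / var**2 - 3.0


def _robust_mad(x: np.ndarray) -> float:
    p10, p90 = np.percentile(x, [10, 90])
    sub = x[(x >= p10) & (x <= p90)]
    if sub.size == 0:  # every value outside the 10-90 percentile band
        return 0.0
    return float(np.abs(sub - sub.mean()).mean())


def intensity_features(volume: VolumeImage, mask: VoiMask) -> dict[str, float]:
    """The 18 first-order intensity features of the within-VOI voxels."""
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    x = volume.values[mask.values].astype(np.float64)
    mu, var, skew, kurt = _population_moments(x)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    sd = np.sqrt(var)
    return {
        "mean": mu,
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "variance": var,
        "standard_deviation": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x**2).sum()),
        "root_mean_square": float(np.sqrt((x**2).mean())),
        "mean_absolute_deviation": float(np.abs(x - mu).mean()),
        "robust_mean_absolute_deviation": _robust_mad(x),
        "interquartile_range": float(p75 - p25),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "coefficient_of_variation": sd / mu if mu != 0 else 0.0,
        "quartile_coefficient_of_dispersion": (
            (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else 0.0
        ),
    }


def histogram_features(q: QuantizedVoi) -> dict[str, float]:
    """The 20 histogram features on the 64-level quantized VOI.

    The histogram gradient uses central differences with one-sided
    differences at the ends; ``max_gradient_level`` is the (smallest)
    level at which the gradient of the counts is maximal.
    """
    if q.n_bins != HISTOGRAM_BINS:
        raise ValueError(f"histogram features require n_bins={HISTOGRAM_BINS}")
    levels = q.voi_levels.astype(np.float64)
    counts = np.bincount(q.voi_levels, minlength=HISTOGRAM_BINS + 1)[1:].astype(
        np.float64
    )
    p = counts / counts.sum()
    mu, var, skew, kurt = _population_moments(levels)
    p10, p25, p75, p90 = np.percentile(levels, [10, 25, 75, 90])
    occupied = p > 0
    grad = np.empty(HISTOGRAM_BINS)
    grad[0] = counts[1] - counts[0]
    grad[-1] = counts[-1] - counts[-2]
    grad[1:-1] = (counts[2:] - counts[:-2]) / 2.0
    imax = int(np.argmax(grad))  # argmax takes the smallest index on ties
    return {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(np.median(levels)),
        "minimum": float(levels.min()),
        "maximum": float(levels.max()),
        "mode": float(np.argmax(counts) + 1),
        "interquartile_range": float(p75 - p25),
        "range": float(levels.max() - levels.min()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "mean_absolute_deviation": float(np.abs(levels - mu).mean()),
        "robust_mean_absolute_deviation": _robust_mad(levels),
        "coefficient_of_variation": np.sqrt(var) / mu if mu != 0 else 0.0,
        "quartile_coefficient_of_dispersion": (
            (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else 0.0
        ),
        "entropy": float(-(p[occupied] * np.log2(p[occupied])).sum()),
        "uniformity": float((p**2).sum()),
        "max_gradient": float(grad[imax]),
        "max_gradient_level": float(imax + 1),
    }
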