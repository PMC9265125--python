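"""Fixed-bin-number quantization of within-VOI intensities.

Gray levels are assigned per image (each wavelet subband is re-quantized
independently, since subbands have unrelated dynamic ranges) over the
within-VOI intensity range:

    level(x) = floor(n_bins * (x - min) / (max - min)) + 1

with the maximum clamped to level ``n_bins`` and a degenerate (constant)
region mapping every voxel to level 1. The scheme is invariant to affine
intensity rescaling x -> a*x + b (a > 0) and monotone in x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import VoiMask, VolumeImage

#: bin counts used for texture features; histogram features fix 64
TEXTURE_BIN_COUNTS = (16, 32, 64, 128)
HISTOGRAM_BINS = 64


@dataclass
class QuantizedVoi:
    """Integer gray levels of the VOI voxels, cropped to the VOI bounding box.

    ``levels`` is 0 outside the VOI and in 1..n_bins inside; ``mask`` marks
    the VOI voxels within the crop. Spatial structure (and voxel spacing)
    is preserved so texture matrices can be built directly.
    """

    levels: np.ndarray  # int32, 0 outside the VOI
    mask: np.ndarray  # bool, same shape as levels
    n_bins: int
    spacing: tuple[float, float, float]
    subband: str = "original"

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_bins):
            raise ValueError("levels outside 1..n_bins")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voi_levels(self) -> np.ndarray:
        """1D array of the within-VOI gray levels."""
        return self.levels[self.mask]


def _crop_to_bbox(mask: np.ndarray):
    idx = [np.flatnonzero(mask.any(axis=tuple(a for a in range(3) if a != ax)))
           for ax in range(3)]
    return tuple(slice(i[0], i[-1] + 1) for i in idx)


def quantize(
    volume: VolumeImage, mask: VoiMask, n_bins: int, subband: str = "original"
) -> QuantizedVoi:
    """Quantize within-VOI intensities to ``n_bins`` gray levels.

    Raises ``ValueError`` for n_bins < 2. The quantization range is the
    within-VOI min/max of this particular image.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    box = _crop_to_bbox(mask.values)
    m = mask.values[box]
    vals = volume.values[box]
    inside = vals[m]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(m.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
    else:
        lv = np.floor(n_bins * (inside - lo) / (hi - lo)).astype(np.int32) + 1
        np.clip(lv, 1, n_bins, out=lv)
        levels[m] = lv
    return QuantizedVoi(levels, m, n_bins, volume.spacing, subband)
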