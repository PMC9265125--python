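"""Single-level undecimated 3D wavelet decomposition (Coiflet 1).

The low- (L) and high-pass (H) Coiflet-1 analysis filters are applied
separably along x, y and z in all 8 combinations, yielding the subbands
LLL ... HHH alongside the original image. The transform is undecimated
(stationary): every subband keeps the input grid, so the VOI mask applies
to all 9 images without resampling. Boundaries use symmetric (mirror)
padding. Subband labels order the filter letters as (x, y, z): "HLL" is
high-pass along x, low-pass along y and z.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import convolve1d

from .image_io import VolumeImage

_WAVELET = pywt.Wavelet("coif1")
LOW_PASS = np.asarray(_WAVELET.dec_lo, dtype=np.float64)
HIGH_PASS = np.asarray(_WAVELET.dec_hi, dtype=np.float64)
FILTER_LENGTH = len(LOW_PASS)  # 6 taps

#: the 9 images feature extraction runs on, in canonical order
SUBBAND_LABELS = ("original", "LLL", "HLL", "LHL", "LLH", "HHL", "HLH", "LHH", "HHH")
WAVELET_LABELS = SUBBAND_LABELS[1:]


def decompose(volume: VolumeImage) -> dict[str, VolumeImage]:
    """Decompose a volume into its 8 wavelet subbands plus the original.

    Returns a mapping from subband label to a :class:`VolumeImage` on the
    input grid. Linear in the input; a spatially constant volume has
    identically zero response in every subband containing an H.

    Raises
    ------
    ValueError
        If any volume dimension is shorter than the 6-tap filter support.
    """
    data = volume.values
    if min(data.shape) < FILTER_LENGTH:
        raise ValueError(
            f"volume shape {data.shape} too small for the {FILTER_LENGTH}-tap "
            "Coiflet-1 filters"
        )
    out: dict[str, VolumeImage] = {
        "original": VolumeImage(data.copy(), volume.spacing, volume.origin)
    }
    for label in WAVELET_LABELS:
        band = data
        for axis, letter in enumerate(label):
            taps = LOW_PASS if letter == "L" else HIGH_PASS
            # "reflect" = half-sample symmetric padding (edge value repeats)
            band = convolve1d(band, taps, axis=axis, mode="reflect")
        out[label] = VolumeImage(band, volume.spacing, volume.origin)
    return out
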