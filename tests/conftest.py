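import numpy as np
import pytest

from sbradiomics.discretize import QuantizedVoi
from sbradiomics.features import extract_cohort
from sbradiomics.image_io import VoiMask, VolumeImage
from sbradiomics.synthetic import CohortConfig, generate_cohort

#: compact cohort geometry used when a test only needs plausible volumes fast
SMALL_GRID = dict(
    grid_shape=(24, 24, 12), voxel_spacing=(1.0, 1.0, 2.0), voi_radius_range=(4.0, 6.0)
)


def make_volume(values, spacing=(1.0, 1.0, 1.0)) -> VolumeImage:
    return VolumeImage(np.asarray(values, dtype=np.float64), spacing)


def make_mask(values, spacing=(1.0, 1.0, 1.0)) -> VoiMask:
    return VoiMask(np.asarray(values), spacing)


def random_quantized(rng, shape=(5, 5, 5), n_bins=16, mask_p=1.0) -> QuantizedVoi:
    """A random fully- or partially-masked quantized VOI for oracle checks."""
    mask = (
        np.ones(shape, dtype=bool)
        if mask_p >= 1.0
        else rng.random(shape) < mask_p
    )
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_bins + 1, size=int(mask.sum()))
    return QuantizedVoi(levels, mask, n_bins, (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_case():
    """One small two-sequence synthetic case."""
    cfg = CohortConfig(n_cases_per_class=1, seed=11, **SMALL_GRID)
    return generate_cohort(cfg)[0]


@pytest.fixture(scope="session")
def small_table():
    """Feature table of a compact 8-vs-8 cohort (reused across tests)."""
    cfg = CohortConfig(n_cases_per_class=8, effect_size=2.0, seed=5, **SMALL_GRID)
    return extract_cohort(generate_cohort(cfg))
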