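"""Morphology, intensity and histogram features."""

import numpy as np
import pytest

from sbradiomics.discretize import QuantizedVoi, quantize
from sbradiomics.firstorder import (
    HISTOGRAM_FEATURES,
    INTENSITY_FEATURES,
    MORPHOLOGY_FEATURES,
    histogram_features,
    intensity_features,
    morphology_features,
)

from conftest import make_mask, make_volume


# ------------------------------------------------------------ morphology


def test_voxel_volume_is_count_times_voxel_size():
    mask = np.zeros((6, 6, 6))
    mask[1:4, 1:5, 2:4] = 1  # 3*4*2 = 24 voxels
    feats = morphology_features(make_mask(mask, spacing=(1.0, 1.0, 3.0)))
    assert feats["voxel_volume"] == pytest.approx(24 * 3.0)


def test_single_voxel_shape_consistency():
    """The sphericity family must be internally consistent on its own mesh
    (compactness_2 = sphericity^3); with the voxel-face surface (A=6, V=1)
    the closed form gives (36*pi)^(1/3)/6 ~ 0.806."""
    mask = np.zeros((5, 5, 5))
    mask[2, 2, 2] = 1
    feats = morphology_features(make_mask(mask))
    assert feats["voxel_volume"] == pytest.approx(1.0)
    assert feats["compactness_2"] == pytest.approx(feats["sphericity"] ** 3, rel=1e-10)
    assert feats["max_3d_diameter"] == pytest.approx(1.0)
    voxel_face_sphericity = (36 * np.pi) ** (1 / 3) / 6
    assert voxel_face_sphericity == pytest.approx(0.8060, abs=1e-3)


def test_digitized_ball_is_nearly_spherical():
    r = 15
    n = 2 * r + 3
    c = n // 2
    idx = np.indices((n, n, n))
    mask = ((idx - c) ** 2).sum(axis=0) <= r**2
    feats = morphology_features(make_mask(mask))
    assert 0.95 <= feats["sphericity"] <= 1.001
    assert feats["mesh_volume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)
    assert feats["max_3d_diameter"] == pytest.approx(2 * r, rel=0.05)
    assert feats["surface_to_volume_ratio"] == pytest.approx(
        feats["surface_area"] / feats["mesh_volume"]
    )


def test_morphology_uses_spacing():
    mask = np.zeros((6, 6, 6))
    mask[2:4, 2:4, 2:4] = 1
    iso = morphology_features(make_mask(mask, spacing=(1, 1, 1)))
    aniso = morphology_features(make_mask(mask, spacing=(1, 1, 3)))
    assert aniso["voxel_volume"] == pytest.approx(3 * iso["voxel_volume"])
    assert aniso["sphericity"] < iso["sphericity"]


# ------------------------------------------------------------- intensity


def _intensity(values, spacing=(1, 1, 1)):
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return intensity_features(
        make_volume(arr, spacing), make_mask(np.ones(arr.shape), spacing)
    )


def test_intensity_hand_examples():
    f = _intensity([1, 2, 3, 4])
    assert f["mean"] == pytest.approx(2.5)
    assert f["range"] == pytest.approx(3.0)
    assert f["skewness"] == pytest.approx(0.0, abs=1e-12)
    assert f["variance"] == pytest.approx(1.25)  # population convention
    assert _intensity([1, 2])["energy"] == pytest.approx(5.0)


def test_constant_region_degenerate_conventions():
    f = _intensity([4.2] * 10)
    assert f["variance"] == 0.0
    assert f["skewness"] == 0.0
    assert f["kurtosis"] == 0.0


def test_intensity_affine_transformation_rules():
    rng = np.random.default_rng(2)
    x = rng.random(40) * 10
    a, b = 2.5, -4.0
    f0, f1 = _intensity(x), _intensity(a * x + b)
    assert f1["mean"] == pytest.approx(a * f0["mean"] + b)
    assert f1["variance"] == pytest.approx(a**2 * f0["variance"])
    assert f1["skewness"] == pytest.approx(f0["skewness"])


def test_feature_rosters_have_contract_sizes():
    assert len(MORPHOLOGY_FEATURES) == 8
    assert len(INTENSITY_FEATURES) == 18
    assert len(HISTOGRAM_FEATURES) == 20


# ------------------------------------------------------------- histogram


def _hist_from_values(values):
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    q = quantize(make_volume(arr), make_mask(np.ones(arr.shape)), 64)
    return histogram_features(q)


def test_single_level_histogram():
    f = _hist_from_values([5.0] * 30)
    assert f["uniformity"] == pytest.approx(1.0)
    assert f["entropy"] == pytest.approx(0.0)
    assert f["mode"] == 1.0


def test_two_equal_levels_at_extremes():
    f = _hist_from_values([0.0] * 10 + [1.0] * 10)
    assert f["minimum"] == 1.0 and f["maximum"] == 64.0
    assert f["entropy"] == pytest.approx(1.0)
    assert f["uniformity"] == pytest.approx(0.5)


def test_mode_tie_breaks_to_smallest_level():
    levels = np.array([1] * 5 + [2] * 3 + [3] * 5, dtype=np.int32).reshape(-1, 1, 1)
    q = QuantizedVoi(levels, np.ones(levels.shape, bool), 64, (1, 1, 1))
    assert histogram_features(q)["mode"] == 1.0


def test_entropy_bounded_by_log_bins():
    rng = np.random.default_rng(4)
    f = _hist_from_values(rng.random(500))
    assert 0 < f["entropy"] <= np.log2(64)
    # uniform occupancy attains the bound
    f_uniform = _hist_from_values(np.repeat(np.linspace(0, 1, 64), 3))
    assert f_uniform["entropy"] == pytest.approx(np.log2(64))
    assert f_uniform["uniformity"] == pytest.approx(1 / 64)


def test_histogram_requires_64_bins():
    levels = np.ones((8, 1, 1), dtype=np.int32)
    q = QuantizedVoi(levels, np.ones(levels.shape, bool), 32, (1, 1, 1))
    with pytest.raises(ValueError, match="64"):
        histogram_features(q)


def test_max_gradient_level_points_at_steepest_rise():
    # counts: 1 voxel at level 1, 8 at level 64; the one-sided difference at
    # the top bin (8 - 0) dominates every central difference
    f = _hist_from_values([0.0] + [0.02] * 8)
    assert f["max_gradient_level"] == 64.0
    assert f["max_gradient"] == pytest.approx(8.0)
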