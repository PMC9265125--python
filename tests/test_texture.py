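"""Texture matrices: hand-enumerable cases, conservation laws, and
agreement with brute-force enumeration oracles."""

import numpy as np
import pytest

from sbradiomics.discretize import QuantizedVoi, quantize
from sbradiomics.registry import EXPECTED_COUNTS, TEXTURE_FAMILIES, family_features
from sbradiomics.texture import (
    TEXTURE_FAMILY_FUNCS,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngldm_matrix,
    ngtdm_features,
    ngtdm_table,
)

from conftest import make_mask, make_volume, random_quantized
from oracles import TEXTURE_ORACLES


def _const_voi(shape=(3, 3, 3), n_bins=16):
    levels = np.ones(shape, dtype=np.int32)
    return QuantizedVoi(levels, np.ones(shape, bool), n_bins, (1, 1, 1))


def _line_voi(levels_1d, n_bins=16, axis=2):
    arr = np.asarray(levels_1d, dtype=np.int32)
    shape = [1, 1, 1]
    shape[axis] = len(arr)
    levels = arr.reshape(shape)
    return QuantizedVoi(levels, np.ones(levels.shape, bool), n_bins, (1, 1, 1))


# ------------------------------------------------------------------ GLCM


def test_glcm_constant_voi_single_entry():
    f = glcm_features(_const_voi())
    p = glcm_matrix(_const_voi())
    assert p[0, 0] == pytest.approx(1.0)
    assert p.sum() == pytest.approx(1.0)
    assert f["inverse_difference_moment"] == pytest.approx(1.0)
    assert f["correlation"] == 0.0  # degenerate variance guard


def test_glcm_two_voxel_pair():
    q = _line_voi([1, 2], axis=0)
    p = glcm_matrix(q)
    assert p[0, 1] == pytest.approx(0.5)
    assert p[1, 0] == pytest.approx(0.5)
    assert glcm_features(q)["contrast"] == pytest.approx(1.0)


def test_glcm_matrix_is_symmetric_probability():
    q = random_quantized(np.random.default_rng(0), (6, 5, 4), 16)
    p = glcm_matrix(q)
    assert np.allclose(p, p.T)
    assert p.sum() == pytest.approx(1.0, abs=1e-10)
    assert (p >= 0).all()


def test_glcm_single_voxel_rejected():
    with pytest.raises(ValueError):
        glcm_features(_line_voi([1]))


# ----------------------------------------------------------------- GLRLM


def test_glrlm_constant_line_runs():
    # 1x1x4 constant VOI: one run of length 4 along z, four runs of length 1
    # in each of the other 12 directions
    R = glrlm_matrix(_line_voi([1, 1, 1, 1]))
    assert R[0, 3] == 1
    assert R[0, 0] == 48
    assert R.sum() == 49


def test_glrlm_all_distinct_levels_gives_singleton_runs():
    q = _line_voi([1, 2, 3, 4])
    f = glrlm_features(q)
    R = glrlm_matrix(q)
    assert (R[:, 1:] == 0).all()
    n_runs = R.sum()
    assert f["run_nonuniformity"] == pytest.approx(n_runs)


# ----------------------------------------------------------------- GLSZM


def test_glszm_constant_voi_single_zone():
    q = _const_voi((2, 3, 2))
    Z = glszm_matrix(q)
    assert Z.sum() == 1
    assert Z[0, 11] == 1
    f = glszm_features(q)
    assert f["low_gray_level_emphasis"] == pytest.approx(1.0)
    assert f["zone_size_variance"] == pytest.approx(0.0)


def test_glszm_distinct_levels_all_singleton_zones():
    q = _line_voi([1, 2, 3, 4, 5], n_bins=16)
    Z = glszm_matrix(q)
    assert Z[:, 0].sum() == 5 and Z[:, 1:].sum() == 0


def test_glszm_mass_conservation():
    for seed in range(5):
        q = random_quantized(np.random.default_rng(seed), (5, 4, 6), 8, mask_p=0.7)
        Z = glszm_matrix(q)
        sizes = np.arange(1, Z.shape[1] + 1)
        assert (Z * sizes).sum() == q.voxel_count


# ----------------------------------------------------------------- NGLDM


def test_ngldm_constant_cube_center_dependence():
    M = ngldm_matrix(_const_voi((3, 3, 3)))
    assert M[0, 26] == 1  # interior voxel has all 26 neighbors equal
    assert M.sum() == 27


def test_ngldm_single_voxel():
    M = ngldm_matrix(_line_voi([1]))
    assert M[0, 0] == 1 and M.sum() == 1


def test_ngldm_mass_conservation():
    for seed in range(5):
        q = random_quantized(np.random.default_rng(seed + 10), (4, 5, 4), 16, 0.6)
        assert ngldm_matrix(q).sum() == q.voxel_count


# ----------------------------------------------------------------- NGTDM


def test_ngtdm_constant_voi_zero_differences():
    n_i, s_i = ngtdm_table(_const_voi())
    assert s_i.sum() == 0.0
    assert ngtdm_features(_const_voi())["contrast"] == 0.0


def test_ngtdm_two_voxel_hand_case():
    n_i, s_i = ngtdm_table(_line_voi([1, 2]))
    assert s_i[0] == pytest.approx(1.0)
    assert s_i[1] == pytest.approx(1.0)
    assert n_i[0] == n_i[1] == 1


# ------------------------------------------------------ oracle agreement


@pytest.mark.parametrize("family", TEXTURE_FAMILIES)
def test_features_match_bruteforce_oracle(family):
    rng = np.random.default_rng(99)
    for trial in range(6):
        shape = tuple(rng.integers(4, 7, size=3))
        n_bins = int(rng.choice([8, 16]))
        q = random_quantized(rng, shape, n_bins, mask_p=0.75 if trial % 2 else 1.0)
        ours = TEXTURE_FAMILY_FUNCS[family](q)
        ref = TEXTURE_ORACLES[family](q.levels, q.mask, q.n_bins)
        for name in family_features(family):
            a, b = ours[name], ref[name]
            assert a == pytest.approx(b, rel=1e-8, abs=1e-10), (family, name)


def test_affine_intensity_invariance_of_all_families():
    rng = np.random.default_rng(5)
    values = rng.random((5, 5, 5)) * 40 + 7
    mask = make_mask(np.ones((5, 5, 5)))
    q0 = quantize(make_volume(values), mask, 16)
    q1 = quantize(make_volume(3.5 * values - 11.0), mask, 16)
    for family, fn in TEXTURE_FAMILY_FUNCS.items():
        f0, f1 = fn(q0), fn(q1)
        for name in f0:
            assert f0[name] == pytest.approx(f1[name], rel=1e-12), (family, name)


def test_registry_counts_are_contractual():
    for fam, expected in EXPECTED_COUNTS.items():
        assert len(family_features(fam)) == expected
    assert [EXPECTED_COUNTS[f] for f in TEXTURE_FAMILIES] == [11, 13, 13, 16, 5]
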