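import numpy as np
import pandas as pd
import pytest

from conftest import make_mask, make_parametric
from dynrad import radiomics as rx
from oracles import all_texture_features_brute


# --------------------------------------------------------------------------
# Discretization
# --------------------------------------------------------------------------

def test_discretize_absolute_examples():
    vals = np.zeros((2, 2, 2))
    vals[0, 0, 0] = 0.0     # -> bin 1
    vals[0, 0, 1] = 0.09    # -> bin 1
    vals[0, 1, 0] = 0.10    # -> bin 2 (left-closed bins)
    vals[0, 1, 1] = 0.55    # -> bin 6
    img = make_parametric(vals, kind="TBR")
    mask = make_mask(np.ones((2, 2, 2)))
    disc = rx.discretize_absolute(img, mask, 0.1)
    assert disc.bin_indices[0, 0, 0] == 1
    assert disc.bin_indices[0, 0, 1] == 1
    assert disc.bin_indices[0, 1, 0] == 2
    assert disc.bin_indices[0, 1, 1] == 6
    assert disc.n_levels == 6


def test_discretize_errors():
    img = make_parametric(-np.ones((2, 2, 2)), kind="TBR")
    mask = make_mask(np.ones((2, 2, 2)))
    with pytest.raises(ValueError, match="negative"):
        rx.discretize_absolute(img, mask, 0.1)
    with pytest.raises(ValueError):
        rx.discretize_absolute(make_parametric(np.ones((2, 2, 2))), mask, 0.0)
    with pytest.raises(ValueError, match="empty"):
        rx.discretize_absolute(make_parametric(np.ones((2, 2, 2))),
                               make_mask(np.zeros((2, 2, 2))), 0.1)


def test_default_bin_sizes_by_kind():
    assert rx.BIN_SIZES == {"TBR": 0.1, "TTP": 1.0}


# --------------------------------------------------------------------------
# Morphology
# --------------------------------------------------------------------------

def test_morphology_cube():
    mask = make_mask(np.pad(np.ones((4, 4, 4), bool), 1), spacing=(2, 2, 2))
    m = rx.extract_morphology(mask)
    assert m["morph_volume_voxel"] == 64 * 8.0
    # mesh volume close to the voxel volume for a compact block (the
    # anti-aliased mesh rounds the cube's corners and edges inward)
    assert abs(m["morph_volume_mesh"] - 512.0) / 512.0 < 0.2
    assert m["morph_elongation"] == pytest.approx(1.0, abs=1e-6)
    assert m["morph_flatness"] == pytest.approx(1.0, abs=1e-6)


def test_morphology_ball_sphericity():
    # digital ball at 1 mm spacing: sphericity near 1 by definition
    r = 10.5
    ax = np.arange(24) + 0.5 - 12.0
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    ball = x ** 2 + y ** 2 + z ** 2 <= r ** 2
    m = rx.extract_morphology(make_mask(ball, spacing=(1, 1, 1)))
    assert 0.93 <= m["morph_sphericity"] <= 1.0
    vol_true = 4.0 / 3.0 * np.pi * r ** 3
    assert abs(m["morph_volume_mesh"] - vol_true) / vol_true < 0.05
    assert abs(m["morph_max_3d_diameter"] - 2 * r) / (2 * r) < 0.1


def test_morphology_ellipsoid_axes():
    ax = np.arange(40) + 0.5 - 20.0
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    ell = (x / 16) ** 2 + (y / 8) ** 2 + (z / 4) ** 2 <= 1.0
    m = rx.extract_morphology(make_mask(ell, spacing=(1, 1, 1)))
    # PCA axis lengths of a solid ellipsoid: 4*sqrt(lambda) ~ 2a/sqrt(5)*...
    assert m["morph_elongation"] == pytest.approx(0.5, abs=0.05)
    assert m["morph_flatness"] == pytest.approx(0.25, abs=0.05)
    assert m["morph_major_axis_length"] > m["morph_minor_axis_length"] > \
        m["morph_least_axis_length"]


def test_morphology_invariant_to_axis_permutation():
    rng = np.random.default_rng(0)
    blob = rng.random((7, 7, 7)) < 0.4
    blob[3, 3, 3] = True
    a = rx.extract_morphology(make_mask(blob))
    b = rx.extract_morphology(make_mask(np.transpose(blob, (2, 0, 1))))
    # voxel-count and PCA quantities are exactly invariant; mesh quantities
    # only approximately (marching-cubes triangulation is not symmetric)
    exact = ["morph_volume_voxel", "morph_major_axis_length",
             "morph_minor_axis_length", "morph_least_axis_length",
             "morph_elongation", "morph_flatness"]
    pd.testing.assert_series_equal(a[exact], b[exact], atol=1e-9, rtol=0)
    pd.testing.assert_series_equal(a, b, rtol=0.02)


# --------------------------------------------------------------------------
# Intensity features
# --------------------------------------------------------------------------

def test_statistical_features_hand_example():
    vals = np.zeros((2, 2, 2))
    vals.ravel()[:4] = [1.0, 2.0, 3.0, 6.0]
    mask = np.zeros((2, 2, 2), bool)
    mask.ravel()[:4] = True
    img = make_parametric(vals, kind="TBR")
    disc = rx.discretize_absolute(img, make_mask(mask), 0.1)
    f = rx.extract_intensity_features(img, make_mask(mask), disc)
    assert f["stat_mean"] == 3.0
    assert f["stat_variance"] == pytest.approx(3.5)      # population
    assert f["stat_median"] == 2.5
    assert f["stat_min"] == 1.0 and f["stat_max"] == 6.0
    assert f["stat_range"] == 5.0
    assert f["stat_energy"] == pytest.approx(1 + 4 + 9 + 36)
    assert f["stat_rms"] == pytest.approx(np.sqrt(50 / 4))
    assert f["stat_mad"] == pytest.approx(np.abs([1, 2, 3, 6] -
                                                 np.float64(3)).mean())
    assert f["stat_cov"] == pytest.approx(np.sqrt(3.5) / 3.0)


def test_histogram_features_constant_region():
    img = make_parametric(np.full((3, 3, 3), 2.25), kind="TBR")
    mask = make_mask(np.ones((3, 3, 3)))
    disc = rx.discretize_absolute(img, mask, 0.1)
    f = rx.extract_intensity_features(img, mask, disc)
    assert f["hist_entropy"] == 0.0
    assert f["hist_uniformity"] == 1.0
    assert f["hist_variance"] == 0.0
    assert f["hist_mode"] == 23.0  # floor(2.25/0.1)+1
    assert np.isfinite(f.values.astype(float)).all()


def test_local_peak_uniform_sphere():
    # constant image: local and global peak equal the constant
    img = make_parametric(np.full((9, 9, 9), 1.7), kind="TBR")
    mask = make_mask(np.ones((9, 9, 9)))
    disc = rx.discretize_absolute(img, mask, 0.1)
    f = rx.extract_intensity_features(img, mask, disc)
    assert f["li_local_peak"] == pytest.approx(1.7)
    assert f["li_global_peak"] == pytest.approx(1.7)


def test_local_peak_hot_voxel():
    vals = np.ones((11, 11, 11))
    vals[5, 5, 5] = 10.0
    img = make_parametric(vals, kind="TBR")
    mask = make_mask(np.ones((11, 11, 11)))
    disc = rx.discretize_absolute(img, mask, 0.1)
    f = rx.extract_intensity_features(img, mask, disc)
    # peak = mean over the 1 cm^3 sphere around the hottest voxel: dilution
    assert 1.0 < f["li_local_peak"] < 10.0
    assert f["li_global_peak"] >= f["li_local_peak"]


# --------------------------------------------------------------------------
# Texture matrices and features
# --------------------------------------------------------------------------

def _random_case(rng, max_side=5):
    shape = tuple(rng.integers(2, max_side + 1, 3))
    vals = rng.uniform(0, 0.8, shape)
    mask = rng.random(shape) < 0.6
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return make_parametric(vals, kind="TBR"), make_mask(mask)


def test_texture_features_match_bruteforce_sample(rng):
    for _ in range(8):
        img, mask = _random_case(rng)
        disc = rx.discretize_absolute(img, mask, 0.1)
        mats = rx.build_texture_matrices(disc)
        fast = rx.extract_texture_features(mats)
        bins_c, mask_c = rx._crop_to_bbox(disc)
        brute = all_texture_features_brute(bins_c, mask_c, disc.n_levels,
                                           mats.n_voxels)
        for name, val in brute.items():
            assert fast[name] == pytest.approx(val, abs=1e-10), name


def test_glcm_hand_example():
    # 2x2x1 grid, levels [[1, 1], [2, 3]]: count pairs by hand
    vals = np.array([[[0.0], [0.0]], [[0.1], [0.2]]])
    img = make_parametric(vals, kind="TBR")
    mask = make_mask(np.ones((2, 2, 1)))
    disc = rx.discretize_absolute(img, mask, 0.1)
    M = rx.build_texture_matrices(disc).glcm
    # unordered neighbour pairs (incl. both in-plane diagonals):
    # (1,1)x1, (1,2)x2, (1,3)x2, (2,3)x1 -> ordered counts are doubled
    expected = np.array([[2, 2, 2], [2, 0, 1], [2, 1, 0]], dtype=float)
    assert np.array_equal(M, expected)


def test_glrlm_hand_example():
    # single in-mask line 1 1 2 along x
    vals = np.array([[[0.0]], [[0.05]], [[0.1]]])
    img = make_parametric(vals, kind="TBR")
    mask = make_mask(np.ones((3, 1, 1)))
    disc = rx.discretize_absolute(img, mask, 0.1)
    M = rx.build_texture_matrices(disc).glrlm
    # direction (1,0,0): run of two 1s, run of one 2.  The other 12
    # directions each see three (or fewer) length-1 runs.
    assert M[0, 1] == 1          # level 1, length 2, once
    assert M.sum() > 3
    assert M.shape[0] == 2


def test_glszm_hand_example():
    # two disconnected same-level zones of sizes 1 and 2
    vals = np.zeros((5, 1, 1))
    vals[0] = 0.1
    vals[3] = 0.1
    vals[4] = 0.1
    img = make_parametric(vals, kind="TBR")
    mask = make_mask(np.ones((5, 1, 1)))
    disc = rx.discretize_absolute(img, mask, 0.1)
    M = rx.build_texture_matrices(disc).glszm
    assert M[1, 0] == 1 and M[1, 1] == 1  # level 2: one size-1, one size-2
    assert M[0, 1] == 1                   # level 1: one size-2 zone


def test_texture_invariance_axis_permutation(rng):
    img, mask = _random_case(rng)
    disc = rx.discretize_absolute(img, mask, 0.1)
    f1 = rx.extract_texture_features(rx.build_texture_matrices(disc))
    perm_img = make_parametric(np.transpose(img.values, (1, 2, 0)),
                               kind="TBR")
    perm_mask = make_mask(np.transpose(mask.values, (1, 2, 0)))
    disc2 = rx.discretize_absolute(perm_img, perm_mask, 0.1)
    f2 = rx.extract_texture_features(rx.build_texture_matrices(disc2))
    pd.testing.assert_series_equal(f1, f2, atol=1e-10, rtol=0)


def test_constant_region_degenerates_are_finite():
    img = make_parametric(np.full((5, 5, 5), 2.0), kind="TBR")
    mask = make_mask(np.ones((5, 5, 5)))
    vec = rx.extract_feature_vector(img, mask)
    assert np.isfinite(vec.values.astype(float)).all()
    assert vec["glcm_joint_entropy"] == 0.0
    assert vec["glcm_energy"] == 1.0
    assert vec["glszm_long_zone_emphasis"] == 125.0 ** 2  # one 125-voxel zone
    assert vec["ngtdm_coarseness"] == 1e6  # capped for flat regions


def test_single_voxel_mask_is_finite():
    img = make_parametric(np.full((3, 3, 3), 1.0), kind="TBR")
    mask = np.zeros((3, 3, 3), bool)
    mask[1, 1, 1] = True
    vec = rx.extract_feature_vector(img, make_mask(mask))
    assert np.isfinite(vec.values.astype(float)).all()


# --------------------------------------------------------------------------
# Feature vector contract
# --------------------------------------------------------------------------

def test_manifest_counts():
    assert len(rx.RADIOMIC_FEATURE_MANIFEST) == 94
    assert len(set(rx.RADIOMIC_FEATURE_MANIFEST)) == 94
    assert len(rx.MORPHOLOGY_FEATURES) == 11
    fams = {}
    for name in rx.RADIOMIC_FEATURE_MANIFEST:
        fams[name.split("_")[0]] = fams.get(name.split("_")[0], 0) + 1
    assert fams == {"stat": 18, "hist": 15, "li": 2, "glcm": 18,
                    "glrlm": 13, "glszm": 16, "ngtdm": 5, "ngldm": 7}


def test_extract_feature_vector_contract(rng):
    img, mask = _random_case(rng, max_side=7)
    vec = rx.extract_feature_vector(img, mask)
    assert list(vec.index) == rx.RADIOMIC_FEATURE_MANIFEST
    assert np.isfinite(vec.values.astype(float)).all()
    # storage-order independence: Fortran-ordered copy gives identical values
    img_f = make_parametric(np.asfortranarray(img.values), kind="TBR")
    mask_f = make_mask(np.asfortranarray(mask.values))
    vec_f = rx.extract_feature_vector(img_f, mask_f)
    pd.testing.assert_series_equal(vec, vec_f)


def test_extract_feature_vector_kind_bin_size():
    vals = np.abs(np.random.default_rng(1).normal(16, 4, (5, 5, 5)))
    mask = make_mask(np.ones((5, 5, 5)))
    ttp = rx.extract_feature_vector(make_parametric(vals, kind="TTP"), mask)
    explicit = rx.extract_feature_vector(make_parametric(vals, kind="TTP"),
                                         mask, bin_size=1.0)
    pd.testing.assert_series_equal(ttp, explicit)
    with pytest.raises(ValueError, match="bin size"):
        rx.extract_feature_vector(make_parametric(vals, kind="SUV"), mask)


def test_write_feature_table(tmp_path):
    df = pd.DataFrame({"subject_id": ["a", "b"], "stat_mean": [1.0, 2.0]})
    rx.write_feature_table(df, tmp_path / "features.csv",
                           settings={"bin_size_tbr": 0.1})
    back = pd.read_csv(tmp_path / "features.csv")
    pd.testing.assert_frame_equal(back, df)
    sidecar = (tmp_path / "features.manifest.json").read_text()
    assert "glcm_joint_max" in sidecar and "13 directions" in sidecar
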