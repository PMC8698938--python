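import numpy as np
import pytest

from conftest import make_dynamic, make_mask, make_parametric
from dynrad import preprocessing as pp
from dynrad.images import DynamicImage, Mask, ParametricImage, \
    default_frame_times
from dynrad.phantom import (ImageGrid, TACModelParams, brain_reference_tac,
                            simulate_tac)


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

def test_resample_identity_passthrough():
    img = make_parametric(np.random.default_rng(0).random((6, 6, 6)))
    out = pp.resample_isotropic(img, target_spacing=2.0)
    assert out is img or np.array_equal(out.values, img.values)


def test_resample_constant_volume_and_mask():
    img = ParametricImage(np.full((8, 8, 8), 3.0), (4.0, 4.0, 4.0))
    out = pp.resample_isotropic(img, target_spacing=2.0)
    assert out.shape == (16, 16, 16)
    assert np.allclose(out.spacing, 2.0)
    # interior is exact; the trailing edge lies beyond the last input voxel
    # center and takes the resampler's default value
    assert np.allclose(out.values[:-1, :-1, :-1], 3.0, atol=1e-6)

    mask = Mask(np.pad(np.ones((4, 4, 4), bool), 2), (4.0, 4.0, 4.0))
    mout = pp.resample_isotropic(mask, target_spacing=2.0)
    assert mout.values.dtype == bool
    # nearest-neighbour: volume preserved under 2x upsampling
    assert mout.n_voxels == mask.n_voxels * 8


def test_resample_dynamic_per_frame():
    rng = np.random.default_rng(1)
    dyn = DynamicImage(rng.random((6, 6, 6, 4)), (4.0, 4.0, 4.0),
                       frame_times=[1, 2, 3, 4])
    out = pp.resample_isotropic(dyn, target_spacing=2.0)
    assert out.shape == (12, 12, 12) and out.n_frames == 4
    ref0 = pp.resample_isotropic(
        ParametricImage(dyn.values[..., 0], (4.0, 4.0, 4.0)), 2.0)
    assert np.allclose(out.values[..., 0], ref0.values, atol=1e-6)


# --------------------------------------------------------------------------
# Brain reference and segmentation
# --------------------------------------------------------------------------

def _uniform_scene(brain_level=1.0, tumor_level=2.0):
    static = np.full((10, 10, 10), 0.2)
    brain = np.zeros((10, 10, 10), bool)
    brain[1:4, 1:4, 1:4] = True
    tumor = np.zeros((10, 10, 10), bool)
    tumor[6:9, 6:9, 6:9] = True
    static[brain] = brain_level
    static[tumor] = tumor_level
    dyn = np.repeat(static[..., None], 30, axis=3)
    return (make_parametric(static, kind="SUV"), make_dynamic(dyn),
            make_mask(brain, role="brain"), make_mask(tumor))


def test_compute_brain_reference():
    static, dyn, brain, _ = _uniform_scene()
    ref = pp.compute_brain_reference(static, dyn, brain)
    assert np.isclose(ref.suv_mean, 1.0)
    assert np.allclose(ref.mean_tac, 1.0)
    assert np.allclose(ref.fitted_mean_tac, 1.0, atol=1e-8)
    with pytest.raises(ValueError):
        pp.compute_brain_reference(static, dyn, make_mask(
            np.zeros((10, 10, 10), bool)))


def test_segment_tumor_threshold_and_seed():
    static, dyn, brain, tumor = _uniform_scene(tumor_level=2.0)
    ref = pp.compute_brain_reference(static, dyn, brain)
    seg = pp.segment_tumor(static, ref, ((5, 10), (5, 10), (5, 10)))
    assert np.array_equal(seg.values, tumor.values)  # 2.0 >= 1.6 x 1.0

    # a second hot component outside the seed box must be excluded
    static2 = static.values.copy()
    static2[0, 0, 0] = 5.0
    seg2 = pp.segment_tumor(make_parametric(static2, kind="SUV"), ref,
                            ((5, 10), (5, 10), (5, 10)))
    assert np.array_equal(seg2.values, tumor.values)

    # seed mask form, and segmentation idempotence as a seed
    seg3 = pp.segment_tumor(static, ref, seg)
    assert np.array_equal(seg3.values, seg.values)


def test_segment_tumor_threshold_boundary():
    # exactly at 1.6 x SUV_mean is included (>= threshold)
    static, dyn, brain, tumor = _uniform_scene(tumor_level=1.6)
    ref = pp.compute_brain_reference(static, dyn, brain)
    seg = pp.segment_tumor(static, ref, ((5, 10), (5, 10), (5, 10)))
    assert np.array_equal(seg.values, tumor.values)
    static2, *_ = _uniform_scene(tumor_level=1.59)
    with pytest.raises(pp.EmptySegmentationError):
        pp.segment_tumor(static2, ref, ((5, 10), (5, 10), (5, 10)))


def test_segment_tumor_empty_seed_error():
    static, dyn, brain, _ = _uniform_scene()
    ref = pp.compute_brain_reference(static, dyn, brain)
    with pytest.raises(pp.EmptySegmentationError):
        pp.segment_tumor(static, ref, ((0, 2), (0, 2), (5, 7)))


def test_segment_tumor_26_connectivity():
    # two voxels touching only at a corner form one 26-connected component
    static, dyn, brain, _ = _uniform_scene()
    vals = static.values.copy()
    vals[6:9, 6:9, 6:9] = 0.2
    vals[6, 6, 6] = 2.0
    vals[7, 7, 7] = 2.0
    ref = pp.compute_brain_reference(static, dyn, brain)
    seg = pp.segment_tumor(make_parametric(vals, kind="SUV"), ref,
                           ((6, 7), (6, 7), (6, 7)))
    assert seg.n_voxels == 2


# --------------------------------------------------------------------------
# HYPR-LR
# --------------------------------------------------------------------------

def test_hypr_exact_on_spatially_constant_frames():
    rng = np.random.default_rng(2)
    levels = rng.uniform(0.5, 2.0, 30)
    dyn = make_dynamic(np.ones((8, 8, 8, 30)) * levels)
    out = pp.hypr_lr_denoise(dyn)
    # G(const frame)/G(const composite) cancels: output equals input
    assert np.allclose(out.values, dyn.values, atol=1e-10)


def test_hypr_segments_and_validation():
    dyn = make_dynamic(np.ones((4, 4, 4, 30)))
    with pytest.raises(ValueError):
        pp.hypr_lr_denoise(dyn, segments=((1, 8), (9, 20)))  # frames 21-30 uncovered
    with pytest.raises(ValueError):
        pp.hypr_lr_denoise(dyn, segments=((0, 30),))  # 1-based indices
    out = pp.hypr_lr_denoise(dyn, segments=((1, 20), (20, 30)))
    assert out.values.shape == dyn.values.shape


def test_hypr_reduces_noise_preserves_kinetics():
    rng = np.random.default_rng(3)
    times = default_frame_times()
    clean = simulate_tac(TACModelParams(amplitude=1.0, peak_time=12.0,
                                        washout_rate=0.02, baseline=0.3),
                         times)
    vol = np.ones((12, 12, 12, 30)) * clean
    noisy = vol + rng.normal(0, 0.25, vol.shape)
    den = pp.hypr_lr_denoise(make_dynamic(noisy))
    inner = (slice(3, 9),) * 3
    err_before = np.abs(noisy[inner] - vol[inner]).mean()
    err_after = np.abs(den.values[inner] - vol[inner]).mean()
    assert err_after < 0.5 * err_before


# --------------------------------------------------------------------------
# TAC fitting
# --------------------------------------------------------------------------

def test_fit_tac_reproduces_line_exactly():
    times = default_frame_times()
    line = 0.5 + 0.1 * times
    fitted = pp.fit_tac(line, times)
    assert np.allclose(fitted, line, atol=1e-8)  # splines reproduce lines


def test_fit_tac_outlier_robustness():
    times = default_frame_times()
    clean = simulate_tac(TACModelParams(amplitude=1.0, peak_time=15.0,
                                        washout_rate=0.02, baseline=0.3),
                         times)
    corrupted = clean.copy()
    corrupted[2] += 0.15 * clean.max()  # early-frame spike
    fitted = pp.fit_tac(corrupted, times)
    assert times[np.argmax(fitted)] == times[np.argmax(clean)]


def test_fit_tacs_vectorized_matches_single():
    rng = np.random.default_rng(4)
    times = default_frame_times()
    tacs = rng.random((20, 30))
    batch = pp.fit_tacs(tacs, times)
    single = np.stack([pp.fit_tac(t, times) for t in tacs])
    assert np.allclose(batch, single, atol=1e-10)


def test_fit_tac_all_zero_warns():
    times = default_frame_times()
    out = pp.fit_tac(np.zeros(30), times)
    assert np.allclose(out, 0.0)


# --------------------------------------------------------------------------
# Parametric images
# --------------------------------------------------------------------------

def test_make_tbr_image_values():
    static, dyn, brain, tumor = _uniform_scene(brain_level=1.0,
                                               tumor_level=2.5)
    ref = pp.compute_brain_reference(static, dyn, brain)
    tbr, tbr_mean = pp.make_tbr_image(static, ref, tumor)
    assert tbr.kind == "TBR"
    assert np.allclose(tbr.values[tumor.values], 2.5)
    assert np.isclose(tbr_mean, 2.5)
    assert np.all(tbr.values[~tumor.values] == 0)


def test_make_ttp_image_recovers_planted_peaks():
    times = default_frame_times()
    brain_tac = brain_reference_tac(times)
    shape = (6, 6, 6)
    planted = np.random.default_rng(5).integers(4, 28, shape).astype(float)
    dyn = np.zeros(shape + (30,))
    for idx in np.ndindex(shape):
        ratio = simulate_tac(TACModelParams(
            amplitude=1.0, peak_time=float(planted[idx]), washout_rate=0.02,
            baseline=0.3), times)
        dyn[idx] = ratio * brain_tac
    tumor = make_mask(np.ones(shape, bool))
    ref = pp.BrainReference(1.0, brain_tac, pp.fit_tac(brain_tac, times))
    ttp, valid = pp.make_ttp_image(make_dynamic(dyn), ref, tumor)
    assert ttp.kind == "TTP"
    assert valid.n_voxels == tumor.n_voxels
    # noiseless: the fitted ratio's argmax recovers every planted peak
    grid_truth = times[np.abs(times[None, :] -
                              planted.ravel()[:, None]).argmin(axis=1)]
    assert np.array_equal(ttp.values[tumor.values], grid_truth)


def test_make_ttp_image_drops_zero_voxels():
    shape = (4, 4, 4)
    dyn = np.ones(shape + (30,))
    dyn[0, 0, 0] = 0.0
    tumor = make_mask(np.ones(shape, bool))
    times = default_frame_times()
    ref = pp.BrainReference(1.0, np.ones(30), np.ones(30))
    ttp, valid = pp.make_ttp_image(make_dynamic(dyn), ref, tumor)
    assert valid.n_voxels == tumor.n_voxels - 1
    assert not valid.values[0, 0, 0]
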