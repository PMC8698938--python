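"""From raw dynamic/static PET volumes to TBR and TTP parametric images.

The analysis chain is: resample everything to an isotropic 2 mm grid,
compute the healthy-brain reference (SUV_mean and fitted mean TAC), segment
the tumor at 1.6 x brain SUV_mean with seeded connected-component selection,
denoise the dynamic series with HYPR-LR, and synthesize the two parametric
images — static TBR (SUV normalized by brain SUV_mean) and voxel-level TTP
(time of the maximum of the fitted voxel TAC divided by the fitted mean
brain TAC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import gaussian_filter, label

from .images import DynamicImage, Mask, ParametricImage

__all__ = [
    "BrainReference",
    "EmptySegmentationError",
    "resample_isotropic",
    "compute_brain_reference",
    "segment_tumor",
    "hypr_lr_denoise",
    "fit_tac",
    "fit_tacs",
    "make_tbr_image",
    "make_ttp_image",
    "register_frames_identity",
    "DEFAULT_SPACING_MM",
    "DEFAULT_HYPR_SEGMENTS",
    "DEFAULT_FWHM_MM",
    "TUMOR_THRESHOLD_RATIO",
    "DEFAULT_SPLINE_LAM",
]

log = logging.getLogger("dynrad")

DEFAULT_SPACING_MM = 2.0
TUMOR_THRESHOLD_RATIO = 1.6
# Composite frame ranges (1-based, inclusive): uptake, specific retention,
# equilibrium phases of a 30 x 1-min acquisition.
DEFAULT_HYPR_SEGMENTS = ((1, 8), (8, 20), (20, 30))
DEFAULT_FWHM_MM = 9.0
# Smoothing parameter of the cubic smoothing spline used for TAC fitting,
# fixed once on phantom calibration runs (see docs/methods.md).
DEFAULT_SPLINE_LAM = 0.01

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class EmptySegmentationError(RuntimeError):
    """No voxel survives thresholding / seeded component selection."""


@dataclass
class BrainReference:
    """Healthy-brain normalizers: static SUV_mean and the (fitted) mean TAC."""

    suv_mean: float
    mean_tac: np.ndarray
    fitted_mean_tac: np.ndarray

    def __post_init__(self):
        if not self.suv_mean > 0:
            raise ValueError("brain SUV_mean must be positive")


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

def _resample_3d(values, spacing, target, interpolator):
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.transpose(values.astype(np.float64), (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    out_size = [int(np.ceil(n * s / t))
                for n, s, t in zip(values.shape, spacing, target)]
    out = sitk.Resample(
        img, out_size, sitk.Transform(), interpolator,
        img.GetOrigin(), tuple(float(t) for t in target),
        img.GetDirection(), 0.0, sitk.sitkFloat64)
    return np.transpose(sitk.GetArrayFromImage(out), (2, 1, 0))


def resample_isotropic(image, target_spacing=DEFAULT_SPACING_MM):
    """Resample to an isotropic grid covering the input physical extent.

    Linear interpolation for images; masks use nearest neighbour and are
    re-binarized.  Inputs already on the target grid pass through untouched.
    """
    target = np.asarray([target_spacing] * 3, dtype=float) \
        if np.isscalar(target_spacing) else np.asarray(target_spacing, float)
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    if image.values.size == 0:
        raise ValueError("cannot resample an empty image")
    spacing = np.asarray(image.spacing, dtype=float)
    if np.allclose(spacing, target):
        return image

    if isinstance(image, Mask):
        res = _resample_3d(image.values.astype(float), spacing, target,
                           sitk.sitkNearestNeighbor)
        return Mask(res > 0.5, target, role=image.role)
    if isinstance(image, ParametricImage):
        res = _resample_3d(image.values, spacing, target, sitk.sitkLinear)
        return ParametricImage(res, target, kind=image.kind)
    if isinstance(image, DynamicImage):
        frames = [
            _resample_3d(image.values[..., f], spacing, target, sitk.sitkLinear)
            for f in range(image.n_frames)
        ]
        return DynamicImage(np.stack(frames, axis=3), target,
                            image.frame_times)
    raise TypeError(f"unsupported image type {type(image)!r}")


# --------------------------------------------------------------------------
# Brain reference and tumor segmentation
# --------------------------------------------------------------------------

def compute_brain_reference(static: ParametricImage, dynamic: DynamicImage,
                            brain: Mask) -> BrainReference:
    if brain.n_voxels == 0:
        raise ValueError("brain mask is empty")
    if static.shape != brain.shape or dynamic.shape != brain.shape:
        raise ValueError("brain mask must share the image grid")
    suv_mean = float(static.values[brain.values].mean())
    mean_tac = dynamic.values[brain.values].mean(axis=0).astype(float)
    fitted = fit_tac(mean_tac, dynamic.frame_times)
    return BrainReference(suv_mean, mean_tac, fitted)


def segment_tumor(static: ParametricImage, ref: BrainReference,
                  seed_region) -> Mask:
    """Threshold at 1.6 x brain SUV_mean, keep components touching the seed.

    ``seed_region`` is a :class:`Mask` or a bounding box
    ``((x0, x1), (y0, y1), (z0, z1))`` of half-open voxel ranges standing in
    for the manual interaction of a semi-automatic workflow.
    """
    above = static.values >= TUMOR_THRESHOLD_RATIO * ref.suv_mean
    if not above.any():
        raise EmptySegmentationError(
            "no voxel reaches 1.6 x brain SUV_mean")
    if isinstance(seed_region, Mask):
        seed = seed_region.values
    else:
        seed = np.zeros(static.shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = seed_region
        seed[x0:x1, y0:y1, z0:z1] = True
    labels, n = label(above, structure=_STRUCT_26)
    keep = np.unique(labels[seed & above])
    keep = keep[keep > 0]
    if keep.size == 0:
        raise EmptySegmentationError(
            "no thresholded component intersects the seed region")
    return Mask(np.isin(labels, keep), static.spacing, role="tumor")


# --------------------------------------------------------------------------
# HYPR-LR denoising
# --------------------------------------------------------------------------

def hypr_lr_denoise(dynamic: DynamicImage,
                    segments=DEFAULT_HYPR_SEGMENTS,
                    fwhm_mm: float = DEFAULT_FWHM_MM) -> DynamicImage:
    """HYPR-LR: for frame *f* in segment *s* with composite C_s (time-average
    of the segment's frames), output ``C_s * G(f) / G(C_s)`` where *G* is
    Gaussian smoothing at the given FWHM.  Voxels where ``G(C_s)`` falls
    below 1e-8 x image max are set to zero.
    """
    n = dynamic.n_frames
    segments = [tuple(s) for s in segments]
    for lo, hi in segments:
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"segment ({lo}, {hi}) outside 1..{n}")
    assignment = np.full(n, -1, dtype=int)
    for si, (lo, hi) in enumerate(segments):
        for f in range(lo - 1, hi):
            if assignment[f] < 0:
                assignment[f] = si
    if np.any(assignment < 0):
        missing = np.where(assignment < 0)[0] + 1
        raise ValueError(f"segments do not cover frames {missing.tolist()}")

    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) \
        / np.asarray(dynamic.spacing, dtype=float)

    def G(vol):
        return gaussian_filter(vol, sigma=sigma_vox, mode="nearest")

    values = dynamic.values.astype(float)
    eps = 1e-8 * float(np.max(values)) if values.size else 0.0
    out = np.empty_like(values)
    for si, (lo, hi) in enumerate(segments):
        comp = values[..., lo - 1:hi].mean(axis=3)
        g_comp = G(comp)
        safe = g_comp > eps
        for f in np.where(assignment == si)[0]:
            ratio = np.zeros_like(comp)
            np.divide(G(values[..., f]), g_comp, out=ratio, where=safe)
            out[..., f] = comp * ratio
    return DynamicImage(out, dynamic.spacing, dynamic.frame_times)


def register_frames_identity(dynamic: DynamicImage) -> DynamicImage:
    """Motion-correction hook.  Phantoms are motion-free, so the default
    registration is the identity; replace for real data."""
    return dynamic


# --------------------------------------------------------------------------
# TAC fitting
# --------------------------------------------------------------------------

_SMOOTHER_CACHE: dict = {}


def _smoother_matrix(times: tuple, lam: float) -> np.ndarray:
    """Linear smoother S of the cubic smoothing spline at the sample points.

    The spline fit is linear in the data, so S is obtained once by fitting
    the identity's columns; batched fitting is then a matrix product.
    """
    key = (times, lam)
    if key not in _SMOOTHER_CACHE:
        t = np.asarray(times, dtype=float)
        n = len(t)
        S = np.empty((n, n))
        eye = np.eye(n)
        for j in range(n):
            S[:, j] = make_smoothing_spline(t, eye[:, j], lam=lam)(t)
        _SMOOTHER_CACHE[key] = S
    return _SMOOTHER_CACHE[key]


def fit_tacs(tacs: np.ndarray, times, lam: float = DEFAULT_SPLINE_LAM) -> np.ndarray:
    """Fit many TACs at once: rows of ``tacs`` are curves over ``times``."""
    tacs = np.atleast_2d(np.asarray(tacs, dtype=float))
    S = _smoother_matrix(tuple(np.asarray(times, float)), lam)
    return tacs @ S.T


def fit_tac(tac, times=None, lam: float = DEFAULT_SPLINE_LAM) -> np.ndarray:
    """Deterministic cubic-smoothing-spline fit of one TAC, evaluated at the
    same frame times.  An all-zero TAC returns all zeros (flagged)."""
    tac = np.asarray(tac, dtype=float)
    if times is None:
        times = np.arange(1, len(tac) + 1, dtype=float)
    if np.all(tac == 0):
        log.warning("fit_tac: all-zero TAC, returning zeros")
        return np.zeros_like(tac)
    return fit_tacs(tac[None, :], times, lam)[0]


# --------------------------------------------------------------------------
# Parametric image synthesis
# --------------------------------------------------------------------------

def make_tbr_image(static: ParametricImage, ref: BrainReference,
                   tumor: Mask):
    """TBR = SUV / brain SUV_mean over the tumor mask (zero elsewhere).

    Returns ``(tbr_image, tbr_mean)`` with the mask-mean TBR as the named
    scalar the reference model consumes.
    """
    values = np.zeros(static.shape)
    values[tumor.values] = static.values[tumor.values] / ref.suv_mean
    tbr_mean = float(values[tumor.values].mean())
    return ParametricImage(values, static.spacing, kind="TBR"), tbr_mean


def make_ttp_image(dynamic: DynamicImage, ref: BrainReference,
                   tumor: Mask, lam: float = DEFAULT_SPLINE_LAM):
    """Voxel-level time-to-peak of the fitted TAC ratio, in minutes.

    Each tumor voxel's TAC is spline-fitted and divided by the fitted mean
    brain TAC; TTP is the frame time of the ratio's maximum (earliest sample
    on ties/plateaus).  All-zero voxels are flagged invalid and dropped from
    the returned mask.
    """
    if np.any(ref.fitted_mean_tac <= 0):
        raise ValueError("fitted mean brain TAC must be positive everywhere")
    times = dynamic.frame_times
    tacs = dynamic.values[tumor.values].astype(float)
    valid_rows = ~np.all(tacs == 0, axis=1)
    if not np.all(valid_rows):
        log.warning("make_ttp_image: %d all-zero voxels excluded",
                    int((~valid_rows).sum()))
    fitted = fit_tacs(tacs[valid_rows], times, lam)
    ratio = fitted / ref.fitted_mean_tac
    ttp = times[np.argmax(ratio, axis=1)]

    out = np.zeros(dynamic.shape)
    valid = np.zeros(dynamic.shape, dtype=bool)
    coords = np.where(tumor.values)
    vc = tuple(c[valid_rows] for c in coords)
    out[vc] = ttp
    valid[vc] = True
    return (ParametricImage(out, dynamic.spacing, kind="TTP"),
            Mask(valid, dynamic.spacing, role="tumor"))
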