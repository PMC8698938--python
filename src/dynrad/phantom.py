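"""Synthetic dynamic-PET phantom cohorts with known ground truth.

The generator emulates a 30 x 1-min amino-acid brain PET protocol: each
subject carries an ellipsoidal tumor whose voxel kinetics follow a
gamma-variate rise with exponential washout, a spherical healthy-brain
reference region with a fixed population time-activity curve (TAC), and a
static image defined as the time-average of frames 11-30 (the last 20 min of
the acquisition).  Spatial texture is planted in both the tumor-to-brain
ratio (TBR) and the time-to-peak (TTP) fields through smooth Gaussian random
fields, scanner (batch) effects are applied as additive shift plus
multiplicative scale on those generating fields, and progression labels
(progression-free survival below six months) are planted with configurable
effect size and prevalence.

Every artifact is reproducible from ``(config, seed)``; per-voxel truth maps
for TTP and TBR are stored so downstream parametric-image synthesis can be
verified exactly.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .images import DynamicImage, Mask, ParametricImage, default_frame_times, \
    write_nifti, read_nifti

__all__ = [
    "TACModelParams",
    "TextureFieldSpec",
    "ClinicalRecord",
    "SubjectSpec",
    "ImageGrid",
    "CohortConfig",
    "PhantomCohort",
    "simulate_tac",
    "brain_reference_tac",
    "build_phantom",
    "simulate_cohort",
    "oracle_signal_auc",
    "save_cohort",
]

# Frames whose time-average defines the static image (last 20 of 30 min),
# 0-based slice.
STATIC_FRAME_SLICE = slice(10, 30)

# Six-month dichotomization threshold in days.
PFS_THRESHOLD_DAYS = 183


# --------------------------------------------------------------------------
# Voxel kinetics
# --------------------------------------------------------------------------

@dataclass
class TACModelParams:
    """Parameters of the piecewise tumor-to-brain ratio kinetic model.

    The curve rises as a gamma-variate normalized to peak exactly at
    ``peak_time`` with value ``baseline + amplitude`` and then decays
    exponentially at ``washout_rate`` (flat plateau when zero).
    """

    amplitude: float
    peak_time: float
    rise_shape: float = 3.0
    washout_rate: float = 0.0
    baseline: float = 0.0

    def __post_init__(self):
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not (1.0 <= self.peak_time <= 30.0):
            raise ValueError("peak_time must lie in [1, 30] min")
        if not self.rise_shape > 0:
            raise ValueError("rise_shape must be > 0")
        if self.washout_rate < 0:
            raise ValueError("washout_rate must be >= 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")


def simulate_tac(params: TACModelParams, times) -> np.ndarray:
    """Evaluate the kinetic model at ``times`` (minutes).

    The result is unimodal with its continuous-time maximum at
    ``params.peak_time``; on a sampling grid the argmax falls on the sample
    nearest the peak (up to the rise/washout asymmetry of the model).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1D vector")
    tp, r = params.peak_time, params.rise_shape
    rise = (times / tp) ** r * np.exp(r * (1.0 - times / tp))
    decay = np.exp(-params.washout_rate * (times - tp))
    curve = params.baseline + params.amplitude * np.where(times <= tp, rise, decay)
    return curve


def brain_reference_tac(times=None) -> np.ndarray:
    """Population healthy-brain TAC: early moderate peak, slow washout."""
    if times is None:
        times = default_frame_times()
    return simulate_tac(
        TACModelParams(amplitude=0.8, peak_time=6.0, rise_shape=2.0,
                       washout_rate=0.004, baseline=0.4),
        times,
    )


# --------------------------------------------------------------------------
# Subject and cohort specifications
# --------------------------------------------------------------------------

@dataclass
class TextureFieldSpec:
    """Smooth Gaussian-random-field spec: mean level, fluctuation amplitude
    (SD of the field) and spatial correlation length in mm."""

    mean: float
    amplitude: float
    correlation_mm: float = 6.0


@dataclass
class ClinicalRecord:
    age: float
    sex: int
    who_grade: int
    idh: int
    codeletion_1p19q: int
    prior_resection: int
    mri_contrast_enhancement: int

    def __post_init__(self):
        if self.who_grade not in (3, 4):
            raise ValueError("who_grade must be 3 or 4")
        for name in ("sex", "idh", "codeletion_1p19q", "prior_resection",
                     "mri_contrast_enhancement"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be binary")


@dataclass
class SubjectSpec:
    subject_id: str
    label_pfs_days: int
    batch_id: str
    center: str
    tumor_center_mm: tuple
    tumor_radii_mm: tuple
    tbr_texture: TextureFieldSpec
    ttp_texture: TextureFieldSpec
    clinical: ClinicalRecord


@dataclass
class ImageGrid:
    shape: tuple = (28, 28, 28)
    spacing: tuple = (2.0, 2.0, 2.0)

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


# Canonical per-batch (additive TBR shift, multiplicative scale, additive TTP
# shift in min); index 0 is the reference scanner and carries no effect.
_BATCH_EFFECT_TABLE = [
    (0.0, 1.00, 0.0),
    (0.12, 1.10, 1.2),
    (-0.10, 0.92, -1.0),
    (0.08, 1.15, 1.5),
]


@dataclass
class CohortConfig:
    """Study-condition settings for a phantom cohort.

    Defaults mirror the multicentric cohort scale: 55 training-center and 30
    test-center subjects, progression prevalence 61/85, two scanners per
    center with the reference scanner first in the training center.
    """

    n_per_center: dict = field(default_factory=lambda: {"A": 55, "B": 30})
    batches_per_center: dict = field(default_factory=lambda: {
        "A": ["vereos", "biograph6"], "B": ["mct", "signa"]})
    prevalence: float = 61.0 / 85.0
    effect: str = "none"              # none | static | dynamic | both
    effect_size: float = 1.0
    batch_effect_size: float = 1.0
    snr_dynamic: float | None = 10.0  # tumor activity / frame noise SD
    noise_static: float = 0.05        # fraction of healthy-brain SUV_mean
    grid_shape: tuple = (28, 28, 28)
    grid_spacing: tuple = (2.0, 2.0, 2.0)
    tumor_radii_mm: tuple = (8.0, 7.0, 7.0)
    tbr_mean: float = 2.3
    tbr_amplitude: float = 0.35
    ttp_mean_min: float = 16.0
    ttp_amplitude_min: float = 4.0
    correlation_mm: float = 6.0
    # Shift applied to progressors when the corresponding effect is planted.
    tbr_shift_per_unit: float = 0.4
    ttp_shift_per_unit_min: float = -6.0
    harmonization: bool = True

    def __post_init__(self):
        if self.effect not in ("none", "static", "dynamic", "both"):
            raise ValueError("effect must be none|static|dynamic|both")
        all_batches = [b for bs in self.batches_per_center.values() for b in bs]
        if len(set(all_batches)) != len(all_batches):
            raise ValueError("batch ids must be unique across centers")
        if self.harmonization and len(all_batches) < 2:
            raise ValueError(
                "harmonization requires at least 2 batches in the cohort")

    @property
    def reference_batch(self) -> str:
        first_center = sorted(self.batches_per_center)[0]
        return self.batches_per_center[first_center][0]

    @property
    def all_batches(self) -> list:
        return [b for c in sorted(self.batches_per_center)
                for b in self.batches_per_center[c]]

    def batch_effects(self) -> dict:
        """Per-batch (tbr_shift, scale, ttp_shift) scaled by batch_effect_size."""
        out = {}
        for i, b in enumerate(self.all_batches):
            shift, scale, tshift = _BATCH_EFFECT_TABLE[i % len(_BATCH_EFFECT_TABLE)]
            s = self.batch_effect_size
            out[b] = (shift * s, 1.0 + (scale - 1.0) * s, tshift * s)
        return out

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "grid_spacing", "tumor_radii_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PhantomCohort:
    subjects: list
    dynamic_images: dict
    static_images: dict
    tumor_masks: dict
    brain_masks: dict
    truth_ttp: dict
    truth_tbr: dict
    manifest: pd.DataFrame
    config: CohortConfig

    def manifest_hash(self) -> str:
        buf = io.StringIO()
        self.manifest.to_csv(buf, index=False, float_format="%.10g")
        h = hashlib.sha256(buf.getvalue().encode())
        for spec in self.subjects:
            h.update(np.ascontiguousarray(
                self.dynamic_images[spec.subject_id].values).tobytes())
            h.update(np.ascontiguousarray(
                self.static_images[spec.subject_id].values).tobytes())
        return h.hexdigest()


# --------------------------------------------------------------------------
# Phantom construction
# --------------------------------------------------------------------------

def _smooth_field(shape, spacing, corr_mm, rng) -> np.ndarray:
    """Unit-SD smooth Gaussian random field via filtered white noise."""
    from scipy.ndimage import gaussian_filter
    white = rng.standard_normal(shape)
    sigma_vox = corr_mm / np.asarray(spacing, float)
    f = gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipsoid_mask(grid: ImageGrid, center_mm, radii_mm) -> np.ndarray:
    coords = [np.arange(n) * s + s / 2.0
              for n, s in zip(grid.shape, grid.spacing)]
    xg, yg, zg = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    return ((xg - cx) / rx) ** 2 + ((yg - cy) / ry) ** 2 + \
        ((zg - cz) / rz) ** 2 <= 1.0


# Uptake threshold the segmentation stage relies on: tumor voxels are
# constructed to exceed 1.6 x healthy-brain SUV_mean.
SEGMENTATION_TBR_FLOOR = 1.8
MIN_TUMOR_VOXELS = 64
RESAMPLED_VOXEL_MM3 = 8.0  # 2 mm isotropic analysis grid


def build_phantom(spec: SubjectSpec, grid: ImageGrid, seed,
                  snr_dynamic: float | None = None,
                  noise_static: float = 0.0):
    """Build one subject's artifacts.

    Returns ``(dynamic, static, tumor_mask, brain_mask, truth_ttp, truth_tbr)``
    where the static SUV image is the frame 11-30 time-average of the
    noise-free dynamic signal plus optional static noise, and the truth maps
    hold the per-voxel planted TTP (min) and TBR values on the native grid.
    """
    rng = np.random.default_rng(seed)
    grid = grid if isinstance(grid, ImageGrid) else ImageGrid(*grid)
    shape = tuple(grid.shape)
    spacing = np.asarray(grid.spacing, dtype=float)
    times = default_frame_times()

    center = np.asarray(spec.tumor_center_mm, float)
    radii = np.asarray(spec.tumor_radii_mm, float)
    extent = grid.extent_mm
    if np.any(center - radii < 0) or np.any(center + radii > extent):
        raise ValueError("tumor extends outside the field of view")
    if (4.0 / 3.0) * np.pi * np.prod(radii) < MIN_TUMOR_VOXELS * RESAMPLED_VOXEL_MM3:
        raise ValueError(
            "tumor volume below 64 voxels on the 2 mm analysis grid")

    tumor = _ellipsoid_mask(grid, center, radii)
    brain_center = 0.27 * extent
    brain_center[2] = 0.5 * extent[2]
    brain = _ellipsoid_mask(grid, brain_center, (7.0, 7.0, 7.0))
    if np.any(tumor & brain):
        raise ValueError("tumor and healthy-brain regions overlap")

    # Planted spatial fields.
    tbr_field = spec.tbr_texture.mean + spec.tbr_texture.amplitude * \
        _smooth_field(shape, spacing, spec.tbr_texture.correlation_mm, rng)
    tbr_field = np.clip(tbr_field, SEGMENTATION_TBR_FLOOR, None)
    ttp_field = spec.ttp_texture.mean + spec.ttp_texture.amplitude * \
        _smooth_field(shape, spacing, spec.ttp_texture.correlation_mm, rng)
    # Planted peak times are quantized to the 1-min frame grid: a peak
    # halfway between frames is not representable at protocol resolution and
    # would make the per-voxel ground truth ill-defined (knife-edge argmax).
    ttp_field = np.clip(np.round(ttp_field), 2.0, 29.0)

    brain_tac = brain_reference_tac(times)
    brain_suv_mean = brain_tac[STATIC_FRAME_SLICE].mean()

    dyn = np.empty(shape + (len(times),), dtype=np.float32)
    # Background: low flat uptake.
    dyn[...] = (0.3 * brain_tac).astype(np.float32)
    dyn[brain] = brain_tac.astype(np.float32)

    # Tumor voxels: ratio-curve shape set by the planted TTP, rescaled so the
    # frame 11-30 average of ratio*brain equals the planted TBR exactly.
    idx = np.argwhere(tumor)
    tvox = ttp_field[tumor]
    bvox = tbr_field[tumor]
    base = np.empty((len(idx), len(times)))
    for i, (tp, tb) in enumerate(zip(tvox, bvox)):
        curve = simulate_tac(
            TACModelParams(amplitude=1.0, peak_time=float(tp),
                           rise_shape=3.0, washout_rate=0.02, baseline=0.3),
            times)
        late = (curve * brain_tac)[STATIC_FRAME_SLICE].mean()
        base[i] = curve * (tb * brain_suv_mean / late)
    dyn[tumor] = (base * brain_tac).astype(np.float32)

    clean_static = dyn[..., STATIC_FRAME_SLICE].mean(axis=3)

    if snr_dynamic is not None:
        tumor_level = float(dyn[tumor].mean())
        sd = tumor_level / float(snr_dynamic)
        dyn = dyn + rng.normal(0.0, sd, dyn.shape).astype(np.float32)
    static = clean_static.astype(float)
    if noise_static > 0:
        static = static + rng.normal(
            0.0, noise_static * brain_suv_mean, shape)

    # Per-voxel truth TTP: argmax of the ratio curve on the frame grid.
    tt = times[np.argmax(base, axis=1)]
    truth_ttp = np.zeros(shape)
    truth_ttp[tumor] = tt
    truth_tbr = np.zeros(shape)
    truth_tbr[tumor] = bvox

    dynamic = DynamicImage(dyn, spacing, times)
    static_img = ParametricImage(static, spacing, kind="SUV")
    return (dynamic, static_img, Mask(tumor, spacing, "tumor"),
            Mask(brain, spacing, "brain"), truth_ttp, truth_tbr)


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

def _draw_clinical(rng) -> ClinicalRecord:
    return ClinicalRecord(
        age=float(np.clip(np.round(rng.normal(57.0, 12.0), 1), 21.0, 80.0)),
        sex=int(rng.random() < 0.46),
        who_grade=4 if rng.random() < 0.7 else 3,
        idh=int(rng.random() < 0.35),
        codeletion_1p19q=int(rng.random() < 0.12),
        prior_resection=int(rng.random() < 0.65),
        mri_contrast_enhancement=int(rng.random() < 0.8),
    )


def simulate_cohort(config: CohortConfig, seed) -> PhantomCohort:
    """Generate a full phantom cohort under the configured study conditions."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    grid = ImageGrid(config.grid_shape, config.grid_spacing)
    extent = grid.extent_mm
    effects = config.batch_effects()

    subjects, rows = [], []
    dynamic_images, static_images = {}, {}
    tumor_masks, brain_masks = {}, {}
    truth_ttp, truth_tbr = {}, {}

    subject_seeds = iter(ss.spawn(sum(config.n_per_center.values())))

    for center in sorted(config.n_per_center):
        n = config.n_per_center[center]
        batches = config.batches_per_center[center]
        n_pos = int(round(config.prevalence * n))
        labels = np.zeros(n, dtype=int)
        labels[:n_pos] = 1
        rng.shuffle(labels)
        for i in range(n):
            sid = f"{center}{i:03d}"
            progressed = bool(labels[i])
            pfs = int(rng.integers(30, PFS_THRESHOLD_DAYS)) if progressed \
                else int(rng.integers(PFS_THRESHOLD_DAYS, 731))
            batch = batches[i % len(batches)]
            tbr_shift, scale, ttp_shift = effects[batch]

            tbr_mean = config.tbr_mean + tbr_shift
            ttp_mean = config.ttp_mean_min + ttp_shift
            if progressed and config.effect in ("static", "both"):
                tbr_mean += config.tbr_shift_per_unit * config.effect_size
            if progressed and config.effect in ("dynamic", "both"):
                ttp_mean += config.ttp_shift_per_unit_min * config.effect_size
            tbr_amp = config.tbr_amplitude * scale
            ttp_amp = config.ttp_amplitude_min * scale

            # mild per-subject jitter of tumor placement/size
            jitter = rng.uniform(-1.5, 1.5, 3)
            t_center = 0.62 * extent + jitter
            radii = np.asarray(config.tumor_radii_mm) * rng.uniform(0.95, 1.1)

            spec = SubjectSpec(
                subject_id=sid, label_pfs_days=pfs, batch_id=batch,
                center=center, tumor_center_mm=tuple(t_center),
                tumor_radii_mm=tuple(radii),
                tbr_texture=TextureFieldSpec(tbr_mean, tbr_amp,
                                             config.correlation_mm),
                ttp_texture=TextureFieldSpec(ttp_mean, ttp_amp,
                                             config.correlation_mm),
                clinical=_draw_clinical(rng),
            )
            dyn, stat, tmask, bmask, t_ttp, t_tbr = build_phantom(
                spec, grid, next(subject_seeds),
                snr_dynamic=config.snr_dynamic,
                noise_static=config.noise_static)
            subjects.append(spec)
            dynamic_images[sid] = dyn
            static_images[sid] = stat
            tumor_masks[sid] = tmask
            brain_masks[sid] = bmask
            truth_ttp[sid] = t_ttp
            truth_tbr[sid] = t_tbr
            rows.append({
                "subject_id": sid, "center": center, "batch_id": batch,
                "pfs_days": pfs, "label": int(progressed),
                **asdict(spec.clinical),
            })

    manifest = pd.DataFrame(rows)
    return PhantomCohort(subjects, dynamic_images, static_images,
                         tumor_masks, brain_masks, truth_ttp, truth_tbr,
                         manifest, config)


def oracle_signal_auc(cohort: PhantomCohort) -> float:
    """AUC of the planted ground-truth signal feature against the labels.

    The signal feature is the subject-mean of the truth field carrying the
    planted effect (mean truth TTP for dynamic effects, mean truth TBR for
    static ones); progression is coded so larger feature values score higher.
    """
    from sklearn.metrics import roc_auc_score
    cfg = cohort.config
    y = cohort.manifest["label"].to_numpy()
    if cfg.effect in ("dynamic", "both"):
        maps, flip = cohort.truth_ttp, cfg.ttp_shift_per_unit_min < 0
    else:
        maps, flip = cohort.truth_tbr, cfg.tbr_shift_per_unit < 0
    masks = cohort.tumor_masks
    x = np.array([maps[s.subject_id][masks[s.subject_id].values].mean()
                  for s in cohort.subjects])
    if flip:
        x = -x
    return float(roc_auc_score(y, x))


def save_cohort(cohort: PhantomCohort, directory) -> None:
    """Write cohort artifacts: NIfTI volumes/masks, CSV manifest, YAML config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_csv(directory / "manifest.csv", index=False)
    cohort.config.to_yaml(directory / "config.yaml")
    for spec in cohort.subjects:
        sid = spec.subject_id
        write_nifti(cohort.dynamic_images[sid], directory / f"{sid}_dynamic.nii.gz")
        write_nifti(cohort.static_images[sid], directory / f"{sid}_static.nii.gz")
        write_nifti(cohort.tumor_masks[sid], directory / f"{sid}_tumor.nii.gz")
        write_nifti(cohort.brain_masks[sid], directory / f"{sid}_brain.nii.gz")
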