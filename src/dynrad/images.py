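"""Shared image containers and NIfTI I/O.

Volumes are stored as plain numpy arrays in ``(x, y, z[, frame])`` order with
an isotropic-or-not voxel ``spacing`` in millimetres.  Dynamic acquisitions
additionally carry ``frame_times`` in minutes; the convention throughout the
package is that frame *i* (1-based) is stamped with its end time of *i*
minutes for a 30 x 1-min protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DynamicImage",
    "ParametricImage",
    "Mask",
    "default_frame_times",
    "read_nifti",
    "write_nifti",
    "read_frame_times",
    "write_frame_times",
]

N_FRAMES = 30

PARAMETRIC_KINDS = ("SUV", "TBR", "TTP")


def default_frame_times(n_frames: int = N_FRAMES) -> np.ndarray:
    """End-of-frame times in minutes for ``n_frames`` 1-min frames."""
    return np.arange(1, n_frames + 1, dtype=float)


def _check_spacing(spacing) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing}")
    return spacing


@dataclass
class DynamicImage:
    """4D activity volume ``(x, y, z, frame)`` with frame times in minutes."""

    values: np.ndarray
    spacing: np.ndarray
    frame_times: np.ndarray = field(default_factory=default_frame_times)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(float)
        if self.values.ndim != 4:
            raise ValueError("DynamicImage expects a 4D array (x, y, z, frame)")
        self.spacing = _check_spacing(self.spacing)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape[0] != self.values.shape[3]:
            raise ValueError("frame_times length must match the frame axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    @property
    def shape(self):
        return self.values.shape[:3]


@dataclass
class ParametricImage:
    """3D parametric map tagged by kind (SUV, TBR or TTP)."""

    values: np.ndarray
    spacing: np.ndarray
    kind: str = "SUV"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ParametricImage expects a 3D array")
        self.spacing = _check_spacing(self.spacing)
        if self.kind not in PARAMETRIC_KINDS:
            raise ValueError(f"kind must be one of {PARAMETRIC_KINDS}")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class Mask:
    """3D boolean mask sharing the grid of the image it annotates."""

    values: np.ndarray
    spacing: np.ndarray
    role: str = "tumor"

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("Mask expects a 3D array")
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self):
        return self.values.shape


# --------------------------------------------------------------------------
# NIfTI I/O.  The affine is diagonal (RAS, origin at zero): phantoms carry no
# anatomical orientation, only voxel spacing matters downstream.
# --------------------------------------------------------------------------

def write_nifti(image, path) -> None:
    path = Path(path)
    affine = np.diag(list(np.asarray(image.spacing, float)) + [1.0])
    data = image.values.astype(np.float32)
    if isinstance(image, Mask):
        data = image.values.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path, kind: str | None = None, role: str | None = None,
               frame_times=None):
    """Load a NIfTI volume as the matching container.

    4D data yields a :class:`DynamicImage`; 3D data yields a
    :class:`ParametricImage` (``kind``, default SUV) or a :class:`Mask` when
    ``role`` is given.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if data.ndim == 4:
        if frame_times is None:
            frame_times = default_frame_times(data.shape[3])
        return DynamicImage(data, spacing, frame_times)
    if role is not None:
        return Mask(data > 0, spacing, role=role)
    return ParametricImage(data.astype(float), spacing, kind=kind or "SUV")


def write_frame_times(frame_times, path) -> None:
    """Sidecar JSON of frame timing: index plus start/end in seconds."""
    frame_times = np.asarray(frame_times, dtype=float)
    starts = np.concatenate([[0.0], frame_times[:-1]]) * 60.0
    ends = frame_times * 60.0
    rows = [
        {"frame": i + 1, "start_s": float(s), "end_s": float(e)}
        for i, (s, e) in enumerate(zip(starts, ends))
    ]
    Path(path).write_text(json.dumps(rows, indent=1))


def read_frame_times(path) -> np.ndarray:
    rows = json.loads(Path(path).read_text())
    return np.asarray([r["end_s"] for r in rows], dtype=float) / 60.0
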