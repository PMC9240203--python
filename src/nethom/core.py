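"""Core in-memory containers shared across the pipeline.

Images live in memory as plain float64 arrays indexed ``(x, y, z, t)``
together with a 4x4 grid-to-world affine and the repetition time (TR, in
seconds).  NIfTI-1 is the on-disk representation throughout; nibabel does
all reading and writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TimeSeriesImage",
    "BrainMask",
    "MotionTrace",
    "load_motion_trace",
    "save_motion_trace",
]


@dataclass
class TimeSeriesImage:
    """A 4-D BOLD time series on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel time series.
    affine : ndarray, shape (4, 4)
        Grid-to-world map; world coordinates are in millimetres.
    tr : float
        Repetition time in seconds (sampling interval of the t axis).
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.tr > 0:
            raise ValueError("TR must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Voxel edge lengths (mm) along the three grid axes."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "TimeSeriesImage":
        """Copy carrying new voxel data but the same affine and TR."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = list(img.header.get_zooms())
        zooms = zooms[:3] + [self.tr]
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "TimeSeriesImage":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4-D image")
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(data=data, affine=np.asarray(img.affine), tr=tr)


@dataclass
class BrainMask:
    """Boolean 3-D grid sharing an affine with the images it masks."""

    data: np.ndarray
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """In-mask voxel indices, shape (n_voxels, 3), C order."""
        return np.argwhere(self.data)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "BrainMask":
        img = nib.load(str(path))
        return cls(data=np.asanyarray(img.dataobj) > 0, affine=np.asarray(img.affine))


@dataclass
class MotionTrace:
    """Rigid-body motion parameters, one row per volume.

    Columns 0-2 are translations in mm (x, y, z); columns 3-5 are rotations
    in degrees (pitch, roll, yaw).
    """

    values: np.ndarray

    TRANSLATION_AXES = (0, 1, 2)
    ROTATION_AXES = (3, 4, 5)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(
                f"motion trace must be T x 6, got shape {self.values.shape}"
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def discard_initial(self, n: int) -> "MotionTrace":
        if n >= self.n_volumes:
            raise ValueError("cannot discard all rows of a motion trace")
        return MotionTrace(self.values[n:].copy())


def save_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), trace.values, fmt="%.8f")


def load_motion_trace(path: str | Path) -> MotionTrace:
    values = np.loadtxt(str(path), ndmin=2)
    return MotionTrace(values)
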