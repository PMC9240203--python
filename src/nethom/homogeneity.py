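"""Network homogeneity (NH) maps.

NH of a voxel is the mean Pearson correlation of its time series with every
other voxel inside a network mask.  The per-voxel mean correlation is Fisher
z-transformed (atanh, after clipping to keep degenerate inputs finite), and
maps are then spatially standardized within the mask (zero mean, unit SD)
before group comparison.

The fast path standardizes every in-mask series to zero mean and unit norm,
so the full row sum of the correlation matrix is a single matrix-vector
product: O(N*T) time and O(N) extra memory instead of the O(N^2*T)
correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import BrainMask, TimeSeriesImage

__all__ = ["NHMap", "compute_nh_map", "standardize_nh_map", "CLIP"]

#: correlations are clipped to +/- (1 - CLIP) before atanh
CLIP = 1e-7

RAW_R = "raw_r"
FISHER_Z = "fisher_z"
STANDARDIZED = "standardized"


@dataclass
class NHMap:
    """Per-voxel homogeneity values on a mask; out-of-mask voxels are NaN."""

    data: np.ndarray  # 3-D, NaN outside the mask
    mask: np.ndarray  # boolean 3-D
    affine: np.ndarray
    stage: str
    subject_id: str = ""

    @property
    def values(self) -> np.ndarray:
        """In-mask values in C voxel order."""
        return self.data[self.mask]

    def save(self, path: str | Path) -> None:
        # NaN is an in-memory convention only; on disk out-of-mask voxels are 0
        out = np.where(self.mask, self.data, 0.0).astype(np.float32)
        nib.save(nib.Nifti1Image(out, self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path, mask: BrainMask, stage: str, subject_id: str = "") -> "NHMap":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        data = np.where(mask.data, data, np.nan)
        return cls(data=data, mask=mask.data.copy(), affine=np.asarray(img.affine), stage=stage, subject_id=subject_id)


def compute_nh_map(
    img: TimeSeriesImage, mask: BrainMask, subject_id: str = ""
) -> NHMap:
    """Fisher-z network homogeneity map of one subject.

    For in-mask voxel i with standardized series z_i (zero mean, unit norm),
    NH_i = (sum_j z_i . z_j - 1) / (N - 1), which equals the mean of the
    voxel's correlations with all *other* in-mask voxels.  The result is
    clipped to |r| <= 1 - 1e-7 and passed through atanh.
    """
    if img.grid_shape != mask.data.shape:
        raise ValueError("mask grid does not match image")
    idx = np.argwhere(mask.data)
    n = idx.shape[0]
    if n < 2:
        raise ValueError("mask must contain at least 2 voxels")
    if img.n_volumes < 3:
        raise ValueError("need at least 3 time points")

    ts = img.data[idx[:, 0], idx[:, 1], idx[:, 2], :]  # N x T
    ts = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ts, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        coords = idx[bad][:10].tolist()
        raise ValueError(f"constant time series inside the mask at voxels {coords}")
    z = ts / norms[:, None]

    total = z @ z.sum(axis=0)  # includes the self-correlation of 1
    nh = (total - 1.0) / (n - 1)
    nh = np.clip(nh, -(1.0 - CLIP), 1.0 - CLIP)
    fisher = np.arctanh(nh)

    data = np.full(img.grid_shape, np.nan)
    data[idx[:, 0], idx[:, 1], idx[:, 2]] = fisher
    return NHMap(data=data, mask=mask.data.copy(), affine=img.affine.copy(), stage=FISHER_Z, subject_id=subject_id)


def standardize_nh_map(nh: NHMap) -> NHMap:
    """Spatially standardize a Fisher-z map within the mask (mean 0, SD 1)."""
    if nh.stage != FISHER_Z:
        raise ValueError(f"expected a {FISHER_Z!r}-stage map, got {nh.stage!r}")
    vals = nh.values
    sd = vals.std()
    if sd == 0:
        raise ValueError("in-mask SD is zero; cannot standardize")
    data = nh.data.copy()
    data[nh.mask] = (vals - vals.mean()) / sd
    return replace(nh, data=data, stage=STANDARDIZED)
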