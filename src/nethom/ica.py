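"""Group spatial ICA and template-based default-mode-network mask extraction.

The standard three-step group ICA is implemented: per-subject temporal PCA
reduction, temporal concatenation with a second group-level reduction, and
fixed-point (FastICA, negentropy) spatial unmixing; per-subject time courses
are obtained by back reconstruction through the stored projections.  The DMN
component is selected by spatial correlation of the |z| map with a binary
template and thresholded into a mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import BrainMask, TimeSeriesImage

__all__ = [
    "ReducedData",
    "ComponentSet",
    "IcaConvergenceError",
    "group_reduce",
    "separate_components",
    "select_dmn_component",
    "build_dmn_mask",
    "extract_dmn",
]


class IcaConvergenceError(RuntimeError):
    def __init__(self, max_iter: int):
        super().__init__(f"FastICA did not converge within {max_iter} iterations")
        self.max_iter = max_iter


@dataclass
class ReducedData:
    """Temporally concatenated per-subject principal subspaces."""

    concatenated: np.ndarray  # (n_subjects * k, n_voxels)
    subject_bases: list  # per subject: (T, k) orthonormal temporal basis
    voxel_indices: np.ndarray  # (n_voxels, 3) in-brain coordinates
    grid_shape: tuple
    affine: np.ndarray
    k_per_subject: int


@dataclass
class ComponentSet:
    """Spatial maps (z-scaled over in-brain voxels) plus per-subject time courses."""

    maps: np.ndarray  # (n_components, n_voxels)
    timecourses: list  # per subject: (T, n_components)
    voxel_indices: np.ndarray
    grid_shape: tuple
    affine: np.ndarray
    explained_variance: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, index: int) -> np.ndarray:
        vol = np.zeros(self.grid_shape)
        idx = self.voxel_indices
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = self.maps[index]
        return vol


def _in_brain(images: list[TimeSeriesImage], brain_mask: BrainMask | None) -> np.ndarray:
    if brain_mask is not None:
        return np.argwhere(brain_mask.data)
    # default: voxels with temporal variance in the first image
    var = images[0].data.var(axis=-1)
    return np.argwhere(var > 0)


def group_reduce(
    images: list[TimeSeriesImage],
    n_components: int,
    brain_mask: BrainMask | None = None,
    k_per_subject: int | None = None,
) -> ReducedData:
    """Per-subject temporal PCA followed by temporal concatenation.

    Each subject's (T x V) matrix is projected onto its top ``k`` left
    singular vectors (k defaults to 2 * n_components, capped at T - 1); the
    reduced matrices are stacked along the reduced-time axis.  The temporal
    bases are kept so component time courses can be back reconstructed.
    """
    if len(images) < 2:
        raise ValueError("group ICA needs at least two subjects")
    grid = images[0].grid_shape
    if any(im.grid_shape != grid for im in images):
        raise ValueError("all images must share a grid")
    T = images[0].n_volumes
    k = k_per_subject or min(2 * n_components, T - 1)
    if n_components > k * len(images):
        raise ValueError("n_components exceeds retained dimensions")
    if k >= T:
        raise ValueError("too few time points for the requested reduction")

    idx = _in_brain(images, brain_mask)
    blocks = []
    bases = []
    for im in images:
        X = im.data[idx[:, 0], idx[:, 1], idx[:, 2], :].T  # T x V
        X = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        blocks.append(s[:k, None] * Vt[:k])  # k x V, variance-bearing
        bases.append(U[:, :k])
    return ReducedData(
        concatenated=np.vstack(blocks),
        subject_bases=bases,
        voxel_indices=idx,
        grid_shape=grid,
        affine=images[0].affine,
        k_per_subject=k,
    )


def separate_components(
    reduced: ReducedData,
    n_components: int,
    seed: int = 0,
    max_iter: int = 1000,
    n_restarts: int = 3,
    allow_nonconverged: bool = False,
) -> ComponentSet:
    """Spatial ICA on the concatenated reduced data.

    Sources are the spatial maps (independent over voxels).  Maps are
    z-scaled over in-brain voxels and signed so each map's skewness is
    non-negative; FastICA initialisation is fixed by ``seed`` so results are
    reproducible.

    When the fixed-point iteration fails to converge (typical when most of
    the retained subspace is Gaussian noise, where the unmixing rotation of
    the noise directions is not identifiable), up to ``n_restarts`` seeded
    restarts are tried; if none converges an :class:`IcaConvergenceError` is
    raised unless ``allow_nonconverged`` is set, in which case the estimate
    from the first restart is returned (deterministic given ``seed``) and
    ``ComponentSet.converged`` is False.  Sparse, genuinely non-Gaussian
    network maps are recovered accurately either way.
    """
    Y = reduced.concatenated  # (m, V)
    if n_components > min(Y.shape):
        raise ValueError("n_components exceeds the reduced data rank")
    sources = None
    converged = False
    fallback = None
    for attempt in range(max(n_restarts, 1)):
        ica = FastICA(
            n_components=n_components,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(Y.T)  # (V, n_components)
                converged = True
                break
            except ConvergenceWarning:
                if fallback is None:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        fallback = (ica, ica.fit_transform(Y.T))
    if not converged:
        if not allow_nonconverged:
            raise IcaConvergenceError(max_iter)
        ica, sources = fallback
    maps = sources.T  # (n_components, V)

    # z-scale and fix the sign ambiguity by non-negative skewness
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    sk = stats.skew(maps, axis=1)
    maps[sk < 0] *= -1.0

    # back reconstruction: subject time courses via the pseudoinverse of the maps
    pinv_maps = np.linalg.pinv(maps)  # (V, n_components)
    timecourses = []
    for basis, block in zip(
        reduced.subject_bases,
        np.split(reduced.concatenated, len(reduced.subject_bases), axis=0),
    ):
        subject_data = basis @ block  # T x V (reduced reconstruction)
        timecourses.append(subject_data @ pinv_maps)

    total_var = float((Y**2).sum())
    recon = ica.inverse_transform(sources, copy=True)
    resid = float(((Y.T - recon) ** 2).sum())
    explained = np.array([1.0 - resid / total_var]) if total_var > 0 else np.array([0.0])

    return ComponentSet(
        maps=maps,
        timecourses=timecourses,
        voxel_indices=reduced.voxel_indices,
        grid_shape=reduced.grid_shape,
        affine=reduced.affine,
        explained_variance=explained,
        converged=converged,
    )


def select_dmn_component(
    components: ComponentSet, template: BrainMask
) -> tuple[int, float]:
    """Pick the component whose |z| map best matches a binary network template.

    Returns the argmax of the Pearson correlation between |z| and the
    template indicator over in-brain voxels; ties break toward the lower
    component index.
    """
    if template.data.shape != components.grid_shape:
        raise ValueError("template grid does not match components")
    idx = components.voxel_indices
    tvec = template.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    if tvec.sum() == 0:
        raise ValueError("empty template")
    scores = np.empty(components.n_components)
    for i in range(components.n_components):
        a = np.abs(components.maps[i])
        if a.std() == 0 or tvec.std() == 0:
            scores[i] = -np.inf
        else:
            scores[i] = np.corrcoef(a, tvec)[0, 1]
    best = int(np.argmax(scores))  # argmax returns the first (lowest) index on ties
    return best, float(scores[best])


def build_dmn_mask(
    components: ComponentSet, index: int, z_threshold: float = 1.5
) -> BrainMask:
    """Threshold a component z map into a network mask (z > threshold)."""
    if z_threshold < 0:
        raise ValueError("z threshold must be non-negative")
    vol = components.map_volume(index)
    inbrain = np.zeros(components.grid_shape, dtype=bool)
    idx = components.voxel_indices
    inbrain[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    mask = (vol > z_threshold) & inbrain
    if not mask.any():
        raise ValueError(f"mask is empty at z > {z_threshold}")
    return BrainMask(
        mask,
        components.affine,
        provenance={
            "component_index": index,
            "z_threshold": z_threshold,
            "n_voxels": int(mask.sum()),
        },
    )


def extract_dmn(
    images: list[TimeSeriesImage],
    template: BrainMask,
    n_components: int = 20,
    seed: int = 0,
    z_threshold: float = 1.5,
    brain_mask: BrainMask | None = None,
    allow_nonconverged: bool = True,
) -> tuple[BrainMask, ComponentSet, int, float]:
    """End-to-end: reduce, unmix, select against the template, build the mask."""
    reduced = group_reduce(images, n_components, brain_mask=brain_mask)
    comps = separate_components(
        reduced, n_components, seed=seed, allow_nonconverged=allow_nonconverged
    )
    index, score = select_dmn_component(comps, template)
    mask = build_dmn_mask(comps, index, z_threshold)
    mask.provenance["template_match_score"] = score
    return mask, comps, index, score
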