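"""Seeded two-group synthetic BOLD cohorts with known network-homogeneity effects.

The generator emulates a resting-state cohort of epilepsy patients and
healthy controls: every in-network voxel carries a shared low-frequency
(0.01-0.08 Hz) network signal at a configurable coupling weight, on top of
AR(1) Gaussian noise and a slow scanner drift.  Group differences are
injected by raising or lowering the coupling inside designated ROIs for one
group only, so the downstream homogeneity analysis has a recoverable ground
truth.  Motion traces are bounded random walks; a helper injects gross
motion to exercise the exclusion screen.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so a cohort is a pure function of
its spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import BrainMask, MotionTrace, TimeSeriesImage, save_motion_trace

__all__ = [
    "ROI",
    "EffectROI",
    "ClinicalDistributions",
    "CohortSpec",
    "GroundTruth",
    "default_dmn_rois",
    "default_nuisance_rois",
    "generate_subject",
    "simulate_cohort",
    "generate_cohort",
    "inject_gross_motion",
    "band_limited_signal",
    "dmn_template_mask",
    "PATIENT",
    "CONTROL",
]

PATIENT = "patient"
CONTROL = "control"

#: Random-walk bound (mm / degrees) for clean motion traces; kept well under
#: the 2 mm / 2 degree exclusion thresholds so unperturbed subjects pass.
_MOTION_BOUND = 1.5


@dataclass(frozen=True)
class ROI:
    """A labelled set of voxels given as an (n, 3) integer index array."""

    label: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] == 0:
            raise ValueError(f"ROI {self.label!r}: indices must be non-empty (n, 3)")
        object.__setattr__(self, "indices", idx)

    @classmethod
    def box(
        cls, label: str, corner: tuple[int, int, int], size: tuple[int, int, int]
    ) -> "ROI":
        grids = np.meshgrid(
            *[np.arange(c, c + s) for c, s in zip(corner, size)], indexing="ij"
        )
        return cls(label, np.stack([g.ravel() for g in grids], axis=1))

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[self.indices[:, 0], self.indices[:, 1], self.indices[:, 2]] = True
        return m


@dataclass(frozen=True)
class EffectROI:
    """Group effect: ``direction`` raises or lowers patient coupling by ``delta``."""

    label: str
    direction: str  # "increase" | "decrease"
    delta: float
    group: str = PATIENT

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"direction must be increase/decrease, got {self.direction!r}")
        if not 0 <= self.delta < 1:
            raise ValueError("coupling delta must lie in [0, 1)")


def default_dmn_rois(grid_shape: tuple[int, int, int] = (30, 36, 30)) -> list[ROI]:
    """Box ROIs standing in for the canonical default-mode regions.

    Positions are proportional placements on the grid of the medial
    prefrontal cortex, posterior cingulate / bilateral precuneus, bilateral
    lateral temporal cortex and right inferior parietal lobe.
    """
    nx, ny, nz = grid_shape

    def box(label, fx, fy, fz, size):
        corner = (int(fx * nx), int(fy * ny), int(fz * nz))
        corner = tuple(
            min(max(c, 0), n - s) for c, n, s in zip(corner, grid_shape, size)
        )
        return ROI.box(label, corner, size)

    size = (
        max(4, nx // 5),
        max(4, ny // 6),
        max(4, nz // 5),
    )
    return [
        box("MPFC", 0.40, 0.70, 0.45, size),
        box("PCu_L", 0.25, 0.12, 0.55, size),
        box("PCu_R", 0.55, 0.12, 0.55, size),
        box("LTC_L", 0.05, 0.40, 0.25, size),
        box("ITG_R", 0.75, 0.45, 0.10, size),
        box("IPL_R", 0.75, 0.15, 0.75, size),
    ]


def default_nuisance_rois(grid_shape: tuple[int, int, int] = (30, 36, 30)) -> list[ROI]:
    """Non-network boxes whose mean series stand in for WM and CSF signals."""
    nx, ny, nz = grid_shape
    s = (3, 3, 3)
    wm = ROI.box("WM", (0, 0, 0), s)
    csf = ROI.box("CSF", (nx - 3, ny - 3, nz - 3), s)
    return [wm, csf]


def _table1_clinical_defaults() -> dict:
    # Group means/SDs match the published cohort demographics.
    return {
        "age": {PATIENT: (27.91, 6.48), CONTROL: (26.96, 5.31)},
        "education_years": {PATIENT: (13.01, 2.67), CONTROL: (13.67, 1.88)},
        "illness_duration": {PATIENT: (8.49, 7.1), CONTROL: None},
        "reaction_time": {PATIENT: (91.60, 54.85), CONTROL: (85.0, 50.0)},
        "mmse": {PATIENT: (27.0, 1.8), CONTROL: (27.8, 1.5)},
        "male_fraction": {PATIENT: 23 / 43, CONTROL: 22 / 42},
    }


@dataclass(frozen=True)
class ClinicalDistributions:
    """Sampling parameters for the phenotype table (means and SDs per group)."""

    params: dict = field(default_factory=_table1_clinical_defaults)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; identical specs give identical data."""

    n_patients: int = 43
    n_controls: int = 42
    grid_shape: tuple[int, int, int] = (30, 36, 30)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_volumes: int = 240
    tr_seconds: float = 2.0
    dmn_roi_set: tuple[ROI, ...] = None  # type: ignore[assignment]
    effect_rois: tuple[EffectROI, ...] = None  # type: ignore[assignment]
    base_coupling: float = 0.5
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 0.3
    motion_sigma_mm: float = 0.05
    band_hz: tuple[float, float] = (0.01, 0.08)
    n_discard: int = 5
    clinical: ClinicalDistributions = field(default_factory=ClinicalDistributions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dmn_roi_set is None:
            object.__setattr__(
                self, "dmn_roi_set", tuple(default_dmn_rois(self.grid_shape))
            )
        else:
            object.__setattr__(self, "dmn_roi_set", tuple(self.dmn_roi_set))
        if self.effect_rois is None:
            # Default effects mirror the reported group differences: raised
            # homogeneity in bilateral precuneus / right IPL, lowered in
            # right inferior temporal and left lateral temporal cortex.
            object.__setattr__(
                self,
                "effect_rois",
                (
                    EffectROI("PCu_L", "increase", 0.3),
                    EffectROI("PCu_R", "increase", 0.3),
                    EffectROI("IPL_R", "increase", 0.3),
                    EffectROI("ITG_R", "decrease", 0.3),
                    EffectROI("LTC_L", "decrease", 0.3),
                ),
            )
        else:
            object.__setattr__(self, "effect_rois", tuple(self.effect_rois))
        self.validate()

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive integers")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("both groups need at least one subject")
        if not self.dmn_roi_set:
            raise ValueError("dmn_roi_set must not be empty")
        labels = {r.label for r in self.dmn_roi_set}
        for eff in self.effect_rois:
            if eff.label not in labels:
                raise ValueError(f"effect ROI {eff.label!r} not in dmn_roi_set")
        if not 0 < self.base_coupling < 1:
            raise ValueError("base_coupling must lie in (0, 1)")
        max_delta = max((e.delta for e in self.effect_rois), default=0.0)
        if self.base_coupling + max_delta >= 1:
            raise ValueError("base_coupling + max delta must stay below 1")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.drift_amplitude < 0 or self.motion_sigma_mm < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_volumes <= self.n_discard:
            raise ValueError("n_volumes must exceed the number of discarded volumes")
        for roi in self.dmn_roi_set:
            if (roi.indices < 0).any() or (
                roi.indices >= np.array(self.grid_shape)
            ).any():
                raise ValueError(f"ROI {roi.label!r} exceeds the grid")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def dmn_mask(self) -> BrainMask:
        m = np.zeros(self.grid_shape, dtype=bool)
        for roi in self.dmn_roi_set:
            m |= roi.mask(self.grid_shape)
        return BrainMask(m, self.affine, provenance={"source": "ground-truth ROI union"})

    def coupling_map(self, group: str) -> np.ndarray:
        """Per-voxel coupling weight for the given group."""
        c = np.zeros(self.grid_shape)
        for roi in self.dmn_roi_set:
            c[roi.mask(self.grid_shape)] = self.base_coupling
        for eff in self.effect_rois:
            if group != eff.group:
                continue
            roi = next(r for r in self.dmn_roi_set if r.label == eff.label)
            sign = 1.0 if eff.direction == "increase" else -1.0
            c[roi.mask(self.grid_shape)] = np.clip(
                self.base_coupling + sign * eff.delta, 0.0, 1.0 - 1e-9
            )
        return c


@dataclass
class GroundTruth:
    """Everything a recovery test needs: coupling maps, labels, effect masks."""

    coupling: dict  # group -> 3-D weight map
    effect_masks: dict  # label -> (direction, boolean 3-D mask)
    dmn_mask: BrainMask
    nuisance_rois: list
    groups: list  # per-subject labels, cohort order


def band_limited_signal(
    rng: np.random.Generator, n: int, tr: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian signal with spectral support restricted to ``band``.

    White noise is masked in the frequency domain (real FFT) so that all
    power sits at frequencies ``band[0] <= f <= band[1]``.
    """
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("band contains no resolvable frequency for this length/TR")
    spec = np.fft.rfft(rng.standard_normal(n))
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate band-limited signal")
    return x / sd


def _ar1_noise(rng: np.random.Generator, shape: tuple, phi: float) -> np.ndarray:
    """AR(1) innovations along the last axis, standardized to unit variance."""
    white = rng.standard_normal(shape)
    if phi == 0:
        return white
    noise = lfilter([1.0], [1.0, -phi], white, axis=-1)
    # stationary SD of AR(1) driven by unit-variance innovations
    noise *= np.sqrt(1.0 - phi**2)
    return noise


def _bounded_walk(rng: np.random.Generator, n: int, sigma: float, bound: float) -> np.ndarray:
    steps = rng.normal(0.0, sigma, size=n)
    out = np.empty(n)
    x = 0.0
    for i, s in enumerate(steps):
        x += s
        # reflect at the bounds so clean traces stay inside the screen
        if x > bound:
            x = 2 * bound - x
        elif x < -bound:
            x = -2 * bound - x
        out[i] = x
    return out


def generate_subject(
    spec: CohortSpec, group: str, subject_seed: int
) -> tuple[TimeSeriesImage, MotionTrace, GroundTruth]:
    """Simulate one subject's 4-D image and motion trace.

    The voxel series is ``c * s + a_d * d + sqrt(1 - c^2) * e`` where ``s`` is
    the subject's shared band-limited network signal, ``d`` a linear scanner
    drift and ``e`` unit-variance AR(1) noise, so that (drift aside) the
    correlation of two in-network voxels is the product of their coupling
    weights.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"unknown group {group!r}")
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))
    T = spec.n_volumes
    c = spec.coupling_map(group)

    signal = band_limited_signal(rng, T, spec.tr_seconds, spec.band_hz)
    drift = np.arange(T, dtype=float)
    drift -= drift.mean()
    drift /= drift.std()

    noise = _ar1_noise(rng, spec.grid_shape + (T,), spec.ar1_coefficient)
    data = (
        c[..., None] * signal[None, None, None, :]
        + spec.drift_amplitude * drift[None, None, None, :]
        + np.sqrt(np.clip(1.0 - c**2, 0.0, None))[..., None] * noise
    )
    img = TimeSeriesImage(data, spec.affine, spec.tr_seconds)

    trace = np.column_stack(
        [
            _bounded_walk(rng, T, spec.motion_sigma_mm, _MOTION_BOUND)
            for _ in range(6)
        ]
    )
    motion = MotionTrace(trace)

    truth = GroundTruth(
        coupling={group: c},
        effect_masks={
            e.label: (
                e.direction,
                next(r for r in spec.dmn_roi_set if r.label == e.label).mask(
                    spec.grid_shape
                ),
            )
            for e in spec.effect_rois
        },
        dmn_mask=spec.dmn_mask(),
        nuisance_rois=default_nuisance_rois(spec.grid_shape),
        groups=[group],
    )
    return img, motion, truth


def inject_gross_motion(trace: MotionTrace, axis: int, magnitude: float) -> MotionTrace:
    """Rescale one motion axis so its maximal absolute excursion equals ``magnitude``."""
    if not 0 <= axis <= 5:
        raise ValueError(f"axis must be 0..5, got {axis}")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    values = trace.values.copy()
    col = values[:, axis]
    peak = np.abs(col).max()
    if peak == 0:
        col = np.zeros_like(col)
        col[len(col) // 2] = magnitude
        values[:, axis] = col
    else:
        values[:, axis] = col * (magnitude / peak)
    return MotionTrace(values)


def _sample_clinical(
    rng: np.random.Generator, group: str, clinical: ClinicalDistributions, age: float
) -> dict:
    p = clinical.params

    def draw(key):
        pair = p[key][group]
        if pair is None:
            return np.nan
        mean, sd = pair
        return rng.normal(mean, sd)

    duration = np.nan
    onset = np.nan
    if group == PATIENT and p["illness_duration"][PATIENT] is not None:
        mean, sd = p["illness_duration"][PATIENT]
        duration = max(rng.normal(mean, sd), 0.1)
        duration = min(duration, max(age - 1.0, 0.5))
        onset = age - duration
    return {
        "education_years": max(draw("education_years"), 0.0),
        "illness_duration": duration,
        "onset_age": onset,
        "reaction_time": max(draw("reaction_time"), 1.0),
        "mmse": float(np.clip(draw("mmse"), 24, 30)),
        "sex": "M" if rng.random() < p["male_fraction"][group] else "F",
    }


def _phenotype_row(
    rng: np.random.Generator, sid: str, group: str, clinical: ClinicalDistributions
) -> dict:
    mean, sd = clinical.params["age"][group]
    age = max(rng.normal(mean, sd), 18.0)
    row = {"subject_id": sid, "group": group, "age": age}
    row.update(_sample_clinical(rng, group, clinical, age))
    return row


def simulate_cohort(spec: CohortSpec):
    """In-memory cohort: (subject_id, group, image, motion) list, phenotype, truth."""
    spec.validate()
    subjects = []
    rows = []
    groups = []
    n_total = spec.n_patients + spec.n_controls
    for i in range(n_total):
        group = PATIENT if i < spec.n_patients else CONTROL
        sid = f"sub-{i + 1:03d}"
        img, motion, _ = generate_subject(spec, group, subject_seed=i + 1)
        pheno_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 100_000 + i])
        )
        rows.append(_phenotype_row(pheno_rng, sid, group, spec.clinical))
        subjects.append((sid, group, img, motion))
        groups.append(group)
    phenotype = pd.DataFrame(rows)
    truth = GroundTruth(
        coupling={PATIENT: spec.coupling_map(PATIENT), CONTROL: spec.coupling_map(CONTROL)},
        effect_masks={
            e.label: (
                e.direction,
                next(r for r in spec.dmn_roi_set if r.label == e.label).mask(
                    spec.grid_shape
                ),
            )
            for e in spec.effect_rois
        },
        dmn_mask=spec.dmn_mask(),
        nuisance_rois=default_nuisance_rois(spec.grid_shape),
        groups=groups,
    )
    return subjects, phenotype, truth


def generate_cohort(spec: CohortSpec, out_dir: str | Path, force: bool = False) -> Path:
    """Write a full cohort to ``out_dir``: NIfTI images, motion text files,
    phenotype TSV and ground-truth sidecars.  Refuses to overwrite an
    existing cohort directory unless ``force`` is set."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} already contains files; pass force=True")
    out.mkdir(parents=True, exist_ok=True)

    subjects, phenotype, truth = simulate_cohort(spec)
    for sid, _group, img, motion in subjects:
        img.save(out / f"{sid}_bold.nii.gz")
        save_motion_trace(motion, out / f"{sid}_motion.txt")
    phenotype.to_csv(out / "phenotype.tsv", sep="\t", index=False, float_format="%.6f")

    truth.dmn_mask.save(out / "ground_truth_dmn_mask.nii.gz")
    for group, cmap in truth.coupling.items():
        nii = TimeSeriesImage(cmap[..., None], spec.affine, spec.tr_seconds)
        nii.save(out / f"ground_truth_coupling_{group}.nii.gz")
    meta = {
        "effect_rois": [
            {"label": e.label, "direction": e.direction, "delta": e.delta}
            for e in spec.effect_rois
        ],
        "dmn_rois": {r.label: r.indices.tolist() for r in spec.dmn_roi_set},
        "nuisance_rois": {r.label: r.indices.tolist() for r in truth.nuisance_rois},
        "groups": truth.groups,
        "seed": spec.seed,
        "n_volumes": spec.n_volumes,
        "tr_seconds": spec.tr_seconds,
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=1))
    return out


def dmn_template_mask(spec: CohortSpec) -> BrainMask:
    """Template used for ICA component selection: the DMN ROI boxes.

    Stands in for the canonical network templates used with group ICA
    toolboxes; real (MNI-space) templates can be supplied instead wherever a
    mask is accepted.
    """
    mask = spec.dmn_mask()
    mask.provenance = {"source": "synthetic DMN box template"}
    return mask
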