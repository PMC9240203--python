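"""Desk-scale validation studies run on synthetic cohorts.

These routines exercise the full analysis chain (simulate -> preprocess ->
NH -> group statistics) under controlled conditions where the right answer
is known: null cohorts for false-positive calibration of the GRF cluster
inference, and cohorts with injected coupling effects for sign/location
recovery.  They are used by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .homogeneity import compute_nh_map, standardize_nh_map
from .preprocess import PreprocessConfig, preprocess_subject
from .stats import NHGroupModel
from .synthetic import CohortSpec, EffectROI, ROI, simulate_cohort

__all__ = [
    "nh_maps_for_cohort",
    "null_calibration",
    "effect_recovery",
    "dice",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean volumes."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 0.0 if denom == 0 else 2.0 * float((a & b).sum()) / float(denom)


def nh_maps_for_cohort(spec: CohortSpec, fwhm_mm: float = 8.0):
    """Simulate a cohort and carry every subject to a standardized NH map.

    Nuisance regression uses the simulator's WM/CSF stand-in ROI means plus
    the motion parameters; NH is computed over the ground-truth network mask.
    Returns (maps, groups, ground_truth).
    """
    subs, _, truth = simulate_cohort(spec)
    cfg = PreprocessConfig(n_discard=spec.n_discard, band_hz=spec.band_hz, fwhm_mm=fwhm_mm)
    maps, groups = [], []
    for sid, group, img, trace in subs:
        kept = img.data[..., cfg.n_discard :]
        nuis = np.column_stack(
            [
                kept[r.indices[:, 0], r.indices[:, 1], r.indices[:, 2], :].mean(axis=0)
                for r in truth.nuisance_rois
            ]
        )
        res = preprocess_subject(img, trace, cfg, nuisance_signals=nuis, subject_id=sid)
        if res.rejected:
            continue
        nh = compute_nh_map(res.image, truth.dmn_mask, subject_id=sid)
        maps.append(standardize_nh_map(nh))
        groups.append(group)
    return maps, groups, truth


def _null_spec(seed: int) -> CohortSpec:
    # one ~2000-voxel network block, no group effect
    roi = ROI.box("NET", (2, 2, 2), (12, 14, 12))
    return CohortSpec(
        n_patients=10,
        n_controls=10,
        grid_shape=(16, 18, 16),
        n_volumes=120,
        dmn_roi_set=(roi,),
        effect_rois=(),
        seed=seed,
    )


def null_calibration(
    n_datasets: int = 200, seed: int = 0, voxel_p: float = 0.001, cluster_p: float = 0.01
) -> dict:
    """Fraction of null cohorts yielding any GRF-surviving cluster.

    Each dataset is a 10-vs-10 cohort sharing one network signal with no
    group difference; the family-wise false-positive rate over datasets
    should not exceed the nominal cluster alpha by much.
    """
    hits = 0
    for i in range(n_datasets):
        maps, groups, _ = nh_maps_for_cohort(_null_spec(seed + 17 * i + 1))
        res = NHGroupModel(maps, groups).fit(voxel_p=voxel_p, cluster_p=cluster_p)
        hits += len(res.clusters) > 0
    return {
        "n_datasets": n_datasets,
        "n_with_false_positive": hits,
        "false_positive_rate": hits / n_datasets,
    }


def _recovery_spec(seed: int) -> CohortSpec:
    return CohortSpec(
        n_patients=20,
        n_controls=20,
        grid_shape=(20, 24, 20),
        n_volumes=150,
        effect_rois=(
            EffectROI("PCu_R", "increase", 0.3),
            EffectROI("ITG_R", "decrease", 0.3),
        ),
        seed=seed,
    )


def effect_recovery(
    n_seeds: int = 50, seed: int = 0, dice_threshold: float = 0.5
) -> dict:
    """Recovery of two injected coupling effects (one increase, one decrease).

    A seed counts as a success when, for each effect ROI, some surviving
    cluster of the matching sign overlaps the ROI with Dice above the
    threshold.
    """
    wanted = {"PCu_R": "patients>controls", "ITG_R": "patients<controls"}
    successes = 0
    dice_scores = []
    for i in range(n_seeds):
        maps, groups, truth = nh_maps_for_cohort(_recovery_spec(seed + 31 * i + 7))
        res = NHGroupModel(maps, groups).fit()
        per_roi = {}
        for label, direction in wanted.items():
            _, gt_mask = truth.effect_masks[label]
            best = 0.0
            for c in res.clusters:
                if c.direction != direction:
                    continue
                cm = np.zeros_like(gt_mask)
                cm[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = True
                best = max(best, dice(cm, gt_mask))
            per_roi[label] = best
        dice_scores.append(per_roi)
        successes += all(v > dice_threshold for v in per_roi.values())
    return {
        "n_seeds": n_seeds,
        "n_success": successes,
        "success_rate": successes / n_seeds,
        "mean_dice_increase": float(np.mean([d["PCu_R"] for d in dice_scores])),
        "mean_dice_decrease": float(np.mean([d["ITG_R"] for d in dice_scores])),
    }
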