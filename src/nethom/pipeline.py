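"""End-to-end orchestration: simulate -> preprocess -> DMN mask -> NH ->
group stats -> classification, driven by one config and one seed.

Each stage writes into its own subdirectory of the output root together
with a small ``.stage.json`` recording the hash of the configuration that
produced it; a rerun skips stages whose recorded hash matches (delete the
directory to force recomputation).  A run manifest collects per-stage
output digests so reproducibility can be checked file by file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import build_feature_table, cv_svm_grid
from .core import BrainMask, TimeSeriesImage, load_motion_trace
from .homogeneity import NHMap, compute_nh_map, standardize_nh_map
from .ica import extract_dmn
from .preprocess import PreprocessConfig, preprocess_subject
from .stats import NHGroupModel, demographics_table, pearson_corr
from .synthetic import CohortSpec, EffectROI, generate_cohort, dmn_template_mask

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]

STAGES = ("cohort", "preprocessed", "dmn", "nh", "stats", "classify")


@dataclass
class RunConfig:
    """Flat, YAML-round-trippable pipeline configuration."""

    seed: int = 0
    out_root: str = "nethom-run"
    # cohort
    n_patients: int = 43
    n_controls: int = 42
    grid_shape: tuple = (30, 36, 30)
    n_volumes: int = 240
    tr_seconds: float = 2.0
    base_coupling: float = 0.5
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 0.3
    motion_sigma_mm: float = 0.05
    effect_rois: tuple = (
        ("PCu_L", "increase", 0.3),
        ("PCu_R", "increase", 0.3),
        ("IPL_R", "increase", 0.3),
        ("ITG_R", "decrease", 0.3),
        ("LTC_L", "decrease", 0.3),
    )
    # preprocessing
    n_discard: int = 5
    fwhm_mm: float = 8.0
    band_hz: tuple = (0.01, 0.08)
    # ICA
    n_components: int = 20
    z_threshold: float = 1.5
    dmn_from_controls_only: bool = True
    # statistics
    voxel_p: float = 0.001
    cluster_p: float = 0.01
    connectivity: int = 26
    # classification
    feature_direction: str = "patients>controls"
    cv_scheme: str = "loocv"

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_patients=self.n_patients,
            n_controls=self.n_controls,
            grid_shape=tuple(self.grid_shape),
            n_volumes=self.n_volumes,
            tr_seconds=self.tr_seconds,
            effect_rois=tuple(EffectROI(l, d, float(x)) for l, d, x in self.effect_rois),
            base_coupling=self.base_coupling,
            ar1_coefficient=self.ar1_coefficient,
            drift_amplitude=self.drift_amplitude,
            motion_sigma_mm=self.motion_sigma_mm,
            band_hz=tuple(self.band_hz),
            n_discard=self.n_discard,
            seed=self.seed,
        )

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            n_discard=self.n_discard, band_hz=tuple(self.band_hz), fwhm_mm=self.fwhm_mm
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["band_hz"] = list(d["band_hz"])
        d["effect_rois"] = [list(e) for e in d["effect_rois"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        if "effect_rois" in d:
            d["effect_rois"] = tuple(tuple(e) for e in d["effect_rois"])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)  # stage -> {digests, seconds, info}
    rejections: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _digest_tree(directory: Path) -> dict:
    out = {}
    for f in sorted(directory.rglob("*")):
        if f.is_file() and f.name != ".stage.json":
            out[str(f.relative_to(directory))] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out


def _config_hash(parts: dict) -> str:
    return hashlib.sha256(json.dumps(parts, sort_keys=True, default=str).encode()).hexdigest()


def _stage_fresh(stage_dir: Path, chash: str) -> bool:
    marker = stage_dir / ".stage.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == chash
    except json.JSONDecodeError:
        return False


def _mark_stage(stage_dir: Path, chash: str) -> None:
    (stage_dir / ".stage.json").write_text(json.dumps({"config_hash": chash}))


def run_pipeline(config: RunConfig, log=print) -> RunManifest:
    """Run every stage in order; returns the manifest (also written to disk)."""
    root = Path(config.out_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    full_hash = _config_hash(asdict(config))

    def finish_stage(name: str, stage_dir: Path, t0: float, info: dict | None = None):
        entry = {"digests": _digest_tree(stage_dir), "seconds": round(time.time() - t0, 3)}
        if info:
            entry["info"] = info
        manifest.stages[name] = entry
        manifest.save(root / "manifest.json")

    try:
        _run_stages(config, root, manifest, full_hash, finish_stage, log)
    except Exception as exc:
        manifest.stages["error"] = {"info": {"failed": str(exc)}}
        manifest.save(root / "manifest.json")
        raise
    config.to_yaml(root / "config.yaml")
    manifest.save(root / "manifest.json")
    return manifest


def _run_stages(config, root, manifest, full_hash, finish_stage, log):
    spec = config.cohort_spec()

    # -- simulate ----------------------------------------------------------
    cohort_dir = root / "cohort"
    chash = _config_hash({"stage": "cohort", "spec": manifest.config})
    t0 = time.time()
    if not _stage_fresh(cohort_dir, chash):
        log("stage cohort: simulating")
        generate_cohort(spec, cohort_dir, force=True)
        _mark_stage(cohort_dir, chash)
    else:
        log("stage cohort: up to date")
    finish_stage("cohort", cohort_dir, t0)

    phenotype = pd.read_csv(cohort_dir / "phenotype.tsv", sep="\t")
    truth = json.loads((cohort_dir / "ground_truth.json").read_text())
    nuisance_rois = {
        k: np.asarray(v, dtype=int) for k, v in truth["nuisance_rois"].items()
    }

    # -- preprocess --------------------------------------------------------
    pre_dir = root / "preprocessed"
    t0 = time.time()
    pcfg = config.preprocess_config()
    if not _stage_fresh(pre_dir, chash):
        log("stage preprocess: running")
        pre_dir.mkdir(exist_ok=True)
        rejections = []
        for sid in phenotype["subject_id"]:
            img = TimeSeriesImage.load(cohort_dir / f"{sid}_bold.nii.gz")
            trace = load_motion_trace(cohort_dir / f"{sid}_motion.txt")
            kept = img.data[..., pcfg.n_discard :]
            nuis = np.column_stack(
                [
                    kept[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)
                    for idx in nuisance_rois.values()
                ]
            )
            res = preprocess_subject(img, trace, pcfg, nuisance_signals=nuis, subject_id=sid)
            if res.rejected:
                rejections.append(
                    {"subject_id": sid, "axis": res.screen.axis, "peak": res.screen.peak}
                )
            else:
                res.image.save(pre_dir / f"{sid}_preproc.nii.gz")
        pd.DataFrame(rejections, columns=["subject_id", "axis", "peak"]).to_csv(
            pre_dir / "rejections.tsv", sep="\t", index=False
        )
        _mark_stage(pre_dir, chash)
    else:
        log("stage preprocess: up to date")
    rejections = pd.read_csv(pre_dir / "rejections.tsv", sep="\t")
    manifest.rejections = rejections["subject_id"].tolist()
    accepted = phenotype[~phenotype["subject_id"].isin(manifest.rejections)].reset_index(
        drop=True
    )
    finish_stage("preprocessed", pre_dir, t0, {"n_rejected": len(manifest.rejections)})

    def load_pre(sid):
        return TimeSeriesImage.load(pre_dir / f"{sid}_preproc.nii.gz")

    # -- DMN mask ----------------------------------------------------------
    dmn_dir = root / "dmn"
    t0 = time.time()
    if not _stage_fresh(dmn_dir, chash):
        log("stage dmn: group ICA")
        dmn_dir.mkdir(exist_ok=True)
        if config.dmn_from_controls_only:
            ica_subjects = accepted[accepted["group"] == "control"]["subject_id"]
        else:
            ica_subjects = accepted["subject_id"]
        images = [load_pre(s) for s in ica_subjects]
        template = dmn_template_mask(spec)
        mask, comps, index, score = extract_dmn(
            images,
            template,
            n_components=min(config.n_components, len(images) * 2),
            seed=config.seed,
            z_threshold=config.z_threshold,
        )
        mask.save(dmn_dir / "dmn_mask.nii.gz")
        (dmn_dir / "selection.json").write_text(
            json.dumps(
                {
                    "component_index": index,
                    "template_match_score": score,
                    "z_threshold": config.z_threshold,
                    "n_components": comps.n_components,
                    "n_mask_voxels": mask.n_voxels,
                }
            )
        )
        _mark_stage(dmn_dir, chash)
    else:
        log("stage dmn: up to date")
    mask = BrainMask.load(dmn_dir / "dmn_mask.nii.gz")
    finish_stage("dmn", dmn_dir, t0)

    # -- NH maps -----------------------------------------------------------
    nh_dir = root / "nh"
    t0 = time.time()
    if not _stage_fresh(nh_dir, chash):
        log("stage nh: computing homogeneity maps")
        nh_dir.mkdir(exist_ok=True)
        rows = []
        for sid in accepted["subject_id"]:
            nh = compute_nh_map(load_pre(sid), mask, subject_id=sid)
            nh.save(nh_dir / f"{sid}_nh_fisherz.nii.gz")
            std = standardize_nh_map(nh)
            std.save(nh_dir / f"{sid}_nh_standardized.nii.gz")
            rows.append([sid] + std.values.tolist())
        cols = ["subject_id"] + [f"v{i}" for i in range(mask.n_voxels)]
        pd.DataFrame(rows, columns=cols).to_csv(
            nh_dir / "nh_standardized_wide.tsv", sep="\t", index=False, float_format="%.6f"
        )
        _mark_stage(nh_dir, chash)
    else:
        log("stage nh: up to date")
    nh_maps = [
        NHMap.load(nh_dir / f"{sid}_nh_standardized.nii.gz", mask, "standardized", sid)
        for sid in accepted["subject_id"]
    ]
    finish_stage("nh", nh_dir, t0)

    # -- group stats -------------------------------------------------------
    stats_dir = root / "stats"
    t0 = time.time()
    stats_dir.mkdir(exist_ok=True)
    log("stage stats: group comparison")
    model = NHGroupModel(nh_maps, accepted["group"].tolist())
    results = model.fit(
        voxel_p=config.voxel_p, cluster_p=config.cluster_p, connectivity=config.connectivity
    )
    results.cluster_table().to_csv(stats_dir / "clusters.tsv", sep="\t", index=False)
    demographics_table(accepted).to_csv(stats_dir / "demographics.tsv", sep="\t", index=False)
    (stats_dir / "summary.txt").write_text(results.summary() + "\n")

    # clinical correlations in patients: cluster-mean NH vs RT / duration / onset
    from .stats import extract_cluster_means

    corr_rows = []
    pat_mask = (accepted["group"] == "patient").to_numpy()
    pat_maps = [m for m, keep in zip(nh_maps, pat_mask) if keep]
    for ci, cluster in enumerate(results.clusters):
        means = extract_cluster_means(pat_maps, cluster)
        for var in ("reaction_time", "illness_duration", "onset_age"):
            vals = accepted.loc[pat_mask, var].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if ok.sum() >= 3 and np.std(means[ok]) > 0 and np.std(vals[ok]) > 0:
                r, p = pearson_corr(means[ok], vals[ok])
                corr_rows.append(
                    {"cluster": ci, "direction": cluster.direction, "variable": var, "r": r, "p": p}
                )
    pd.DataFrame(corr_rows, columns=["cluster", "direction", "variable", "r", "p"]).to_csv(
        stats_dir / "clinical_correlations.tsv", sep="\t", index=False
    )
    _mark_stage(stats_dir, chash)
    finish_stage("stats", stats_dir, t0, {"n_clusters": len(results.clusters)})

    # -- classification ----------------------------------------------------
    cls_dir = root / "classify"
    t0 = time.time()
    cls_dir.mkdir(exist_ok=True)
    selected = [c for c in results.clusters if c.direction == config.feature_direction]
    if not selected:
        selected = results.clusters
    if selected:
        log(f"stage classify: {len(selected)} cluster feature(s)")
        table = build_feature_table(nh_maps, selected, accepted)
        table.to_csv(cls_dir / "features.tsv", sep="\t", index=False, float_format="%.6f")
        result = cv_svm_grid(table, scheme=config.cv_scheme)
        result.grid_surface.to_csv(cls_dir / "grid_surface.tsv", sep="\t", index=False)
        (cls_dir / "result.json").write_text(
            json.dumps(
                {
                    "tp": result.tp,
                    "fn": result.fn,
                    "tn": result.tn,
                    "fp": result.fp,
                    "accuracy_pct": result.accuracy,
                    "sensitivity_pct": result.sensitivity,
                    "specificity_pct": result.specificity,
                    "best_c": result.best_c,
                    "best_gamma": result.best_gamma,
                    "scheme": result.scheme,
                },
                indent=1,
            )
        )
        info = {"accuracy_pct": result.accuracy}
    else:
        log("stage classify: no surviving clusters; skipped")
        (cls_dir / "result.json").write_text(json.dumps({"skipped": "no clusters"}))
        info = {"skipped": True}
    _mark_stage(cls_dir, chash)
    finish_stage("classify", cls_dir, t0, info)
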