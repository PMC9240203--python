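# nethom

Network homogeneity (NH) analysis of resting-state fMRI for two-group
case-control studies, with a fully synthetic validation path.

NH measures how coherently each voxel participates in a brain network: for
voxel *i* inside a network mask of *N* voxels,

    NH_i = (1 / (N - 1)) * Σ_{j ≠ i} r(x_i, x_j)

the mean Pearson correlation of its time series with every other in-mask
voxel, Fisher z-transformed (atanh) and spatially standardized per subject.
Group differences in NH maps are assessed with voxel-wise pooled two-sample
t-tests corrected at the cluster level by Gaussian random field (GRF)
theory (voxel p < 0.001, cluster p < 0.01), and cluster-mean NH values are
used as features for an RBF-kernel SVM (grid-searched over C and γ,
leave-one-out cross-validation) to classify patients against controls.
The motivating application is default-mode-network homogeneity in right
temporal lobe epilepsy, but nothing in the code is specific to that
population.

Because clinical resting-state datasets are rarely shareable, the package
ships a seeded synthetic-cohort generator: two groups of 4-D NIfTI images
whose in-network voxels share a band-limited (0.01–0.08 Hz) signal at known
coupling weights, with AR(1) noise, scanner drift, rigid-body motion traces
and a phenotype table. Group effects are injected by changing coupling in
chosen ROIs, so every downstream stage — preprocessing, ICA mask
extraction, NH, GRF inference, SVM — can be validated against ground truth.

## Worked example

```python
from nethom import CohortSpec, EffectROI, NHGroupModel
from nethom.experiments import nh_maps_for_cohort

spec = CohortSpec(
    n_patients=20, n_controls=20,
    grid_shape=(20, 24, 20), n_volumes=150,
    effect_rois=(EffectROI("PCu_R", "increase", 0.3),
                 EffectROI("ITG_R", "decrease", 0.3)),
    seed=7,
)
maps, groups, truth = nh_maps_for_cohort(spec)   # simulate -> preprocess -> NH
results = NHGroupModel(maps, groups).fit(voxel_p=0.001, cluster_p=0.01)
print(results.summary())
```

prints

```
Network homogeneity group comparison
====================================
patients: 20   controls: 20   df: 38
mask voxels: 384
smoothness FWHM (mm): 5.68, 5.55, 5.57   resels: 24.90
thresholds: voxel p < 0.001, cluster p < 0.01 (GRF)
surviving clusters: 11
        direction  peak_x_mm  peak_y_mm  peak_z_mm  extent_voxels  peak_t  p_corrected
patients>controls         33          6         42             65   18.63     2.63e-12
patients<controls         54         36         12             64  -22.49    3.415e-12
patients>controls          3         36         24             28   9.261    1.447e-07
...
```

The two dominant clusters are the two injected ROIs: the raised-coupling
box (right precuneus analog) surfaces as patients > controls and the
lowered-coupling box (right inferior temporal analog) as
patients < controls, each recovered at essentially its full 4×4×4 = 64-voxel
extent with the correct sign. The smaller secondary clusters are genuine
consequences of the generative model rather than false positives: NH is a
network-wide statistic, so changing coupling in one region shifts every
other voxel's mean correlation, and per-subject spatial standardization
redistributes part of the effect across the mask. Feeding the increased-NH
cluster means into the SVM stage (`nethom.classify.build_feature_table` +
`cv_svm_grid`) then yields a leave-one-out accuracy, sensitivity and
specificity with the selected (C, γ) pair.

The same analysis runs from the shell as one reproducible pipeline:

```
nethom run --config run.yaml --out myrun --seed 7
nethom report --run-dir myrun
```

with per-stage outputs (cohort, preprocessed images, DMN mask from group
ICA of the controls, NH maps, cluster/demographics/correlation tables,
SVM result) and a manifest of SHA-256 digests for every file.

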