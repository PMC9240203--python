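# Methods

`nethom` implements a complete network-homogeneity (NH) analysis of
resting-state fMRI for a two-group (patients vs healthy controls) design,
together with a synthetic-cohort generator that makes every stage of the
analysis testable against a known ground truth. This note documents the
models, the defaults and why they were chosen, the numerical conventions,
and what the synthetic validation does and does not demonstrate.

## The network homogeneity statistic

For a network mask with N voxels and a subject's preprocessed time series
x_i(t), the homogeneity of voxel i is the mean Pearson correlation with
every *other* in-mask voxel:

    NH_i = (1 / (N - 1)) * sum_{j != i} r(x_i, x_j)

The self-correlation is excluded, hence the N - 1 denominator. NH_i is
variance-stabilized with the Fisher transform z_i = atanh(NH_i), and each
subject's map is then spatially standardized within the mask (zero mean,
unit SD) before group comparison. The two transforms are kept as explicit,
separately testable stages (`fisher_z`, `standardized`).

Numerics: correlations are clipped to |r| <= 1 - 1e-7 before atanh, so
degenerate inputs (identical or exactly anti-correlated series, which occur
in synthetic edge cases but not in measured data) stay finite. The fast
path standardizes each series to zero mean and unit norm, making the full
correlation row sum a single matrix-vector product — O(N·T) time, O(N)
extra memory — and is verified in tests to equal the O(N²·T) correlation
matrix computation to 1e-10. Out-of-mask voxels are NaN in memory and 0 in
written NIfTI files, with the mask saved alongside.

## Preprocessing

The chain is: discard initial volumes -> motion screen -> nuisance
regression -> spatial smoothing -> detrend + bandpass. Defaults: discard 5
volumes; reject subjects exceeding 2 mm translation or 2 degrees rotation
on any axis (strict inequalities — a peak of exactly 2.0 passes); regress
six motion parameters plus white-matter and CSF reference signals, with the
global signal deliberately *not* removed; smooth with an 8 mm FWHM Gaussian;
bandpass 0.01–0.08 Hz with linear detrending. The motion trace covers all
acquired volumes and its first rows are dropped in lockstep with the
discarded volumes.

Design choices worth calling out:

- **Ideal (FFT-mask) bandpass.** Frequency bins outside [low, high] are
  zeroed rather than attenuated by an IIR/FIR design. This matches common
  resting-state toolchain behaviour and makes the filter contract exactly
  testable. Detrending and bandpassing are fused into a single orthogonal
  projection (the removed subspace is the out-of-band Fourier span plus the
  linear ramp), which makes the combined operation idempotent — applying it
  twice equals applying it once — a property a naive detrend-then-mask
  sequence does not have.
- **Smoothing boundary.** `scipy.ndimage.gaussian_filter` with zero-padding
  (`mode="constant"`): mass is conserved for interior voxels and attenuated
  at grid edges. Sigma per axis is fwhm / (voxel_size · 2·sqrt(2·ln 2)).
- **Nuisance signals in synthetic space.** No tissue segmentation exists for
  simulated brains, so the white-matter and CSF reference series are the
  mean signals of two designated non-network ROIs written by the simulator.
  Zero-variance regressor columns (e.g. a perfectly still motion trace) are
  dropped before the fit; a genuinely rank-deficient design raises an error
  naming the dependent columns.
- **Stage order.** Nuisance regression precedes smoothing, smoothing
  precedes filtering. With every stage except the screen being linear, the
  order mainly affects edge behaviour; it is fixed and logged per subject.

Slice-timing correction and template normalization are out of scope: the
simulator generates all subjects on a shared 3 mm grid.

## Synthetic cohorts

Each subject's voxel series is

    x_v(t) = c_v · s(t) + a_d · d(t) + sqrt(1 - c_v²) · e_v(t)

where s(t) is a subject-specific band-limited (0.01–0.08 Hz) unit-variance
network signal shared by all in-network voxels, d(t) a unit-variance linear
scanner drift with amplitude a_d, and e_v(t) unit-variance AR(1) Gaussian
noise. Ignoring drift, the correlation of two in-network voxels is the
product of their coupling weights c_i·c_j, so the expected NH profile is
known analytically and effects are injected by raising or lowering c inside
designated ROIs for the patient group. Defaults: base coupling 0.5, AR(1)
coefficient 0.3, drift amplitude 0.3, effect delta 0.3 in five box ROIs
mirroring the regions where group differences are expected (bilateral
precuneus and right inferior parietal lobe increased; right inferior
temporal and left lateral temporal cortex decreased).

Cohort defaults are 43 patients and 42 controls with TR 2 s and 240
volumes; clinical covariates (age, sex, education, illness duration, onset
age, reaction time, MMSE) are drawn from group-specific normal
distributions matching the demographics the analysis is designed around and
are independent of the imaging signal by default. Illness duration is
patient-only; onset age is age minus duration. Motion traces are reflected
random walks bounded at 1.5 mm / 1.5 degrees so clean subjects always pass
the screen; `inject_gross_motion` rescales one axis to a chosen peak to
exercise rejection paths.

What the simulator does *not* emulate: hemodynamic response shapes,
physiological (cardiac/respiratory) noise, susceptibility artifacts,
multi-site effects, spatial correlation of the raw noise (spatial structure
enters only through smoothing), or anatomically realistic network
geometry. Passing tests therefore demonstrate the correctness and
calibration of the *algorithms* under the stated generative model, not
performance on measured fMRI.

## DMN extraction by group ICA

Standard three-step group spatial ICA: per-subject temporal PCA (top k
left-singular directions, k = 2 · n_components by default), temporal
concatenation, then FastICA (fixed-point, logcosh negentropy) treating
voxels as samples, so the estimated sources are spatial maps. Maps are
z-scaled over in-brain voxels and signed so skewness is non-negative,
resolving the ICA sign ambiguity. Per-subject time courses are back
reconstructed through the stored PCA bases and the pseudoinverse of the
maps; only the group map feeds mask construction.

The component whose |z| map best correlates with a binary network template
is selected (ties to the lower index); the mask is the set of in-brain
voxels with z above a threshold (default 1.5, recorded in the mask's
provenance). Model order (default 20, capped at twice the subject count in
the pipeline), threshold, and controls-only estimation (default on) are all
configuration, since none is prescribed by convention alone.

**Convergence.** FastICA's fixed point is only identifiable for
non-Gaussian sources. In noise-dominated data — including these synthetic
cohorts, where after whitening most retained directions are Gaussian — the
rotation of the noise subspace never settles and sklearn reports
non-convergence, even though the sparse (highly non-Gaussian) network map
itself stabilizes accurately: on a noise-dominated test cohort the selected
map correlates ~0.92 with the true support and the thresholded mask reaches
Dice ~0.87. `separate_components` therefore tries a few seeded restarts and
raises a convergence error by default, but callers (including the pipeline)
may pass `allow_nonconverged=True` to accept the deterministic
first-restart estimate, flagged via `ComponentSet.converged`.

## Group statistics and GRF cluster inference

Voxel-wise pooled-variance (Student) two-sample t within the mask, sign
convention patients minus controls. Pooled rather than Welch was chosen
because it reproduces conventional neuroimaging practice and the published
demographic statistics this package mirrors; Welch is not offered to keep
one code path. Zero-pooled-variance voxels get t = 0.

Cluster-level correction follows classical Gaussian random field theory:

1. **Smoothness.** Residual maps (per-group deviations from the group mean)
   are standardized within the mask; the lag-1 spatial autocorrelation per
   axis is estimated from mean squared neighbour differences
   (E[(Δx)²] = 2(1 - ρ₁)) and inverted under a Gaussian autocorrelation
   model, FWHM² = -2·ln2 / ln ρ₁ in voxel units, floored at one voxel.
   The discrete estimator recovers a known 8 mm kernel within a few percent
   on a 3 mm grid (test tolerance 15%).
2. **Resel counts.** R₀..R₃ by lattice counting of the mask's points,
   edges, faces and cubes, combined with the per-axis FWHM — the standard
   volumetrics for Euler-characteristic expectations on an irregular search
   region.
3. **Cluster p.** For threshold u (the Gaussian quantile equivalent of the
   voxel-wise alpha), the expected cluster count is E[m] = Σ R_d · ρ_d(u)
   with the Gaussian EC densities ρ_d; the expected cluster size is
   E[n] = S·Φ̄(u)/E[m]; the extent distribution is approximated as
   P(n ≥ k) = exp(-β·k^(2/3)) with β = (Γ(5/2)/E[n])^(2/3); and the
   corrected p is 1 - exp(-E[m]·P(n ≥ k)).

Two-sided inference runs as two one-sided analyses at voxel_p/2 so each
cluster carries a direction. Connected components use 26-connectivity by
default (6/18 available); peak voxels break ties toward the smallest linear
index so reports are deterministic. Calibration on 200 null cohorts
(10 vs 10, ~2000-voxel mask, T = 120) keeps the family-wise false-positive
rate at or below 0.05 at nominal cluster p < 0.01 — the loose bound
acknowledges the approximations (Gaussianized t field, extent
approximation, discrete smoothness estimation) at desk scale.

Demographics tables use the same pooled t (from summary statistics, so
printed group means/SDs can be checked directly) and a Pearson chi-square
without continuity correction for sex. Clinical correlations are plain
Pearson r with the t-based two-sided p, reported uncorrected; listwise
deletion handles missing values.

## Classification

Cluster-mean NH features feed an RBF-kernel SVM grid-searched over
C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and γ ∈ {2⁻¹⁵, …, 2³} under leave-one-out
cross-validation by default (k-fold available; the scheme is recorded in
the result). Features are z-scored per fold using training rows only —
verified in tests by reproducing a fold by hand — and the best (C, γ) is
chosen by pooled held-out accuracy with ties resolved toward smaller C then
smaller γ, so the search is deterministic. The positive class is the
patient group: sensitivity counts patients, specificity controls.
Accuracy/sensitivity/specificity are rendered as percentages at two
decimals with full precision retained internally.

## Pipeline and reproducibility

`run_pipeline` chains the stages under a single flat YAML-round-trippable
config with one global seed; per-subject randomness is derived through
`numpy.random.SeedSequence` spawning so subjects are independent and the
whole run is a pure function of the config. Each stage directory carries a
hash of the producing config; reruns skip up-to-date stages and a deleted
stage directory is regenerated bit-identically. The manifest records
per-stage SHA-256 digests, timings and the rejection list.

## Problem sizes used in validation

The validation studies run at desk scale by design: null calibration uses
10 vs 10 subjects, a 2016-voxel single-block mask on a 16×18×16 grid and
T = 120 volumes over 200 datasets; effect recovery uses 20 vs 20 subjects,
a 20×24×20 grid, T = 150 and 50 seeds with delta 0.3. These sizes give
stable rates while keeping a full run in minutes; the statistical
contracts they check (false-positive control, sign/location recovery) are
size-free statements.

## Known limitations

- GRF corrected p-values rely on Gaussianized t thresholds and the
  exponential extent approximation; they are approximate for few subjects
  and small masks, which is why calibration is asserted as a bound (≤ 0.05)
  rather than equality with the nominal 0.01.
- The smoothness estimator assumes a Gaussian spatial autocorrelation and
  stationarity over the mask.
- ICA model order, mask threshold, and template are configuration, not
  estimated; the shipped template is a synthetic box layout, with real
  templates accepted as user input.
- NH depends on the preprocessing order (notably smoothing before
  correlation); the order is fixed and logged rather than varied.
- The simulator's clinical covariates are independent of imaging by
  default, so clinical-correlation analyses on synthetic data are expected
  to be null.
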