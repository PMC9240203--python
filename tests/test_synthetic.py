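"""Synthetic cohort generator: determinism, spectral structure, injected effects."""

import numpy as np
import pytest

from nethom.core import MotionTrace
from nethom.preprocess import PreprocessConfig, screen_motion
from nethom.synthetic import (
    CohortSpec,
    EffectROI,
    ROI,
    band_limited_signal,
    generate_cohort,
    generate_subject,
    inject_gross_motion,
    simulate_cohort,
)

SMALL = dict(grid_shape=(12, 12, 12), n_volumes=80)


def small_spec(**kw):
    defaults = dict(
        n_patients=3,
        n_controls=3,
        dmn_roi_set=(
            ROI.box("A", (1, 1, 1), (3, 3, 3)),
            ROI.box("B", (7, 7, 7), (3, 3, 3)),
        ),
        effect_rois=(EffectROI("A", "increase", 0.3),),
        seed=11,
        **SMALL,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestSpecValidation:
    def test_effect_roi_must_exist(self):
        with pytest.raises(ValueError, match="not in dmn_roi_set"):
            small_spec(effect_rois=(EffectROI("nope", "increase", 0.2),))

    def test_coupling_budget(self):
        with pytest.raises(ValueError, match="below 1"):
            small_spec(base_coupling=0.8, effect_rois=(EffectROI("A", "increase", 0.3),))

    def test_non_positive_grid_rejected(self):
        with pytest.raises(ValueError):
            small_spec(grid_shape=(0, 12, 12), n_volumes=80)

    def test_empty_roi_set_rejected(self):
        with pytest.raises(ValueError):
            small_spec(dmn_roi_set=(), effect_rois=())

    def test_volumes_must_exceed_discard(self):
        with pytest.raises(ValueError, match="discard"):
            small_spec(grid_shape=(12, 12, 12), n_volumes=5)


class TestGenerateSubject:
    def test_deterministic(self):
        spec = small_spec()
        img1, tr1, _ = generate_subject(spec, "patient", 5)
        img2, tr2, _ = generate_subject(spec, "patient", 5)
        np.testing.assert_array_equal(img1.data, img2.data)
        np.testing.assert_array_equal(tr1.values, tr2.values)

    def test_motion_trace_shape_and_bounds(self):
        spec = small_spec()
        _, trace, _ = generate_subject(spec, "control", 2)
        assert trace.values.shape == (spec.n_volumes, 6)
        assert np.abs(trace.values).max() < 2.0  # clean subjects pass the screen

    def test_null_effect_correlations_match_across_rois(self):
        """With delta=0 everywhere, expected in-ROI correlation is the same in
        both ROIs and both groups."""
        spec = small_spec(effect_rois=(), drift_amplitude=0.0, n_volumes=300)
        img, _, truth = generate_subject(spec, "patient", 1)
        means = []
        for roi in spec.dmn_roi_set:
            ts = img.data[roi.mask(spec.grid_shape)]
            r = np.corrcoef(ts)
            means.append(r[np.triu_indices_from(r, 1)].mean())
        # both ROIs share base coupling 0.5 -> expected pairwise r = 0.25
        assert abs(means[0] - means[1]) < 0.15
        assert abs(np.mean(means) - 0.25) < 0.1

    def test_full_coupling_no_noise_degenerate(self):
        """Coupling ~1 with no drift: every in-mask pair is near-perfectly correlated."""
        spec = small_spec(
            base_coupling=1.0 - 1e-9, effect_rois=(), drift_amplitude=0.0
        )
        img, _, _ = generate_subject(spec, "control", 3)
        ts = img.data[spec.dmn_mask().data]
        r = np.corrcoef(ts)
        assert r[np.triu_indices_from(r, 1)].min() > 0.999

    def test_effect_direction_sign(self):
        """Monte-Carlo: mean patient-minus-control correlation difference in an
        increase ROI is positive in nearly all seeds."""
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            spec = small_spec(seed=seed, drift_amplitude=0.0, n_volumes=150)
            roi = spec.dmn_roi_set[0]  # "A", increase for patients
            diffs = []
            for group, sgn in (("patient", 1), ("control", -1)):
                img, _, _ = generate_subject(spec, group, 1)
                ts = img.data[roi.mask(spec.grid_shape)]
                r = np.corrcoef(ts)
                diffs.append(sgn * r[np.triu_indices_from(r, 1)].mean())
            wins += (diffs[0] + diffs[1]) > 0
        assert wins >= int(0.95 * n_seeds)

    def test_rejects_unknown_group(self):
        with pytest.raises(ValueError):
            generate_subject(small_spec(), "alien", 0)


class TestSpectralStructure:
    def test_network_signal_band_limited(self, rng):
        """Ground-truth network signal has <1% power outside 0.01-0.08 Hz."""
        for seed in range(5):
            g = np.random.default_rng(seed)
            s = band_limited_signal(g, 240, 2.0, (0.01, 0.08))
            freqs = np.fft.rfftfreq(240, d=2.0)
            power = np.abs(np.fft.rfft(s)) ** 2
            out = power[(freqs < 0.01) | (freqs > 0.08)].sum()
            assert out / power.sum() < 0.01
            assert abs(s.mean()) < 1e-12 and abs(s.std() - 1.0) < 1e-12

    def test_effect_monotonicity(self):
        """Expected in-ROI correlation strictly increases with coupling delta."""
        means = []
        for delta in (0.0, 0.15, 0.3, 0.45):
            acc = []
            for seed in range(8):
                spec = small_spec(
                    seed=seed,
                    base_coupling=0.4,
                    effect_rois=(EffectROI("A", "increase", delta),),
                    drift_amplitude=0.0,
                    n_volumes=200,
                )
                img, _, _ = generate_subject(spec, "patient", 1)
                ts = img.data[spec.dmn_roi_set[0].mask(spec.grid_shape)]
                r = np.corrcoef(ts)
                acc.append(r[np.triu_indices_from(r, 1)].mean())
            means.append(np.mean(acc))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestInjectGrossMotion:
    def test_peak_equals_magnitude_other_axes_unchanged(self, rng):
        trace = MotionTrace(rng.normal(0, 0.1, size=(50, 6)))
        out = inject_gross_motion(trace, axis=2, magnitude=2.5)
        assert np.abs(out.values[:, 2]).max() == pytest.approx(2.5)
        np.testing.assert_array_equal(out.values[:, [0, 1, 3, 4, 5]], trace.values[:, [0, 1, 3, 4, 5]])

    @pytest.mark.parametrize(
        "magnitude,accepted", [(2.5, False), (0.5, True), (2.0, True)]
    )
    def test_screen_interaction(self, rng, magnitude, accepted):
        """Strict 2 mm threshold: 2.5 rejected, 0.5 and exactly 2.0 accepted."""
        trace = MotionTrace(rng.normal(0, 0.05, size=(50, 6)))
        out = inject_gross_motion(trace, axis=0, magnitude=magnitude)
        assert bool(screen_motion(out, PreprocessConfig())) is accepted

    def test_invalid_axis(self, rng):
        with pytest.raises(ValueError):
            inject_gross_motion(MotionTrace(np.zeros((5, 6))), 6, 1.0)


class TestGenerateCohort:
    def test_file_layout_and_determinism(self, tmp_path):
        spec = small_spec(n_patients=2, n_controls=2)
        d1 = generate_cohort(spec, tmp_path / "a")
        d2 = generate_cohort(spec, tmp_path / "b")
        assert len(list(d1.glob("*_bold.nii.gz"))) == 4
        pheno1 = (d1 / "phenotype.tsv").read_bytes()
        pheno2 = (d2 / "phenotype.tsv").read_bytes()
        assert pheno1 == pheno2
        import nibabel as nib

        a = np.asanyarray(nib.load(d1 / "sub-001_bold.nii.gz").dataobj)
        b = np.asanyarray(nib.load(d2 / "sub-001_bold.nii.gz").dataobj)
        np.testing.assert_array_equal(a, b)

    def test_refuses_overwrite(self, tmp_path):
        spec = small_spec(n_patients=1, n_controls=1)
        generate_cohort(spec, tmp_path / "c")
        with pytest.raises(FileExistsError):
            generate_cohort(spec, tmp_path / "c")
        generate_cohort(spec, tmp_path / "c", force=True)

    def test_phenotype_groups_and_columns(self):
        _, pheno, truth = simulate_cohort(small_spec(n_patients=4, n_controls=3))
        assert (pheno["group"] == "patient").sum() == 4
        assert (pheno["group"] == "control").sum() == 3
        for col in ("age", "sex", "education_years", "illness_duration", "onset_age", "reaction_time", "mmse"):
            assert col in pheno.columns
        # illness duration is patient-only
        assert pheno.loc[pheno.group == "control", "illness_duration"].isna().all()
        assert truth.groups == pheno["group"].tolist()

    def test_age_sampling_matches_configured_means(self):
        """Across seeds, sample group age means stay within 3 SE of the
        configured population means (27.91 / 26.96 years)."""
        ages_p, ages_c = [], []
        for seed in range(12):
            _, pheno, _ = simulate_cohort(
                small_spec(n_patients=10, n_controls=10, seed=seed, grid_shape=(6, 6, 6), n_volumes=20, n_discard=2,
                           dmn_roi_set=(ROI.box("A", (1, 1, 1), (3, 3, 3)),), effect_rois=())
            )
            ages_p.extend(pheno.loc[pheno.group == "patient", "age"])
            ages_c.extend(pheno.loc[pheno.group == "control", "age"])
        se_p = 6.48 / np.sqrt(len(ages_p))
        se_c = 5.31 / np.sqrt(len(ages_c))
        # truncation at 18 biases the mean up slightly; stay within 3 SE
        assert abs(np.mean(ages_p) - 27.91) < 3 * se_p + 0.2
        assert abs(np.mean(ages_c) - 26.96) < 3 * se_c + 0.2
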