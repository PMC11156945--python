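"""Generators: determinism, invariants, planted-structure recoverability."""

import numpy as np
import pandas as pd
import pytest

from olfatau.exceptions import AtlasError, GeometryError, ParameterError
from olfatau.imaging_io import ODORANT_COLUMNS, regional_means, validate_subject_table
from olfatau.synthetic_data import (
    CohortSpec,
    ExpressionTruth,
    SpreadTruth,
    TractPhantomSpec,
    generate_cohort,
    generate_expression,
    generate_regional_tau,
    generate_tract_md,
    make_synthetic_atlas,
    paint_volumes,
)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        spec = CohortSpec(n_subjects=418, seed=11)
        pd.testing.assert_frame_equal(generate_cohort(spec), generate_cohort(spec))

    def test_schema_and_composite_invariants(self, small_cohort):
        validate_subject_table(small_cohort)

    def test_noise_free_composite_equals_rounded_trend(self):
        spec = CohortSpec(
            n_subjects=80,
            score_noise_sd=0.0,
            outlier_fraction=0.0,
            odorant_difficulties=np.full(40, 0.3),
            seed=5,
        )
        t = generate_cohort(spec)
        a0, a1, a2 = spec.quadratic_coeffs
        trend = a0 + a1 * t["age"] + a2 * t["age"] ** 2
        assert (t["upsit"].to_numpy() == np.clip(np.rint(trend), 0, 40)).all()

    def test_zero_age_slope_gives_null_age_regression(self):
        # pooled t statistic of composite-on-age slope over repeated cohorts
        tstats = []
        for s in range(50):
            spec = CohortSpec(
                n_subjects=100, quadratic_coeffs=(33.0, 0.0, 0.0), seed=1000 + s
            )
            t = generate_cohort(spec)
            x = np.column_stack([np.ones(len(t)), t["age"]])
            beta, res, *_ = np.linalg.lstsq(x, t["upsit"].to_numpy(float), rcond=None)
            resid = t["upsit"] - x @ beta
            se = np.sqrt(
                resid.var(ddof=2) * np.linalg.inv(x.T @ x)[1, 1]
            )
            tstats.append(beta[1] / se)
        assert abs(np.mean(tstats)) < 0.5

    def test_outliers_shifted_down(self):
        spec = CohortSpec(n_subjects=300, outlier_fraction=0.1, seed=2)
        t = generate_cohort(spec)
        a0, a1, a2 = spec.quadratic_coeffs
        trend = a0 + a1 * t["age"] + a2 * t["age"] ** 2
        dev = t["upsit"] - trend
        assert (dev[t["is_outlier"]] < -6).all()

    def test_independent_response_model_keeps_schema(self):
        t = generate_cohort(CohortSpec(n_subjects=50, response_model="independent", seed=3))
        validate_subject_table(t)

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_subjects": 0},
            {"outlier_fraction": 1.0},
            {"odorant_difficulties": np.full(39, 0.3)},
            {"odorant_difficulties": np.full(40, 1.5)},
            {"response_model": "copula"},
        ],
    )
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ParameterError):
            generate_cohort(CohortSpec(**bad))


class TestRegionalTau:
    def test_no_edges_no_systematic_progression(self, small_cohort):
        truth = SpreadTruth(edges=(), seed=4)
        panel = generate_regional_tau(small_cohort, truth)
        drift = (panel.followup - panel.baseline).mean()
        assert (drift.abs() < 3 * truth.noise_sd / np.sqrt(len(small_cohort))).all()

    def test_single_edge_positive_partial_corr(self, small_cohort):
        truth = SpreadTruth(edges=(("Amyg", "PirF", 0.05),), seed=4)
        panel = generate_regional_tau(small_cohort, truth)
        from olfatau._stats import partial_corr

        r = partial_corr(
            panel.baseline["Amyg"], panel.followup["PirF"], panel.baseline[["PirF"]].to_numpy()
        )
        assert r > 0.3

    def test_bitwise_deterministic(self, small_cohort):
        truth = SpreadTruth(seed=9)
        p1 = generate_regional_tau(small_cohort, truth)
        p2 = generate_regional_tau(small_cohort, truth)
        assert np.array_equal(p1.baseline.to_numpy(), p2.baseline.to_numpy())
        assert np.array_equal(p1.followup.to_numpy(), p2.followup.to_numpy())

    def test_self_edge_rejected(self):
        with pytest.raises(ParameterError):
            SpreadTruth(edges=(("Amyg", "Amyg", 0.1),)).validate()


class TestPaintVolumes:
    def test_zero_noise_zero_smoothing_roi_means_exact(self, small_cohort, atlas):
        truth = SpreadTruth(seed=1)
        panel = generate_regional_tau(small_cohort, truth)
        vol = paint_volumes(panel.baseline, atlas)
        means = regional_means(vol, atlas, apply_mask=False)
        for r in panel.regions:
            np.testing.assert_allclose(means[r], panel.baseline[r], rtol=1e-12)

    def test_smoothing_preserves_subject_ranking(self, small_cohort, atlas):
        truth = SpreadTruth(seed=1)
        panel = generate_regional_tau(small_cohort, truth)
        vol = paint_volumes(panel.baseline, atlas, smoothing_fwhm=4.0, voxel_noise_sd=0.02, seed=2)
        means = regional_means(vol, atlas, apply_mask=False)
        for r in panel.regions:
            assert np.corrcoef(means[r], panel.baseline[r])[0, 1] > 0.9

    def test_empty_region_raises(self, small_cohort):
        atlas = make_synthetic_atlas(shape=(20, 20, 20), seed=3)
        lab = atlas.label_of("Hipp")
        atlas.labels[atlas.labels == lab] = 0  # hollow the region out
        panel = generate_regional_tau(small_cohort, SpreadTruth(seed=1))
        with pytest.raises(AtlasError):
            paint_volumes(panel.baseline, atlas)


class TestTractPhantom:
    def test_mask_within_radius_and_nonempty(self, small_cohort):
        spec = TractPhantomSpec(seed=0)
        mask, _ = generate_tract_md(small_cohort, spec)
        assert mask.mask.sum() > 0
        idx = np.argwhere(mask.mask)
        world = idx * spec.voxel_size + mask.affine[:3, 3]
        from scipy.spatial import cKDTree

        d, _ = cKDTree(mask.curve_points).query(world)
        assert d.max() <= spec.radius + 1e-9

    def test_degenerate_curve_rejected(self, small_cohort):
        spec = TractPhantomSpec(
            curve_control_points=np.array([[0.0, 0, 0], [0.0, 0, 0], [10.0, 0, 0]])
        )
        with pytest.raises(GeometryError):
            generate_tract_md(small_cohort, spec)

    def test_effect_voxels_track_upsit(self, small_cohort):
        spec = TractPhantomSpec(effect_segments=tuple(range(40, 61)), md_noise_sd=1e-9, seed=0)
        mask, md = generate_tract_md(small_cohort, spec)
        sel = np.isin(mask.truth_segment, list(range(40, 61))) & mask.mask
        dev = small_cohort["upsit"] - small_cohort["upsit"].mean()
        vox = md.data[:, sel].mean(axis=1) - spec.baseline_md
        np.testing.assert_allclose(vox, spec.effect_size * dev, atol=1e-8)


class TestExpression:
    def test_high_within_cluster_correlation_limit(self):
        truth = ExpressionTruth(n_genes=40, k_clusters=2, within_cluster_corr=0.99, seed=0)
        expr = generate_expression(truth)
        c = np.corrcoef(expr.values.to_numpy())
        within = c[:20, :20][np.triu_indices(20, 1)]
        assert within.mean() > 0.95

    def test_single_cluster_has_uniform_coexpression(self):
        truth = ExpressionTruth(n_genes=60, k_clusters=1, within_cluster_corr=0.5, seed=1)
        expr = generate_expression(truth)
        c = np.corrcoef(expr.values.to_numpy())
        off = c[np.triu_indices(60, 1)]
        # every pair shares one factor: no block structure, common mean r
        assert abs(off.mean() - 0.5) < 0.1

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ParameterError):
            generate_expression(ExpressionTruth(within_cluster_corr=1.0))

    def test_hemisphere_split_even(self):
        with pytest.raises(ParameterError):
            generate_expression(ExpressionTruth(n_regions=67))
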