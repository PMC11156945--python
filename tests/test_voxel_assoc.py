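"""Voxel-wise GLM, smoothness estimation, Monte-Carlo nulls."""

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from olfatau._stats import t_to_z, two_sided_p_from_t
from olfatau.exceptions import DesignError, EstimationError, ParameterError
from olfatau.imaging_io import VolumeSet, build_design
from olfatau.voxel_assoc import (
    cluster_correct,
    count_map,
    estimate_smoothness,
    fit_voxel_glm,
    glm_residuals,
    odorant_count_null,
)


def _vol(data):
    shape = data.shape[1:]
    return VolumeSet(data=data, affine=np.diag([2.0, 2, 2, 1]), mask=np.ones(shape, bool))


class TestFitVoxelGlm:
    def test_matches_scalar_regression_formula(self, rng):
        n = 30
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        import pandas as pd

        table = pd.DataFrame({"x": x})
        design = build_design(table, predictor="x", covariates=[])
        vol = _vol(y.reshape(n, 1, 1, 1))
        smap = fit_voxel_glm(vol, design)
        # closed-form simple-regression t statistic
        xc = x - x.mean()
        beta = (xc @ y) / (xc @ xc)
        resid = y - y.mean() - beta * xc
        se = np.sqrt(resid @ resid / (n - 2) / (xc @ xc))
        np.testing.assert_allclose(smap.t[0], beta / se, rtol=1e-10)

    def test_matches_statsmodels(self, rng):
        import pandas as pd
        import statsmodels.api as sm

        n = 40
        table = pd.DataFrame(
            {"x": rng.standard_normal(n), "c1": rng.standard_normal(n), "c2": rng.integers(0, 2, n)}
        )
        y = rng.standard_normal(n)
        design = build_design(table, predictor="x", covariates=["c1", "c2"])
        smap = fit_voxel_glm(_vol(y.reshape(n, 1, 1, 1)), design)
        fit = sm.OLS(y, design.values).fit()
        np.testing.assert_allclose(smap.t[0], fit.tvalues[design.predictor_index], rtol=1e-10)

    def test_null_predictor_false_positive_rate(self, rng, small_cohort):
        table = small_cohort
        design = build_design(table, predictor="upsit", covariates=["age", "sex"])
        vol = _vol(rng.standard_normal((len(table), 6, 6, 6)))
        smap = fit_voxel_glm(vol, design)
        p = smap.p_values()
        assert abs((p < 0.05).mean() - 0.05) < 0.03

    def test_exact_fit_voxel_capped_and_flagged(self, rng):
        import pandas as pd

        n = 20
        x = rng.standard_normal(n)
        table = pd.DataFrame({"x": x})
        design = build_design(table, predictor="x", covariates=[])
        data = np.stack([x, rng.standard_normal(n)], axis=1).reshape(n, 2, 1, 1)
        smap = fit_voxel_glm(_vol(data), design)
        assert smap.capped[0] and not smap.capped[1]
        assert np.isfinite(smap.z).all()

    def test_rank_deficient_design_rejected_before_fit(self, rng, small_cohort):
        t = small_cohort.copy()
        t["dup"] = t["age"]
        with pytest.raises(DesignError):
            build_design(t, predictor="upsit", covariates=["age", "dup"])


class TestZTransform:
    def test_monotone_sign_preserving_and_p_matching(self):
        t = np.array([-5.0, -1.2, 0.0, 0.7, 3.3, 8.0])
        z, capped = t_to_z(t, df=50)
        assert not capped.any()
        assert (np.sign(z) == np.sign(t)).all()
        assert (np.diff(z) > 0).all()
        np.testing.assert_allclose(
            2 * stats.norm.sf(np.abs(z)), two_sided_p_from_t(t, 50), rtol=1e-12
        )


class TestEstimateSmoothness:
    def test_white_noise_near_voxel_size(self, rng):
        vol = _vol(rng.standard_normal((10, 24, 24, 24)))
        f = estimate_smoothness(vol)
        assert abs(f - 2.0) / 2.0 < 0.2

    def test_smoothed_noise_adds_in_quadrature(self, rng):
        sigma_vox = 6.0 / 2.3548 / 2.0  # 6 mm kernel on a 2 mm grid
        data = gaussian_filter(rng.standard_normal((10, 32, 32, 32)), (0, *[sigma_vox] * 3))
        f = estimate_smoothness(_vol(data))
        expected = np.sqrt(6.0**2 + 2.0**2)
        assert abs(f - expected) / expected < 0.15

    def test_constant_residuals_rejected(self):
        with pytest.raises(EstimationError):
            estimate_smoothness(_vol(np.ones((2, 10, 10, 10))))

    def test_tiny_mask_rejected(self, rng):
        vol = VolumeSet(
            data=rng.standard_normal((2, 4, 4, 4)),
            affine=np.diag([2.0, 2, 2, 1]),
            mask=np.zeros((4, 4, 4), bool),
        )
        with pytest.raises(EstimationError):
            estimate_smoothness(vol)


class TestCountNull:
    def test_alpha_to_zero_threshold_one(self):
        null = odorant_count_null(
            np.ones((6, 6, 6), bool), (2.0, 2, 2), fwhm_est=2.0, n_iter=200, alpha=1e-12, seed=0
        )
        assert null.threshold_count == 1

    def test_seed_reproducible(self):
        kw = dict(fwhm_est=3.0, n_iter=150, alpha=0.05, seed=7)
        a = odorant_count_null(np.ones((6, 6, 6), bool), (2.0, 2, 2), **kw)
        b = odorant_count_null(np.ones((6, 6, 6), bool), (2.0, 2, 2), **kw)
        assert a.threshold_count == b.threshold_count
        np.testing.assert_array_equal(a.count_histogram, b.count_histogram)

    def test_low_iterations_refused(self):
        with pytest.raises(ParameterError):
            odorant_count_null(np.ones((6, 6, 6), bool), (2.0, 2, 2), fwhm_est=2.0, n_iter=50)

    def test_subvoxel_smoothness_refused(self):
        with pytest.raises(ParameterError):
            odorant_count_null(np.ones((6, 6, 6), bool), (2.0, 2, 2), fwhm_est=1.0, n_iter=200)


class TestCountMap:
    def test_identical_maps_counts_zero_or_full(self, rng, small_cohort):
        design = build_design(small_cohort, predictor="upsit", covariates=["age"])
        vol = _vol(rng.standard_normal((len(small_cohort), 5, 5, 5)))
        smap = fit_voxel_glm(vol, design)
        cmap = count_map([smap] * 40, threshold_count=10)
        assert set(np.unique(cmap.counts)) <= {0, 40}

    def test_missing_maps_recorded_and_excluded(self, rng, small_cohort):
        design = build_design(small_cohort, predictor="upsit", covariates=["age"])
        vol = _vol(rng.standard_normal((len(small_cohort), 5, 5, 5)))
        smap = fit_voxel_glm(vol, design)
        cmap = count_map([smap, None, smap], threshold_count=3)
        assert cmap.missing == [1]
        assert cmap.n_valid_maps == 2


class TestClusterCorrect:
    def test_empty_suprathreshold_set_is_empty_result(self, rng, small_cohort):
        design = build_design(small_cohort, predictor="upsit", covariates=["age"])
        vol = _vol(rng.standard_normal((len(small_cohort), 6, 6, 6)) * 1e-6)
        smap = fit_voxel_glm(vol, design)
        smap.z[:] = 0.0
        res = cluster_correct(smap, fwhm_est=3.0, n_iter=150, seed=0)
        assert res.n_clusters == 0

    def test_huge_planted_effect_hits_p_floor(self, rng, small_cohort):
        design = build_design(small_cohort, predictor="upsit", covariates=["age"])
        n = len(small_cohort)
        upsit = small_cohort["upsit"].to_numpy(float)
        data = rng.standard_normal((n, 8, 8, 8)) * 0.1
        data += upsit[:, None, None, None] * 0.5  # whole-volume effect
        smap = fit_voxel_glm(_vol(data), design)
        res = cluster_correct(smap, fwhm_est=3.0, n_iter=200, seed=0)
        big = int(np.argmax(res.sizes))
        assert res.below_resolution[big]
        assert res.cluster_p[big] <= 1.0 / 200 + 1e-9

    def test_connectivity_option_changes_clustering(self):
        from olfatau.voxel_assoc import _connectivity_structure

        assert _connectivity_structure(6).sum() == 7
        assert _connectivity_structure(26).sum() == 27
        with pytest.raises(ParameterError):
            _connectivity_structure(18)

    def test_results_invariant_to_subject_order(self, rng, small_cohort):
        perm = rng.permutation(len(small_cohort))
        design = build_design(small_cohort, predictor="upsit", covariates=["age", "sex"])
        table_p = small_cohort.iloc[perm].reset_index(drop=True)
        design_p = build_design(table_p, predictor="upsit", covariates=["age", "sex"])
        data = rng.standard_normal((len(small_cohort), 5, 5, 5))
        s1 = fit_voxel_glm(_vol(data), design)
        s2 = fit_voxel_glm(_vol(data[perm]), design_p)
        np.testing.assert_allclose(s1.t, s2.t, rtol=1e-9)
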