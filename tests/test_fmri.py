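"""Motion estimation/realignment, smoothing, and the GLM stack."""

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from somnofuse.core import (
    ConfigurationError,
    DesignMatrix,
    MotionTrace,
    PreconditionError,
    StatMap,
    VolumeSeries,
)
from somnofuse.fmri_preprocess import (
    FWHM_TO_SIGMA,
    apply_rigid,
    estimate_motion,
    motion_summary,
    smooth,
)
from somnofuse.glm import (
    contrast_tmap,
    fit_first_level,
    intersect_maps,
    label_regions,
    second_level_ttest,
    t_cutoff,
    threshold_map,
)


def smooth_random_volume(shape=(16, 16, 16), sigma=1.0, seed=0):
    g = np.random.default_rng(seed)
    return gaussian_filter(g.standard_normal(shape), sigma)


class TestEstimateMotion:
    VS = (3.0, 3.0, 3.0)

    def _series(self, volumes):
        return VolumeSeries(np.stack(volumes, axis=-1), tr=1.0, voxel_size=self.VS)

    def test_identical_volumes_zero_parameters(self):
        base = smooth_random_volume()
        trace, _ = estimate_motion(self._series([base, base, base]), reference=0,
                                   two_pass=False)
        assert np.abs(trace.as_columns()).max() <= 1e-3

    def test_integer_translation_recovered(self):
        base = smooth_random_volume()
        moved = apply_rigid(base, np.array([-6.0, 0, 0, 0, 0, 0]), self.VS,
                            float(base.min()), order=3)
        trace, _ = estimate_motion(self._series([base, moved]), reference=0,
                                   two_pass=False)
        assert abs(trace.translations[1, 0] - 6.0) <= 0.3
        assert np.abs(trace.translations[1, 1:]).max() <= 0.3

    def test_rotation_recovered(self):
        base = smooth_random_volume()
        moved = apply_rigid(base, np.array([0, 0, 0, 0, 0, -3.0]), self.VS,
                            float(base.min()), order=3)
        trace, _ = estimate_motion(self._series([base, moved]), reference=0,
                                   two_pass=False)
        assert abs(trace.rotations[1, 2] - 3.0) <= 0.3

    def test_subvoxel_translation_recovered(self):
        base = smooth_random_volume()
        moved = apply_rigid(base, np.array([-1.2, 0.9, 0, 0, 0, 0]), self.VS,
                            float(base.min()), order=3)
        trace, _ = estimate_motion(self._series([base, moved]), reference=0,
                                   two_pass=False)
        assert abs(trace.translations[1, 0] - 1.2) <= 0.3
        assert abs(trace.translations[1, 1] + 0.9) <= 0.3

    def test_realignment_restores_interior(self):
        """Realigned sub-voxel-shifted volumes match the original on the
        interior to within 2% of the intensity range."""
        base = smooth_random_volume()
        moved = apply_rigid(base, np.array([-1.2, 0.9, 0, 0, 0, 0]), self.VS,
                            float(base.min()), order=3)
        _, realigned = estimate_motion(self._series([base, moved]), reference=0,
                                       two_pass=False)
        inner = (slice(3, -3),) * 3
        err = np.abs(realigned.data[inner + (1,)] - base[inner]).mean()
        assert err <= 0.02 * np.ptp(base)

    def test_constant_series_flagged_zero(self):
        series = VolumeSeries(np.ones((8, 8, 8, 3)), tr=1.0)
        trace, _ = estimate_motion(series)
        np.testing.assert_array_equal(trace.as_columns(), 0.0)

    def test_single_volume_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_motion(VolumeSeries(np.zeros((4, 4, 4, 1)), tr=1.0))


class TestSmooth:
    def test_constant_volume_unchanged(self):
        series = VolumeSeries(np.full((8, 8, 8, 2), 7.0), tr=1.0)
        out = smooth(series, (8.0, 8.0, 8.0))
        np.testing.assert_allclose(out.data, 7.0, atol=1e-9)

    def test_impulse_matches_analytic_gaussian(self):
        imp = np.zeros((15, 15, 15, 1))
        imp[7, 7, 7, 0] = 1.0
        fwhm = 4.0
        out = smooth(VolumeSeries(imp, tr=1.0), (fwhm,) * 3)
        sigma = fwhm / FWHM_TO_SIGMA
        # closed-form separable oracle: sampled Gaussian kernel with the
        # same truncation, divided per axis by the in-grid kernel mass
        # (the edge renormalisation smooth() applies)
        radius = int(6.0 * sigma + 0.5)
        kk = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        kk /= kk.sum()
        idx = np.arange(15)
        g1 = kk[idx - 7 + radius]
        mass = np.array([
            kk[np.clip(i - idx + radius, 0, 2 * radius)][
                (i - idx + radius >= 0) & (i - idx + radius <= 2 * radius)
            ].sum()
            for i in idx
        ])
        g1n = g1 / mass
        oracle = g1n[:, None, None] * g1n[None, :, None] * g1n[None, None, :]
        np.testing.assert_allclose(out.data[..., 0], oracle, atol=1e-6)

    def test_global_mean_preserved(self, rng):
        data = rng.uniform(50, 150, (12, 12, 12, 3))
        out = smooth(VolumeSeries(data, tr=1.0), (8.0, 8.0, 8.0))
        np.testing.assert_allclose(out.data.mean(), data.mean(), rtol=5e-3)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ConfigurationError):
            smooth(VolumeSeries(np.zeros((4, 4, 4, 1)), tr=1.0), (-1, 0, 0))


class TestMotionSummary:
    def test_zero_trace_all_zero(self):
        s = motion_summary(MotionTrace(np.zeros((10, 3)), np.zeros((10, 3))))
        assert s.max_abs.max() == 0
        assert s.framewise_displacement.max() == 0
        assert s.drift_statistic == 0.0

    def test_linear_drift_rank_correlation_one(self):
        t = np.linspace(0, 1, 20)
        trace = MotionTrace(np.column_stack([t, 0 * t, 0 * t]), np.zeros((20, 3)))
        s = motion_summary(trace)
        assert s.drift_statistic == pytest.approx(1.0)

    def test_step_displacement_located(self):
        trans = np.zeros((30, 3))
        trans[17:, 0] = 2.0
        s = motion_summary(MotionTrace(trans, np.zeros((30, 3))))
        assert int(np.argmax(s.framewise_displacement)) == 17


def tiny_series(Y, grid=(5, 1, 1)):
    return VolumeSeries(Y.T.reshape(*grid, -1), tr=1.0)


class TestFirstLevel:
    def _random_problem(self, n=20, k=4, v=5, seed=0):
        g = np.random.default_rng(seed)
        X = np.column_stack([g.standard_normal((n, k - 1)), np.ones(n)])
        design = DesignMatrix(
            X, [f"x{i}" for i in range(k - 1)] + ["intercept"],
            ["condition"] * (k - 1) + ["intercept"], 1.0)
        Y = g.standard_normal((n, v))
        return design, Y

    def test_matches_normal_equations(self):
        design, Y = self._random_problem()
        fit = fit_first_level(tiny_series(Y), design)
        X = design.matrix
        oracle = np.linalg.inv(X.T @ X) @ X.T @ Y
        np.testing.assert_allclose(fit.betas, oracle.T, atol=1e-10)

    def test_zero_data_zero_betas(self):
        design, Y = self._random_problem()
        fit = fit_first_level(tiny_series(np.zeros_like(Y)), design)
        np.testing.assert_array_equal(fit.betas, 0.0)
        np.testing.assert_array_equal(fit.residual_variance, 0.0)

    def test_noiseless_synthetic_bold_recovers_planted_betas(self, light_subject):
        from somnofuse.synth import generate_bold

        truth = light_subject.truth
        spec_grid = (12, 14, 12)
        vol = generate_bold(truth.true_design, truth.true_betas, 0.0, spec_grid, 1.0)
        fit = fit_first_level(vol, truth.true_design)
        np.testing.assert_allclose(fit.betas, truth.true_betas, atol=1e-9)

    def test_rank_deficiency_names_columns(self):
        g = np.random.default_rng(0)
        x = g.standard_normal(20)
        X = np.column_stack([x, x, np.ones(20)])
        design = DesignMatrix(X, ["a", "b", "intercept"],
                              ["condition", "condition", "intercept"], 1.0)
        with pytest.raises(Exception, match="collinear"):
            fit_first_level(tiny_series(np.zeros((20, 5))), design)


class TestContrastTmap:
    def test_hand_computed_four_scan_case(self):
        """Single-column pick on a 4-scan problem, checked against the
        hand formula t = c'b / sqrt(s2 c'(X'X)^-1 c)."""
        X = np.array([[1.0, 1], [2.0, 1], [3.0, 1], [4.0, 1]])
        y = np.array([2.0, 3.9, 6.1, 8.0])
        design = DesignMatrix(X, ["slope", "intercept"],
                              ["condition", "intercept"], 1.0)
        fit = fit_first_level(tiny_series(y[:, None], grid=(1, 1, 1)), design)
        tmap = contrast_tmap(fit, [1.0, 0.0])
        b = np.linalg.inv(X.T @ X) @ X.T @ y
        resid = y - X @ b
        s2 = resid @ resid / 2
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0])
        np.testing.assert_allclose(tmap.t_values.ravel()[0], b[0] / se, atol=1e-10)

    def test_zero_contrast_rejected(self):
        X = np.column_stack([np.arange(4.0), np.ones(4)])
        design = DesignMatrix(X, ["a", "intercept"], ["condition", "intercept"], 1.0)
        fit = fit_first_level(tiny_series(np.zeros((4, 1)), grid=(1, 1, 1)), design)
        with pytest.raises(ConfigurationError):
            contrast_tmap(fit, [0.0, 0.0])

    def test_group_indicator_contrast_equals_two_sample_t(self, rng):
        na, nb = 6, 8
        X = np.zeros((na + nb, 2))
        X[:na, 0] = 1
        X[na:, 1] = 1
        y = np.concatenate([rng.standard_normal(na) + 1.0, rng.standard_normal(nb)])
        design = DesignMatrix(X, ["ga", "intercept"], ["condition", "intercept"], 1.0)
        fit = fit_first_level(tiny_series(y[:, None], grid=(1, 1, 1)), design)
        tmap = contrast_tmap(fit, [1.0, -1.0])
        t_oracle, _ = stats.ttest_ind(y[:na], y[na:])
        np.testing.assert_allclose(tmap.t_values.ravel()[0], t_oracle, atol=1e-9)


class TestSecondLevel:
    def test_hand_computed_t(self):
        maps = [np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0, 4.0)]
        # add a voxel with variation so sd > 0 -- use distinct voxel values
        vols = [np.zeros((1, 1, 1)) + v for v in (1.0, 2.0, 3.0, 4.0)]
        res = second_level_ttest(vols)
        assert res.df == 3
        np.testing.assert_allclose(res.t_values.ravel()[0], 3.873, atol=1e-3)

    def test_identical_zero_maps_zero_t(self):
        res = second_level_ttest([np.zeros((2, 2, 2))] * 4)
        np.testing.assert_array_equal(res.t_values, 0.0)

    def test_sign_flip_negates_map(self, rng):
        maps = [rng.standard_normal((3, 3, 3)) for _ in range(5)]
        a = second_level_ttest(maps)
        b = second_level_ttest([-m for m in maps])
        np.testing.assert_allclose(a.t_values, -b.t_values, atol=1e-12)

    def test_single_subject_rejected(self):
        with pytest.raises(PreconditionError):
            second_level_ttest([np.zeros((2, 2, 2))])


class TestThresholdMap:
    def test_df16_cutoff(self):
        assert abs(t_cutoff(16, 0.01) - 2.921) <= 0.001

    def test_all_subthreshold_empty(self, rng):
        sm = StatMap(rng.uniform(-1, 1, (6, 6, 6)), df=16)
        thr = threshold_map(sm, 0.01, 5)
        assert not thr.mask.any() and thr.n_clusters == 0

    def test_min_extent_rule(self):
        t = np.zeros((20, 5, 5))
        t[0:5, 0, 0] = 10.0  # 5-voxel line cluster
        t[8:20, 1, 1] = 10.0  # 12-voxel line cluster
        thr = threshold_map(StatMap(t, df=16), 0.01, min_extent=10)
        assert thr.n_clusters == 1
        assert thr.mask.sum() == 12

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigurationError):
            threshold_map(StatMap(np.zeros((2, 2, 2)), df=5), 1.5, 1)

    def test_sign_recorded(self):
        t = np.zeros((12, 4, 4))
        t[0:11, 0, 0] = 5.0
        t[0:11, 2, 2] = -5.0
        thr = threshold_map(StatMap(t, df=16), 0.01, min_extent=10)
        assert set(np.unique(thr.sign)) == {-1, 0, 1}


class TestIntersectMaps:
    def _thr(self, t, p=0.01, extent=1):
        return threshold_map(StatMap(t, df=16), p, extent)

    def test_identical_maps_all_same_sign(self, rng):
        t = np.where(rng.uniform(size=(6, 6, 6)) > 0.7, 5.0, 0.0)
        a = self._thr(t)
        res = intersect_maps(a, self._thr(t))
        assert res["n_joint"] == a.mask.sum()
        assert res["n_opposite_sign"] == 0

    def test_disjoint_masks_empty(self):
        ta = np.zeros((6, 6, 6)); ta[0, 0, 0] = 5.0
        tb = np.zeros((6, 6, 6)); tb[5, 5, 5] = 5.0
        res = intersect_maps(self._thr(ta), self._thr(tb))
        assert res["n_joint"] == 0

    def test_opposite_signs_tallied(self):
        ta = np.zeros((6, 6, 6)); ta[2, 2, 2] = 5.0
        tb = np.zeros((6, 6, 6)); tb[2, 2, 2] = -5.0
        res = intersect_maps(self._thr(ta), self._thr(tb))
        assert res["n_opposite_sign"] == 1 and res["n_same_sign"] == 0

    def test_commutative(self, rng):
        ta = np.where(rng.uniform(size=(6, 6, 6)) > 0.6, 4.0, 0.0)
        tb = -np.where(rng.uniform(size=(6, 6, 6)) > 0.6, 4.0, 0.0)
        r1 = intersect_maps(self._thr(ta), self._thr(tb))
        r2 = intersect_maps(self._thr(tb), self._thr(ta))
        assert r1["n_joint"] == r2["n_joint"]
        assert r1["n_same_sign"] == r2["n_same_sign"]

    def test_threshold_mismatch_requires_force(self, rng):
        t = np.where(rng.uniform(size=(4, 4, 4)) > 0.5, 5.0, 0.0)
        with pytest.raises(Exception):
            intersect_maps(self._thr(t, p=0.01), self._thr(t, p=0.05))


class TestLabelRegions:
    def _map_in_label(self):
        t = np.zeros((10, 10, 10))
        t[2:5, 2:5, 2:5] = 6.0
        labels = np.zeros((10, 10, 10), int)
        labels[0:6, 0:6, 0:6] = 1
        return threshold_map(StatMap(t, df=16), 0.01, 5), labels

    def test_single_label_full_attribution(self):
        thr, labels = self._map_in_label()
        table = label_regions(thr, labels, {0: "bg", 1: "roi"})
        row = table[table["label"] == "roi"].iloc[0]
        assert row["fraction"] == 1.0 and row["dominant_label"] == "roi"

    def test_split_cluster_counts(self):
        t = np.zeros((10, 4, 4))
        t[0:10, 0, 0] = 6.0
        labels = np.zeros((10, 4, 4), int)
        labels[0:7] = 1
        labels[7:] = 2
        thr = threshold_map(StatMap(t, df=16), 0.01, 5)
        table = label_regions(thr, labels, {1: "a", 2: "b"})
        fracs = dict(zip(table["label"], table["fraction"]))
        assert fracs["a"] == pytest.approx(0.7)
        assert fracs["b"] == pytest.approx(0.3)
        assert (table["dominant_label"] == "a").all()

    def test_empty_map_empty_table(self):
        thr = threshold_map(StatMap(np.zeros((4, 4, 4)), df=16), 0.01, 5)
        table = label_regions(thr, np.zeros((4, 4, 4), int))
        assert table.empty


class TestNullCalibration:
    def test_voxelwise_false_positive_rate(self, rng):
        """Null second-level maps (n=8, 200 voxels): the fraction of |t|
        above the two-sided p=0.01 cutoff is 0.01 +- 0.005 across 100
        repetitions."""
        rates = []
        for _ in range(100):
            maps = [rng.standard_normal((10, 5, 4)) for _ in range(8)]
            sm = second_level_ttest(maps)
            cut = t_cutoff(sm.df, 0.01)
            rates.append(np.mean(np.abs(sm.t_values) > cut))
        assert abs(np.mean(rates) - 0.01) <= 0.005
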