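import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emodyn import estimation as est
from emodyn.design import DesignMatrix, dct_highpass_basis
from emodyn.io_core import StatMap, VolumeSeries


def _design(M, names, tr=2.0, hp=None):
    if hp is None:
        hp = np.zeros((M.shape[0], 0))
    return DesignMatrix(M=M, names=names, tr_s=tr, hp_basis=hp)


def _bold_from(Y, shape3, mask=None):
    """Pack an (n, V) matrix into a VolumeSeries over the given grid."""
    n, V = Y.shape
    data = np.zeros(shape3 + (n,))
    if mask is None:
        mask = np.zeros(shape3, bool)
        mask.ravel()[:V] = True
    data[mask] = Y.T
    return VolumeSeries(data=data, affine=np.eye(4), tr_s=2.0, brain_mask=mask)


class TestFirstLevel:
    def test_noiseless_exact_recovery(self, rng):
        n, p, V = 40, 4, 30
        X = np.column_stack([rng.normal(size=(n, p - 1)), np.ones(n)])
        beta0 = rng.normal(size=(p, V))
        bold = _bold_from(X @ beta0, (4, 4, 4))
        flr = est.fit_first_level(bold, _design(X, ["a", "b", "c", "intercept"]))
        np.testing.assert_allclose(flr.beta.T, beta0, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        n, p, V = 20, 4, 10
        X = np.column_stack([rng.normal(size=(n, p - 1)), np.ones(n)])
        Y = rng.normal(size=(n, V))
        bold = _bold_from(Y, (3, 3, 3))
        flr = est.fit_first_level(bold, _design(X, ["a", "b", "c", "intercept"]))
        # independent dense normal-equations oracle
        beta_o = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(flr.beta.T, beta_o, atol=1e-10)
        resid = Y - X @ beta_o
        sigma2_o = (resid ** 2).sum(axis=0) / (n - p)
        np.testing.assert_allclose(flr.sigma2, sigma2_o, atol=1e-10)
        # t statistics against the closed form
        c = np.array([1.0, 0, 0, 0])
        t_o = beta_o[0] / np.sqrt(sigma2_o * np.linalg.inv(X.T @ X)[0, 0])
        tmap = est.contrast_map(flr, c)
        np.testing.assert_allclose(tmap.values[bold.brain_mask], t_o, atol=1e-8)

    def test_drift_projection_equals_nuisance_columns(self, rng):
        """High-pass by projection is OLS-equivalent to DCT nuisance columns."""
        n, V = 120, 12
        hp = dct_highpass_basis(n, 2.04, 200.0)
        X = np.column_stack([rng.normal(size=(n, 2)), np.ones(n)])
        Y = rng.normal(size=(n, V)) + hp @ rng.normal(size=(hp.shape[1], V))
        bold = _bold_from(Y, (3, 3, 3))
        flr = est.fit_first_level(bold, _design(X, ["a", "b", "intercept"], hp=hp))
        X_aug = np.column_stack([X, hp])
        beta_aug = np.linalg.lstsq(X_aug, Y, rcond=None)[0]
        np.testing.assert_allclose(flr.beta.T, beta_aug[:3], atol=1e-8)
        assert flr.df == n - 3 - hp.shape[1]

    def test_rank_deficient_design_rejected(self, rng):
        X = np.ones((20, 2))
        bold = _bold_from(rng.normal(size=(20, 4)), (2, 2, 2))
        with pytest.raises(ValueError, match="rank"):
            est.fit_first_level(bold, _design(X, ["a", "intercept"]))


class TestContrast:
    def _flr(self, rng):
        n, V = 30, 8
        X = np.column_stack([rng.normal(size=(n, 2)), np.ones(n)])
        bold = _bold_from(rng.normal(size=(n, V)), (2, 2, 2))
        return est.fit_first_level(bold, _design(X, ["a", "b", "intercept"]))

    def test_sign_antisymmetry(self, rng):
        flr = self._flr(rng)
        plus = est.contrast_map(flr, {"a": 1.0})
        minus = est.contrast_map(flr, {"a": -1.0})
        np.testing.assert_allclose(plus.values[flr.mask],
                                   -minus.values[flr.mask], atol=1e-12)

    def test_zero_contrast_rejected(self, rng):
        with pytest.raises(ValueError, match="zero contrast"):
            est.contrast_map(self._flr(rng), {"a": 0.0})

    def test_null_regressor_false_positive_rate(self, rng):
        """A regressor absent from the generating model triggers at ~p_unc."""
        n, V = 60, 4000
        X = np.column_stack([rng.normal(size=(n, 2)), np.ones(n)])
        Y = rng.normal(size=(n, V))          # pure noise: 'b' explains nothing
        bold = _bold_from(Y, (16, 16, 16))
        flr = est.fit_first_level(bold, _design(X, ["a", "b", "intercept"]))
        tmap = est.contrast_map(flr, {"b": 1.0})
        crit = stats.t.isf(0.001, tmap.df)
        rate = float((tmap.values[flr.mask] > crit).mean())
        ci = 1.96 * np.sqrt(0.001 * 0.999 / V)
        assert abs(rate - 0.001) < ci + 1e-3


class TestGroupTtest:
    def test_scalar_oracle_five_subjects(self):
        vals = np.array([2.1, 1.4, 3.3, 0.2, 1.8])
        maps = [np.full((2, 2, 2), v) for v in vals]
        tmap, p2, p1 = est.group_ttest(maps)
        t_o = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
        assert tmap.df == 4
        np.testing.assert_allclose(tmap.values[tmap.mask], t_o, atol=1e-12)
        np.testing.assert_allclose(p2.values[tmap.mask],
                                   2 * stats.t.sf(abs(t_o), 4), atol=1e-12)

    def test_zero_variance_guard(self):
        maps = [np.full((2, 2, 2), 3.0)] * 4
        tmap, p2, _ = est.group_ttest(maps)
        assert np.all(np.isinf(tmap.values[tmap.mask]))
        assert np.all(p2.values[tmap.mask] == 0.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            est.group_ttest([np.zeros((2, 2, 2))] * 2)

    def test_null_calibration(self, rng):
        n, shape = 32, (30, 30, 30)
        maps = list(rng.normal(size=(n, *shape)))
        _, _, p1 = est.group_ttest(maps)
        rate = float((p1.values[p1.mask] < 0.001).mean())
        V = np.prod(shape)
        ci = 1.96 * np.sqrt(0.001 * 0.999 / V)
        assert abs(rate - 0.001) < ci + 5e-4


class TestClusters:
    def _tmap(self, values, df=30):
        return StatMap(values=values.astype(float), kind="t", df=df,
                       affine=np.diag([3.0, 3, 3, 1]),
                       mask=np.ones(values.shape, bool))

    def test_nine_voxel_blob_below_extent_threshold(self):
        vol = np.zeros((12, 12, 12))
        vol[2:5, 2:5, 2] = 10.0      # 9 voxels
        table, keep = est.threshold_clusters(self._tmap(vol), k_extent=10)
        assert table.empty
        assert not keep.any()

    def test_two_blobs_sorted_by_size(self):
        vol = np.zeros((20, 20, 8))
        vol[1:6, 1:4, 2] = 8.0       # 15 voxels
        vol[10:14, 10:13, 4] = 9.0   # 12 voxels
        table, _ = est.threshold_clusters(self._tmap(vol), k_extent=10)
        assert list(table["n_voxels"]) == [15, 12]
        assert table.loc[1, "peak_t"] == pytest.approx(9.0)

    def test_matches_flood_fill_oracle(self, rng):
        def flood_sizes(supra, neighbours):
            seen = np.zeros_like(supra, bool)
            sizes = []
            for start in np.argwhere(supra):
                if seen[tuple(start)]:
                    continue
                stack, size = [tuple(start)], 0
                seen[tuple(start)] = True
                while stack:
                    v = stack.pop()
                    size += 1
                    for d in neighbours:
                        w = tuple(np.array(v) + d)
                        if all(0 <= w[i] < supra.shape[i] for i in range(3)) \
                                and supra[w] and not seen[w]:
                            seen[w] = True
                            stack.append(w)
                sizes.append(size)
            return sorted(sizes, reverse=True)

        # 18-connectivity: face + edge neighbours
        neighbours = [tuple(np.array(d) - 1) for d in np.ndindex(3, 3, 3)
                      if tuple(np.array(d) - 1) != (0, 0, 0)
                      and np.abs(np.array(d) - 1).sum() <= 2]
        for _ in range(50):
            vol = rng.normal(size=(10, 10, 10)) * 3
            tmap = self._tmap(vol)
            crit = stats.t.isf(0.001, 30)
            table, _ = est.threshold_clusters(tmap, k_extent=1)
            assert list(table["n_voxels"]) == flood_sizes(vol > crit, neighbours)


class TestFdr:
    def _pmap(self, p):
        vol = np.array(p).reshape(-1, 1, 1)
        return StatMap(vol, "p", 10, np.eye(4), np.ones(vol.shape, bool))

    def test_three_value_hand_example(self):
        q = est.fdr_voxelwise(self._pmap([0.001, 0.02, 0.9]))
        np.testing.assert_allclose(q.values[q.mask], [0.003, 0.03, 0.9], atol=1e-12)

    def test_equal_ps_unchanged(self):
        q = est.fdr_voxelwise(self._pmap([0.2] * 5))
        np.testing.assert_allclose(q.values[q.mask], 0.2)

    def test_monotone_in_p(self, rng):
        p = rng.random(50)
        q = est.fdr_voxelwise(self._pmap(p)).values.ravel()
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestSignFlipFwer:
    def test_planted_effect_saturates_p(self, rng):
        n_sub, shape = 10, (12, 12, 12)
        maps = rng.normal(size=(n_sub, *shape))
        maps[:, 3:8, 3:8, 3:8] += 5.0      # 125-voxel strong effect
        table, _, _ = est.cluster_fwer_signflip(list(maps), n_perms=200, seed=1)
        assert not table.empty
        assert table["cluster_p_fwer"].min() == pytest.approx(1 / 201)

    def test_too_many_perms_for_few_subjects(self):
        maps = [np.zeros((4, 4, 4))] * 3
        with pytest.raises(ValueError, match="sign patterns"):
            est.cluster_fwer_signflip(maps, n_perms=1000)


class TestRoi:
    def test_null_center_gives_bonferroni_half(self, rng):
        shape = (6, 6, 6)
        # antisymmetric subject means: exactly zero mean, nonzero variance
        vals = np.array([1.0, -1.0, 0.5, -0.5, 0.25, -0.25])
        maps = [np.full(shape, v) for v in vals]
        roi = np.zeros(shape, bool); roi[2:4, 2:4, 2:4] = True
        r = est.roi_mean_test(maps, roi, "roi", "explosiveness",
                              n_tests_in_family=4)
        assert r.T == pytest.approx(0.0)
        assert r.p_bonferroni == pytest.approx(min(1.0, 0.5 * 4))

    def test_negative_effect_one_sided_ceiling(self, rng):
        maps = [np.full((5, 5, 5), -2.0 + 0.1 * rng.normal()) for _ in range(12)]
        roi = np.ones((5, 5, 5), bool)
        r = est.roi_mean_test(maps, roi, "roi", "accumulation", n_tests_in_family=4)
        assert r.T < -3
        assert r.p_bonferroni == 1.0     # mirrors a strongly negative one-sided test

    def test_power_matches_noncentral_t(self, rng):
        """Empirical one-sided test power vs the noncentral-t closed form."""
        n, effect, reps, alpha = 32, 0.5, 400, 0.05
        crit = stats.t.isf(alpha, n - 1)
        power_theory = stats.nct.sf(crit, n - 1, effect * np.sqrt(n))
        roi = np.ones((2, 2, 2), bool)
        hits = 0
        for _ in range(reps):
            subj = rng.normal(effect, 1.0, n)
            maps = [np.full((2, 2, 2), v) for v in subj]
            r = est.roi_mean_test(maps, roi, "roi", "x", n_tests_in_family=1)
            hits += r.p_raw < alpha
        assert abs(hits / reps - power_theory) < 0.03 + 2 * np.sqrt(
            power_theory * (1 - power_theory) / reps)

    def test_empty_roi_rejected(self):
        maps = [np.zeros((4, 4, 4))] * 5
        with pytest.raises(ValueError, match="no voxels"):
            est.roi_mean_test(maps, np.zeros((4, 4, 4), bool), "r", "x")


class TestInsulaSplit:
    def test_partition_property(self):
        mask = np.zeros((10, 20, 10), bool)
        mask[4:6, :, 4:6] = True
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[1, 3] = -30.0    # world y spans [-30, 27]
        ant, post = est.split_insula_mask(mask, affine, -10.0)
        assert ant.any() and post.any()
        assert not (ant & post).any()
        np.testing.assert_array_equal(ant | post, mask)

    def test_everything_anterior_warns_empty_posterior(self, caplog):
        mask = np.zeros((4, 4, 4), bool)
        mask[:, 2:, :] = True
        affine = np.eye(4)       # world y = voxel j >= 0 > -10
        with caplog.at_level("WARNING", logger="emodyn"):
            ant, post = est.split_insula_mask(mask, affine, -10.0)
        assert not post.any()
        assert "posterior side is empty" in caplog.text

    def test_membership_matches_affine_oracle(self, rng):
        for _ in range(100):
            A = np.eye(4)
            A[:3, :3] = rng.normal(size=(3, 3))
            A[:3, 3] = rng.normal(scale=20, size=3)
            mask = rng.random((6, 6, 6)) > 0.5
            if not mask.any():
                continue
            ant, post = est.split_insula_mask(mask, A, -10.0)
            for idx in np.argwhere(mask):
                y = (A @ np.array([*idx, 1.0]))[1]
                assert ant[tuple(idx)] == (y > -10.0)
                assert post[tuple(idx)] == (y <= -10.0)
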