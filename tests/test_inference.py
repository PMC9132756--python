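import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbconn.inference import (
    GroupConnectivityModel,
    GroupDesign,
    TfceParams,
    chi2_2x2,
    permutation_fwe,
    stack_maps,
    t_from_summary,
    tfce,
    voxel_stat_map,
)
from rbconn.volumes import ConnMap, VolumeGrid


def make_maps(values: np.ndarray, grid_shape=None, fisher=True):
    """Wrap an (n_subjects x p) matrix as a list of Fisher-scale ConnMaps on
    a (p,1,1) grid (or the first p raster voxels of grid_shape)."""
    n, p = values.shape
    if grid_shape is None:
        grid_shape = (p, 1, 1)
        coords = np.column_stack([np.arange(p), np.zeros(p, int), np.zeros(p, int)])
    else:
        grid = np.indices(grid_shape).reshape(3, -1).T
        order = np.lexsort((grid[:, 0], grid[:, 1], grid[:, 2]))
        coords = grid[order][:p]
    return [ConnMap(values=values[i], method="RBC", voxel_index=coords,
                    lam=50.0, fisher=fisher) for i in range(n)], VolumeGrid(grid_shape)


def two_group_design(n1, n2, nuisance=None, contrast="two-sided"):
    reg = np.r_[np.zeros(n1), np.ones(n2)]
    return GroupDesign(subjects=[f"s{i}" for i in range(n1 + n2)],
                       regressor=reg, nuisance=nuisance, contrast=contrast)


class TestSummaryStats:
    def test_pooled_t_equal_means_is_zero(self):
        t, _ = t_from_summary(10.0, 2.0, 20, 10.0, 3.0, 25)
        assert t == 0.0

    def test_pooled_t_matches_scipy_from_samples(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1.2, 18)
        t, p = t_from_summary(a.mean(), a.std(ddof=1), 15, b.mean(), b.std(ddof=1), 18)
        ref = stats.ttest_ind(b, a, equal_var=True)
        np.testing.assert_allclose([t, p], [ref.statistic, ref.pvalue], rtol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            t_from_summary(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            t_from_summary(1, 1.0, 1, 2, 1.0, 10)

    def test_chi2_perfect_separation(self):
        chi2, _ = chi2_2x2([[10, 0], [0, 10]])
        np.testing.assert_allclose(chi2, 20.0)

    def test_chi2_proportional_rows_is_zero(self):
        chi2, p = chi2_2x2([[20, 10], [40, 20]])
        np.testing.assert_allclose(chi2, 0.0, atol=1e-12)
        np.testing.assert_allclose(p, 1.0)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2([[5, 0], [7, 0]])


class TestGroupDesign:
    def test_from_dataframe_group_coding(self):
        df = pd.DataFrame({
            "subject_id": list("abcdef"),
            "group": ["control"] * 3 + ["patient"] * 3,
            "age": [30, 40, 50, 35, 45, 55],
            "gender": ["M", "F", "M", "F", "M", "F"],
        })
        d = GroupDesign.from_dataframe(df, regressor="group", nuisance=["age", "gender"])
        np.testing.assert_array_equal(d.regressor, [0, 0, 0, 1, 1, 1])
        assert d.nuisance.shape == (6, 2)  # age + one gender dummy

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            GroupDesign(subjects=["a", "b", "c"], regressor=np.ones(3))

    def test_rank_deficient_nuisance_rejected(self):
        z = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="rank"):
            two_group_design(3, 3, nuisance=z)


class TestVoxelStatMap:
    def test_identical_groups_give_zero(self):
        values = np.tile(np.linspace(0.3, 0.9, 5), (8, 1))
        maps, _ = make_maps(values)
        t = voxel_stat_map(maps, two_group_design(4, 4))
        np.testing.assert_allclose(t, 0.0, atol=1e-10)

    def test_reduces_to_pooled_two_sample_t(self, rng):
        values = rng.normal(0.5, 0.1, (12, 20))
        maps, _ = make_maps(values)
        t = voxel_stat_map(maps, two_group_design(6, 6))
        ref = stats.ttest_ind(values[6:], values[:6], equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-10)

    def test_matches_per_voxel_regression_oracle(self, rng):
        n, p = 15, 7
        values = rng.normal(size=(n, p))
        x = rng.normal(size=n)
        z = rng.normal(size=(n, 2))
        design = GroupDesign(subjects=[str(i) for i in range(n)], regressor=x,
                             nuisance=z)
        maps, _ = make_maps(values)
        t = voxel_stat_map(maps, design)
        X = np.column_stack([np.ones(n), z, x])
        for v in range(p):
            beta, *_ = np.linalg.lstsq(X, values[:, v], rcond=None)
            resid = values[:, v] - X @ beta
            df = n - X.shape[1]
            cov = np.linalg.inv(X.T @ X) * (resid @ resid) / df
            expected = beta[-1] / np.sqrt(cov[-1, -1])
            assert abs(t[v] - expected) < 1e-10

    def test_too_few_per_group_rejected(self, rng):
        values = rng.normal(size=(5, 4))
        maps, _ = make_maps(values)
        with pytest.raises(ValueError, match="3 subjects"):
            voxel_stat_map(maps, two_group_design(2, 3))

    def test_stack_rejects_mixed_methods(self, rng):
        values = rng.normal(size=(4, 3))
        maps, _ = make_maps(values)
        maps[1] = ConnMap(values=values[1], method="GBC",
                          voxel_index=maps[0].voxel_index, fisher=True)
        with pytest.raises(ValueError, match="mix"):
            stack_maps(maps)

    def test_stack_drops_voxels_missing_in_any_subject(self, rng):
        values = rng.normal(size=(4, 5))
        values[2, 3] = np.nan
        maps, _ = make_maps(values)
        stacked, idx, _ = stack_maps(maps)
        assert stacked.shape == (4, 4)
        assert not any((idx == [3, 0, 0]).all(axis=1))


class TestTfce:
    def test_all_zero_map(self):
        params = TfceParams()
        out = tfce(np.zeros((4, 4, 4)), params, np.ones((4, 4, 4), bool))
        np.testing.assert_array_equal(out, 0.0)

    def test_constant_map_closed_form(self):
        shape = (3, 3, 3)
        mask = np.zeros(shape, bool)
        mask[:2, :2, :2] = True  # k = 8 connected voxels
        c = 2.0
        params = TfceParams(E=0.5, H=2.0, dh=0.1)
        out = tfce(np.where(mask, c, 0.0), params, mask)
        hs = np.arange(0.1, c + 1e-9, 0.1)
        expected = sum(8 ** 0.5 * h ** 2 * 0.1 for h in hs)
        np.testing.assert_allclose(out[mask], expected, rtol=1e-10)
        np.testing.assert_array_equal(out[~mask], 0.0)

    def test_single_voxel_riemann_sum_approaches_cube_over_three(self):
        shape = (5, 5, 5)
        mask = np.ones(shape, bool)
        stat = np.zeros(shape)
        h0 = 3.0
        stat[2, 2, 2] = h0
        params = TfceParams(E=0.5, H=2.0, dh=h0 / 2000)
        out = tfce(stat, params, mask)
        # e(h) = 1, so TFCE -> integral of h^2 dh = h0^3 / 3
        np.testing.assert_allclose(out[2, 2, 2], h0**3 / 3, rtol=2e-3)

    def test_monotone_in_the_stat_map(self, rng):
        shape = (4, 4, 4)
        mask = np.ones(shape, bool)
        stat = np.abs(rng.normal(size=shape))
        params = TfceParams(dh=0.05)
        base = tfce(stat, params, mask)
        higher = tfce(stat + 0.3, params, mask)
        assert (higher >= base - 1e-12).all()

    def test_connectivity_neighborhoods(self):
        # two diagonal voxels: one component under 26-connectivity,
        # two separate voxels under 6-connectivity
        shape = (3, 3, 3)
        mask = np.ones(shape, bool)
        stat = np.zeros(shape)
        stat[0, 0, 0] = stat[1, 1, 1] = 1.0
        p26 = TfceParams(connectivity=26, dh=0.5)
        p6 = TfceParams(connectivity=6, dh=0.5)
        out26 = tfce(stat, p26, mask)
        out6 = tfce(stat, p6, mask)
        assert out26[0, 0, 0] > out6[0, 0, 0]
        np.testing.assert_allclose(out26[0, 0, 0] / out6[0, 0, 0], np.sqrt(2))

    def test_nonfinite_rejected(self):
        stat = np.zeros((3, 3, 3))
        stat[1, 1, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            tfce(stat, TfceParams(), np.ones((3, 3, 3), bool))


class TestPermutationFwe:
    def test_identical_maps_give_p_one(self):
        values = np.tile(np.linspace(0.2, 0.8, 6), (10, 1))
        maps, grid = make_maps(values)
        res = permutation_fwe(maps, two_group_design(5, 5), grid,
                              n_perm=99, seed=3)
        np.testing.assert_array_equal(res.fwe_p, 1.0)
        np.testing.assert_allclose(res.stat_map, 0.0, atol=1e-10)

    def test_p_floor(self, rng):
        values = rng.normal(size=(12, 8))
        values[6:, :4] += 3.0
        maps, grid = make_maps(values)
        res = permutation_fwe(maps, two_group_design(6, 6), grid,
                              n_perm=49, seed=4)
        assert res.fwe_p.min() >= 1.0 / (res.n_perm + 1)
        assert (res.fwe_p <= 1.0).all()

    def test_exhaustive_enumeration_is_seed_invariant(self, rng):
        values = rng.normal(size=(8, 6))
        values[4:, :3] += 1.5
        maps, grid = make_maps(values)
        design = two_group_design(4, 4, contrast="greater")  # C(8,4)=70
        r1 = permutation_fwe(maps, design, grid, n_perm=500, seed=1)
        r2 = permutation_fwe(maps, design, grid, n_perm=500, seed=99)
        assert r1.exhaustive and r1.n_perm == 70
        np.testing.assert_array_equal(r1.fwe_p, r2.fwe_p)

    def test_subject_order_invariance_when_enumerated(self, rng):
        values = rng.normal(size=(8, 6))
        values[4:, :3] += 1.5
        maps, grid = make_maps(values)
        design = two_group_design(4, 4, contrast="greater")
        r1 = permutation_fwe(maps, design, grid, n_perm=500, seed=1)
        order = rng.permutation(8)
        maps2 = [maps[i] for i in order]
        design2 = GroupDesign(subjects=[design.subjects[i] for i in order],
                              regressor=design.regressor[order],
                              contrast="greater")
        r2 = permutation_fwe(maps2, design2, grid, n_perm=500, seed=1)
        np.testing.assert_allclose(np.sort(r1.fwe_p), np.sort(r2.fwe_p), atol=1e-12)

    def test_few_permutations_warns(self, rng):
        # continuous regressor, 3 subjects: 3! = 6 distinct permutations
        values = rng.normal(size=(3, 5))
        maps, grid = make_maps(values)
        design = GroupDesign(subjects=["a", "b", "c"],
                             regressor=np.array([1.0, 2.0, 3.0]))
        with pytest.warns(UserWarning, match="distinct permutations"):
            permutation_fwe(maps, design, grid, n_perm=50, seed=2)

    def test_planted_effect_detected_with_freedman_lane(self, rng):
        # strong localized effect + a nuisance covariate correlated with age
        n1 = n2 = 10
        n, p = n1 + n2, 27
        age = rng.uniform(20, 60, n)
        values = rng.normal(0.5, 0.05, (n, p)) + 0.002 * age[:, None]
        values[n1:, :8] += 0.5
        maps, grid = make_maps(values, grid_shape=(3, 3, 3))
        design = two_group_design(n1, n2, nuisance=age[:, None])
        res = permutation_fwe(maps, design, grid, n_perm=199, seed=5)
        assert res.fwe_p[:8].min() < 0.05
        assert res.fwe_p[8:].min() > 0.05

    def test_seed_required(self, rng):
        values = rng.normal(size=(8, 5))
        maps, grid = make_maps(values)
        with pytest.raises(ValueError, match="seed"):
            permutation_fwe(maps, two_group_design(4, 4), grid, n_perm=10)


class TestModelFrontend:
    def test_model_fit_and_summary(self, rng):
        values = rng.normal(0.5, 0.1, (12, 10))
        values[6:, :3] += 0.6
        maps, grid = make_maps(values)
        model = GroupConnectivityModel(maps, two_group_design(6, 6), grid)
        res = model.fit(n_perm=99, seed=11)
        text = res.summary()
        assert "Permutation TFCE" in text and "significant voxels" in text
        d = res.to_dict()
        assert d["n_voxels"] == 10
        assert d["n_perm"] == res.n_perm

    def test_model_stat_map_matches_function(self, rng):
        values = rng.normal(size=(10, 6))
        maps, grid = make_maps(values)
        design = two_group_design(5, 5)
        model = GroupConnectivityModel(maps, design, grid)
        np.testing.assert_allclose(model.stat_map(),
                                   voxel_stat_map(maps, design), atol=1e-12)

    def test_raw_maps_warn(self, rng):
        values = rng.uniform(0.1, 0.9, (8, 5))
        maps, grid = make_maps(values, fisher=False)
        with pytest.warns(UserWarning, match="Fisher"):
            GroupConnectivityModel(maps, two_group_design(4, 4), grid)
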