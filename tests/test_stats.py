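"""Allometry, PCA, CVA, Procrustes ANOVA and geographic regression."""

import numpy as np
import pytest
from scipy.stats import kstest

from morphodrift import (
    LandmarkError,
    allometry,
    anova_dfs,
    cva,
    geo_regression,
    gpa,
    make_mean_shape,
    procrustes_anova,
    shape_pca,
)
from morphodrift.align import AlignedDataset


def synthetic_aligned(rng, n=30, k=8, size_effect=0.0, direction=None,
                      sizes=None, noise=0.01):
    """Hand-built AlignedDataset: template + noise (+ allometric deformation)."""
    base = make_mean_shape(k, "helix").coords
    log_cs = rng.normal(0.0, 0.2, n) if sizes is None else np.log(sizes)
    flat = base.ravel() + noise * rng.standard_normal((n, 3 * k))
    if size_effect:
        flat = flat + size_effect * np.outer(log_cs, direction)
    return AlignedDataset(
        shape_coords=flat.reshape(n, k, 3),
        centroid_sizes=np.exp(log_cs),
        consensus=flat.mean(axis=0).reshape(k, 3),
        specimen_ids=[f"s{i}" for i in range(n)],
        n_iterations=1, converged=True, scaled=True,
    )


class TestAllometry:
    def test_null_has_small_percent_and_calibrated_p(self, rng):
        pvals = []
        for _ in range(200):
            aligned = synthetic_aligned(rng, n=25, k=6)
            res = allometry(aligned, n_perm=99, seed=1)
            pvals.append(res.p_permutation)
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.08)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_constructed_size_effect_recovered(self, rng):
        v = rng.standard_normal(18)
        v /= np.linalg.norm(v)
        aligned = synthetic_aligned(rng, n=50, k=6, size_effect=0.3, direction=v,
                                    noise=0.005)
        res = allometry(aligned, n_perm=999, seed=2)
        r = np.corrcoef(res.coefficients, v)[0, 1]
        assert abs(r) > 0.99
        assert res.significant

    def test_residuals_uncorrelated_with_size(self, rng):
        aligned = synthetic_aligned(rng, n=40, k=6, size_effect=0.2,
                                    direction=np.ones(18) / np.sqrt(18))
        res = allometry(aligned, n_perm=0)
        x = np.log(aligned.centroid_sizes)
        xc = x - x.mean()
        resid = res.residuals - res.residuals.mean(axis=0)
        assert np.abs(xc @ resid).max() < 1e-10

    def test_no_permutations_gives_parametric_only(self, rng):
        res = allometry(synthetic_aligned(rng), n_perm=0)
        assert res.p_permutation is None
        assert 0 <= res.p_parametric <= 1

    def test_constant_size_rejected(self, rng):
        aligned = synthetic_aligned(rng, sizes=np.full(30, 2.0))
        with pytest.raises(LandmarkError, match="no size variation"):
            allometry(aligned, n_perm=0)


class TestShapePCA:
    def test_collinear_data_has_one_nonzero_eigenvalue(self, rng):
        t = rng.standard_normal(20)
        direction = rng.standard_normal(6)
        data = 3.0 + np.outer(t, direction)
        res = shape_pca(data)
        assert res.eigenvalues[0] > 0
        assert np.all(res.eigenvalues[1:] < 1e-12 * res.eigenvalues[0])

    def test_eigenvalue_sum_matches_total_variance(self, rng):
        data = rng.standard_normal((15, 9))
        res = shape_pca(data)
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(np.cov(data, rowvar=False)), rel=1e-10)

    def test_eigenvalues_match_characteristic_polynomial_roots(self, rng):
        data = rng.standard_normal((5, 6))
        cov = np.cov(data, rowvar=False)
        roots = np.sort(np.real(np.roots(np.poly(cov))))[::-1]
        res = shape_pca(data)
        np.testing.assert_allclose(res.eigenvalues, np.clip(roots, 0, None), atol=1e-8)

    def test_scores_centered_with_diagonal_covariance(self, rng):
        res = shape_pca(rng.standard_normal((20, 5)))
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(np.cov(res.scores, rowvar=False),
                                   np.diag(res.eigenvalues), atol=1e-10)

    def test_nan_rejected(self, rng):
        data = rng.standard_normal((10, 4))
        data[3, 2] = np.nan
        with pytest.raises(LandmarkError, match="non-finite"):
            shape_pca(data)


class TestCVA:
    def test_three_groups_give_two_cvs_summing_to_100(self, rng):
        data = rng.standard_normal((30, 12))
        groups = np.repeat(["a", "b", "c"], 10)
        data[10:20] += 1.0
        res = cva(data, groups)
        assert len(res.eigenvalues) == 2
        assert res.percent_among.sum() == pytest.approx(100.0)

    def test_two_groups_one_cv(self, rng):
        data = rng.standard_normal((20, 6))
        res = cva(data, np.repeat(["a", "b"], 10))
        assert len(res.eigenvalues) == 1
        assert res.percent_among[0] == pytest.approx(100.0)

    def test_cv1_matches_fisher_discriminant_direction(self, rng):
        # closed-form oracle for 2 groups: w = Sigma_W^-1 (mu1 - mu2)
        n = 200
        data = rng.standard_normal((2 * n, 3)) @ np.diag([1.0, 2.0, 0.5])
        data[n:] += np.array([3.0, -2.0, 1.0])
        groups = np.repeat(["a", "b"], n)
        res = cva(data, groups)
        mu_a, mu_b = data[:n].mean(axis=0), data[n:].mean(axis=0)
        pooled = ((data[:n] - mu_a).T @ (data[:n] - mu_a)
                  + (data[n:] - mu_b).T @ (data[n:] - mu_b)) / (2 * n - 2)
        fisher = np.linalg.solve(pooled, mu_a - mu_b)
        cos = fisher @ res.canonical_vectors[:, 0] / (
            np.linalg.norm(fisher) * np.linalg.norm(res.canonical_vectors[:, 0]))
        assert abs(cos) > 0.999

    def test_invariant_to_affine_basis_change(self, rng):
        data = rng.standard_normal((60, 4))
        groups = np.repeat(["a", "b", "c"], 20)
        data[20:40, 0] += 2.0
        data[40:, 1] -= 2.0
        a = cva(data, groups)
        m = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        b = cva(data @ m, groups)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, rtol=1e-8)
        for j in range(2):
            r = np.corrcoef(a.scores[:, j], b.scores[:, j])[0, 1]
            assert abs(r) > 1 - 1e-8

    def test_rank_deficient_shape_data_handled(self, cranium_dataset):
        aligned = gpa(cranium_dataset)
        groups = cranium_dataset.metadata_column("locality")
        res = cva(aligned.flat(), groups)  # p=72 >> n per group
        assert len(res.eigenvalues) == 3   # 4 localities
        assert res.percent_among.sum() == pytest.approx(100.0)

    def test_singleton_group_rejected(self, rng):
        data = rng.standard_normal((11, 4))
        groups = np.array(["a"] * 10 + ["b"])
        with pytest.raises(LandmarkError, match="2 specimens"):
            cva(data, groups)


class TestProcrustesAnova:
    def test_goodall_df_convention_matches_study_tables(self):
        assert anova_dfs(k=24, n=56) == (65, 3510)
        assert anova_dfs(k=15, n=51) == (38, 1862)

    @pytest.mark.parametrize("k,n,dfs", [(24, 56, (65, 3510)), (15, 51, (38, 1862))])
    def test_full_anova_reports_those_dfs(self, rng, k, n, dfs):
        aligned = synthetic_aligned(rng, n=n, k=k)
        sexes = np.array(["M", "F"])[np.arange(n) % 2]
        res = procrustes_anova(aligned, factors=["sex"], factor_values={"sex": sexes},
                               n_perm=0)[0]
        assert (res.df_effect, res.df_error) == dfs

    def test_single_factor_ss_decomposition(self, rng):
        aligned = synthetic_aligned(rng, n=24, k=6)
        groups = np.repeat(["a", "b", "c"], 8)
        res = procrustes_anova(aligned, factors=["loc"], factor_values={"loc": groups},
                               n_perm=0)[0]
        y = aligned.flat()
        ss_total = float(((y - y.mean(axis=0)) ** 2).sum())
        assert res.ss_effect + res.ss_error == pytest.approx(ss_total, rel=1e-10)

    def test_type_one_error_calibrated_under_null(self, rng):
        # identical group distributions: permutation p should reject at ~alpha
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            aligned = synthetic_aligned(rng, n=20, k=5)
            groups = np.repeat(["a", "b"], 10)
            res = procrustes_anova(aligned, factors=["loc"],
                                   factor_values={"loc": groups},
                                   n_perm=99, seed=int(rng.integers(2 ** 31)))[0]
            rejections += res.p_permutation <= 0.05
        rate = rejections / n_rep
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < half_width + 1e-12

    def test_group_shift_detected(self, rng):
        aligned = synthetic_aligned(rng, n=30, k=6, noise=0.01)
        aligned.shape_coords[15:] += 0.02
        groups = np.repeat(["a", "b"], 15)
        res = procrustes_anova(aligned, factors=["loc"], factor_values={"loc": groups},
                               n_perm=199, seed=5)[0]
        assert res.p_permutation < 0.05

    def test_aliased_factor_rejected(self, rng):
        aligned = synthetic_aligned(rng, n=20, k=5)
        groups = np.repeat(["a", "b"], 10)
        with pytest.raises(LandmarkError, match="aliased"):
            procrustes_anova(aligned, factors=["loc", "same"],
                             factor_values={"loc": groups, "same": groups}, n_perm=0)


class TestGeoRegression:
    def test_linear_signal_recovered(self, rng):
        lat = rng.uniform(-32, -16, 40)
        lon = rng.uniform(22, 32, 40)
        pc1 = 2.0 * lat + 1e-9 * rng.standard_normal(40)
        res = geo_regression(pc1, latitude=lat, longitude=lon)
        assert res.table.loc["latitude", "slope"] == pytest.approx(2.0, rel=1e-6)
        assert res.table.loc["latitude", "r2"] == pytest.approx(1.0, abs=1e-9)

    def test_null_p_values_uniform(self, rng):
        pvals = []
        for _ in range(500):
            lat = rng.uniform(-32, -16, 20)
            lon = rng.uniform(22, 32, 20)
            pc1 = rng.standard_normal(20)
            pvals.append(geo_regression(pc1, latitude=lat, longitude=lon)
                         .table.loc["latitude", "p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(LandmarkError, match="n >= 3"):
            geo_regression(np.array([1.0, 2.0]), latitude=np.array([1.0, 2.0]),
                           longitude=np.array([3.0, 4.0]))

    def test_constant_coordinate_rejected(self, rng):
        with pytest.raises(LandmarkError, match="constant"):
            geo_regression(rng.standard_normal(10), latitude=np.full(10, -20.0),
                           longitude=rng.uniform(22, 32, 10))


class TestBalanceSexes:
    def test_balanced_counts_within_each_locality(self):
        from morphodrift import SimulationConfig, simulate_dataset
        from morphodrift.stats import balance_sexes
        import pandas as pd

        ds = simulate_dataset(SimulationConfig(k=8, g=3, n_per_group=[9, 7, 6], seed=2))
        out = balance_sexes(ds, seed=5)
        sex = out.metadata_column("sex")
        loc = out.metadata_column("locality")
        for lev in pd.unique(loc):
            m = ((loc == lev) & (sex == "M")).sum()
            f = ((loc == lev) & (sex == "F")).sum()
            assert m == f

    def test_seeded_subsampling_reproducible(self):
        from morphodrift import SimulationConfig, simulate_dataset
        from morphodrift.stats import balance_sexes

        ds = simulate_dataset(SimulationConfig(k=8, g=3, n_per_group=9, seed=2))
        a = balance_sexes(ds, seed=5)
        b = balance_sexes(ds, seed=5)
        assert a.specimen_ids == b.specimen_ids
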