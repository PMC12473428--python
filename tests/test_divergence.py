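import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from seedpheno.divergence import (
    DissimilarityMatrix,
    MLMSolution,
    cluster_criteria,
    fit_mlm,
    gower_matrix,
    intergroup_distances,
    range_normalize,
    select_group_count,
    ward_linkage,
)


def profiles_from(rows, columns=None, index=None):
    arr = np.asarray(rows, float)
    columns = columns or [f"t{i}" for i in range(arr.shape[1])]
    index = index or [f"G{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=index, columns=columns)


class TestGower:
    def test_identical_profiles_zero(self):
        p = profiles_from([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        d = gower_matrix(p)
        assert d.values[0, 1] == 0.0

    def test_opposite_extremes_give_one(self):
        p = profiles_from([[0.0, 5.0], [2.0, 9.0]])
        assert gower_matrix(p).values[0, 1] == pytest.approx(1.0)

    def test_hand_case(self):
        p = profiles_from([[0, 0], [1, 2], [2, 4]])
        d = gower_matrix(p).values
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 2] == pytest.approx(1.0)
        assert d[1, 2] == pytest.approx(0.5)

    @pytest.mark.parametrize("n,t,seed", [(4, 3, 0), (6, 5, 1), (8, 2, 2), (8, 7, 3)])
    def test_matches_exhaustive_pairwise_oracle(self, n, t, seed):
        rng = np.random.default_rng(seed)
        p = profiles_from(rng.normal(size=(n, t)) * rng.uniform(0.5, 20, size=t))
        d = gower_matrix(p).values
        rngs = p.max() - p.min()
        for i, j in itertools.combinations(range(n), 2):
            expected = np.mean(
                [abs(p.iloc[i, k] - p.iloc[j, k]) / rngs.iloc[k] for k in range(t)]
            )
            assert d[i, j] == pytest.approx(expected, abs=1e-12)
        assert d.min() >= 0 and d.max() <= 1

    def test_zero_range_trait_dropped_with_warning(self):
        p = profiles_from([[1.0, 7.0], [2.0, 7.0]])
        with pytest.warns(UserWarning, match="zero-range"):
            d = gower_matrix(p)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        p = profiles_from([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="non-finite"):
            gower_matrix(p)


class TestWard:
    def test_two_items_merge_at_their_dissimilarity(self):
        d = DissimilarityMatrix(np.array([[0.0, 0.37], [0.37, 0.0]]), ["a", "b"])
        tree = ward_linkage(d)
        assert tree.heights[0] == pytest.approx(0.37)

    def test_tight_pairs_merge_first(self):
        # brute-force check over all merge orders for n = 4: the two
        # tight pairs must merge before the final high join
        p = profiles_from([[0.0], [0.01], [1.0], [1.01]])
        tree = ward_linkage(gower_matrix(p))
        first_two = set(map(int, tree.linkage[:2, :2].ravel()))
        assert first_two == {0, 1, 2, 3}
        assert tree.heights[2] == max(tree.heights)

    @pytest.mark.parametrize("seed", range(4))
    def test_heights_nondecreasing_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        p = profiles_from(rng.normal(size=(9, 4)))
        tree = ward_linkage(gower_matrix(p))
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_cut_labels_all_leaves(self):
        p = profiles_from(np.random.default_rng(1).normal(size=(7, 3)))
        tree = ward_linkage(gower_matrix(p))
        cut = tree.cut(3)
        assert sorted(cut.unique()) == [1, 2, 3]
        assert len(cut) == 7


class TestMLM:
    def test_k1_is_saturated_normal_loglik(self):
        rng = np.random.default_rng(0)
        p = profiles_from(rng.normal(size=(10, 2)))
        sol = fit_mlm(p, pd.Series(1, index=p.index), 1)
        x = p.to_numpy()
        cov = np.cov(x.T, bias=True) + 1e-8 * np.trace(np.cov(x.T, bias=True)) / 2 * np.eye(2)
        expected = multivariate_normal.logpdf(x, x.mean(0), cov).sum()
        assert sol.log_likelihood == pytest.approx(expected, rel=1e-9)
        assert sol.n_iter == 0

    def test_two_far_clouds_perfectly_assigned(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, size=(8, 2))
        b = rng.normal(20.0, 1.0, size=(8, 2))
        p = profiles_from(np.vstack([a, b]))
        tree = ward_linkage(gower_matrix(p))
        sol2 = fit_mlm(p, tree.cut(2), 2)
        labels = sol2.assignments.to_numpy()
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        sol1 = fit_mlm(p, pd.Series(1, index=p.index), 1)
        assert sol2.log_likelihood > sol1.log_likelihood

    def test_k2_attains_exhaustive_partition_maximum(self):
        """CEM from the Ward cut reaches the global 2-partition optimum (n = 6)."""
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]], float)
        p = profiles_from(pts)
        sol = fit_mlm(p, ward_linkage(gower_matrix(p)).cut(2), 2)

        def partition_loglik(mask):
            groups = [pts[mask], pts[~mask]]
            means = [g.mean(0) for g in groups]
            resid = np.vstack([g - m for g, m in zip(groups, means)])
            cov = resid.T @ resid / len(pts)
            cov += 1e-8 * np.trace(cov) / 2 * np.eye(2)
            return sum(
                multivariate_normal.logpdf(g, m, cov).sum() for g, m in zip(groups, means)
            )

        best = max(
            partition_loglik(np.array(bits, bool))
            for bits in itertools.product([False, True], repeat=6)
            if 0 < sum(bits) < 6
        )
        assert sol.log_likelihood == pytest.approx(best, rel=1e-9)

    def test_k_exceeding_n_rejected(self):
        p = profiles_from([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="exceeds"):
            fit_mlm(p, pd.Series([1, 2], index=p.index), 3)


class TestCriteria:
    def test_identical_points_report_missing(self):
        p = profiles_from(np.ones((5, 3)))
        crit = cluster_criteria(p, ward_linkage(gower_matrix_allow(p)), 3)
        assert crit.table["pseudo_f"].isna().all()
        assert crit.table["log_likelihood"].isna().all()

    def test_kmax_bounds(self):
        p = profiles_from(np.random.default_rng(0).normal(size=(5, 2)))
        tree = ward_linkage(gower_matrix(p))
        with pytest.raises(ValueError, match="kmax"):
            cluster_criteria(p, tree, 5)

    @pytest.mark.parametrize("seed", range(3))
    def test_pseudo_f_peaks_at_true_k(self, seed):
        from seedpheno.simulate import default_config, simulate_phenotypes

        cfg = default_config(g=43, r=4, n_groups=4, delta=4.0, seed=seed)
        table, _ = simulate_phenotypes(cfg)
        p = table.genotype_means()
        crit = cluster_criteria(p, ward_linkage(gower_matrix(p)))
        t = crit.table.dropna(subset=["pseudo_f"])
        assert int(t.loc[t["pseudo_f"].idxmax(), "k"]) == 4


def gower_matrix_allow(p):
    """Gower on constant profiles: all-zero dissimilarity carrier."""
    n = len(p)
    return DissimilarityMatrix(np.zeros((n, n)), [str(i) for i in p.index])


class TestSelection:
    @staticmethod
    def criteria_from_loglik(lls):
        from seedpheno.divergence import ClusterCriteria

        table = pd.DataFrame({"k": range(1, len(lls) + 1), "log_likelihood": lls})
        table["pseudo_f"] = np.nan
        table["pseudo_t2"] = np.nan
        table["delta_log_likelihood"] = table["log_likelihood"].diff()
        return ClusterCriteria(table=table, solutions={})

    def test_single_dominant_jump(self):
        crit = self.criteria_from_loglik([-100.0, -50.0, -48.0, -47.0])
        assert select_group_count(crit) == 2

    def test_linear_profile_tie_breaks_small(self):
        crit = self.criteria_from_loglik([0.0, 10.0, 20.0, 30.0])
        assert select_group_count(crit) == 2

    def test_late_jump_detected(self):
        crit = self.criteria_from_loglik([0.0, 5.0, 11.0, 60.0, 64.0])
        assert select_group_count(crit) == 4

    def test_requires_candidates(self):
        crit = self.criteria_from_loglik([np.nan])
        with pytest.raises(ValueError):
            select_group_count(crit)


class TestIntergroup:
    @staticmethod
    def solution_1d(means, var, sizes):
        assign = pd.Series(
            np.repeat(np.arange(1, len(means) + 1), sizes),
            index=[f"g{i}" for i in range(sum(sizes))],
        )
        return MLMSolution(
            k=len(means),
            assignments=assign,
            means=pd.DataFrame({"t": means}, index=range(1, len(means) + 1)),
            covariance=pd.DataFrame([[var]], index=["t"], columns=["t"]),
            log_likelihood=0.0,
            n_iter=1,
        )

    def test_closed_form_1d(self):
        sol = self.solution_1d([0.0, 3.0], 1.0, [3, 3])
        d = intergroup_distances(sol)
        assert d.loc[1, 2] == pytest.approx(9.0)

    def test_identical_means_zero(self):
        sol = self.solution_1d([2.0, 2.0], 1.5, [2, 2])
        assert intergroup_distances(sol).loc[1, 2] == pytest.approx(0.0)

    def test_symmetry_zero_diagonal_random(self):
        rng = np.random.default_rng(3)
        p = profiles_from(rng.normal(size=(12, 3)))
        tree = ward_linkage(gower_matrix(p))
        sol = fit_mlm(range_normalize(p), tree.cut(3), 3)
        d = intergroup_distances(sol)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d.to_numpy() >= 0).all()

    def test_k1_rejected(self):
        sol = self.solution_1d([1.0], 1.0, [4])
        with pytest.raises(ValueError):
            intergroup_distances(sol)
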