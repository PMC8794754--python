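import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from dcornet.coexpression import (
    adjacency,
    cluster_genes,
    correlation_matrix,
    correlation_pvalue,
    cut_modules,
    gene_module_stats,
    merge_close_modules,
    mm_gs_correlation,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit_index,
    select_significant_modules,
    tom_similarity,
)
from dcornet.io_preprocess import ExpressionDataset, ExpressionError
from dcornet.synthetic_data import SimulationConfig, generate_two_condition_expression


def _dataset(values, conditions=None):
    values = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(len(values))],
    )
    values.columns = [f"s{j}" for j in range(values.shape[1])]
    if conditions is None:
        half = values.shape[1] // 2
        conditions = ["A"] * half + ["B"] * (values.shape[1] - half)
    return ExpressionDataset(values, pd.Series(conditions, index=values.columns))


class TestCorrelationMatrix:
    def test_unit_diagonal(self, tiny_dataset):
        cm = correlation_matrix(tiny_dataset)
        assert np.allclose(np.diag(cm), 1.0)

    def test_anticorrelated_pair(self):
        ds = _dataset([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        cm = correlation_matrix(ds)
        assert cm.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        # oracle: covariance / (sd_x * sd_y), computed longhand
        rng = np.random.default_rng(5)
        x = rng.normal(size=(5, 12))
        cm = correlation_matrix(_dataset(x)).to_numpy()
        for i in range(5):
            for j in range(5):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert cm[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_named(self):
        ds = _dataset([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ExpressionError, match="g0"):
            correlation_matrix(ds)

    def test_bicor_close_to_pearson_on_clean_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 200))
        x[1] = x[0] * 0.8 + 0.3 * rng.normal(size=200)
        p = correlation_matrix(_dataset(x), "pearson").to_numpy()
        b = correlation_matrix(_dataset(x), "bicor").to_numpy()
        assert np.abs(p - b).max() < 0.1
        assert np.allclose(b, b.T) and np.allclose(np.diag(b), 1.0)

    def test_bicor_downweights_outlier(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 60))
        x[1] = x[0] + 0.1 * rng.normal(size=60)
        x_out = x.copy()
        x_out[1, 0] = 50.0  # one gross outlier
        p = correlation_matrix(_dataset(x_out), "pearson").iloc[0, 1]
        b = correlation_matrix(_dataset(x_out), "bicor").iloc[0, 1]
        assert b > p  # bicor recovers more of the true correlation (~1)

    def test_bicor_mad_zero_falls_back(self):
        # median-heavy gene: MAD = 0, bicor still defined via Pearson fallback
        x = np.array(
            [
                [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 1.0, 9.0],
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            ]
        )
        b = correlation_matrix(_dataset(x), "bicor")
        assert np.isfinite(b.to_numpy()).all()


class TestScaleFreeFit:
    @staticmethod
    def _power_law_sample(gamma, n=3000, lo=1.0, hi=100.0, seed=0):
        # inverse-CDF draw from p(k) ~ k^-gamma on [lo, hi]
        u = (np.arange(n) + 0.5) / n
        if gamma == 1.0:
            return lo * (hi / lo) ** u
        a = 1.0 - gamma
        return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)

    def test_decreasing_power_law_positive(self):
        r2 = scale_free_fit_index(self._power_law_sample(2.0))
        assert r2 > 0.99

    def test_increasing_distribution_negative(self):
        # p(k) ~ k^{+2}: exactly log-log linear with positive slope
        r2 = scale_free_fit_index(self._power_law_sample(-2.0))
        assert r2 < -0.99

    def test_matches_independent_least_squares(self):
        # oracle: same quantile binning, regression done longhand via lstsq
        k = np.random.default_rng(3).uniform(0.1, 50, size=1000)
        edges = np.unique(np.quantile(k, np.linspace(0, 1, 11)))
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, len(edges) - 2)
        xs, ys = [], []
        for b in range(len(edges) - 1):
            sel = idx == b
            width = edges[b + 1] - edges[b]
            if sel.any() and width > 0 and k[sel].mean() > 0:
                xs.append(np.log10(k[sel].mean()))
                ys.append(np.log10(sel.sum() / len(k) / width))
        X = np.column_stack([np.ones(len(xs)), xs])
        beta, *_ = np.linalg.lstsq(X, np.array(ys), rcond=None)
        resid = np.array(ys) - X @ beta
        ss_tot = ((np.array(ys) - np.mean(ys)) ** 2).sum()
        r2 = (1 - resid @ resid / ss_tot) * -np.sign(beta[1])
        assert scale_free_fit_index(k) == pytest.approx(r2, abs=1e-10)

    def test_degenerate_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert scale_free_fit_index(np.full(50, 3.0)) == 0.0

    def test_negative_connectivity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            scale_free_fit_index([-1.0, 2.0])


class TestAdjacency:
    @pytest.fixture
    def cm(self):
        r = np.array([[1.0, 0.5, -0.5], [0.5, 1.0, 0.25], [-0.5, 0.25, 1.0]])
        return pd.DataFrame(r, index=list("abc"), columns=list("abc"))

    def test_power_arithmetic(self, cm):
        a = adjacency(cm, 3)
        assert a.loc["a", "b"] == pytest.approx(0.125)

    def test_unsigned_uses_absolute_value(self, cm):
        a = adjacency(cm, 3)
        assert a.loc["a", "c"] == pytest.approx(0.125)

    def test_power_one_is_abs_identity(self, cm):
        a = adjacency(cm, 1)
        assert np.allclose(a.to_numpy(), np.abs(cm.to_numpy()) - np.eye(3))

    def test_signed_formula(self, cm):
        a = adjacency(cm, 2, signed=True)
        assert a.loc["a", "c"] == pytest.approx(((1 - 0.5) / 2) ** 2)

    def test_monotone_in_beta(self):
        rng = np.random.default_rng(7)
        r = np.clip(rng.uniform(-1, 1, size=(15, 15)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        cm = pd.DataFrame(r)
        prev = adjacency(cm, 1).to_numpy()
        for beta in range(2, 8):
            cur = adjacency(cm, beta).to_numpy()
            assert (cur <= prev + 1e-15).all()
            prev = cur

    def test_beta_below_one_rejected(self, cm):
        with pytest.raises(ValueError, match="beta"):
            adjacency(cm, 0.5)


class TestPickSoftThreshold:
    def test_generator_defaults_reach_target(self, default_dataset):
        cm = correlation_matrix(default_dataset)
        sft = pick_soft_threshold(cm)
        assert sft.reached_target
        row = sft.table[sft.table["power"] == sft.power].iloc[0]
        assert row["r_squared"] >= 0.9
        # lower powers fit worse than the chosen one
        below = sft.table[sft.table["power"] < sft.power]
        assert (below["r_squared"] < 0.9).all()

    def test_chosen_is_smallest_reaching_target(self, default_dataset):
        cm = correlation_matrix(default_dataset)
        sft = pick_soft_threshold(cm)
        reaching = sft.table[sft.table["r_squared"] >= sft.target_r2]["power"]
        assert sft.power == int(reaching.min())

    def test_mean_connectivity_strictly_decreasing(self, default_dataset):
        cm = correlation_matrix(default_dataset)
        sft = pick_soft_threshold(cm)
        k = sft.table["mean_connectivity"].to_numpy()
        assert (np.diff(k) < 0).all()

    def test_fallback_argmax_with_warning(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(30, 20))  # pure noise rarely reaches 0.9 quickly
        cm = correlation_matrix(_dataset(x))
        with pytest.warns(UserWarning, match="argmax"):
            sft = pick_soft_threshold(cm, powers=(1, 2), target_r2=0.999)
        assert not sft.reached_target
        assert sft.power in (1, 2)


class TestTOM:
    def test_three_node_hand_computation(self):
        a = pd.DataFrame(0.5 * (np.ones((3, 3)) - np.eye(3)))
        tom = tom_similarity(a)
        # (l_12 + a_12)/(min(k)+1-a_12) = (0.25 + 0.5)/(1 + 1 - 0.5)
        assert tom.iloc[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(np.diag(tom), 1.0)

    def test_isolated_pair_closed_form(self):
        for x in (0.2, 0.6, 0.9):
            a = np.zeros((4, 4))
            a[0, 1] = a[1, 0] = x
            tom = tom_similarity(pd.DataFrame(a))
            assert tom.iloc[0, 1] == pytest.approx(x, abs=1e-12)
            assert tom.iloc[2, 3] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        # O(n^3) triple loop straight from the definition
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 21))
            a = rng.uniform(0, 0.95, size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = tom_similarity(pd.DataFrame(a)).to_numpy()
            k = a.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        expected = 1.0
                    else:
                        ell = sum(a[i, u] * a[u, j] for u in range(n))
                        expected = (ell + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                    assert abs(tom[i, j] - expected) < 1e-12

    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(pd.DataFrame(a))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            tom_similarity(pd.DataFrame(np.eye(3)))


class TestClusterGenes:
    @staticmethod
    def _naive_average_linkage(d):
        """O(n^3) text-book agglomeration, returns sorted merge heights."""
        clusters = {i: [i] for i in range(len(d))}
        heights = []
        while len(clusters) > 1:
            best = None
            for ci in sorted(clusters):
                for cj in sorted(clusters):
                    if ci >= cj:
                        continue
                    dist = np.mean([d[a, b] for a in clusters[ci] for b in clusters[cj]])
                    if best is None or dist < best[0]:
                        best = (dist, ci, cj)
            dist, ci, cj = best
            heights.append(dist)
            clusters[ci] = clusters[ci] + clusters.pop(cj)
        return sorted(heights)

    def test_matches_naive_oracle_on_six_leaves(self):
        rng = np.random.default_rng(2)
        tom = rng.uniform(0, 1, size=(6, 6))
        tom = (tom + tom.T) / 2
        np.fill_diagonal(tom, 1.0)
        dend = cluster_genes(pd.DataFrame(tom))
        expected = self._naive_average_linkage(1.0 - tom)
        assert np.allclose(sorted(dend.linkage[:, 2]), expected, atol=1e-10)

    def test_two_perfect_blocks_split_at_top(self):
        tom = np.zeros((6, 6))
        tom[:3, :3] = 0.9
        tom[3:, 3:] = 0.9
        np.fill_diagonal(tom, 1.0)
        dend = cluster_genes(pd.DataFrame(tom, index=list("abcdef"), columns=list("abcdef")))
        top = fcluster(dend.linkage, t=2, criterion="maxclust")
        assert len(set(top[:3])) == 1 and len(set(top[3:])) == 1
        assert top[0] != top[3]

    def test_single_gene_tree(self):
        tom = pd.DataFrame([[1.0]], index=["g"], columns=["g"])
        dend = cluster_genes(tom)
        assert dend.n_leaves == 1 and len(dend.linkage) == 0


class TestCutModules:
    def test_planted_modules_recovered(self, default_sim):
        ds, truth = default_sim
        cm = correlation_matrix(ds)
        sft = pick_soft_threshold(cm)
        tom = tom_similarity(adjacency(cm, sft.power))
        modules = cut_modules(cluster_genes(tom))
        ari = adjusted_rand_score(truth.module_of_gene.to_numpy(), modules.to_numpy())
        assert len(set(modules) - {0}) == 2
        assert ari >= 0.9

    def test_min_size_larger_than_n_gives_all_grey(self, default_dataset):
        cm = correlation_matrix(default_dataset.subset_genes(default_dataset.gene_ids[:40]))
        tom = tom_similarity(adjacency(cm, 6))
        modules = cut_modules(cluster_genes(tom), min_module_size=1000)
        assert (modules == 0).all()

    def test_pure_noise_mostly_grey(self):
        rng = np.random.default_rng(0)
        ds = _dataset(rng.normal(size=(100, 80)))
        cm = correlation_matrix(ds)
        tom = tom_similarity(adjacency(cm, 6))
        modules = cut_modules(cluster_genes(tom), min_module_size=30)
        assert (modules == 0).mean() >= 0.9

    def test_bad_deep_split_rejected(self, default_dataset):
        cm = correlation_matrix(default_dataset.subset_genes(default_dataset.gene_ids[:10]))
        dend = cluster_genes(tom_similarity(adjacency(cm, 3)))
        with pytest.raises(ValueError, match="deep_split"):
            cut_modules(dend, deep_split=7)


class TestModuleEigengenes:
    def test_identical_genes_give_shared_profile(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        ds = _dataset(np.tile(v, (4, 1)))
        modules = pd.Series([1, 1, 1, 1], index=ds.gene_ids)
        mes = module_eigengenes(ds, modules)
        me = mes.eigengenes["ME1"].to_numpy()
        vz = (v - v.mean()) / v.std(ddof=1)
        assert np.corrcoef(me, v)[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(me, vz, atol=1e-10)
        assert mes.variance_explained[1] == pytest.approx(1.0)

    def test_mirror_pair_variance_explained(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        ds = _dataset(np.vstack([v, -v]))
        modules = pd.Series([1, 1], index=ds.gene_ids)
        mes = module_eigengenes(ds, modules)
        assert mes.variance_explained[1] == pytest.approx(1.0)

    def test_factor_module_tracks_latent_factor(self, default_sim):
        ds, truth = default_sim
        mes = module_eigengenes(ds, truth.module_of_gene)
        for label, factor in ((1, "M1"), (2, "M2")):
            r = np.corrcoef(
                mes.eigengenes[f"ME{label}"], truth.module_factors[factor]
            )[0, 1]
            assert abs(r) >= 0.95

    def test_gene_permutation_invariance(self, default_sim):
        ds, truth = default_sim
        mes1 = module_eigengenes(ds, truth.module_of_gene)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.gene_ids)
        ds_perm = ds.subset_genes(list(perm))
        mes2 = module_eigengenes(ds_perm, truth.module_of_gene.loc[perm])
        assert np.allclose(
            mes1.eigengenes.to_numpy(), mes2.eigengenes.to_numpy(), atol=1e-10
        )

    def test_singleton_module_rejected(self, tiny_dataset):
        modules = pd.Series([1, 2, 2], index=tiny_dataset.gene_ids)
        with pytest.raises(ExpressionError, match="fewer than 2"):
            module_eigengenes(tiny_dataset, modules)


class TestMergeCloseModules:
    def test_split_module_remerged(self, default_sim):
        ds, truth = default_sim
        # artificially split planted module 1 into two labels
        modules = truth.module_of_gene.copy()
        members = modules.index[modules == 1]
        modules.loc[members[:25]] = 3
        merged, mes = merge_close_modules(ds, modules)
        labels_of_members = set(merged.loc[members])
        assert len(labels_of_members) == 1
        assert len(mes.module_labels) == 2

    def test_distinct_modules_untouched(self, default_sim):
        ds, truth = default_sim
        merged, _ = merge_close_modules(ds, truth.module_of_gene)
        assert merged.equals(truth.module_of_gene)

    def test_single_module_identity(self, default_sim):
        ds, truth = default_sim
        modules = truth.module_of_gene.where(truth.module_of_gene == 1, 0)
        merged, mes = merge_close_modules(ds, modules)
        assert merged.equals(modules)
        assert mes.module_labels == [1]


class TestTraitStatistics:
    def test_eigengene_equal_to_trait(self, default_dataset):
        trait = default_dataset.trait
        eg = pd.DataFrame({"ME1": (trait - trait.mean()) / trait.std(ddof=1)})
        from dcornet.coexpression import ModuleEigengenes

        mes = ModuleEigengenes(eigengenes=eg, variance_explained=pd.Series({1: 1.0}))
        out = module_trait_correlation(mes, trait)
        assert out.loc[1, "r"] == pytest.approx(1.0)
        assert out.loc[1, "p"] == 0.0

    def test_hand_sized_p_value_oracle(self):
        # n = 6 fixture: p from the exact t transform, computed longhand
        x = np.array([0.2, 1.1, -0.4, 2.0, 0.7, -1.5])
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        r = float(np.corrcoef(x, y)[0, 1])
        from scipy.stats import t as t_dist

        t_stat = r * np.sqrt((6 - 2) / (1 - r**2))
        expected_p = 2 * t_dist.sf(abs(t_stat), df=4)
        assert correlation_pvalue(r, 6) == pytest.approx(expected_p, abs=1e-10)

    def test_constant_trait_rejected(self, default_sim):
        ds, truth = default_sim
        mes = module_eigengenes(ds, truth.module_of_gene)
        trait = pd.Series(1, index=ds.sample_ids)
        with pytest.raises(ExpressionError, match="constant"):
            module_trait_correlation(mes, trait)

    def test_gene_module_stats_extremes(self, default_sim):
        ds, truth = default_sim
        mes = module_eigengenes(ds, truth.module_of_gene)
        # gene equal to its eigengene -> MM = 1; gene equal to trait -> |GS| = 1
        values = ds.values.copy()
        values.loc["G0000"] = mes.eigengenes["ME1"].to_numpy()
        values.loc["G0001"] = ds.trait.to_numpy(dtype=float)
        ds2 = ExpressionDataset(values, ds.condition)
        stats = gene_module_stats(ds2, truth.module_of_gene, mes, ds2.trait)
        assert stats.loc["G0000", "MM"] == pytest.approx(1.0, abs=1e-10)
        assert abs(stats.loc["G0001", "GS"]) == pytest.approx(1.0, abs=1e-10)

    def test_mm_gs_correlation_high_for_trait_module(self, default_sim):
        ds, truth = default_sim
        mes = module_eigengenes(ds, truth.module_of_gene)
        stats = gene_module_stats(ds, truth.module_of_gene, mes, ds.trait)
        r, p = mm_gs_correlation(stats, 1)
        assert r > 0.5
        assert p < 0.01


class TestSelectSignificantModules:
    @staticmethod
    def _frame(rs):
        return pd.DataFrame({"r": rs, "p": [1e-10] * len(rs)}, index=range(1, len(rs) + 1))

    def test_strong_module_selected(self):
        trait = self._frame([0.77])
        assert select_significant_modules(trait, pd.Series({1: 0.87})) == [1]

    def test_weak_mmgs_excluded(self):
        trait = self._frame([0.52])
        assert select_significant_modules(trait, pd.Series({1: 0.38})) == []

    def test_boundary_is_strict(self):
        trait = self._frame([0.5])
        assert select_significant_modules(trait, pd.Series({1: 0.9})) == []
        trait2 = self._frame([0.9])
        assert select_significant_modules(trait2, pd.Series({1: 0.5})) == []

    def test_negative_trait_correlation_counts(self):
        trait = self._frame([-0.62])
        assert select_significant_modules(trait, pd.Series({1: 0.83})) == [1]
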