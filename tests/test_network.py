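"""Adjacency, topological overlap, module detection, eigengenes, traits."""

import numpy as np
import pandas as pd
import pytest

import oncohub as oh
from oncohub.network import (AdjacencyParams, eigengene_variance_explained,
                             scale_free_fit, tom_dissimilarity)


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference implementation of the topological overlap matrix."""
    n = a.shape[0]
    out = np.eye(n)
    k = np.array([a[i].sum() - a[i, i] for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_adjacency(rng, n):
    r = rng.uniform(0, 1, size=(n, n))
    a = (r + r.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_beta_one_unsigned_equals_abs_correlation(self, rng):
        x = rng.normal(size=(6, 40))
        adj = oh.adjacency(x, AdjacencyParams(beta=1)).to_numpy()
        expected = np.abs(np.corrcoef(x))
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_anticorrelated_pair_unsigned_beta6_is_one(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        adj = oh.adjacency(x, AdjacencyParams(beta=6)).to_numpy()
        assert adj[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_five_gene_brute_force(self, rng):
        x = rng.normal(size=(5, 30))
        beta = 6
        adj = oh.adjacency(x, AdjacencyParams(beta=beta)).to_numpy()
        corr = np.corrcoef(x)
        for i in range(5):
            for j in range(5):
                expected = 1.0 if i == j else abs(corr[i, j]) ** beta
                assert adj[i, j] == pytest.approx(expected, abs=1e-12)

    def test_signed_mode(self, rng):
        x = rng.normal(size=(4, 25))
        adj = oh.adjacency(x, AdjacencyParams(beta=2, mode="signed")).to_numpy()
        corr = np.corrcoef(x)
        expected = ((1 + corr) / 2) ** 2
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_increasing_beta_weakly_decreases_offdiagonal(self, rng):
        x = rng.normal(size=(10, 30))
        prev = None
        for beta in (1, 2, 4, 6, 8, 12):
            adj = oh.adjacency(x, AdjacencyParams(beta=beta)).to_numpy()
            off = adj[~np.eye(10, dtype=bool)]
            if prev is not None:
                assert (off <= prev + 1e-12).all()
            prev = off

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            AdjacencyParams(beta=0.5)


class TestTopologicalOverlap:
    def test_two_gene_network_formula(self):
        # no shared neighbours: l = 0, min k = a, so omega = a/(a + 1 - a) = a
        a = 0.37
        adj = np.array([[1.0, a], [a, 1.0]])
        tom = oh.topological_overlap(adj).to_numpy()
        assert tom[0, 1] == pytest.approx(a, abs=1e-12)
        assert tom[0, 0] == 1.0

    def test_complete_graph_has_full_overlap(self):
        adj = np.ones((5, 5))
        tom = oh.topological_overlap(adj).to_numpy()
        np.testing.assert_allclose(tom, 1.0)

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_matches_brute_force(self, rng, n):
        adj = random_adjacency(rng, n)
        tom = oh.topological_overlap(adj).to_numpy()
        np.testing.assert_allclose(tom, brute_force_tom(adj), atol=1e-12)

    def test_entries_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            adj = random_adjacency(rng, 12)
            tom = oh.topological_overlap(adj).to_numpy()
            assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            oh.topological_overlap(bad)


def block_dissimilarity(sizes, within=0.0, between=1.0):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


class TestClusterModules:
    def test_two_separated_blocks(self):
        part = oh.cluster_modules(block_dissimilarity([40, 40]), min_size=30)
        assert part.n_modules == 2
        assert sorted(part.sizes()) == [40, 40]
        assert (part.labels != 0).all()

    def test_small_branch_left_unassigned(self):
        part = oh.cluster_modules(block_dissimilarity([40, 10]), min_size=30)
        assert part.n_modules == 1
        assert (part.labels == 0).sum() == 10

    def test_min_size_larger_than_gene_count(self):
        part = oh.cluster_modules(block_dissimilarity([10]), min_size=30)
        assert part.n_modules == 0
        assert (part.labels == 0).all()

    def test_gene_order_permutation_invariance(self, rng):
        from sklearn.metrics import adjusted_rand_score
        d = block_dissimilarity([35, 45, 40], within=0.1)
        d += rng.uniform(0, 0.05, size=d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        genes = [f"g{i}" for i in range(d.shape[0])]
        df = pd.DataFrame(d, index=genes, columns=genes)
        part = oh.cluster_modules(df, min_size=30)
        perm = rng.permutation(genes)
        part_p = oh.cluster_modules(df.loc[perm, perm], min_size=30)
        aligned = part_p.labels.loc[part.labels.index]
        assert adjusted_rand_score(part.labels, aligned) == pytest.approx(1.0)

    def test_quantile_cut_mode(self):
        part = oh.cluster_modules(block_dissimilarity([40, 40]), min_size=30,
                                  cut=0.99)
        assert part.n_modules in (1, 2)  # static quantile cut stays available


class TestEigengenes:
    def test_identical_gene_module_recovers_common_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = np.tile(profile, (6, 1))
        labels = pd.Series(1, index=range(6))
        me = oh.module_eigengenes(pd.DataFrame(x), oh.ModulePartition(labels))
        standardized = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(me["ME1"], standardized, atol=1e-9)

    def test_sign_flip_invariant_after_orientation(self, rng):
        x = rng.normal(size=(8, 20))
        labels = pd.Series(1, index=range(8))
        me_a = oh.module_eigengenes(pd.DataFrame(x), oh.ModulePartition(labels))
        me_b = oh.module_eigengenes(pd.DataFrame(-x), oh.ModulePartition(labels))
        corr = np.corrcoef(me_a["ME1"], me_b["ME1"])[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-9)

    def test_unit_variance(self, rng):
        x = rng.normal(size=(10, 30))
        labels = pd.Series([1] * 5 + [2] * 5, index=range(10))
        me = oh.module_eigengenes(pd.DataFrame(x), oh.ModulePartition(labels))
        np.testing.assert_allclose(me.std(ddof=1), 1.0, atol=1e-9)

    def test_noiseless_module_fully_explained_by_pc1(self):
        cfg = oh.SimConfig(seed=3, noise_sd=0.0, batch_sd=0.0, n_genes=200,
                           n_modules=2, module_sizes=(40, 40),
                           trait_effect=(0.5, 0.0),
                           samples_per_phenotype={p: 10 for p in
                                                  oh.SimConfig().phenotypes})
        comp, _, truth = oh.generate_compendium(cfg)
        labels = pd.Series({g: truth.module_of_gene[g] for g in comp.gene_ids})
        part = oh.ModulePartition(labels)
        ve = eigengene_variance_explained(comp, part)
        np.testing.assert_allclose(ve, 1.0, atol=1e-9)


class TestMergeModules:
    def make_latent_data(self, rng):
        """Modules 1 and 2 share a latent factor; module 3 is independent."""
        n = 60
        f_shared = rng.normal(size=n)
        f_other = rng.normal(size=n)
        rows, labels = [], []
        for lab, factor in ((1, f_shared), (2, f_shared), (3, f_other)):
            for _ in range(10):
                rows.append(factor + rng.normal(0, 0.1, size=n))
                labels.append(lab)
        return pd.DataFrame(rows), pd.Series(labels)

    def test_same_latent_modules_merge(self, rng):
        x, labels = self.make_latent_data(rng)
        merged = oh.merge_modules(x, oh.ModulePartition(labels, min_size=5), 0.25)
        assert merged.n_modules == 2
        # the two shared-factor modules carry one label, the third another
        l0 = merged.labels
        shared = set(l0[(labels == 1).to_numpy()]) | set(l0[(labels == 2).to_numpy()])
        assert len(shared) == 1
        assert set(l0[(labels == 3).to_numpy()]).isdisjoint(shared)

    def test_orthogonal_eigengenes_never_merge(self, rng):
        n = 40
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        f2 = f2 - f2 @ f1 / (f1 @ f1) * f1  # orthogonalize
        rows = [f1 + rng.normal(0, 0.05, n) for _ in range(8)]
        rows += [f2 + rng.normal(0, 0.05, n) for _ in range(8)]
        labels = pd.Series([1] * 8 + [2] * 8)
        merged = oh.merge_modules(pd.DataFrame(rows),
                                  oh.ModulePartition(labels, min_size=5), 0.25)
        assert merged.n_modules == 2

    def test_identical_eigengene_modules_merge(self, rng):
        f = rng.normal(size=30)
        rows = [f for _ in range(6)] + [2 * f for _ in range(6)]
        labels = pd.Series([1] * 6 + [2] * 6)
        merged = oh.merge_modules(pd.DataFrame(rows),
                                  oh.ModulePartition(labels, min_size=3), 0.25)
        assert merged.n_modules == 1


class TestSoftThreshold:
    def test_singleton_grid_returns_that_beta(self, rng):
        x = rng.normal(size=(30, 20))
        params = oh.pick_soft_threshold(x, grid=[6])
        assert params.beta == 6

    def test_modular_data_reaches_fit_target(self, default_study):
        comp, _ = oh.quantile_normalize(default_study.compendium), None
        params = oh.pick_soft_threshold(comp)
        table = params.fit_table
        assert table.loc[table["beta"] == params.beta, "fit"].iloc[0] >= 0.8

    def test_pure_noise_falls_back_to_best_fit(self, rng):
        x = rng.normal(size=(100, 12))
        params = oh.pick_soft_threshold(x, grid=[1, 2], r2_target=0.999)
        assert params.beta in (1.0, 2.0)
        # the maximizing rule applied: chosen beta has the max defined fit
        valid = params.fit_table.dropna(subset=["fit"])
        assert params.beta == valid.loc[valid["fit"].idxmax(), "beta"]

    def test_degenerate_connectivity_is_nan(self):
        assert np.isnan(scale_free_fit(np.full(50, 3.0)))

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            oh.pick_soft_threshold(rng.normal(size=(10, 5)))


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigengene_gives_r_one(self, rng):
        me = pd.DataFrame({"ME1": rng.normal(size=50)},
                          index=[f"s{i}" for i in range(50)])
        traits = pd.DataFrame({"t": me["ME1"]}, index=me.index)
        out = oh.module_trait_correlation(me, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(0.0, abs=1e-30)

    def test_p_value_matches_t_distribution(self, rng):
        from scipy import stats
        me = pd.DataFrame({"ME1": rng.normal(size=40)},
                          index=[f"s{i}" for i in range(40)])
        traits = pd.DataFrame({"t": rng.normal(size=40)}, index=me.index)
        out = oh.module_trait_correlation(me, traits)
        r, n = out["r"].iloc[0], 40
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.t.sf(abs(t), n - 2))

    def test_zero_variance_trait_reported_missing(self, rng):
        me = pd.DataFrame({"ME1": rng.normal(size=10)},
                          index=[f"s{i}" for i in range(10)])
        traits = pd.DataFrame({"flat": np.ones(10)}, index=me.index)
        out = oh.module_trait_correlation(me, traits)
        assert np.isnan(out["r"].iloc[0]) and np.isnan(out["p"].iloc[0])

    def test_planted_disease_module_positive_and_significant(self, pipeline_result):
        res = pipeline_result
        mt = res.module_trait
        sel = mt[(mt["trait"] == "phenotype_rank") & (mt["r"] > 0)
                 & (mt["p"] < 0.01)]
        # the three planted disease modules show up, background modules do not
        assert len(sel) == len(res.study.truth.disease_modules)
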