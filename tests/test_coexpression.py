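import numpy as np
import pandas as pd
import pytest

from gfsbrain import coexpression as coex
from gfsbrain import synthetic as syn


def brute_force_tom(a):
    n = len(a)
    k = a.sum(axis=1)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


class TestTopologicalOverlap:
    def test_complete_graph_closed_form(self):
        a = np.ones((4, 4)) - np.eye(4)
        tom = coex.topological_overlap(a)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(tom[off], 1.0)

    def test_empty_graph(self):
        tom = coex.topological_overlap(np.zeros((5, 5)))
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 1, size=(6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            assert np.allclose(coex.topological_overlap(a), brute_force_tom(a), atol=1e-12)

    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            coex.topological_overlap(a)

    def test_range(self, rng):
        a = rng.uniform(0, 1, size=(10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = coex.topological_overlap(a)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12
        assert np.allclose(tom, tom.T)


class TestAdjacency:
    def test_beta_monotonicity(self, rng):
        values = pd.DataFrame(rng.normal(size=(20, 15)),
                              index=[f"g{i}" for i in range(20)])
        a1 = coex.adjacency_matrix(values, beta=2).to_numpy()
        a2 = coex.adjacency_matrix(values, beta=5).to_numpy()
        assert (a2 <= a1 + 1e-12).all()

    def test_noise_has_low_scale_free_fit_at_beta_one(self, rng):
        values = pd.DataFrame(rng.normal(size=(200, 30)),
                              index=[f"g{i}" for i in range(200)])
        a = coex.adjacency_matrix(values, beta=1)
        assert coex.scale_free_fit(a) < 0.8

    def test_select_requires_enough_genes_and_samples(self, rng):
        small = pd.DataFrame(rng.normal(size=(10, 20)))
        with pytest.raises(ValueError, match="30 genes"):
            coex.select_soft_threshold(small)
        narrow = pd.DataFrame(rng.normal(size=(50, 5)))
        with pytest.raises(ValueError, match="8 samples"):
            coex.select_soft_threshold(narrow)


class TestModuleDetection:
    def _two_block_values(self, rng, n_per=60, n_samples=40, rho=0.9):
        curves = rng.normal(size=(2, n_samples))
        rows, labels = [], []
        a = np.sqrt(rho / (1 - rho))
        for m in range(2):
            for _ in range(n_per):
                rows.append(a * curves[m] + rng.normal(size=n_samples))
                labels.append(m + 1)
        idx = [f"g{i:03d}" for i in range(2 * n_per)]
        return pd.DataFrame(rows, index=idx), np.array(labels)

    def test_two_planted_blocks_recovered(self, rng):
        values, labels = self._two_block_values(rng)
        ms = coex.run_wgcna(values, beta=6, min_module_size=30)
        from sklearn.metrics import adjusted_rand_score

        assert len(set(ms.assignment) - {0}) == 2
        assert adjusted_rand_score(labels, ms.assignment.values) >= 0.9

    def test_duplicate_genes_always_co_assigned(self, rng):
        values, _ = self._two_block_values(rng, n_per=40)
        values.loc["dup_a"] = values.iloc[0]
        values.loc["dup_b"] = values.iloc[0]
        ms = coex.run_wgcna(values, beta=6, min_module_size=10)
        assert ms.assignment["dup_a"] == ms.assignment["dup_b"]

    def test_permutation_equivariance(self, rng):
        values, _ = self._two_block_values(rng, n_per=35)
        ms1 = coex.run_wgcna(values, beta=6, min_module_size=20)
        perm = rng.permutation(len(values))
        shuffled = values.iloc[perm]
        ms2 = coex.run_wgcna(shuffled, beta=6, min_module_size=20)
        joined = pd.concat([ms1.assignment.rename("a"), ms2.assignment.rename("b")], axis=1)
        # same partition (labels may swap): contingency rows are pure
        table = joined.groupby(["a", "b"]).size().unstack(fill_value=0)
        assert ((table > 0).sum(axis=1) == 1).all()

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        values = pd.DataFrame(rng.normal(size=(10, 12)),
                              index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning):
            out = coex.detect_modules(np.ones((10, 10)) - np.eye(10),
                                      list(values.index), min_module_size=30)
        assert (out == 0).all()


class TestEigengene:
    def test_identical_profiles_correlate_one(self, rng):
        profile = rng.normal(size=25)
        values = pd.DataFrame([profile + 1e-9 * rng.normal(size=25) for _ in range(6)],
                              index=[f"g{i}" for i in range(6)])
        assignment = pd.Series(1, index=values.index)
        eg = coex.module_eigengene(values, assignment)[1]
        assert abs(np.linalg.norm(eg) - 1.0) < 1e-9
        for _, row in values.iterrows():
            assert abs(np.corrcoef(eg, row)[0, 1]) > 0.999

    def test_sign_orientation_non_negative_mean_correlation(self, rng):
        values = pd.DataFrame(rng.normal(size=(8, 30)),
                              index=[f"g{i}" for i in range(8)])
        assignment = pd.Series(1, index=values.index)
        eg = coex.module_eigengene(values, assignment)[1]
        z = values.sub(values.mean(axis=1), axis=0).div(values.std(axis=1, ddof=0), axis=0)
        cors = [np.corrcoef(eg, row)[0, 1] for _, row in z.iterrows()]
        assert np.mean(cors) >= 0

    def test_pc1_beats_any_single_member(self, rng):
        values = pd.DataFrame(rng.normal(size=(10, 40)),
                              index=[f"g{i}" for i in range(10)])
        assignment = pd.Series(1, index=values.index)
        eg = coex.module_eigengene(values, assignment)[1].to_numpy()
        z = values.sub(values.mean(axis=1), axis=0).div(
            values.std(axis=1, ddof=0), axis=0
        ).to_numpy()

        def explained(direction):
            d = direction / np.linalg.norm(direction)
            return float(((z @ d) ** 2).sum())

        best_member = max(explained(z[i]) for i in range(len(z)))
        assert explained(eg) >= best_member - 1e-9


class TestHubGenes:
    def test_strong_gene_is_hub(self):
        genes = ["gHub", "gA", "gB", "gC"]
        a = np.full((4, 4), 0.5)
        a[0, :] = a[:, 0] = 0.95
        np.fill_diagonal(a, 0.0)
        adj = pd.DataFrame(a, index=genes, columns=genes)
        assignment = pd.Series(1, index=genes)
        assert coex.hub_genes(adj, assignment)[1] == "gHub"

    def test_two_gene_tie_breaks_lexicographically(self):
        genes = ["zz", "aa"]
        a = np.array([[0.0, 0.7], [0.7, 0.0]])
        adj = pd.DataFrame(a, index=genes, columns=genes)
        assignment = pd.Series(1, index=genes)
        assert coex.hub_genes(adj, assignment)[1] == "aa"

    def test_planted_hub_recovered(self):
        genes = [f"g{i:03d}" for i in range(60)]
        tp = list(np.linspace(-0.5, 40, 60))
        hits = 0
        for seed in range(10):
            expr, truth = syn.simulate_expression(
                genes, n_modules=1, module_corr=0.8, dev_timepoints=tp, seed=seed
            )
            dev = expr.subset_samples(expr.metadata.index.str.startswith("dev_"))
            ms = coex.run_wgcna(dev.values, beta=6, min_module_size=30)
            hits += truth.hub_genes[1] in set(ms.hubs.values())
        assert hits >= 8
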