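import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexpipe.network import (
    NetworkConfig,
    build_adjacency,
    build_network,
    correlation_matrix,
    detect_communities,
    merge_similar,
    scan_soft_threshold,
    topological_overlap,
)
from tests.conftest import make_planted_expression


class TestCorrelationMatrix:
    def test_duplicated_gene_correlates_one(self, rng):
        x = rng.normal(size=8)
        df = pd.DataFrame([x, x, rng.normal(size=8)], index=["a", "b", "c"])
        corr = correlation_matrix(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_gene_correlates_minus_one(self, rng):
        x = rng.normal(size=10)
        df = pd.DataFrame([x, -x], index=["a", "neg"])
        corr = correlation_matrix(df)
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)

    def test_definitional_oracle(self, rng):
        mat = rng.normal(size=(5, 4))
        df = pd.DataFrame(mat, index=list("abcde"))
        corr = correlation_matrix(df).to_numpy()
        for i in range(5):
            for j in range(5):
                xi, xj = mat[i] - mat[i].mean(), mat[j] - mat[j].mean()
                expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_named(self, rng):
        df = pd.DataFrame([np.ones(5), rng.normal(size=5)], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(df)

    def test_too_few_samples(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 2)), index=list("abc"))
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(df)


class TestBuildAdjacency:
    def test_perfect_correlation_any_power(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        for beta in (1, 5, 13):
            adj = build_adjacency(r, NetworkConfig(power=beta))
            assert adj[0, 1] == pytest.approx(1.0)

    def test_unsigned_power13_arithmetic(self):
        r = np.array([[1.0, 0.8], [0.8, 1.0]])
        adj = build_adjacency(r, NetworkConfig(power=13))
        assert adj[0, 1] == pytest.approx(0.8**13)
        assert adj[0, 1] == pytest.approx(0.05497558138880003)

    def test_unsigned_sign_symmetry(self, rng):
        r = np.clip(rng.uniform(-1, 1, size=(6, 6)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        a1 = build_adjacency(r, NetworkConfig(power=7))
        a2 = build_adjacency(-r, NetworkConfig(power=7))
        offdiag = ~np.eye(6, dtype=bool)
        assert np.allclose(a1[offdiag], a2[offdiag])

    def test_signed_mode_formula(self):
        r = np.array([[1.0, -0.5], [-0.5, 1.0]])
        adj = build_adjacency(r, NetworkConfig(power=2, signed_mode="signed"))
        assert adj[0, 1] == pytest.approx(0.25**2)

    def test_diagonal_zeroed(self, rng):
        r = np.corrcoef(rng.normal(size=(5, 20)))
        adj = build_adjacency(r, NetworkConfig(power=3))
        assert np.all(np.diag(adj) == 0)

    def test_monotone_in_power(self, rng):
        r = np.corrcoef(rng.normal(size=(10, 30)))
        offdiag = ~np.eye(10, dtype=bool)
        prev = build_adjacency(r, NetworkConfig(power=1))
        for beta in range(2, 15):
            cur = build_adjacency(r, NetworkConfig(power=beta))
            assert np.all(cur[offdiag] <= prev[offdiag] + 1e-15)
            prev = cur

    def test_bounds_random_inputs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r = np.corrcoef(rng.normal(size=(8, 12)))
            adj = build_adjacency(r, NetworkConfig(power=int(rng.integers(1, 20))))
            assert adj.min() >= 0 and adj.max() <= 1
            assert np.allclose(adj, adj.T)


class TestTopologicalOverlap:
    def test_isolated_nodes(self):
        tom = topological_overlap(np.zeros((3, 3)))
        assert tom[0, 1] == 0
        assert np.all(np.diag(tom) == 1)

    def test_perfect_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = topological_overlap(a)
        offdiag = ~np.eye(3, dtype=bool)
        assert np.allclose(tom[offdiag], 1.0)

    def test_bruteforce_oracle(self, rng):
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(6) if u not in (i, j))
                # include u == i, u == j terms as the matrix product does:
                # a_ii = a_jj = 0, so they vanish
                ki = sum(a[i, u] for u in range(6))
                kj = sum(a[j, u] for u in range(6))
                expected = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounds_property(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 12))
            a = rng.uniform(0, 1, size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            tom = topological_overlap(a)
            assert tom.min() >= 0 and tom.max() <= 1
            assert np.allclose(tom, tom.T)

    def test_asymmetric_rejected(self):
        a = np.array([[0.0, 0.5], [0.1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


class TestSoftThresholdScan:
    def test_empty_powers_rejected(self, rng):
        r = np.corrcoef(rng.normal(size=(40, 30)))
        with pytest.raises(ValueError, match="empty"):
            scan_soft_threshold(r, powers=())

    def test_flat_connectivity_degenerate(self):
        r = np.full((40, 40), 0.5)
        np.fill_diagonal(r, 1.0)
        with pytest.warns(UserWarning):
            scan = scan_soft_threshold(r, powers=(2,))
        assert scan.table.r_squared.iloc[0] == 0.0

    def test_matches_independent_binned_regression(self):
        df, _ = make_planted_expression(module_sizes=(25, 25), loading=0.8,
                                        n_samples=80, seed=2)
        r = np.corrcoef(df.to_numpy())
        cfg = NetworkConfig(n_degree_bins=10)
        scan = scan_soft_threshold(r, powers=(2, 6), config=cfg)
        for _, row in scan.table.iterrows():
            adj = np.abs(r) ** row.power
            np.fill_diagonal(adj, 0.0)
            k = adj.sum(axis=1)
            edges = np.linspace(k.min(), k.max(), 11)
            idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
            xs, ys = [], []
            for b in range(10):
                mask = idx == b
                if mask.any() and k[mask].mean() > 0:
                    xs.append(np.log10(k[mask].mean()))
                    ys.append(np.log10(mask.mean()))
            slope, _ = np.polyfit(xs, ys, 1)
            rr = np.corrcoef(xs, ys)[0, 1]
            expected = -np.sign(slope) * rr**2
            assert row.r_squared == pytest.approx(expected, abs=1e-10)

    def test_exact_power_law_degree_sequence_fits(self):
        # degree values 10*2^b with counts 1600/k follow an exact discrete
        # power law (slope -1); each distinct value falls in its own
        # equal-width bin, so the binned log-log regression is exact
        from coexpipe.network import _scale_free_fit

        ks, counts = [10, 20, 40, 80, 160], [160, 80, 40, 20, 10]
        k = np.repeat(ks, counts).astype(float)
        r2, slope = _scale_free_fit(k, n_bins=15)
        assert r2 >= 0.99
        assert slope == pytest.approx(-1.0, abs=1e-10)

    def test_power_law_like_connectivity_scores_high(self):
        # continuous power-law-ish degree sequence: binned fit is high but
        # not exact (within-bin curvature)
        n = 400
        target_k = 50.0 * (np.arange(1, n + 1) ** -0.7)
        r = np.sqrt(np.outer(target_k, target_k) / target_k.sum())
        r = np.clip(r, 0, 0.999)
        np.fill_diagonal(r, 1.0)
        scan = scan_soft_threshold(r, powers=(1,), config=NetworkConfig(n_degree_bins=15))
        assert scan.table.r_squared.iloc[0] >= 0.9

    def test_recommends_smallest_power_reaching_target(self):
        df, _ = make_planted_expression(module_sizes=(40, 40), loading=0.9,
                                        n_samples=150, seed=5, n_background=40)
        r = np.corrcoef(df.to_numpy())
        scan = scan_soft_threshold(r, powers=(1, 2, 3, 4, 6, 8, 10))
        tab = scan.table
        reaching = tab[tab.r_squared >= 0.80]
        if len(reaching):
            assert scan.recommended == reaching.power.iloc[0]
        else:
            assert scan.recommended == tab.loc[tab.r_squared.idxmax(), "power"]


class TestDetectCommunities:
    def test_two_perfect_blocks(self):
        df, truth = make_planted_expression(module_sizes=(50, 50), loading=0.95,
                                            n_samples=120, seed=7)
        net = build_network(df, NetworkConfig(power=6, min_module_size=20))
        part = detect_communities(net)
        assert len(part.communities) == 2
        assert adjusted_rand_score(truth.to_numpy(), part.labels.to_numpy()) == 1.0

    def test_pure_noise_all_background(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(80, 60)),
                          index=[f"g{i}" for i in range(80)])
        net = build_network(df, NetworkConfig(power=6, min_module_size=30))
        part = detect_communities(net)
        assert part.communities == [] or max(
            (part.labels == c).sum() for c in part.communities) < 80

    def test_three_block_recovery_over_seeds(self):
        scores = []
        for seed in range(10):
            df, truth = make_planted_expression(module_sizes=(50, 50, 50),
                                                loading=0.8, n_samples=100,
                                                seed=seed)
            net = build_network(df, NetworkConfig(power=6, min_module_size=30))
            part = detect_communities(net)
            scores.append(adjusted_rand_score(truth.to_numpy(), part.labels.to_numpy()))
        assert np.mean(scores) >= 0.9

    def test_gene_order_invariance(self):
        df, truth = make_planted_expression(module_sizes=(30, 30), loading=0.9,
                                            n_samples=80, seed=11)
        cfg = NetworkConfig(power=6, min_module_size=20)
        part1 = detect_communities(build_network(df, cfg))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(df))
        part2 = detect_communities(build_network(df.iloc[perm], cfg))
        aligned = part2.labels.reindex(part1.labels.index)
        assert adjusted_rand_score(part1.labels.to_numpy(), aligned.to_numpy()) == 1.0

    def test_fewer_genes_than_min_size(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(5, 20)), index=list("abcde"))
        net = build_network(df, NetworkConfig(power=2, min_module_size=30))
        with pytest.warns(UserWarning, match="min_module_size"):
            part = detect_communities(net)
        assert (part.labels == 0).all()

    def test_small_instance_matches_exhaustive_average_linkage(self):
        """<= 8 genes: clustering agrees with a hand-rolled agglomerative
        average-linkage enumeration."""
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.normal(size=(8, 25)),
                          index=[f"g{i}" for i in range(8)])
        net = build_network(df, NetworkConfig(power=2, min_module_size=1))
        d = 1 - net.tom
        np.fill_diagonal(d, 0)

        # oracle: naive average linkage
        clusters = {i: [i] for i in range(8)}
        merges = []
        next_id = 8
        while len(clusters) > 1:
            best = None
            for a in clusters:
                for b in clusters:
                    if a >= b:
                        continue
                    dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                    if best is None or dist < best[0] - 1e-15:
                        best = (dist, a, b)
            dist, a, b = best
            merges.append(dist)
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1

        part = detect_communities(net, NetworkConfig(power=2, min_module_size=1,
                                                     tree_cut_height=2.0))
        assert np.allclose(np.sort(part.merge_heights), np.sort(merges), atol=1e-10)


class TestMergeSimilar:
    def _make(self, labels_dict, eigs):
        labels = pd.Series(labels_dict, name="community")
        from coexpipe.network import ModulePartition
        return ModulePartition(labels=labels), pd.DataFrame(eigs)

    def test_identical_eigengenes_merged(self, rng):
        e = rng.normal(size=20)
        e /= np.linalg.norm(e)
        part, eigs = self._make(
            {f"g{i}": 1 for i in range(5)} | {f"h{i}": 2 for i in range(5)},
            {1: e, 2: e.copy()},
        )
        merged = merge_similar(part, eigs.T, 0.25)
        assert len(merged.communities) == 1
        assert merged.merge_history

    def test_orthogonal_not_merged(self, rng):
        e1 = rng.normal(size=50)
        e2 = rng.normal(size=50)
        e2 -= e2 @ e1 / (e1 @ e1) * e1  # orthogonalize -> r ~ 0
        part, eigs = self._make(
            {f"g{i}": 1 for i in range(5)} | {f"h{i}": 2 for i in range(5)},
            {1: e1, 2: e2},
        )
        merged = merge_similar(part, eigs.T, 0.25)
        assert len(merged.communities) == 2

    def test_dissimilarity_below_cut_merged(self, rng):
        # construct eigengenes with correlation ~0.8 (dissimilarity 0.2 < 0.25)
        base = rng.normal(size=2000)
        noisy = 0.8 * base + np.sqrt(1 - 0.64) * rng.normal(size=2000)
        r = np.corrcoef(base, noisy)[0, 1]
        assert 1 - r < 0.25
        part, eigs = self._make(
            {f"g{i}": 1 for i in range(5)} | {f"h{i}": 2 for i in range(5)},
            {1: base, 2: noisy},
        )
        merged = merge_similar(part, eigs.T, 0.25)
        assert len(merged.communities) == 1

    def test_dissimilarity_above_cut_kept(self, rng):
        base = rng.normal(size=2000)
        noisy = 0.5 * base + np.sqrt(0.75) * rng.normal(size=2000)
        r = np.corrcoef(base, noisy)[0, 1]
        assert 1 - r > 0.25
        part, eigs = self._make(
            {f"g{i}": 1 for i in range(5)} | {f"h{i}": 2 for i in range(5)},
            {1: base, 2: noisy},
        )
        merged = merge_similar(part, eigs.T, 0.25)
        assert len(merged.communities) == 2
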