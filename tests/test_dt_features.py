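import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crhunter._aa import AA_INDEX
from crhunter.dt_features import (
    PairWeightMatrix,
    me_score,
    network_features,
    pair_frequency,
    train_pair_weights,
)
from crhunter.structure_model import CatalyticAnnotation
from crhunter.tessellation import ResidueContactGraph, contact_graph, microenvironment, tessellate

from conftest import random_structure, structure_from_points


def _graph(counts, n):
    return ResidueContactGraph(n_residues=n, facet_counts=counts)


def _toy(sequence, counts):
    """Structure with one CA per residue (positions irrelevant for F/W)."""
    points = np.arange(len(sequence) * 3, dtype=float).reshape(-1, 3)
    structure = structure_from_points(points, [1] * len(sequence), sequence=sequence)
    return structure, _graph(counts, len(sequence))


class TestPairFrequency:
    def test_counts_by_neighbor_type(self):
        structure, graph = _toy("HDDS", {(0, 1): 10, (0, 2): 11, (0, 3): 9})
        freq = pair_frequency(structure, graph, 0, cutoff=9)
        assert freq[AA_INDEX["H"], AA_INDEX["D"]] == 2
        assert freq[AA_INDEX["H"], AA_INDEX["S"]] == 1
        assert freq.sum() == 3
        # only the query-type row may be populated
        assert np.all(freq[np.arange(20) != AA_INDEX["H"]] == 0)

    def test_isolated_residue_zero_vector(self):
        structure, graph = _toy("HD", {})
        assert pair_frequency(structure, graph, 0).sum() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_sum_equals_microenvironment_size(self, seed):
        rng = np.random.default_rng(seed)
        structure = random_structure(rng, n_atoms=60, n_residues=12)
        graph = contact_graph(structure, tessellate(structure))
        for i in range(12):
            freq = pair_frequency(structure, graph, i, cutoff=3)
            assert freq.sum() == len(microenvironment(graph, i, cutoff=3))


class TestTrainPairWeights:
    def test_single_pair_no_pseudocount(self):
        structure, graph = _toy("HD", {(0, 1): 12})
        w = train_pair_weights(
            [(structure, graph, CatalyticAnnotation("t", frozenset({0})))],
            pseudocount=0.0,
        )
        # neighborhood of the catalytic H: one D; N_HD=1, N_H=1 (query), N_D=1
        assert w.values[AA_INDEX["H"], AA_INDEX["D"]] == pytest.approx(1.0)
        assert w.values.sum() == pytest.approx(1.0)
        assert w.n_catalytic == 1

    def test_mean_of_identical_neighborhoods(self):
        structure, graph = _toy("HDHD", {(0, 1): 12, (2, 3): 12})
        single = train_pair_weights(
            [(structure, graph, CatalyticAnnotation("t", frozenset({0})))]
        )
        both = train_pair_weights(
            [(structure, graph, CatalyticAnnotation("t", frozenset({0, 2})))]
        )
        np.testing.assert_allclose(both.values, single.values)

    def test_empty_neighborhood_skipped_and_counted(self):
        structure, graph = _toy("HD", {(0, 1): 12})
        w = train_pair_weights(
            [(structure, graph, CatalyticAnnotation("t", frozenset({0, 1})))],
        )
        # residue 1's only neighbor is residue 0 at count 12 -> both usable;
        # now sever residue 1 by lowering the count below the cutoff
        structure2, graph2 = _toy("HDC", {(0, 1): 12, (1, 2): 3})
        w2 = train_pair_weights(
            [(structure2, graph2, CatalyticAnnotation("t", frozenset({0, 2})))],
        )
        assert w2.n_catalytic == 1 and w2.n_skipped == 1

    def test_no_usable_catalytic_raises(self):
        structure, graph = _toy("HD", {})
        with pytest.raises(ValueError):
            train_pair_weights(
                [(structure, graph, CatalyticAnnotation("t", frozenset({0})))]
            )

    def test_matches_bruteforce_oracle_and_order_invariance(self, small_bench, small_cache):
        triples = [
            (r.structure, small_cache.graph(r), r.annotation) for r in small_bench.records
        ]
        w = train_pair_weights(triples, pseudocount=0.5)

        # independent loop over catalytic residues, literal formula
        total = np.zeros((20, 20))
        used = 0
        for structure, graph, ann in triples:
            for res in ann.catalytic_indices:
                neigh = microenvironment(graph, res, 9)
                if not neigh:
                    continue
                used += 1
                m = AA_INDEX[structure.residues[res].aa]
                types = [m] + [AA_INDEX[structure.residues[j].aa] for j, _ in neigh]
                for n in range(20):
                    n_mn = sum(1 for j, _ in neigh if AA_INDEX[structure.residues[j].aa] == n)
                    if n_mn:
                        total[m, n] += n_mn / ((types.count(m) + 0.5) * (types.count(n) + 0.5))
        np.testing.assert_allclose(w.values, total / used, atol=1e-12)

        w_rev = train_pair_weights(list(reversed(triples)), pseudocount=0.5)
        np.testing.assert_allclose(w.values, w_rev.values)


class TestMeScore:
    def test_zero_vector_scores_zero(self):
        assert me_score(np.zeros((20, 20)), PairWeightMatrix(np.ones((20, 20)), 1)) == 0.0

    def test_single_entry_linearity(self):
        freq = np.zeros((20, 20))
        freq[AA_INDEX["H"], AA_INDEX["D"]] = 2
        weights = np.zeros((20, 20))
        weights[AA_INDEX["H"], AA_INDEX["D"]] = 0.3
        assert me_score(freq, PairWeightMatrix(weights, 1)) == pytest.approx(0.6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_additivity(self, seed):
        rng = np.random.default_rng(seed)
        f1, f2 = rng.integers(0, 5, (20, 20)), rng.integers(0, 5, (20, 20))
        w = PairWeightMatrix(rng.random((20, 20)), 1)
        assert me_score(f1 + f2, w) == pytest.approx(me_score(f1, w) + me_score(f2, w))


def floyd_warshall_oracle(n, edges):
    """Brute-force shortest paths, path counts, triangles; all four measures."""
    inf = float("inf")
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    adj = [[False] * n for _ in range(n)]
    for a, b in edges:
        dist[a][b] = dist[b][a] = 1
        adj[a][b] = adj[b][a] = True
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]

    # shortest-path counts by dynamic programming over increasing distance
    npaths = [[0] * n for _ in range(n)]
    for s in range(n):
        npaths[s][s] = 1
        order = sorted((d, v) for v, d in enumerate(dist[s]) if d < inf)
        for d, v in order:
            if v == s:
                continue
            npaths[s][v] = sum(npaths[s][u] for u in range(n) if adj[u][v] and dist[s][u] == d - 1)

    degree = [sum(adj[i]) for i in range(n)]
    closeness = []
    for i in range(n):
        reach = [j for j in range(n) if j != i and dist[i][j] < inf]
        total = sum(dist[i][j] for j in reach)
        closeness.append((len(reach) / total) * (len(reach) / (n - 1)) if total else 0.0)
    betweenness = [0.0] * n
    if n > 2:
        for v in range(n):
            acc = 0.0
            for s in range(n):
                for t in range(s + 1, n):
                    if v in (s, t) or dist[s][t] == inf or npaths[s][t] == 0:
                        continue
                    if dist[s][v] + dist[v][t] == dist[s][t]:
                        acc += npaths[s][v] * npaths[v][t] / npaths[s][t]
            betweenness[v] = acc * 2.0 / ((n - 1) * (n - 2))
    clustering = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            clustering.append(0.0)
            continue
        triangles = sum(
            1 for a in range(k) for b in range(a + 1, k) if adj[nbrs[a]][nbrs[b]]
        )
        clustering.append(2.0 * triangles / (k * (k - 1)))
    return degree, closeness, betweenness, clustering


class TestNetworkFeatures:
    def _features(self, n, edges):
        counts = {(min(a, b), max(a, b)): 9 for a, b in edges}
        return network_features(ResidueContactGraph(n, counts), cutoff=9)

    def test_five_node_star(self):
        nf = self._features(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        assert nf.loc[0, "degree"] == 4
        assert nf.loc[0, "closeness"] == pytest.approx(1.0)
        assert nf.loc[0, "betweenness"] == pytest.approx(1.0)
        assert nf.loc[0, "clustering"] == 0.0
        for leaf in range(1, 5):
            assert nf.loc[leaf, "closeness"] == pytest.approx(4 / 7)
            assert nf.loc[leaf, "betweenness"] == 0.0

    def test_triangle(self):
        nf = self._features(3, [(0, 1), (1, 2), (0, 2)])
        assert (nf["clustering"] == 1.0).all()
        assert (nf["betweenness"] == 0.0).all()

    def test_isolated_nodes_score_zero(self):
        nf = self._features(4, [(0, 1)])
        assert nf.loc[2].tolist() == [0, 0.0, 0.0, 0.0]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 26))
        edges = [
            (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.2
        ]
        nf = self._features(n, edges)
        degree, closeness, betweenness, clustering = floyd_warshall_oracle(n, edges)
        np.testing.assert_allclose(nf["degree"], degree)
        np.testing.assert_allclose(nf["closeness"], closeness, atol=1e-12)
        np.testing.assert_allclose(nf["betweenness"], betweenness, atol=1e-12)
        np.testing.assert_allclose(nf["clustering"], clustering, atol=1e-12)
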