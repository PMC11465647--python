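"""Co-occurrence projection, degree/strength, PageRank and top-k ranking."""

from collections import Counter
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from chemstripes.network import (
    CentralityResult,
    ConvergenceError,
    build_network,
    degree_centrality,
    pagerank_centrality,
    top_k,
    write_edgelist_csv,
)
from chemstripes.patent_core import dedupe_records
from conftest import record


def pagerank_oracle(weights: np.ndarray, damping: float) -> np.ndarray:
    """Dense power iteration on the explicit Google matrix, independent of
    the package's sparse implementation."""
    n = weights.shape[0]
    strength = weights.sum(axis=1)
    p = np.zeros((n, n))
    for i in range(n):
        if strength[i] > 0:
            p[i] = weights[i] / strength[i]
        else:
            p[i] = 1.0 / n  # dangling: uniform
    google = (1 - damping) / n + damping * p
    x = np.full(n, 1.0 / n)
    for _ in range(10_000):
        x_new = x @ google
        if np.abs(x_new - x).sum() < 1e-14:
            return x_new
        x = x_new
    return x


def random_net(rng, n):
    """Random weighted network plus its dense weight matrix."""
    w = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        if rng.random() < 0.15:
            w[i, j] = w[j, i] = rng.integers(1, 10)
    g = nx.Graph()
    g.add_nodes_from(range(1, n + 1))
    for i, j in combinations(range(n), 2):
        if w[i, j]:
            g.add_edge(i + 1, j + 1, weight=int(w[i, j]))
    from chemstripes.network import CoocNetwork

    return CoocNetwork(graph=g), w


class TestBuildNetwork:
    def test_one_patent_three_cids_makes_triangle(self):
        net = build_network([record("US-1-A", cids={1, 2, 3})], {1, 2, 3})
        assert net.weight(1, 2) == net.weight(1, 3) == net.weight(2, 3) == 1

    def test_coappearance_weighting(self):
        recs = [record("US-1-A", cids={1, 2}), record("US-2-A", cids={1, 2})]
        net = build_network(recs, {1, 2})
        assert net.weight(1, 2) == 2

    def test_isolates_kept_as_nodes(self):
        net = build_network([record("US-1-A", cids={1})], {1, 2, 3})
        assert net.nodes == [1, 2, 3]
        assert net.graph.number_of_edges() == 0

    def test_cids_outside_list_ignored(self):
        net = build_network([record("US-1-A", cids={1, 2, 99})], {1, 2})
        assert net.nodes == [1, 2] and net.weight(1, 2) == 1

    def test_weights_match_pair_count_oracle(self, small_corpus):
        _, records, _ = small_corpus
        deduped = dedupe_records(records)
        cid_list = set(range(1, 201))
        net = build_network(deduped, cid_list)
        oracle: Counter = Counter()
        for r in deduped:
            for a, b in combinations(sorted(cid_list & r.cids), 2):
                oracle[(a, b)] += 1
        for (a, b), w in oracle.items():
            assert net.weight(a, b) == w
        assert net.total_weight() == sum(oracle.values())

    def test_weight_conservation_sum_of_pairs(self, small_corpus):
        _, records, _ = small_corpus
        deduped = dedupe_records(records)
        net = build_network(deduped, set(range(1, 201)))
        expected = sum(
            len(r.cids) * (len(r.cids) - 1) // 2 for r in deduped
        )
        assert net.total_weight() == expected

    def test_region_filter_weights_bounded_by_unfiltered(self, small_corpus):
        _, records, _ = small_corpus
        deduped = dedupe_records(records)
        cid_list = set(range(1, 201))
        full = build_network(deduped, cid_list)
        china = build_network(deduped, cid_list, region="China")
        for a, b, d in china.graph.edges(data=True):
            assert d["weight"] <= full.weight(a, b)
        assert china.n_patents <= full.n_patents

    def test_empty_cid_list_rejected(self):
        with pytest.raises(ValueError):
            build_network([], set())


class TestDegree:
    def test_triangle_unweighted(self):
        net = build_network([record("US-1-A", cids={1, 2, 3})], {1, 2, 3})
        assert all(s == 2 for s in degree_centrality(net).scores.values())

    def test_strength_sums_incident_weights(self):
        recs = [record(f"US-{i}-A", cids={1, 2}) for i in range(3)] + [
            record(f"EP-{i}-A", cids={1, 3}) for i in range(5)
        ]
        net = build_network(recs, {1, 2, 3})
        strength = degree_centrality(net, weighted=True).scores
        assert strength[1] == 8 and strength[2] == 3 and strength[3] == 5

    def test_matches_adjacency_row_sums(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            net, w = random_net(rng, int(rng.integers(5, 50)))
            strength = degree_centrality(net, weighted=True).scores
            degree = degree_centrality(net).scores
            for i, node in enumerate(net.nodes):
                assert strength[node] == pytest.approx(w[i].sum())
                assert degree[node] == (w[i] > 0).sum()


class TestPageRank:
    def test_two_nodes_one_edge_symmetric(self):
        net = build_network([record("US-1-A", cids={1, 2})], {1, 2})
        scores = pagerank_centrality(net).scores
        assert scores[1] == pytest.approx(0.5, abs=1e-12)
        assert scores[2] == pytest.approx(0.5, abs=1e-12)

    def test_scores_sum_to_one(self, small_corpus):
        _, records, _ = small_corpus
        net = build_network(dedupe_records(records), set(range(1, 201)))
        scores = pagerank_centrality(net).scores
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            net, w = random_net(rng, int(rng.integers(3, 50)))
            got = pagerank_centrality(net, tol=1e-12)
            expect = pagerank_oracle(w, 0.85)
            diff = max(
                abs(got.scores[node] - expect[i])
                for i, node in enumerate(net.nodes)
            )
            assert diff < 1e-8

    def test_damping_to_zero_gives_uniform(self):
        rng = np.random.default_rng(5)
        net, _ = random_net(rng, 20)
        scores = pagerank_centrality(net, damping=1e-6).scores
        for s in scores.values():
            assert s == pytest.approx(1 / 20, abs=1e-4)

    def test_nonconvergence_reported(self):
        rng = np.random.default_rng(5)
        net, _ = random_net(rng, 30)
        with pytest.raises(ConvergenceError, match="residual"):
            pagerank_centrality(net, tol=1e-15, max_iter=2)

    def test_invalid_damping_rejected(self):
        net = build_network([record("US-1-A", cids={1, 2})], {1, 2})
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                pagerank_centrality(net, damping=bad)


class TestTopK:
    def test_descending_by_score(self):
        result = CentralityResult("degree", {1: 0.5, 2: 0.3, 3: 0.2})
        assert top_k(result, 2) == [(1, 0.5), (2, 0.3)]

    def test_tie_broken_by_ascending_cid(self):
        result = CentralityResult("degree", {10: 1.0, 7: 1.0, 3: 0.5})
        assert [cid for cid, _ in top_k(result, 2)] == [7, 10]

    def test_consistent_with_full_sort(self, small_corpus):
        _, records, _ = small_corpus
        net = build_network(dedupe_records(records), set(range(1, 201)))
        result = degree_centrality(net, weighted=True)
        full = sorted(result.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        assert top_k(result, 25) == full[:25]

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            top_k(CentralityResult("degree", {1: 1.0}), 0)


def test_planted_hubs_dominate_strength(small_corpus):
    spec, records, truth = small_corpus
    net = build_network(dedupe_records(records), set(range(1, spec.n_cids + 1)))
    top3 = {cid for cid, _ in top_k(degree_centrality(net, weighted=True), 3)}
    assert top3 == set(truth.hub_cids)


def test_edgelist_export(tmp_path):
    recs = [record("US-1-A", cids={1, 2}), record("US-2-A", cids={1, 2, 3})]
    net = build_network(recs, {1, 2, 3})
    path = write_edgelist_csv(net, tmp_path / "edges.csv")
    lines = path.read_text().splitlines()
    assert lines[0] == "cid_a,cid_b,weight"
    assert "1,2,2" in lines
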