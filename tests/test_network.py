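import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plankton_assembly import (
    CommunityTable, ValidationError, build_network, filter_prevalence,
    merge_domains, network_stats, spearman_matrix, write_graphml,
)


def brute_force_betweenness(edges):
    """Exhaustive normalized betweenness via BFS path counting."""
    adj = {}
    for _, row in edges.iterrows():
        adj.setdefault(row["node_a"], set()).add(row["node_b"])
        adj.setdefault(row["node_b"], set()).add(row["node_a"])
    nodes = sorted(adj)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.permutations(nodes, 2):
        # enumerate all shortest paths s->t with BFS layers
        dist = {s: 0}
        parents = {s: []}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        parents[v] = [u]
                        nxt.append(v)
                    elif dist[v] == dist[u] + 1:
                        parents[v].append(u)
            frontier = nxt
        if t not in dist:
            continue
        paths = []

        def walk(v, acc):
            if v == s:
                paths.append(acc)
                return
            for u in parents[v]:
                walk(u, acc + [u])

        walk(t, [t])
        n_paths = len(paths)
        inner_counts = {}
        for path in paths:
            for v in path[1:-1]:
                inner_counts[v] = inner_counts.get(v, 0) + 1
        for v, c in inner_counts.items():
            bc[v] += c / n_paths
    n = len(nodes)
    norm = (n - 1) * (n - 2)  # ordered pairs, undirected graph
    return {v: bc[v] / norm for v in nodes}


def correlated_block_table(seed, n_samples=30, block=10, background=60):
    """Two latent factors each driving one ASV block, plus an uncorrelated
    background pool large enough to keep compositional closure weak."""
    rng = np.random.default_rng(seed)
    f = rng.lognormal(0, 1, size=(n_samples, 2))
    noise = rng.lognormal(0, 0.2, size=(n_samples, 2 * block))
    blocks = np.hstack([
        np.outer(f[:, 0], np.ones(block)),
        np.outer(f[:, 1], np.ones(block)),
    ]) * noise
    bg = rng.lognormal(1.5, 0.6, size=(n_samples, background))
    lam = np.hstack([blocks, bg])
    counts = rng.poisson(2000 * lam / lam.sum(axis=1, keepdims=True))
    counts[:, 0] += 1
    return CommunityTable(pd.DataFrame(
        counts, index=[f"S{i}" for i in range(n_samples)],
        columns=[f"A{j}" for j in range(2 * block + background)]))


class TestPrevalenceFilter:
    def test_27_sample_half_rule(self):
        counts = np.zeros((27, 2), dtype=int)
        counts[:14, 0] = 5   # present in 14 > 13.5 -> keep
        counts[:13, 1] = 5   # present in 13 < 13.5 -> drop
        table = CommunityTable(pd.DataFrame(
            counts, index=[f"S{i}" for i in range(27)],
            columns=["keep", "drop"]))
        out = filter_prevalence(table, 0.5)
        assert out.asv_ids == ["keep"]

    def test_literal_count_override(self):
        counts = np.zeros((27, 1), dtype=int)
        counts[:14, 0] = 5
        table = CommunityTable(pd.DataFrame(
            counts, index=[f"S{i}" for i in range(27)], columns=["x"]))
        with pytest.raises(ValidationError):
            filter_prevalence(table, min_present=14)  # needs > 14

    def test_ubiquitous_asv_always_kept(self, toy_table):
        out = filter_prevalence(toy_table, 0.99)
        assert "ASV_4" in out.asv_ids


class TestSpearman:
    def test_monotone_pair_is_one(self):
        # constant row totals so relative abundances stay monotone
        counts = pd.DataFrame({"A": [1, 2, 3, 4, 5, 6],
                               "B": [2, 4, 9, 16, 25, 36],
                               "C": [6, 5, 4, 3, 2, 1]},
                              index=[f"S{i}" for i in range(6)])
        counts["D"] = 60 - counts.sum(axis=1)
        rho, p = spearman_matrix(CommunityTable(counts))
        assert rho.loc["A", "A"] == 1.0
        assert rho.loc["A", "B"] == pytest.approx(1.0)
        assert rho.loc["A", "C"] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 4, size=(6, 5)) * 2,
            index=[f"S{i}" for i in range(6)],
            columns=[f"A{j}" for j in range(5)])
        counts += 1
        table = CommunityTable(counts)
        rho, _ = spearman_matrix(table)
        rel = table.relative_abundance()
        for a in table.asv_ids:
            for b in table.asv_ids:
                ra = stats.rankdata(rel[a])
                rb = stats.rankdata(rel[b])
                expected = np.corrcoef(ra, rb)[0, 1]
                assert rho.loc[a, b] == pytest.approx(expected, abs=1e-10)

    def test_constant_asv_flagged_nan(self):
        # constant relative abundance needs a constant total too
        counts = pd.DataFrame({"A": [5, 5, 5, 5, 5],
                               "B": [1, 2, 3, 4, 5],
                               "C": [9, 8, 7, 6, 5]},
                              index=[f"S{i}" for i in range(5)])
        counts["D"] = 30 - counts.sum(axis=1)
        table = CommunityTable(counts)
        rho, pv = spearman_matrix(table)
        assert np.isnan(rho.loc["A", "B"])
        assert np.isnan(pv.loc["A", "B"])
        assert rho.loc["B", "C"] == pytest.approx(-1.0)


class TestBuildNetwork:
    def frame(self, vals):
        ids = list("abc")
        return pd.DataFrame(vals, index=ids, columns=ids)

    def test_threshold_rules(self):
        rho = self.frame([[1, .7, -.7], [.7, 1, .61], [-.7, .61, 1]])
        p = self.frame([[0, .001, .001], [.001, 0, .02], [.001, .02, 0]])
        edges = build_network(rho, p)
        got = {(r["node_a"], r["node_b"]): r["sign"]
               for _, r in edges.iterrows()}
        assert got == {("a", "b"): "positive", ("a", "c"): "negative"}

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(1)
        n = 12
        r = np.clip(squareform_sym(rng.uniform(-1, 1, n * (n - 1) // 2)), -1, 1)
        np.fill_diagonal(r, 1.0)
        p = squareform_sym(rng.uniform(0, 0.05, n * (n - 1) // 2))
        ids = [f"A{i}" for i in range(n)]
        rho = pd.DataFrame(r, index=ids, columns=ids)
        pv = pd.DataFrame(p, index=ids, columns=ids)
        base = len(build_network(rho, pv, 0.4, 0.02))
        assert len(build_network(rho, pv, 0.6, 0.02)) <= base
        assert len(build_network(rho, pv, 0.4, 0.005)) <= base


def squareform_sym(vec):
    from scipy.spatial.distance import squareform
    return squareform(vec)


class TestNetworkStats:
    def edges_of(self, pairs):
        return pd.DataFrame([
            {"node_a": a, "node_b": b, "rho": 0.8, "p": 0.001,
             "sign": "positive"} for a, b in pairs
        ])

    def test_path_graph_middle_node_maximal(self):
        st_ = network_stats(self.edges_of([("a", "b"), ("b", "c")]))
        assert st_.betweenness.idxmax() == "b"

    def test_complete_graph_zero_betweenness(self):
        pairs = list(itertools.combinations("abcd", 2))
        st_ = network_stats(self.edges_of(pairs))
        assert (st_.betweenness == 0).all()

    def test_betweenness_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i:02d}" for i in range(18)]
        pairs = [p for p in itertools.combinations(nodes, 2)
                 if rng.random() < 0.15]
        pairs += [(nodes[i], nodes[i + 1]) for i in range(17)]  # connected
        edges = self.edges_of(sorted(set(pairs)))
        st_ = network_stats(edges)
        oracle = brute_force_betweenness(edges)
        for node, val in oracle.items():
            assert st_.betweenness[node] == pytest.approx(val, abs=1e-10)

    def test_planted_hubs_rank_top(self):
        spokes_a = [("hub1", f"x{i}") for i in range(5)]
        spokes_b = [("hub2", f"y{i}") for i in range(5)]
        bridge = [("hub1", "hub2")]
        st_ = network_stats(self.edges_of(spokes_a + spokes_b + bridge), k=2)
        assert set(st_.core_nodes) == {"hub1", "hub2"}

    def test_positive_negative_ratio(self):
        edges = self.edges_of([("a", "b"), ("b", "c"), ("c", "d")])
        edges.loc[2, "sign"] = "negative"
        st_ = network_stats(edges)
        assert st_.pos_neg_ratio == pytest.approx(2.0)

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx
        edges = self.edges_of([("a", "b"), ("b", "c")])
        path = tmp_path / "net.graphml"
        write_graphml(edges, path)
        g = nx.read_graphml(path)
        assert set(g.nodes) == {"a", "b", "c"}
        assert g.edges[("a", "b")]["sign"] == "positive"


def planted_block_of(node):
    i = int(node[1:])
    return 0 if i < 10 else 1 if i < 20 else None


class TestPlantedBlocks:
    def test_most_edges_fall_within_blocks(self):
        good = 0
        total = 0
        for seed in range(10):
            table = correlated_block_table(seed)
            rho, p = spearman_matrix(filter_prevalence(table, 0.5))
            edges = build_network(rho, p, rho_min=0.6, p_max=0.01)
            if edges.empty:
                continue
            same = sum(
                planted_block_of(a) is not None
                and planted_block_of(a) == planted_block_of(b)
                for a, b in zip(edges["node_a"], edges["node_b"]))
            good += same
            total += len(edges)
        assert total > 0
        assert good / total >= 0.9


class TestMergeDomains:
    def test_disjoint_merge_concatenates(self, toy_table):
        other = CommunityTable(
            toy_table.counts.rename(columns=lambda c: c.replace("ASV",
                                                                "EUK")))
        merged = merge_domains([toy_table, other])
        assert merged.n_asvs == toy_table.n_asvs * 2

    def test_merge_commutes_with_prevalence_filter(self, toy_table):
        other = CommunityTable(
            toy_table.counts.rename(columns=lambda c: c.replace("ASV",
                                                                "EUK")))
        a = filter_prevalence(merge_domains([toy_table, other]), 0.5)
        b = merge_domains([
            filter_prevalence(toy_table, 0.5),
            filter_prevalence(other, 0.5),
        ])
        assert set(a.asv_ids) == set(b.asv_ids)

    def test_collision_without_tags_errors(self, toy_table):
        with pytest.raises(ValidationError, match="colliding"):
            merge_domains([toy_table, toy_table])

    def test_domain_tags_disambiguate(self, toy_table):
        merged = merge_domains([toy_table, toy_table],
                               domains=["bacteria", "eukaryote"])
        assert merged.n_asvs == toy_table.n_asvs * 2
        assert any(c.startswith("bacteria|") for c in merged.asv_ids)

    def test_sample_mismatch_errors(self, toy_table):
        other = CommunityTable(
            toy_table.counts.iloc[:2].rename(
                columns=lambda c: c.replace("ASV", "EUK")))
        with pytest.raises(ValidationError):
            merge_domains([toy_table, other])
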