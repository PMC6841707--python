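import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from floodnet.core import CountTable, SampleHierarchy, ValidationError
from floodnet.networks import (
    CooccurrenceNetwork,
    cscore,
    cscore_test,
    detect_modules,
    infer_network,
    keystone_taxa,
    modularity_q,
    node_metrics,
    zone_affinity,
    zone_edge_summary,
)


def net_from_graph(g: nx.Graph) -> CooccurrenceNetwork:
    edges = pd.DataFrame(
        [{"taxon_a": a, "taxon_b": b, "r": 0.9, "p": 0.001, "sign": "positive"} for a, b in g.edges()],
        columns=["taxon_a", "taxon_b", "r", "p", "sign"],
    )
    return CooccurrenceNetwork(graph=g, edges=edges)


# ---------------------------------------------------------------------------
# C-score
# ---------------------------------------------------------------------------

class TestCScore:
    def test_checkerboard_unit(self):
        assert cscore(np.array([[1, 0], [0, 1]])) == 1.0

    def test_identical_rows_zero(self):
        m = np.array([[1, 1, 0], [1, 1, 0], [1, 1, 0]])
        assert cscore(m) == 0.0

    def test_matches_pairwise_definition(self, rng):
        m = (rng.random((8, 10)) < 0.4).astype(int)
        pairs = []
        for i, j in itertools.combinations(range(8), 2):
            ri, rj = m[i].sum(), m[j].sum()
            s = int((m[i] & m[j]).sum())
            pairs.append((ri - s) * (rj - s))
        assert cscore(m) == pytest.approx(np.mean(pairs))

    def test_null_preserves_margins_and_seeded(self, rng):
        m = (rng.random((10, 12)) < 0.4).astype(int)
        m[0, 0] = 1
        a = cscore_test(m, n_null=99, seed=3)
        b = cscore_test(m, n_null=99, seed=3)
        assert a.observed == b.observed and a.ses == b.ses
        assert a.n_null == 99

    def test_degenerate_rows_warn(self):
        m = np.array([[1, 1, 1], [1, 0, 1], [0, 1, 1], [1, 1, 0]])
        with pytest.warns(UserWarning, match="degenerate"):
            cscore_test(m, n_null=99, seed=0)

    def test_n_null_floor(self):
        with pytest.raises(ValidationError):
            cscore_test(np.eye(3, dtype=int), n_null=10)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

class TestInferNetwork:
    def make_table(self, mat: np.ndarray) -> CountTable:
        return CountTable(
            pd.DataFrame(
                mat.astype(int),
                index=[f"t{i}" for i in range(mat.shape[0])],
                columns=[f"s{j}" for j in range(mat.shape[1])],
            )
        )

    def test_proportional_taxa_edge_r1(self, rng):
        base = rng.integers(10, 100, 30)
        other = rng.integers(20, 200, 30)
        mat = np.vstack([base, 2 * base, other])
        net = infer_network(self.make_table(mat), min_samples=10)
        row = net.edges[(net.edges.taxon_a == "t0") & (net.edges.taxon_b == "t1")]
        assert len(row) == 1 and row.iloc[0]["sign"] == "positive"
        assert row.iloc[0]["r"] > 0.99

    def test_threshold_excludes_r_below_0_6(self, rng):
        # pair with r ~ 0.59 (below the inclusive 0.6 cutoff); a filler taxon
        # keeps sample totals constant so closure cannot distort the correlation
        n = 200
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 -= z2.mean() + z1 * (z1 @ z2) / (z1 @ z1)  # exact Gram-Schmidt
        z2 /= z2.std()
        rho = 0.59
        t0 = np.round(1000 + 100 * z1).astype(int)
        t1 = np.round(1000 + 100 * (rho * z1 + np.sqrt(1 - rho**2) * z2)).astype(int)
        filler = 50_000 - t0 - t1
        t = self.make_table(np.vstack([t0, t1, filler]))
        r = np.corrcoef(t.relative_abundance().to_numpy())[0, 1]
        assert 0.55 < r < 0.6  # p is tiny at n=200, so only the r rule can exclude
        net = infer_network(t, min_samples=10)
        assert not (
            ((net.edges.taxon_a == "t0") & (net.edges.taxon_b == "t1")).any()
        )

    def test_min_samples_guard(self, rng):
        mat = rng.integers(1, 50, (4, 5))
        with pytest.raises(ValidationError, match="insufficient"):
            infer_network(self.make_table(mat))

    def test_edges_satisfy_threshold_rule(self, rng):
        mat = rng.integers(0, 60, (15, 25)) + 1
        net = infer_network(self.make_table(mat), r_threshold=0.3, p_max=0.05, min_samples=10)
        net.validate_edges()  # asserts |r| >= threshold and p <= p_max on every edge


# ---------------------------------------------------------------------------
# Node metrics vs brute force
# ---------------------------------------------------------------------------

def brute_force_metrics(g: nx.Graph):
    """Exhaustive-path oracle for degree, scaled closeness, and betweenness."""
    nodes = list(g.nodes())
    n = len(nodes)
    sp = dict(nx.all_pairs_shortest_path_length(g))
    k = {v: g.degree(v) for v in nodes}
    cc = {}
    for v in nodes:
        reach = [u for u in nodes if u != v and u in sp[v]]
        if not reach:
            cc[v] = 0.0
            continue
        total = sum(sp[v][u] for u in reach)
        cc[v] = (len(reach) / total) * (len(reach) / (n - 1))
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in sp[s]:
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p) / len(paths)
            bc[v] += frac
    norm = (n - 1) * (n - 2) / 2
    bc = {v: val / norm if norm > 0 else 0.0 for v, val in bc.items()}
    return k, cc, bc


class TestNodeMetrics:
    def test_path_graph_center(self):
        g = nx.path_graph(["A", "B", "C"])
        m = node_metrics(net_from_graph(g))
        assert m.loc["B", "betweenness"] == 1.0
        assert m.loc["B", "closeness"] == 1.0

    def test_complete_graph_no_betweenness(self):
        g = nx.complete_graph(6)
        m = node_metrics(net_from_graph(g))
        assert (m["betweenness"] == 0).all()

    def test_random_graphs_match_brute_force(self, rng):
        """degree/closeness/betweenness equal the exhaustive-path oracle, n <= 10."""
        for trial in range(100):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.7), seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            m = node_metrics(net_from_graph(g))
            k, cc, bc = brute_force_metrics(g)
            for v in g.nodes():
                assert m.loc[v, "degree"] == k[v]
                assert m.loc[v, "closeness"] == pytest.approx(cc[v], abs=1e-12)
                assert m.loc[v, "betweenness"] == pytest.approx(bc[v], abs=1e-12)


# ---------------------------------------------------------------------------
# Modules and keystones
# ---------------------------------------------------------------------------

class TestModules:
    def test_two_triangles_q_half(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        res = detect_modules(net_from_graph(g))
        assert res["Q"] == pytest.approx(0.5)
        assert res["n_modules"] == 2

    def test_single_community_q_zero(self):
        g = nx.complete_graph(5)
        assert modularity_q(g, {v: 0 for v in g.nodes()}) == pytest.approx(0.0, abs=1e-12)

    def test_reported_q_matches_definition(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(int(rng.integers(5, 12)), 0.4, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            res = detect_modules(net_from_graph(g))
            assert res["Q"] == pytest.approx(modularity_q(g, res["partition"]), abs=1e-12)

    def test_edgeless_network(self):
        g = nx.empty_graph(4)
        res = detect_modules(net_from_graph(g))
        assert res["Q"] == 0.0 and res["n_modules"] == 4

    def test_louvain_seeded(self):
        g = nx.karate_club_graph()
        a = detect_modules(net_from_graph(g), method="louvain", seed=5)
        b = detect_modules(net_from_graph(g), method="louvain", seed=5)
        assert a["partition"] == b["partition"]


class TestKeystones:
    def test_regular_ring_no_keystones(self):
        g = nx.cycle_graph(8)
        net = net_from_graph(g)
        node_metrics(net)
        assert keystone_taxa(net) == []

    def test_star_center_only(self):
        g = nx.star_graph(6)  # center 0, leaves 1..6
        net = net_from_graph(g)
        node_metrics(net)
        assert keystone_taxa(net) == [0]

    def test_relabeling_invariance(self, rng):
        g = nx.gnp_random_graph(12, 0.3, seed=9)
        net = net_from_graph(g)
        node_metrics(net)
        ks = set(keystone_taxa(net))
        mapping = {v: f"x{v}" for v in g.nodes()}
        net2 = net_from_graph(nx.relabel_nodes(g, mapping))
        node_metrics(net2)
        assert set(keystone_taxa(net2)) == {mapping[v] for v in ks}

    def test_small_network_empty_with_warning(self):
        g = nx.path_graph(3)
        net = net_from_graph(g)
        node_metrics(net)
        with pytest.warns(UserWarning):
            assert keystone_taxa(net) == []


# ---------------------------------------------------------------------------
# Zone summaries
# ---------------------------------------------------------------------------

class TestZoneSummary:
    def fixture(self):
        rows = []
        for i, (zone, hab) in enumerate(
            [("main-channel", "riffle")] * 3 + [("off-channel", "pond")] * 3
        ):
            rows.append(
                {
                    "sample_id": f"s{i}",
                    "biome": "montane",
                    "floodplain": "F",
                    "zone": zone,
                    "habitat": hab,
                    "x": 0.0,
                    "y": float(i),
                }
            )
        h = SampleHierarchy(pd.DataFrame(rows).set_index("sample_id"))
        counts = pd.DataFrame(
            {  # t0,t1 main-channel-affine; t2,t3 off-channel-affine
                "s0": [30, 28, 2, 1],
                "s1": [32, 30, 1, 2],
                "s2": [29, 31, 2, 1],
                "s3": [2, 1, 30, 29],
                "s4": [1, 2, 28, 31],
                "s5": [2, 2, 31, 30],
            },
            index=["t0", "t1", "t2", "t3"],
        )
        return CountTable(counts), h

    def test_affinity(self):
        t, h = self.fixture()
        aff = zone_affinity(t, h)
        assert aff["t0"] == "main-channel" and aff["t3"] == "off-channel"

    def test_hand_tally(self):
        t, h = self.fixture()
        g = nx.Graph()
        g.add_edge("t0", "t1", r=0.9)
        g.add_edge("t2", "t3", r=0.8)
        g.add_edge("t0", "t2", r=-0.7)
        edges = pd.DataFrame(
            [
                {"taxon_a": "t0", "taxon_b": "t1", "r": 0.9, "p": 0.001, "sign": "positive"},
                {"taxon_a": "t2", "taxon_b": "t3", "r": 0.8, "p": 0.001, "sign": "positive"},
                {"taxon_a": "t0", "taxon_b": "t2", "r": -0.7, "p": 0.001, "sign": "negative"},
            ]
        )
        net = CooccurrenceNetwork(graph=g, edges=edges)
        s = zone_edge_summary(net, h, t)
        assert s["same_zone_positive"] == 2
        assert s["cross_zone_negative"] == 1
        assert s["pct_negative"] == pytest.approx(100 / 3)

    def test_all_positive_same_zone(self):
        t, h = self.fixture()
        g = nx.Graph()
        g.add_edge("t0", "t1", r=0.9)
        edges = pd.DataFrame(
            [{"taxon_a": "t0", "taxon_b": "t1", "r": 0.9, "p": 0.001, "sign": "positive"}]
        )
        s = zone_edge_summary(CooccurrenceNetwork(graph=g, edges=edges), h, t)
        assert s["pct_positive"] == 100.0 and s["cross_zone_positive"] == 0
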