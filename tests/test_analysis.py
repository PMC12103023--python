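"""DTG statistics, module stability, topology metrics, cluster profiling."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from signedrole import (
    EmbeddingTable,
    SignedNetwork,
    classify_dtgs,
    cluster_profile,
    gene_distances,
    gene_sd,
    louvain_modules,
    merge_networks,
    module_stability,
    topology_metrics,
)
from signedrole.analysis import METRIC_COLUMNS
from signedrole.simulate import make_scale_free


def table_for(merged, vectors):
    """EmbeddingTable from {gene::context: vector}."""
    ids = list(vectors)
    mat = np.array([vectors[i] for i in ids], dtype=float)
    return EmbeddingTable(dim=mat.shape[1], ids=ids, matrix=mat)


def two_ctx(genes):
    pos = {(a, b) for a, b in zip(genes, genes[1:])}
    nets = [
        SignedNetwork(pos_edges=pos, neg_edges=set(), context=c) for c in ("c1", "c2")
    ]
    return merge_networks(nets)


class TestGeneDistances:
    def test_identical_vectors_zero_distance(self):
        m = two_ctx(["A", "B"])
        emb = table_for(m, {"A::c1": [1, 2], "A::c2": [1, 2], "B::c1": [0, 0], "B::c2": [0, 0]})
        cen, d, dbar = gene_distances(emb, m, "A")
        assert all(v == pytest.approx(0) for v in d.values()) and dbar == 0

    def test_pair_midpoint_geometry(self):
        m = two_ctx(["A", "B"])
        emb = table_for(m, {"A::c1": [0, 0], "A::c2": [2, 0], "B::c1": [0, 0], "B::c2": [0, 0]})
        cen, d, dbar = gene_distances(emb, m, "A")
        np.testing.assert_allclose(cen, [1, 0])
        assert d["c1"] == pytest.approx(1) and d["c2"] == pytest.approx(1)
        assert dbar == pytest.approx(1)

    def test_pair_distances_are_half_the_separation(self, rng):
        m = two_ctx(["A", "B"])
        v1, v2 = rng.normal(size=4), rng.normal(size=4)
        emb = table_for(
            m,
            {"A::c1": v1, "A::c2": v2, "B::c1": np.zeros(4), "B::c2": np.zeros(4)},
        )
        _, d, _ = gene_distances(emb, m, "A")
        half = 0.5 * np.linalg.norm(v1 - v2)
        assert d["c1"] == pytest.approx(half, abs=1e-9)
        assert d["c2"] == pytest.approx(half, abs=1e-9)

    def test_three_context_hand_arithmetic(self):
        nets = [
            SignedNetwork(pos_edges={("A", "B")}, neg_edges=set(), context=c)
            for c in ("c1", "c2", "c3")
        ]
        m = merge_networks(nets)
        vecs = {"A::c1": [0, 0], "A::c2": [3, 0], "A::c3": [0, 4]}
        vecs.update({f"B::{c}": [0, 0] for c in ("c1", "c2", "c3")})
        emb = table_for(m, vecs)
        cen, d, dbar = gene_distances(emb, m, "A")
        np.testing.assert_allclose(cen, [1, 4 / 3], atol=1e-12)
        expect = {
            "c1": math.hypot(1, 4 / 3),
            "c2": math.hypot(2, 4 / 3),
            "c3": math.hypot(1, 8 / 3),
        }
        for c in expect:
            assert d[c] == pytest.approx(expect[c], abs=1e-9)
        assert dbar == pytest.approx(np.mean(list(expect.values())), abs=1e-9)

    def test_missing_context_raises(self):
        m = two_ctx(["A", "B"])
        emb = table_for(m, {"A::c1": [0.0, 0], "B::c1": [0, 0], "B::c2": [0, 0]})
        with pytest.raises(KeyError, match="c2"):
            gene_distances(emb, m, "A")


class TestGeneSd:
    def test_equal_distances_zero(self):
        assert gene_sd([2.0, 2.0, 2.0]) == 0.0

    def test_pair_closed_form(self):
        assert gene_sd([0.0, 2.0]) == pytest.approx(1.0)

    def test_population_sd_three_values(self):
        assert gene_sd([1.0, 2.0, 3.0]) == pytest.approx(math.sqrt(2 / 3), abs=1e-9)


class TestClassifyDtgs:
    def _report(self, distances, sds=None):
        n = len(distances)
        df = pd.DataFrame(
            {
                "mean_distance": distances,
                "sd": sds if sds is not None else np.zeros(n),
            },
            index=pd.Index([f"g{i:03d}" for i in range(n)], name="gene"),
        )
        return df

    def test_pair_mode_flags_exact_ceiling(self, rng):
        df = classify_dtgs(self._report(rng.permutation(200).astype(float)), C=2)
        assert (df["flag"] == "dtg_mean").sum() == 20
        flagged = set(df[df["flag"] == "dtg_mean"].index)
        top = set(df.nlargest(20, "mean_distance").index)
        assert flagged == top

    def test_degenerate_equal_distances_still_flags_rank_count(self):
        df = classify_dtgs(self._report(np.zeros(50)), C=2)
        assert (df["flag"] == "dtg_mean").sum() == 5  # ceil(0.1 * 50)

    def test_tie_break_is_deterministic_by_gene_id(self):
        df = classify_dtgs(self._report(np.ones(30)), C=2)
        flagged = sorted(df[df["flag"] == "dtg_mean"].index)
        assert flagged == [f"g{i:03d}" for i in range(3)]

    def test_multi_mode_mean_and_sd_rules(self, rng):
        d = np.linspace(0, 1, 100)
        sds = np.zeros(100)
        sds[:5] = 0.9  # low-distance genes with high variability
        df = classify_dtgs(self._report(d, sds), C=5, sd_threshold=0.4)
        assert (df["flag"] == "dtg_mean").sum() == 5  # ceil(0.05*100)
        assert set(df[df["flag"] == "dtg_sd"].index) == {f"g{i:03d}" for i in range(5)}

    def test_auto_sd_threshold_uses_95th_percentile(self, rng):
        sds = rng.random(200)
        df = classify_dtgs(self._report(np.zeros(200), sds), C=3, sd_threshold="auto")
        thr = np.quantile(sds, 0.95)
        assert df.attrs["sd_threshold"] == pytest.approx(thr)

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            classify_dtgs(self._report(np.array([])), C=2)


def clique_edges(names):
    return set(itertools.combinations(sorted(names), 2))


class TestLouvainModules:
    def test_dumbbell_two_modules(self):
        a = [f"a{i}" for i in range(15)]
        b = [f"b{i}" for i in range(15)]
        pos = clique_edges(a) | clique_edges(b) | {("a0", "b0")}
        net = SignedNetwork(pos_edges=pos, neg_edges=set())
        part = louvain_modules(net, min_size=10, seed=0)
        assert sorted(map(len, part.retained)) == [15, 15]
        assert {frozenset(a), frozenset(b)} == set(part.retained)

    def test_small_module_excluded(self):
        a = [f"a{i}" for i in range(15)]
        b = [f"b{i}" for i in range(15)]
        c = [f"c{i}" for i in range(5)]
        pos = (
            clique_edges(a)
            | clique_edges(b)
            | clique_edges(c)
            | {("a0", "b0"), ("b1", "c0")}
        )
        net = SignedNetwork(pos_edges=pos, neg_edges=set())
        part = louvain_modules(net, min_size=10, seed=0)
        assert sorted(map(len, part.retained)) == [15, 15]
        assert len(part.modules) == 3  # the 5-clique is found but not retained

    def test_all_modules_small_warns(self):
        net = SignedNetwork(pos_edges={("a", "b"), ("c", "d")}, neg_edges=set())
        with pytest.warns(UserWarning, match="smaller"):
            part = louvain_modules(net, min_size=10, seed=0)
        assert part.retained == []


class TestModuleStability:
    def _setup(self, module_genes, shared, dists):
        """Anchor module of ``module_genes``; ``shared`` of them exist in c2
        with embedding shift ``dists``."""
        pos1 = clique_edges(module_genes)
        n1 = SignedNetwork(pos_edges=pos1, neg_edges=set(), context="c1")
        pos2 = clique_edges(shared) if len(shared) > 1 else {(shared[0], "zzz")}
        n2 = SignedNetwork(pos_edges=pos2, neg_edges=set(), context="c2")
        m = merge_networks([n1, n2])
        vecs = {}
        for g in module_genes:
            vecs[f"{g}::c1"] = [0.0, 0.0]
        for g, d in zip(shared, dists):
            vecs[f"{g}::c2"] = [d, 0.0]
        if len(shared) == 1:
            vecs["zzz::c2"] = [0.0, 0.0]
        emb = table_for(m, vecs)
        from signedrole.analysis import ModulePartition

        part = ModulePartition(modules=[frozenset(module_genes)], min_size=1)
        return part, emb, m

    def test_fully_shared_identical_embeddings(self):
        genes = [f"m{i}" for i in range(10)]
        part, emb, m = self._setup(genes, genes, [0.0] * 10)
        rep = module_stability(part, emb, m, "c1", "c2")
        assert rep.loc[0, "mean_distance"] == pytest.approx(0)
        assert rep.loc[0, "na_pct"] == pytest.approx(0)

    def test_half_shared_na_fraction(self):
        genes = [f"m{i}" for i in range(10)]
        part, emb, m = self._setup(genes, genes[:5], [1.0] * 5)
        rep = module_stability(part, emb, m, "c1", "c2")
        assert rep.loc[0, "na_pct"] == pytest.approx(0.5)

    def test_mean_distance_hand_example(self):
        genes = ["m0", "m1", "m2", "m3"]
        part, emb, m = self._setup(genes, genes, [1.0, 1.0, 2.0, 4.0])
        rep = module_stability(part, emb, m, "c1", "c2")
        assert rep.loc[0, "mean_distance"] == pytest.approx(2.0, abs=1e-9)

    def test_empty_intersection_gives_nan_and_full_na(self):
        genes = [f"m{i}" for i in range(6)]
        n1 = SignedNetwork(pos_edges=clique_edges(genes), neg_edges=set(), context="c1")
        n2 = SignedNetwork(pos_edges={("x", "y")}, neg_edges=set(), context="c2")
        m = merge_networks([n1, n2])
        emb = table_for(
            m,
            {f"{g}::c1": [0.0, 0] for g in genes}
            | {"x::c2": [0.0, 0], "y::c2": [0.0, 0]},
        )
        from signedrole.analysis import ModulePartition

        part = ModulePartition(modules=[frozenset(genes)], min_size=1)
        rep = module_stability(part, emb, m, "c1", "c2")
        assert math.isnan(rep.loc[0, "mean_distance"])
        assert rep.loc[0, "na_pct"] == pytest.approx(1.0)

    def test_invariant_to_member_order(self):
        genes = [f"m{i}" for i in range(8)]
        part, emb, m = self._setup(genes, genes, list(range(8)))
        from signedrole.analysis import ModulePartition

        rev = ModulePartition(modules=[frozenset(reversed(genes))], min_size=1)
        r1 = module_stability(part, emb, m, "c1", "c2")
        r2 = module_stability(rev, emb, m, "c1", "c2")
        assert r1.loc[0, "mean_distance"] == pytest.approx(r2.loc[0, "mean_distance"])


def brute_force_metrics(net):
    """Independent recomputation: triangle counting for clustering,
    all-pairs shortest paths for betweenness, power iteration for
    eigenvector centrality."""
    nodes = sorted(net.nodes)
    n = len(nodes)
    out = {}
    degs = net.signed_degrees()
    union = net.to_networkx("union")
    # betweenness via explicit path enumeration
    btw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(union, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            btw[v] += frac
    norm = 2 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    # eigenvector by long power iteration on the union adjacency
    A = nx.to_numpy_array(union, nodelist=nodes)
    x = np.ones(n) / math.sqrt(n)
    for _ in range(10000):
        y = A @ x
        if np.linalg.norm(y) == 0:
            break
        x = y / np.linalg.norm(y)
    for i, u in enumerate(nodes):
        dp, dn = degs[u]
        row = {
            "degree_centrality_pos": dp / (n - 1),
            "degree_centrality_neg": dn / (n - 1),
            "betweenness": btw[u] * norm,
            "eigenvector": x[i],
        }
        for sign, cname in (("pos", "clustering_pos"), ("neg", "clustering_neg")):
            sub = net.to_networkx(sign)
            if u not in sub or sub.degree(u) < 2:
                row[cname] = 0.0
            else:
                nbrs = list(sub.neighbors(u))
                links = sum(
                    1 for a, b in itertools.combinations(nbrs, 2) if sub.has_edge(a, b)
                )
                row[cname] = 2 * links / (len(nbrs) * (len(nbrs) - 1))
        out[u] = row
    return out


class TestTopologyMetrics:
    def test_positive_clique_clustering_one(self):
        net = SignedNetwork(pos_edges=clique_edges("abcd"), neg_edges=set())
        df = topology_metrics(net)
        assert np.allclose(df["clustering_pos"], 1.0)

    def test_star_center_degree_centrality(self):
        net = SignedNetwork(
            pos_edges={("h", x) for x in "abcd"}, neg_edges=set()
        )
        df = topology_metrics(net)
        assert df.loc["h", "degree_centrality_pos"] == pytest.approx(1.0)

    def test_path_middle_betweenness(self):
        net = SignedNetwork(pos_edges={("a", "b"), ("b", "c")}, neg_edges=set())
        df = topology_metrics(net)
        assert df.loc["b", "betweenness"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_on_small_graphs(self, seed):
        net = make_scale_free(12, 2, 0.4, seed=seed)
        df = topology_metrics(net)
        oracle = brute_force_metrics(net)
        for u in sorted(net.nodes):
            for col in (
                "degree_centrality_pos",
                "degree_centrality_neg",
                "betweenness",
                "clustering_pos",
                "clustering_neg",
            ):
                assert df.loc[u, col] == pytest.approx(oracle[u][col], abs=1e-9), (u, col)
            assert df.loc[u, "eigenvector"] == pytest.approx(
                oracle[u]["eigenvector"], abs=1e-5
            )

    def test_assortativity_matches_networkx_on_sign_subgraphs(self):
        net = make_scale_free(12, 2, 0.5, seed=3)
        df = topology_metrics(net)
        for sign, col in (("pos", "assortativity_pos"), ("neg", "assortativity_neg")):
            sub = net.to_networkx(sign)
            if sub.number_of_edges() >= 2:
                r = nx.degree_assortativity_coefficient(sub)
                vals = df.loc[sorted(sub.nodes()), col]
                if math.isnan(r):
                    assert vals.isna().all()
                else:
                    assert np.allclose(vals, r)


class TestClusterProfile:
    def _embedding_for(self, net, groups):
        vecs = {}
        for u in net.nodes:
            g = groups[u]
            vecs[u] = [float(g) * 10, float(g) * 10]
        ids = sorted(vecs)
        return EmbeddingTable(
            dim=2, ids=ids, matrix=np.array([vecs[u] for u in ids])
        )

    def test_k1_reproduces_global_means(self):
        net = make_scale_free(20, 2, 0.3, seed=1)
        emb = self._embedding_for(net, dict.fromkeys(net.nodes, 0))
        prof = cluster_profile(emb, net, K=1, seed=0)
        global_means = topology_metrics(net).mean()
        for col in METRIC_COLUMNS:
            if not math.isnan(global_means[col]):
                assert prof.means.loc[0, col] == pytest.approx(global_means[col])

    def test_duplicate_groups_recovered_exactly(self):
        net = make_scale_free(20, 2, 0.3, seed=2)
        nodes = sorted(net.nodes)
        groups = {u: int(i < 10) for i, u in enumerate(nodes)}
        emb = self._embedding_for(net, groups)
        prof = cluster_profile(emb, net, K=2, seed=0)
        labels = prof.assignments
        assert len(set(labels[u] for u in nodes[:10])) == 1
        assert len(set(labels[u] for u in nodes[10:])) == 1
        assert labels[nodes[0]] != labels[nodes[-1]]

    def test_row_scaling_spans_unit_interval(self):
        net = make_scale_free(40, 2, 0.3, seed=3)
        rng = np.random.default_rng(0)
        ids = sorted(net.nodes)
        emb = EmbeddingTable(dim=4, ids=ids, matrix=rng.normal(size=(len(ids), 4)))
        prof = cluster_profile(emb, net, K=5, seed=0)
        for col in prof.scaled.columns:
            vals = prof.scaled[col].dropna()
            if len(vals):
                assert vals.min() == pytest.approx(0.0)
                assert vals.max() == pytest.approx(1.0)
                assert ((vals >= -1e-12) & (vals <= 1 + 1e-12)).all()

    def test_k_exceeding_nodes_rejected(self):
        net = make_scale_free(8, 2, 0.3, seed=4)
        ids = sorted(net.nodes)
        emb = EmbeddingTable(dim=2, ids=ids, matrix=np.zeros((len(ids), 2)))
        with pytest.raises(ValueError):
            cluster_profile(emb, net, K=20, seed=0)
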