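"""Downstream comparative statistics on role embeddings.

* Differentially topological genes (DTGs): for a gene embedded in C
  contexts, the centroid of its context vectors, the per-context Euclidean
  distances to that centroid, their mean, and (for C > 2) their population
  standard deviation.  Genes in the top 10% of distances (C = 2) or the top
  5% of mean distances / above an SD threshold (C > 2) are flagged.
* Gene-module stability: Louvain modules of an anchor context are scored in
  a second context by the mean embedding shift of shared genes and by NA%,
  the fraction of module genes absent from the other context.
* Signed topology metrics and K-means cluster profiling of embeddings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .embedding import EmbeddingTable
from .network import MergedNetwork, SignedNetwork

__all__ = [
    "gene_distances",
    "gene_sd",
    "dtg_report",
    "classify_dtgs",
    "louvain_modules",
    "module_stability",
    "topology_metrics",
    "cluster_profile",
]

METRIC_COLUMNS = [
    "degree_centrality_pos",
    "degree_centrality_neg",
    "betweenness",
    "eigenvector",
    "assortativity_pos",
    "assortativity_neg",
    "clustering_pos",
    "clustering_neg",
]


# ----------------------------------------------------------------------
# DTG identification
# ----------------------------------------------------------------------

def gene_distances(
    emb: EmbeddingTable, merged: MergedNetwork, gene: str
) -> tuple[np.ndarray, dict[str, float], float]:
    """Centroid, per-context centroid distances, and their mean for a gene.

    The centroid is the arithmetic mean of the gene's context vectors; each
    per-context distance is the Euclidean norm to it.  The gene must be
    present (non-isolated) in every context.
    """
    vecs = {}
    for ctx in merged.contexts:
        nid = merged.node_id(gene, ctx)
        if nid not in emb:
            raise KeyError(f"gene {gene!r} has no embedding in context {ctx!r}")
        vecs[ctx] = emb[nid]
    cen = np.mean(list(vecs.values()), axis=0)
    d = {c: float(np.linalg.norm(v - cen)) for c, v in vecs.items()}
    return cen, d, float(np.mean(list(d.values())))


def gene_sd(distances: dict[str, float] | list[float]) -> float:
    """Population SD (divide by C) of a gene's per-context distances."""
    vals = np.asarray(
        list(distances.values()) if isinstance(distances, dict) else distances,
        dtype=float,
    )
    if vals.size < 2:
        raise ValueError("SD needs >= 2 contexts")
    return float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))


def dtg_report(
    emb: EmbeddingTable,
    merged: MergedNetwork,
    top_frac_pair: float = 0.10,
    top_frac_multi: float = 0.05,
    sd_threshold: float | str = 0.4,
) -> pd.DataFrame:
    """Per-gene distance table with DTG flags, over genes shared by all
    contexts.  Genes missing from any context are excluded (their exclusion
    reason is recoverable from the merged gene sets)."""
    contexts = merged.contexts
    shared = sorted(merged.shared_genes())
    shared = [g for g in shared if all(merged.node_id(g, c) in emb for c in contexts)]
    if not shared:
        raise ValueError("no gene is present in every context")
    rows = []
    for g in shared:
        _, d, dbar = gene_distances(emb, merged, g)
        row = {"gene": g, "mean_distance": dbar}
        for c in contexts:
            row[f"d_{c}"] = d[c]
        row["sd"] = gene_sd(d)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene")
    return classify_dtgs(
        df,
        C=len(contexts),
        top_frac_pair=top_frac_pair,
        top_frac_multi=top_frac_multi,
        sd_threshold=sd_threshold,
    )


def classify_dtgs(
    report: pd.DataFrame,
    C: int,
    top_frac_pair: float = 0.10,
    top_frac_multi: float = 0.05,
    sd_threshold: float | str = 0.4,
) -> pd.DataFrame:
    """Assign DTG flags to a distance table.

    C = 2: the ceil(top_frac_pair * N) genes with the largest mean distance
    are flagged ``dtg_mean`` (rank-based, so the degenerate all-equal case
    still flags exactly that count).  C > 2: genes whose mean distance falls
    in the top ``top_frac_multi`` fraction are ``dtg_mean``; remaining genes
    whose SD exceeds ``sd_threshold`` (a float, or ``"auto"`` for the 95th
    percentile of SDs) are ``dtg_sd``.  Ties break by (distance descending,
    gene id ascending).
    """
    if len(report) == 0:
        raise ValueError("no eligible genes")
    df = report.copy()
    order = df.assign(_g=df.index).sort_values(
        ["mean_distance", "_g"], ascending=[False, True], kind="mergesort"
    )
    n = len(df)
    df["flag"] = "not_dtg"
    if C == 2:
        k = math.ceil(top_frac_pair * n)
        df.loc[order.index[:k], "flag"] = "dtg_mean"
    else:
        k = math.ceil(top_frac_multi * n)
        df.loc[order.index[:k], "flag"] = "dtg_mean"
        thr = (
            float(np.quantile(df["sd"], 0.95))
            if isinstance(sd_threshold, str) and sd_threshold == "auto"
            else float(sd_threshold)
        )
        sd_hits = (df["sd"] > thr) & (df["flag"] == "not_dtg")
        df.loc[sd_hits, "flag"] = "dtg_sd"
        df.attrs["sd_threshold"] = thr
    df.attrs["C"] = C
    return df


# ----------------------------------------------------------------------
# Gene modules
# ----------------------------------------------------------------------

@dataclass
class ModulePartition:
    """Louvain modules of one network (unsigned union graph)."""

    modules: list[frozenset[str]]
    min_size: int

    @property
    def retained(self) -> list[frozenset[str]]:
        return [m for m in self.modules if len(m) >= self.min_size]


def louvain_modules(
    net: SignedNetwork, min_size: int = 10, seed: int = 0
) -> ModulePartition:
    """Louvain community detection on the unsigned union graph.

    Signs are ignored for module finding (modularity is undefined with
    negative weights) but preserved everywhere else.  Modules smaller than
    ``min_size`` are excluded from downstream stability reports; a warning
    is issued if nothing survives.
    """
    g = net.to_networkx("union")
    comms = nx.community.louvain_communities(g, seed=seed)
    modules = sorted(
        (frozenset(c) for c in comms), key=lambda m: (-len(m), min(m))
    )
    part = ModulePartition(modules=modules, min_size=min_size)
    if not part.retained:
        warnings.warn(f"all {len(modules)} modules are smaller than {min_size}")
    return part


def module_stability(
    modules: ModulePartition,
    emb: EmbeddingTable,
    merged: MergedNetwork,
    anchor: str,
    other: str,
) -> pd.DataFrame:
    """Stability of each retained anchor-context module in another context.

    mean_distance = mean over module genes shared with the other context of
    the embedding shift ||emb_u(anchor) - emb_u(other)||; NA% = fraction of
    module genes absent from the other context.  An empty intersection
    yields NaN mean distance and NA% = 1.
    """
    other_genes = merged.network(other).nodes
    rows = []
    for mid, mod in enumerate(modules.retained):
        inter = sorted(mod & other_genes)
        inter = [
            g
            for g in inter
            if merged.node_id(g, anchor) in emb and merged.node_id(g, other) in emb
        ]
        if inter:
            dist = float(
                np.mean(
                    [
                        emb.distance(
                            merged.node_id(g, anchor), merged.node_id(g, other)
                        )
                        for g in inter
                    ]
                )
            )
        else:
            dist = float("nan")
        rows.append(
            {
                "module": mid,
                "size": len(mod),
                "mean_distance": dist,
                "na_pct": 1.0 - len(inter) / len(mod),
                "members": ",".join(sorted(mod)),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Topology metrics and cluster profiling
# ----------------------------------------------------------------------

def topology_metrics(
    net: SignedNetwork, centrality_graph: str = "union"
) -> pd.DataFrame:
    """Eight signed topology metrics per node.

    Degree centralities use d+/(n-1) and d-/(n-1) over the full node count;
    clustering and assortativity are computed on the sign-restricted
    subgraphs (the network-level assortativity value is attributed to every
    node carrying at least one edge of that sign, NaN elsewhere);
    betweenness and eigenvector centrality run on the unsigned union by
    default (``centrality_graph`` in {"union", "pos", "neg"}).
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    n = len(nodes)
    degs = net.signed_degrees()
    df = pd.DataFrame(index=pd.Index(nodes, name="gene"), columns=METRIC_COLUMNS, dtype=float)
    denom = max(n - 1, 1)
    df["degree_centrality_pos"] = [degs[u][0] / denom for u in nodes]
    df["degree_centrality_neg"] = [degs[u][1] / denom for u in nodes]
    g_cent = net.to_networkx(centrality_graph)
    g_cent.add_nodes_from(nodes)
    btw = nx.betweenness_centrality(g_cent, normalized=True)
    df["betweenness"] = [btw[u] for u in nodes]
    try:
        eig = nx.eigenvector_centrality(g_cent, max_iter=1000, tol=1e-8)
        df["eigenvector"] = [eig[u] for u in nodes]
    except nx.PowerIterationFailedConvergence:
        warnings.warn("eigenvector centrality failed to converge; reporting NaN")
        df["eigenvector"] = float("nan")
    for sign, col_a, col_c in (
        ("pos", "assortativity_pos", "clustering_pos"),
        ("neg", "assortativity_neg", "clustering_neg"),
    ):
        sub = net.to_networkx(sign)
        clus = nx.clustering(sub) if sub.number_of_nodes() else {}
        df[col_c] = [clus.get(u, 0.0) for u in nodes]
        if sub.number_of_edges() >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = nx.degree_assortativity_coefficient(sub)
        else:
            r = float("nan")
        in_sub = set(sub.nodes())
        df[col_a] = [r if u in in_sub else float("nan") for u in nodes]
    return df


@dataclass
class ClusterProfile:
    """Per-cluster mean topology metrics plus a min-max scaled copy for
    heatmap display (each metric scaled across clusters to [0, 1])."""

    assignments: pd.Series
    means: pd.DataFrame
    scaled: pd.DataFrame


def cluster_profile(
    emb: EmbeddingTable,
    net: SignedNetwork,
    K: int = 10,
    seed: int = 0,
    metrics: pd.DataFrame | None = None,
) -> ClusterProfile:
    """K-means clustering of gene embeddings profiled by topology metrics.

    Embeddings of the network's genes are clustered with seeded k-means++
    (10 restarts); the output is the mean of the eight metrics per cluster,
    with a per-metric min-max scaled copy (the heatmap convention: each
    metric row spans exactly [0, 1] across clusters).
    """
    from sklearn.cluster import KMeans

    genes = [u for u in sorted(net.nodes) if u in emb]
    if len(genes) < K:
        raise ValueError(f"K={K} exceeds the {len(genes)} embeddable genes")
    X = np.stack([emb[u] for u in genes])
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    assign = pd.Series(labels, index=pd.Index(genes, name="gene"), name="cluster")
    mt = metrics if metrics is not None else topology_metrics(net)
    mt = mt.loc[genes]
    means = mt.groupby(assign).mean()
    means.index.name = "cluster"
    rng_ = means.max() - means.min()
    scaled = (means - means.min()) / rng_.replace(0.0, np.nan)
    return ClusterProfile(assignments=assign, means=means, scaled=scaled)
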