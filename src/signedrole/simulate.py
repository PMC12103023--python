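"""Synthetic signed networks for testing and benchmarking.

GRNs are approximately scale-free, so the generators here build
preferential-attachment backbones and decorate them with signs, planted
structural twins, relabelled isomorphic copies, and targeted rewirings whose
ground truth is returned alongside the networks.  All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .network import MergedNetwork, SignedNetwork, merge_networks

__all__ = [
    "make_sim_tree",
    "make_scale_free",
    "make_twins",
    "make_iso_pair",
    "make_perturbed_pair",
    "make_multi_context",
]

Pair = tuple[str, str]


def make_sim_tree() -> SignedNetwork:
    """A fixed 31-gene tree with hub/fan/negative-leaf role structure.

    Root hub S0 activates five intermediate hubs S1..S5; each hub fans out
    to five leaves.  Two leaves (S9 under S1 and S15 under S2) attach by a
    single *negative* edge — a structurally equivalent pair that any
    sign-aware role embedding must place together.  All other edges are
    positive.  Deterministic (no seed).
    """
    pos: set[Pair] = set()
    neg: set[Pair] = set()
    hubs = [f"S{i}" for i in range(1, 6)]
    for h in hubs:
        pos.add(("S0", h))
    leaf = 6
    negative_leaves = {"S9", "S15"}
    for h in hubs:
        for _ in range(5):
            name = f"S{leaf}"
            if name in negative_leaves:
                neg.add((h, name))
            else:
                pos.add((h, name))
            leaf += 1
    return SignedNetwork(pos_edges=pos, neg_edges=neg, context=None)


def make_scale_free(
    n: int,
    m_attach: int = 2,
    neg_fraction: float = 0.3,
    seed: int = 0,
    prefix: str = "g",
) -> SignedNetwork:
    """Preferential-attachment signed network with ``m_attach * (n - m_attach)``
    edges, each independently negative with probability ``neg_fraction``."""
    if not (n > m_attach >= 1):
        raise ValueError("need n > m_attach >= 1")
    if not 0 <= neg_fraction <= 1:
        raise ValueError("neg_fraction must be in [0, 1]")
    g = nx.barabasi_albert_graph(n, m_attach, seed=int(seed))
    rng = np.random.default_rng(seed)
    pos: set[Pair] = set()
    neg: set[Pair] = set()
    for u, v in sorted(g.edges()):
        e = (f"{prefix}{u}", f"{prefix}{v}")
        if rng.random() < neg_fraction:
            neg.add(e)
        else:
            pos.add(e)
    return SignedNetwork(pos_edges=pos, neg_edges=neg)


def make_twins(
    n: int = 150,
    n_pairs: int = 10,
    m_attach: int = 2,
    neg_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[SignedNetwork, list[tuple[str, str]]]:
    """Scale-free network with ``n_pairs`` planted automorphic leaf pairs.

    Each planted pair consists of two new leaves attached to one anchor node
    by edges of the same sign: swapping the two leaves is a graph
    automorphism, so they are perfect structural twins.  Total node count is
    ``n`` (base of n - 2*n_pairs nodes plus the twin leaves).
    """
    base_n = n - 2 * n_pairs
    if base_n <= m_attach:
        raise ValueError("n too small for the requested number of twin pairs")
    net = make_scale_free(base_n, m_attach, neg_fraction, seed)
    rng = np.random.default_rng(seed + 1)
    anchors = rng.choice(sorted(net.nodes), size=n_pairs, replace=False)
    pos, neg = set(net.pos_edges), set(net.neg_edges)
    twins: list[tuple[str, str]] = []
    for p, anchor in enumerate(anchors):
        a, b = f"t{p}a", f"t{p}b"
        target = neg if rng.random() < neg_fraction else pos
        target.add((str(anchor), a))
        target.add((str(anchor), b))
        twins.append((a, b))
    return SignedNetwork(pos_edges=pos, neg_edges=neg), twins


def make_iso_pair(
    base: SignedNetwork, seed: int = 0, contexts: tuple[str, str] = ("c1", "c2")
) -> tuple[MergedNetwork, dict[str, str]]:
    """Merge ``base`` with a randomly relabelled isomorphic copy.

    Returns the merged two-context network and the isomorphism map from the
    first context's gene names onto the second's.
    """
    rng = np.random.default_rng(seed)
    names = sorted(base.nodes)
    permuted = [f"r{i}" for i in rng.permutation(len(names))]
    mapping = dict(zip(names, permuted))
    net_a = base.with_context(contexts[0])
    net_b = base.relabel(mapping).with_context(contexts[1])
    return merge_networks([net_a, net_b]), mapping


def _rewire_gene(
    gene: str,
    base_degree: tuple[int, int],
    pos: set[Pair],
    neg: set[Pair],
    candidates: list[str],
    rng: np.random.Generator,
) -> None:
    """Replace ``gene``'s incident edges in-place: same total degree as in
    the base network, new uniformly drawn neighbours, and d+ shifted by 1
    or 2 relative to the base so the signed degree moves by >= 2 in L1."""
    for e in [e for e in pos if gene in e]:
        pos.discard(e)
    for e in [e for e in neg if gene in e]:
        neg.discard(e)
    dp, dn = base_degree
    deg = dp + dn
    # shift d+ by t (and d- by -t): L1 change = 2t >= 2
    choices = [t for t in (-2, -1, 1, 2) if 0 <= dp + t <= deg]
    t = int(rng.choice(choices))
    new_dp = dp + t
    pool = [c for c in candidates if c != gene]
    nbrs = rng.choice(pool, size=deg, replace=False)
    order = rng.permutation(deg)
    for rank, idx in enumerate(order):
        u, v = (gene, str(nbrs[idx])) if gene <= str(nbrs[idx]) else (str(nbrs[idx]), gene)
        target = pos if rank < new_dp else neg
        other = neg if rank < new_dp else pos
        other.discard((u, v))  # avoid sign conflicts from collisions
        target.add((u, v))


def make_perturbed_pair(
    base: SignedNetwork,
    k_genes: int,
    seed: int = 0,
    contexts: tuple[str, str] = ("c1", "c2"),
) -> tuple[SignedNetwork, SignedNetwork, set[str]]:
    """Paired networks where ``k_genes`` randomly chosen genes are
    structurally rewired in the second copy.

    The rewiring keeps each selected gene's total degree (and hence the
    overall edge density comparable) but redraws its neighbours among the
    non-selected genes and shifts its positive/negative degree split by at
    least one edge, so its signed degree changes by >= 2 in L1 norm.
    Returns (net_A, net_B, perturbed gene set).
    """
    if k_genes >= base.n_nodes / 5:
        raise ValueError("k_genes must be < |V|/5 to bound collateral degree changes")
    rng = np.random.default_rng(seed)
    genes = sorted(base.nodes)
    selected = set() if k_genes == 0 else {
        str(g) for g in rng.choice(genes, size=k_genes, replace=False)
    }
    pos, neg = set(base.pos_edges), set(base.neg_edges)
    # drop edges between two selected genes first (redrawn by both endpoints)
    for e in [e for e in pos | neg if e[0] in selected and e[1] in selected]:
        pos.discard(e)
        neg.discard(e)
    candidates = [g for g in genes if g not in selected]
    degs = base.signed_degrees()
    for gene in sorted(selected):
        _rewire_gene(gene, degs[gene], pos, neg, candidates, rng)
        dp0, dn0 = degs[gene]
        dp1 = sum(1 for e in pos if gene in e)
        dn1 = sum(1 for e in neg if gene in e)
        assert abs(dp1 - dp0) + abs(dn1 - dn0) >= 2, gene
    net_a = base.with_context(contexts[0])
    net_b = SignedNetwork(pos_edges=pos, neg_edges=neg, context=contexts[1])
    return net_a, net_b, selected


def make_multi_context(
    base: SignedNetwork,
    C: int,
    k_genes_per_context: int,
    seed: int = 0,
) -> tuple[MergedNetwork, dict[str, list[str]]]:
    """C perturbed copies of ``base`` with two planted truth classes.

    ``k_genes_per_context`` genes are perturbed in *every* context
    (consistent role change -> high mean embedding distance) and another
    ``k_genes_per_context`` genes are each perturbed in exactly *one*
    context (state-specific change -> high distance SD).  Returns the merged
    network and ``{"all": [...], "single": [...]}`` truth lists.
    """
    if C < 3:
        raise ValueError("multi-context fixtures need C >= 3")
    rng = np.random.default_rng(seed)
    genes = sorted(base.nodes)
    k = k_genes_per_context
    chosen = rng.choice(genes, size=2 * k, replace=False)
    group_all = [str(g) for g in chosen[:k]]
    group_single = [str(g) for g in chosen[k:]]
    single_ctx = rng.integers(0, C, size=k)  # which context perturbs each
    nets = []
    for c in range(C):
        ctx = f"c{c + 1}"
        sel = set(group_all) | {
            g for g, sc in zip(group_single, single_ctx) if sc == c
        }
        if not sel:
            nets.append(base.with_context(ctx))
            continue
        pos, neg = set(base.pos_edges), set(base.neg_edges)
        for e in [e for e in pos | neg if e[0] in sel and e[1] in sel]:
            pos.discard(e)
            neg.discard(e)
        candidates = [g for g in genes if g not in sel]
        crng = np.random.default_rng(seed * 1000 + c + 1)
        base_degs = base.signed_degrees()
        for gene in sorted(sel):
            _rewire_gene(gene, base_degs[gene], pos, neg, candidates, crng)
        nets.append(SignedNetwork(pos_edges=pos, neg_edges=neg, context=ctx))
    truth = {"all": group_all, "single": group_single}
    return merge_networks(nets), truth
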