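"""Structural (role) dissimilarity between genes in signed networks.

The topological identity of a gene is summarised hop by hop: its own signed
degree (hop 0), then the sorted sequence of signed degrees of all genes
exactly k hops away (the "degree ring" R_k).  Two genes are compared with

* EBED — the exponential biased Euclidean distance between two signed
  degrees: ``exp(sqrt(ln^2((du+ +1)/(dv+ +1)) + ln^2((du- +1)/(dv- +1))))``.
  The log tames the power-law degree spread of GRNs and the outer exp
  restores the original scale; identical degrees give exactly 1.
* DTW — dynamic time warping with EBED as local cost aligns the (generally
  unequal-length) degree rings of the two genes at hop k, giving D_k.
* f_k — the cumulative dissimilarity f_0 = EBED(d_u, d_v),
  f_k = f_{k-1} + D_k.  Lower f_k = more similar structural roles.

Hops are measured on the unsigned union of E+ and E-: sign affects cost,
not reachability.  When one gene's ring at hop k is empty while the other's
is not (different eccentricities), the comparison truncates at hop k-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from numba import njit

from .network import MergedNetwork, SignedNetwork

__all__ = [
    "ebed",
    "signed_degree",
    "degree_rings",
    "dtw_distance",
    "dissimilarity_table",
    "DissimilarityTable",
]

NetworkLike = Union[SignedNetwork, MergedNetwork]

MAX_NODES_DEFAULT = 3000


def signed_degree(net: SignedNetwork, u: str) -> tuple[int, int]:
    """[d+, d-] for node ``u`` (delegates to the network container)."""
    return net.signed_degree(u)


def ebed(
    a: Sequence[int], b: Sequence[int], minus_one: bool = False
) -> float:
    """Exponential biased Euclidean distance between two signed degrees.

    Symmetric, >= 1, equal to 1 iff the degrees coincide (with
    ``minus_one=True`` the baseline shifts so identical degrees give 0; kept
    for sensitivity checks only).
    """
    ap, an = float(a[0]), float(a[1])
    bp, bn = float(b[0]), float(b[1])
    if min(ap, an, bp, bn) < 0:
        raise ValueError("signed degrees must be non-negative")
    d = np.exp(
        np.sqrt(
            np.log((ap + 1.0) / (bp + 1.0)) ** 2
            + np.log((an + 1.0) / (bn + 1.0)) ** 2
        )
    )
    return float(d - 1.0 if minus_one else d)


# ----------------------------------------------------------------------
# Degree rings
# ----------------------------------------------------------------------

def _ring_sort_key(d: tuple[int, int]) -> tuple[int, int, int]:
    # canonical order: total degree, then d+, then d-
    return (d[0] + d[1], d[0], d[1])


def degree_rings(
    net: SignedNetwork, u: str, k_max: int
) -> list[list[tuple[int, int]]]:
    """Sorted signed-degree sequences of the nodes exactly 0..k_max hops
    from ``u`` (hop 0 is u itself; hops on the unsigned union graph)."""
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if u not in net.nodes:
        raise KeyError(f"unknown node {u!r}")
    degs = net.signed_degrees()
    adj: dict[str, set[str]] = {n: set() for n in net.nodes}
    for a, b in net.pos_edges | net.neg_edges:
        adj[a].add(b)
        adj[b].add(a)
    rings: list[list[tuple[int, int]]] = [[degs[u]]]
    seen = {u}
    frontier = [u]
    for _ in range(k_max):
        nxt: set[str] = set()
        for n in frontier:
            nxt |= adj[n] - seen
        seen |= nxt
        frontier = sorted(nxt)
        rings.append(sorted((degs[n] for n in frontier), key=_ring_sort_key))
    return rings


# ----------------------------------------------------------------------
# DTW with EBED local cost (exact DP, numba)
# ----------------------------------------------------------------------

@njit(cache=True)
def _dtw_kernel(sp, sn, tp, tn, minus_one):  # pragma: no cover - jitted
    """Exact DTW over log-degree sequences; steps (1,0),(0,1),(1,1), sum
    aggregation.  sp/sn are ln(d+ +1)/ln(d- +1) for the first sequence."""
    ns, nt = sp.shape[0], tp.shape[0]
    big = 1e300
    prev = np.empty(nt + 1)
    cur = np.empty(nt + 1)
    for j in range(nt + 1):
        prev[j] = big
    prev[0] = 0.0
    for i in range(1, ns + 1):
        cur[0] = big
        for j in range(1, nt + 1):
            dp = sp[i - 1] - tp[j - 1]
            dn = sn[i - 1] - tn[j - 1]
            c = np.exp(np.sqrt(dp * dp + dn * dn))
            if minus_one:
                c -= 1.0
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        for j in range(nt + 1):
            prev[j] = cur[j]
        prev[0] = big
    return prev[nt]


def _log_arrays(seq: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(seq, dtype=np.float64).reshape(len(seq), 2)
    return np.log(arr[:, 0] + 1.0), np.log(arr[:, 1] + 1.0)


def dtw_distance(
    s: Sequence[Sequence[int]],
    t: Sequence[Sequence[int]],
    minus_one: bool = False,
) -> float:
    """DTW distance between two signed-degree sequences under EBED cost."""
    if len(s) == 0 or len(t) == 0:
        raise ValueError("DTW is undefined for empty sequences")
    sp, sn = _log_arrays(s)
    tp, tn = _log_arrays(t)
    return float(_dtw_kernel(sp, sn, tp, tn, minus_one))


# ----------------------------------------------------------------------
# All-pairs cumulative dissimilarity table
# ----------------------------------------------------------------------

@dataclass
class DissimilarityTable:
    """Cumulative structural dissimilarity f_k for all unordered node pairs.

    ``f`` has shape (k_max+1, n, n); NaN marks layers where a pair's
    comparison has been truncated (one ring empty).  Symmetric in the pair;
    the diagonal holds self-comparisons.
    """

    nodes: list[str]
    f: np.ndarray  # (k_max+1, n, n)
    minus_one: bool = False

    @property
    def k_max(self) -> int:
        return self.f.shape[0] - 1

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, u: str) -> int:
        return self.nodes.index(u)

    def value(self, k: int, u: str, v: str) -> float:
        return float(self.f[k, self.index(u), self.index(v)])

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, nodes=np.array(self.nodes), f=self.f, minus_one=self.minus_one
        )

    @classmethod
    def load(cls, path: str | Path) -> "DissimilarityTable":
        data = np.load(path, allow_pickle=False)
        return cls(
            nodes=[str(x) for x in data["nodes"]],
            f=data["f"],
            minus_one=bool(data["minus_one"]),
        )


@njit(cache=True)
def _all_pairs_kernel(k_max, offsets, logp, logn, minus_one, f_out):  # pragma: no cover
    """Fill f_out[(k_max+1, n, n)] with cumulative f_k; NaN past truncation.

    ``offsets[k, i]``..``offsets[k, i+1]`` indexes node i's ring-k entries in
    the flat ``logp``/``logn`` arrays (already canonically sorted; offsets
    are global positions across all hops).
    """
    n = offsets.shape[1] - 1
    for i in range(n):
        for j in range(i, n):
            acc = 0.0
            alive = True
            for k in range(k_max + 1):
                if not alive:
                    f_out[k, i, j] = np.nan
                    f_out[k, j, i] = np.nan
                    continue
                s0, s1 = offsets[k, i], offsets[k, i + 1]
                t0, t1 = offsets[k, j], offsets[k, j + 1]
                if s1 == s0 or t1 == t0:
                    alive = False
                    f_out[k, i, j] = np.nan
                    f_out[k, j, i] = np.nan
                    continue
                acc += _dtw_kernel(
                    logp[s0:s1], logn[s0:s1], logp[t0:t1], logn[t0:t1], minus_one
                )
                f_out[k, i, j] = acc
                f_out[k, j, i] = acc


def _collect_rings(
    nodes: list[str],
    degs: dict[str, tuple[int, int]],
    adj: dict[str, list[str]],
    k_max: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BFS rings for every node, flattened into one array for the kernel.

    Returns global offsets (k_max+1, n+1) into flat log(d+1) arrays; the
    segment for (k, i) is offsets[k, i]..offsets[k, i+1].
    """
    n = len(nodes)
    chunks: list[np.ndarray] = []
    offsets = np.zeros((k_max + 1, n + 1), dtype=np.int64)
    # per-node BFS; rings stored hop-major so one hop's segments are contiguous
    per_k: list[list[np.ndarray]] = [[] for _ in range(k_max + 1)]
    for u in nodes:
        seen = {u}
        frontier = [u]
        per_k[0].append(np.asarray([degs[u]], dtype=np.float64))
        for k in range(1, k_max + 1):
            nxt: set[str] = set()
            for a in frontier:
                for b in adj[a]:
                    if b not in seen:
                        nxt.add(b)
            seen |= nxt
            frontier = list(nxt)
            ring = sorted((degs[b] for b in frontier), key=_ring_sort_key)
            per_k[k].append(np.asarray(ring, dtype=np.float64).reshape(len(ring), 2))
    pos = 0
    for k in range(k_max + 1):
        offsets[k, 0] = pos
        for i in range(n):
            pos += len(per_k[k][i])
            offsets[k, i + 1] = pos
        chunks.extend(per_k[k])
    flat = (
        np.concatenate([c for c in chunks if len(c)], axis=0)
        if pos > 0
        else np.zeros((0, 2))
    )
    logp = np.log(flat[:, 0] + 1.0)
    logn = np.log(flat[:, 1] + 1.0)
    return offsets, logp, logn


def _as_union(net: NetworkLike) -> tuple[list[str], dict, dict]:
    """Node list, signed degrees and adjacency on the (merged) union graph."""
    if isinstance(net, MergedNetwork):
        nodes = net.merged_nodes()
        pos, neg = net.merged_edges()
    else:
        nodes = sorted(net.nodes)
        pos, neg = net.pos_edges, net.neg_edges
    dp = {n: 0 for n in nodes}
    dn = {n: 0 for n in nodes}
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for u, v in pos:
        dp[u] += 1
        dp[v] += 1
        adj[u].append(v)
        adj[v].append(u)
    for u, v in neg:
        dn[u] += 1
        dn[v] += 1
        adj[u].append(v)
        adj[v].append(u)
    degs = {n: (dp[n], dn[n]) for n in nodes}
    return nodes, degs, adj


def dissimilarity_table(
    net: NetworkLike,
    k_max: int = 3,
    minus_one: bool = False,
    max_nodes: int = MAX_NODES_DEFAULT,
) -> DissimilarityTable:
    """Cumulative f_k for every unordered node pair of a (merged) network.

    For merged inputs, pairs are taken across the full merged node set, so
    structurally similar genes from different contexts receive small f_k —
    this is what lets one embedding space hold all contexts.  Complete
    all-pairs computation; aborts above ``max_nodes`` nodes.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    nodes, degs, adj = _as_union(net)
    n = len(nodes)
    if n > max_nodes:
        raise ValueError(
            f"{n} nodes exceeds the all-pairs guard ({max_nodes}); raise max_nodes "
            "explicitly or reduce the network (the computation is O(n^2) DTW runs)"
        )
    offsets, logp, logn = _collect_rings(nodes, degs, adj, k_max)
    f = np.empty((k_max + 1, n, n), dtype=np.float64)
    _all_pairs_kernel(k_max, offsets, logp, logn, minus_one, f)
    return DissimilarityTable(nodes=nodes, f=f, minus_one=minus_one)
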