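"""Multilayer context graph over structural similarity.

Layer k connects every pair of genes whose hop-k cumulative dissimilarity
f_k is defined, with weight w_k(u,v) = exp(-f_k(u,v)): structurally similar
genes get heavy links.  Each gene also appears once per layer; directed
inter-layer links join copies of the same gene:

* upward (k -> k+1): weight ln(Gamma_k(u) + e), where Gamma_k(u) counts u's
  layer-k links whose weight strictly exceeds the mean link weight of that
  layer.  Many similar genes at layer k push the walk deeper.
* downward (k -> k-1): weight 1.

Since ln(Gamma + e) >= 1, the upward pull always at least matches the
downward one, biasing walks toward deeper (wider-horizon) layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .similarity import DissimilarityTable

__all__ = [
    "layer_weight",
    "MultilayerContextGraph",
    "build_context_graph",
]


def layer_weight(f_k_value: float) -> float:
    """Intra-layer link weight e^(-f); strictly decreasing in f."""
    if f_k_value < 0:
        raise ValueError("f must be >= 0")
    return math.exp(-f_k_value)


@dataclass
class MultilayerContextGraph:
    """CSR-stored multilayer similarity graph ready for biased random walks.

    Per layer k: ``indptr[k]``/``indices[k]``/``weights[k]`` give each
    node's intra-layer neighbours and weights; ``up_w[k][i]`` is the upward
    inter-layer weight of node i (defined for k < k_max; downward weight is
    identically 1).
    """

    nodes: list[str]
    k_max: int
    indptr: list[np.ndarray]
    indices: list[np.ndarray]
    weights: list[np.ndarray]
    up_w: np.ndarray  # (k_max+1, n); row k_max unused (kept for shape)
    gamma_: np.ndarray  # (k_max+1, n) ints
    node_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.node_index = {u: i for i, u in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def intra_weight(self, k: int, u: str, v: str) -> float | None:
        i, j = self.node_index[u], self.node_index[v]
        lo, hi = self.indptr[k][i], self.indptr[k][i + 1]
        row = self.indices[k][lo:hi]
        hit = np.nonzero(row == j)[0]
        if hit.size == 0:
            return None
        return float(self.weights[k][lo + hit[0]])

    def gamma(self, u: str, k: int) -> int:
        """Number of u's layer-k links with weight strictly above the mean
        link weight of layer k."""
        if self.indices[k].size == 0:
            raise ValueError(f"layer {k} has no intra links")
        return int(self.gamma_[k, self.node_index[u]])

    def interlayer_weights(self, u: str, k: int) -> tuple[float | None, float | None]:
        """(up, down) inter-layer weights for gene u at layer k; None at the
        missing boundary direction."""
        i = self.node_index[u]
        up = float(self.up_w[k, i]) if k < self.k_max else None
        down = 1.0 if k > 0 else None
        return up, down


def build_context_graph(table: DissimilarityTable) -> MultilayerContextGraph:
    """Assemble the multilayer graph from a dissimilarity table.

    Pure function of the table: intra weights e^{-f_k} for every pair with
    f_k defined (truncated pairs are simply absent from deeper layers), then
    Gamma per (node, layer) against the layer-wide mean link weight, then
    upward weights ln(Gamma + e).
    """
    n = table.n_nodes
    k_max = table.k_max
    indptr: list[np.ndarray] = []
    indices: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    gamma = np.zeros((k_max + 1, n), dtype=np.int64)
    up_w = np.ones((k_max + 1, n), dtype=np.float64)
    for k in range(k_max + 1):
        w_full = np.exp(-table.f[k])
        np.fill_diagonal(w_full, np.nan)  # no self links
        mask = ~np.isnan(w_full)
        # layer mean over links = mean over defined off-diagonal entries
        # (each undirected link appears twice; the mean is unaffected)
        if mask.any():
            mean_w = float(w_full[mask].mean())
            gamma[k] = np.nansum(
                np.where(mask, w_full > mean_w, False), axis=1
            )
        ptr = np.zeros(n + 1, dtype=np.int64)
        idx_rows = []
        w_rows = []
        for i in range(n):
            cols = np.nonzero(mask[i])[0]
            idx_rows.append(cols.astype(np.int64))
            w_rows.append(w_full[i, cols])
            ptr[i + 1] = ptr[i] + cols.size
        indptr.append(ptr)
        indices.append(np.concatenate(idx_rows) if n else np.zeros(0, np.int64))
        weights.append(np.concatenate(w_rows) if n else np.zeros(0))
        up_w[k] = np.log(gamma[k] + math.e)
    return MultilayerContextGraph(
        nodes=list(table.nodes),
        k_max=k_max,
        indptr=indptr,
        indices=indices,
        weights=weights,
        up_w=up_w,
        gamma_=gamma,
    )
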