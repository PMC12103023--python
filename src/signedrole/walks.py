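"""Biased random walks on the multilayer context graph.

Each walk starts at a gene's copy in layer 0.  At every step the walker
either moves within the current layer (total probability q, default 0.8,
split across neighbours proportionally to the similarity weights) or
switches layer (probability 1-q, split between the upward weight
ln(Gamma_k(u)+e) and the downward weight 1).  Only intra-layer moves emit a
token; layer switches silently change the similarity horizon.  At the layer
boundaries the whole inter-layer mass goes in the only available direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .context_graph import MultilayerContextGraph

__all__ = ["WalkCorpus", "transition_distribution", "generate_walks"]

# give up on a walk if it bounces between layers this many times per token
_MAX_STALL = 64


@dataclass
class WalkCorpus:
    """A list of token walks (node indices) plus the id vocabulary."""

    nodes: list[str]
    walks: list[np.ndarray]  # int32 node indices
    params: dict

    def as_token_lists(self) -> list[list[str]]:
        return [[self.nodes[i] for i in w] for w in self.walks]

    def __len__(self) -> int:
        return len(self.walks)


def transition_distribution(
    g: MultilayerContextGraph, u: str, k: int, q: float = 0.8
) -> dict:
    """Full outgoing probability distribution of (u, layer k).

    Returns ``{"intra": {node: p}, "up": p, "down": p}``; the three parts
    sum to 1.  Interior layers put mass q on intra moves and 1-q on layer
    switches; a node with no intra links at layer k moves only between
    layers (renormalised, with a warning).
    """
    if not 0 <= k <= g.k_max:
        raise ValueError(f"layer {k} outside 0..{g.k_max}")
    i = g.node_index[u]
    lo, hi = g.indptr[k][i], g.indptr[k][i + 1]
    nbr = g.indices[k][lo:hi]
    w = g.weights[k][lo:hi]
    up_w, down_w = g.interlayer_weights(u, k)
    if up_w is None and down_w is None:  # single-layer graph
        inter_mass = 0.0
        up_p = down_p = 0.0
    else:
        inter_mass = 1.0 - q
        if up_w is None:
            up_p, down_p = 0.0, inter_mass
        elif down_w is None:
            up_p, down_p = inter_mass, 0.0
        else:
            tot = up_w + down_w
            up_p, down_p = inter_mass * up_w / tot, inter_mass * down_w / tot
    if nbr.size == 0:
        if inter_mass == 0.0:
            raise ValueError(f"node {u!r} has no moves at layer {k}")
        warnings.warn(
            f"node {u!r} has no intra links at layer {k}; all mass to layer moves"
        )
        scale = 1.0 / inter_mass
        return {"intra": {}, "up": up_p * scale, "down": down_p * scale}
    intra_mass = 1.0 - up_p - down_p  # q, or 1 on a single-layer graph
    probs = intra_mass * w / w.sum()
    return {
        "intra": {g.nodes[j]: float(p) for j, p in zip(nbr, probs)},
        "up": float(up_p),
        "down": float(down_p),
    }


@njit(cache=True)
def _walk_kernel(  # pragma: no cover - jitted
    starts,
    walk_length,
    q,
    k_max,
    indptr_flat,
    indices_flat,
    cumw_flat,
    layer_ptr_off,
    layer_dat_off,
    up_w,
    seed,
):
    np.random.seed(seed)
    n_walks = starts.shape[0]
    out = np.full((n_walks, walk_length), -1, dtype=np.int32)
    for wi in range(n_walks):
        node = starts[wi]
        layer = 0
        out[wi, 0] = node
        t = 1
        stall = 0
        while t < walk_length:
            p0 = indptr_flat[layer_ptr_off[layer] + node]
            p1 = indptr_flat[layer_ptr_off[layer] + node + 1]
            has_intra = p1 > p0
            r = np.random.random()
            intra_mass = q if k_max > 0 else 1.0
            if has_intra and r < intra_mass:
                # weighted neighbour draw via cumulative weights
                base = layer_dat_off[layer]
                lo, hi = base + p0, base + p1
                total = cumw_flat[hi - 1]
                x = np.random.random() * total
                a, b = lo, hi - 1
                while a < b:
                    mid = (a + b) // 2
                    if cumw_flat[mid] >= x:
                        b = mid
                    else:
                        a = mid + 1
                node = indices_flat[a]
                out[wi, t] = node
                t += 1
                stall = 0
            else:
                # layer switch (or forced when no intra links)
                if layer == 0:
                    layer = min(1, k_max)
                elif layer == k_max:
                    layer -= 1
                else:
                    uw = up_w[layer, node]
                    if np.random.random() < uw / (uw + 1.0):
                        layer += 1
                    else:
                        layer -= 1
                stall += 1
                if stall > _MAX_STALL:
                    break
    return out


def generate_walks(
    g: MultilayerContextGraph,
    walks_per_node: int = 10,
    walk_length: int = 80,
    q: float = 0.8,
    seed: int = 0,
) -> WalkCorpus:
    """Generate ``walks_per_node`` token walks from every gene.

    Every walk starts at layer 0; tokens are appended for the start node and
    for each intra-layer step, so walks have exactly ``walk_length`` tokens
    (shorter only if the walker stalls with no intra moves anywhere).
    Reproducible: a fixed seed yields an identical corpus.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    n = g.n_nodes
    starts = np.repeat(np.arange(n, dtype=np.int32), walks_per_node)
    # shuffle start order so training batches interleave nodes
    rng = np.random.default_rng(seed)
    rng.shuffle(starts)
    # flatten per-layer CSR into single arrays with per-layer offsets
    layer_ptr_off = np.zeros(g.k_max + 1, dtype=np.int64)
    layer_dat_off = np.zeros(g.k_max + 1, dtype=np.int64)
    for k in range(1, g.k_max + 1):
        layer_ptr_off[k] = layer_ptr_off[k - 1] + g.indptr[k - 1].size
        layer_dat_off[k] = layer_dat_off[k - 1] + g.indices[k - 1].size
    indptr_flat = np.concatenate(g.indptr)
    indices_flat = np.concatenate(g.indices).astype(np.int32)
    cumw_flat = np.concatenate(
        [_row_cumsum(g.indptr[k], g.weights[k]) for k in range(g.k_max + 1)]
    )
    raw = _walk_kernel(
        starts,
        walk_length,
        float(q),
        g.k_max,
        indptr_flat,
        indices_flat,
        cumw_flat,
        layer_ptr_off,
        layer_dat_off,
        g.up_w,
        int(seed) % (2**31 - 1),
    )
    walks = [row[row >= 0].copy() for row in raw]
    return WalkCorpus(
        nodes=list(g.nodes),
        walks=walks,
        params={
            "walks_per_node": walks_per_node,
            "walk_length": walk_length,
            "q": q,
            "seed": seed,
        },
    )


def _row_cumsum(indptr: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-row cumulative sums of CSR weights (for in-row sampling)."""
    out = np.empty_like(w)
    for i in range(indptr.size - 1):
        lo, hi = indptr[i], indptr[i + 1]
        out[lo:hi] = np.cumsum(w[lo:hi])
    return out
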