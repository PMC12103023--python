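"""End-to-end orchestration: networks -> dissimilarity -> walks -> embedding.

One call, one run log.  All randomness is controlled by a single seed from
which the walk and training seeds are derived.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Sequence, Union

from .context_graph import build_context_graph
from .embedding import EmbeddingTable, train_embedding
from .network import MergedNetwork, SignedNetwork, merge_networks
from .similarity import MAX_NODES_DEFAULT, dissimilarity_table
from .walks import generate_walks

__all__ = ["embed_networks"]

NetworkInput = Union[SignedNetwork, MergedNetwork, Sequence[SignedNetwork]]


def embed_networks(
    networks: NetworkInput,
    k_max: int = 3,
    walks_per_node: int = 10,
    walk_length: int = 80,
    q: float = 0.8,
    dim: int = 128,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    seed: int = 0,
    minus_one: bool = False,
    max_nodes: int = MAX_NODES_DEFAULT,
    log_path: str | Path | None = None,
) -> EmbeddingTable:
    """Embed one network, or several merged into a shared role space.

    For merged inputs the embedding ids are ``gene::context``, and the
    structural-similarity layers span all contexts, so the same role in two
    cell states lands in the same region of the space.
    """
    if isinstance(networks, (list, tuple)):
        net: SignedNetwork | MergedNetwork = merge_networks(list(networks))
    else:
        net = networks
    stages: dict[str, float] = {}
    t0 = time.perf_counter()
    table = dissimilarity_table(net, k_max=k_max, minus_one=minus_one, max_nodes=max_nodes)
    stages["dissimilarity_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    graph = build_context_graph(table)
    stages["context_graph_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    corpus = generate_walks(
        graph, walks_per_node=walks_per_node, walk_length=walk_length, q=q, seed=seed
    )
    stages["walks_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    emb = train_embedding(
        corpus,
        dim=dim,
        window=window,
        epochs=epochs,
        negative=negative,
        seed=seed + 1,
    )
    stages["training_s"] = time.perf_counter() - t0
    emb.params.update(k_max=k_max, minus_one=minus_one, pipeline_seed=seed)
    if log_path is not None:
        log = {
            "n_nodes": (
                net.n_nodes if isinstance(net, MergedNetwork) else net.n_nodes
            ),
            "k_max": k_max,
            "params": {k: v for k, v in emb.params.items()},
            "stages": stages,
        }
        Path(log_path).write_text(json.dumps(log, indent=2, default=str) + "\n")
    return emb
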