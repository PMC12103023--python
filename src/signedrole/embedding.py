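"""Skip-Gram embeddings of walk corpora.

Genes that co-occur in the biased walks are, by construction of the context
graph, genes with similar structural roles; Skip-Gram with negative
sampling (SGNS) therefore places structurally similar genes — including
genes from different cell-type contexts in a merged run — at nearby points.

The trainer is a standard word2vec-style SGNS: dynamic window, unigram^0.75
negative-sampling distribution, linearly decaying learning rate, single
thread with a fixed RNG seed so training is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .walks import WalkCorpus

__all__ = ["EmbeddingTable", "train_embedding", "save_embeddings", "load_embeddings"]


@dataclass
class EmbeddingTable:
    """Map node-id -> fixed-dimension real vector."""

    dim: int
    ids: list[str]
    matrix: np.ndarray  # (n, dim)
    params: dict = field(default_factory=dict)
    _index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.ids), self.dim):
            raise ValueError("matrix shape does not match ids/dim")
        self._index = {u: i for i, u in enumerate(self.ids)}

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self.matrix[self._index[node_id]]

    def __len__(self) -> int:
        return len(self.ids)

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self[a] - self[b]))

    def pairwise_distances(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.matrix))


@njit(cache=True)
def _sgns_kernel(  # pragma: no cover - jitted
    tokens,
    sent_ptr,
    syn0,
    syn1,
    neg_cdf,
    window,
    negative,
    epochs,
    alpha0,
    alpha_min,
    seed,
):
    np.random.seed(seed)
    n_tokens = tokens.shape[0]
    vocab = syn0.shape[0]
    dim = syn0.shape[1]
    total = epochs * n_tokens
    done = 0
    grad = np.empty(dim)
    for _ in range(epochs):
        for s in range(sent_ptr.shape[0] - 1):
            lo, hi = sent_ptr[s], sent_ptr[s + 1]
            for pos in range(lo, hi):
                alpha = alpha0 - (alpha0 - alpha_min) * (done / total)
                done += 1
                w = tokens[pos]
                b = 1 + int(np.random.random() * window)  # dynamic window
                for c in range(max(lo, pos - b), min(hi, pos + b + 1)):
                    if c == pos:
                        continue
                    ctx = tokens[c]
                    # positive pair (ctx -> predict w) + `negative` noise draws
                    for d in range(dim):
                        grad[d] = 0.0
                    for nidx in range(negative + 1):
                        if nidx == 0:
                            target = w
                            label = 1.0
                        else:
                            x = np.random.random()
                            a, bb = 0, vocab - 1
                            while a < bb:
                                mid = (a + bb) // 2
                                if neg_cdf[mid] >= x:
                                    bb = mid
                                else:
                                    a = mid + 1
                            target = a
                            if target == w:
                                continue
                            label = 0.0
                        dot = 0.0
                        for d in range(dim):
                            dot += syn0[ctx, d] * syn1[target, d]
                        if dot > 6.0:
                            p = 1.0
                        elif dot < -6.0:
                            p = 0.0
                        else:
                            p = 1.0 / (1.0 + np.exp(-dot))
                        g = alpha * (label - p)
                        for d in range(dim):
                            grad[d] += g * syn1[target, d]
                            syn1[target, d] += g * syn0[ctx, d]
                    for d in range(dim):
                        syn0[ctx, d] += grad[d]


def train_embedding(
    corpus: WalkCorpus,
    dim: int = 128,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    seed: int = 0,
) -> EmbeddingTable:
    """Train SGNS embeddings over a walk corpus.

    The vocabulary is every token in the corpus (min count 1 — every
    non-isolated gene gets a vector).  Deterministic for a fixed seed.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not corpus.walks or all(len(w) == 0 for w in corpus.walks):
        raise ValueError("empty walk corpus")
    nodes = corpus.nodes
    vocab = len(nodes)
    counts = np.zeros(vocab, dtype=np.float64)
    lengths = [len(w) for w in corpus.walks if len(w) > 0]
    tokens = np.concatenate([w for w in corpus.walks if len(w) > 0]).astype(np.int64)
    np.add.at(counts, tokens, 1.0)
    if np.any(counts == 0):
        # nodes never visited (possible on pathological graphs) still get a
        # vector from their random initialisation; keep them in the vocab
        counts[counts == 0] = 1e-12
    sent_ptr = np.zeros(len(lengths) + 1, dtype=np.int64)
    np.cumsum(lengths, out=sent_ptr[1:])
    noise = counts**0.75
    neg_cdf = np.cumsum(noise / noise.sum())
    rng = np.random.default_rng(seed)
    syn0 = (rng.random((vocab, dim)) - 0.5) / dim
    syn1 = np.zeros((vocab, dim))
    _sgns_kernel(
        tokens,
        sent_ptr,
        syn0,
        syn1,
        neg_cdf,
        int(window),
        int(negative),
        int(epochs),
        float(alpha),
        float(alpha) * 1e-4 / 0.025,
        int(seed) % (2**31 - 1),
    )
    params = dict(corpus.params)
    params.update(
        dim=dim, window=window, epochs=epochs, negative=negative, alpha=alpha,
        train_seed=seed,
    )
    return EmbeddingTable(dim=dim, ids=list(nodes), matrix=syn0, params=params)


# ----------------------------------------------------------------------
# Word-vector text IO
# ----------------------------------------------------------------------

def save_embeddings(t: EmbeddingTable, path: str | Path) -> Path:
    """Write word2vec-style text: header ``N dim`` then ``id v1 .. vdim``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{len(t.ids)} {t.dim}\n")
        for i, u in enumerate(t.ids):
            if any(ch.isspace() for ch in u):
                raise ValueError(f"node id {u!r} contains whitespace")
            vec = " ".join(f"{x:.8g}" for x in t.matrix[i])
            fh.write(f"{u} {vec}\n")
    return path


def load_embeddings(path: str | Path) -> EmbeddingTable:
    """Read the text format written by :func:`save_embeddings`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    head = lines[0].split()
    if len(head) != 2:
        raise ValueError(f"{path}: malformed header {lines[0]!r}")
    n, dim = int(head[0]), int(head[1])
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) != n:
        raise ValueError(f"{path}: header says {n} rows, found {len(body)}")
    ids: list[str] = []
    mat = np.empty((n, dim))
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) != dim + 1:
            raise ValueError(f"{path}: row {i + 2} has {len(parts) - 1} values, expected {dim}")
        ids.append(parts[0])
        mat[i] = [float(x) for x in parts[1:]]
    return EmbeddingTable(dim=dim, ids=ids, matrix=mat)
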