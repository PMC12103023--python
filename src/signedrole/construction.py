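"""Build signed co-expression GRNs from gene x cell count matrices.

The pipeline mirrors common single-cell practice: select highly variable
genes, correlate every gene pair with Spearman's rho, keep pairs with
p < 0.01 and |rho| above a floor, sign each edge by the sign of rho, and
finally retain only the strongest edges by |rho| (top 2000 by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network import SignedNetwork, _pair

__all__ = [
    "CountMatrix",
    "select_hvg",
    "spearman_grn",
    "top_k_edges",
    "build_grn",
]


@dataclass
class CountMatrix:
    """Dense genes x cells matrix of non-negative counts."""

    values: np.ndarray
    gene_names: list[str]
    cell_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_names), len(self.cell_names)):
            raise ValueError("matrix shape does not match name lists")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("duplicate gene names")
        if (self.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_cells(self) -> int:
        return len(self.cell_names)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CountMatrix":
        """Dense CSV with genes as rows, first column = gene names."""
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), [str(g) for g in df.index], [str(c) for c in df.columns])

    @classmethod
    def read_mtx(
        cls, path: str | Path, genes_path: str | Path, cells_path: str | Path
    ) -> "CountMatrix":
        """MatrixMarket matrix (genes x cells) with sidecar name files."""
        from scipy.io import mmread

        raw = mmread(str(path))
        m = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        genes = Path(genes_path).read_text().split()
        cells = Path(cells_path).read_text().split()
        return cls(m, genes, cells)


def select_hvg(m: CountMatrix, n: int = 2000) -> CountMatrix:
    """Top-n highly variable genes by variance of log1p library-normalised
    counts (depth normalised to the median cell total).  Ties break by gene
    name so the selection is invariant to input gene order."""
    if n > m.n_genes:
        raise ValueError(f"requested {n} HVGs from {m.n_genes} genes")
    totals = m.values.sum(axis=0)
    totals[totals == 0] = 1.0
    norm = m.values / totals * np.median(totals)
    disp = np.log1p(norm).var(axis=1)
    order = sorted(range(m.n_genes), key=lambda i: (-disp[i], m.gene_names[i]))
    keep = sorted(order[:n])
    return CountMatrix(
        m.values[keep], [m.gene_names[i] for i in keep], list(m.cell_names)
    )


def spearman_grn(
    m: CountMatrix,
    p_threshold: float = 0.01,
    rho_threshold: float = 0.3,
    context: str | None = None,
    method: str = "auto",
) -> SignedNetwork:
    """Signed GRN from all-pairs Spearman correlation.

    Edges keep pairs with two-sided p < ``p_threshold`` and
    |rho| >= ``rho_threshold``; edge sign is the sign of rho and |rho| is
    stored as the edge weight (used later for top-k filtering).  p-values
    use the t approximation (``method="t"``); ``"permutation"`` computes an
    exact permutation p-value, chosen automatically for <= 10 cells under
    ``"auto"``.  Constant genes are skipped with a warning.
    """
    if m.n_cells < 3:
        raise ValueError("rank correlation needs >= 3 cells")
    exact = method == "permutation" or (method == "auto" and m.n_cells <= 10)
    X = m.values
    const = X.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant gene(s) skipped (zero rank variance)"
        )
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    pos, neg, weights = set(), set(), {}
    nc = m.n_cells
    # vectorised rho over all pairs via rank correlation matrix
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ranks)
    for i in range(m.n_genes):
        if const[i]:
            continue
        for j in range(i + 1, m.n_genes):
            if const[j]:
                continue
            rho = r[i, j]
            if not np.isfinite(rho) or abs(rho) < rho_threshold:
                continue
            p = _spearman_p(ranks[i], ranks[j], rho, nc, exact)
            if p >= p_threshold:
                continue
            e = _pair(m.gene_names[i], m.gene_names[j])
            (pos if rho > 0 else neg).add(e)
            weights[e] = float(rho)
    return SignedNetwork(pos_edges=pos, neg_edges=neg, context=context, weights=weights)


def _spearman_p(ri: np.ndarray, rj: np.ndarray, rho: float, n: int, exact: bool) -> float:
    if exact:
        res = stats.permutation_test(
            (ri,),
            lambda x: np.corrcoef(x, rj)[0, 1],
            permutation_type="pairings",
            n_resamples=10000,
            alternative="two-sided",
            rng=0,
        )
        return float(res.pvalue)
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), n - 2))


def top_k_edges(
    net: SignedNetwork,
    weights: dict | None = None,
    k: int = 2000,
) -> SignedNetwork:
    """Keep the k edges with largest |weight|.

    Ties straddling rank k break deterministically by (|weight| descending,
    lexicographic pair ascending).  Nodes isolated by the filter drop out.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    w = weights if weights is not None else net.weights
    if w is None:
        raise ValueError("no edge weights available")
    edges = sorted(net.pos_edges | net.neg_edges)
    missing = [e for e in edges if _pair(*e) not in w]
    if missing:
        raise ValueError(f"weights missing for {len(missing)} edge(s), e.g. {missing[0]}")
    ranked = sorted(edges, key=lambda e: (-abs(w[_pair(*e)]), e))
    keep = set(ranked[: min(k, len(ranked))])
    return SignedNetwork(
        pos_edges=net.pos_edges & keep,
        neg_edges=net.neg_edges & keep,
        context=net.context,
        weights={e: w[e] for e in keep if e in w},
        allow_conflicts=net.allow_conflicts,
    )


def build_grn(
    m: CountMatrix,
    n_hvg: int | None = 2000,
    p_threshold: float = 0.01,
    rho_threshold: float = 0.3,
    top_k: int | None = 2000,
    context: str | None = None,
) -> SignedNetwork:
    """End-to-end count matrix -> filtered signed GRN."""
    if n_hvg is not None and n_hvg < m.n_genes:
        m = select_hvg(m, n_hvg)
    net = spearman_grn(m, p_threshold, rho_threshold, context=context)
    if top_k is not None and net.n_edges > top_k:
        net = top_k_edges(net, k=top_k)
    return net
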