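"""Signed gene regulatory networks: containers, IO, and multi-context merging.

A signed GRN is an undirected graph G = (V, E+, E-) whose nodes are genes and
whose edges carry an activation (+) or inhibition (-) sign.  For joint
embedding of several cell types/states, networks are merged as a disjoint
union with node identifiers of the form ``gene::context``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SignedNetwork",
    "MergedNetwork",
    "CONTEXT_SEP",
    "read_edge_list",
    "write_edge_list",
    "merge_networks",
]

CONTEXT_SEP = "::"

Pair = tuple[str, str]


def _pair(u: str, v: str) -> Pair:
    """Canonical unordered pair (lexicographically sorted)."""
    return (u, v) if u <= v else (v, u)


class ValidationError(ValueError):
    """Raised when an edge list or network violates the signed-GRN contract."""


@dataclass
class SignedNetwork:
    """Undirected signed graph over gene nodes.

    Nodes are derived from the edge sets, so isolated genes never occur:
    every retained gene has total signed degree d+ + d- >= 1.  A pair may
    appear in both ``pos_edges`` and ``neg_edges`` only when built with
    ``allow_conflicts=True``, in which case it contributes one unit to each
    of d+ and d-.
    """

    pos_edges: set[Pair]
    neg_edges: set[Pair]
    context: str | None = None
    weights: dict[Pair, float] | None = None
    allow_conflicts: bool = False
    nodes: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.pos_edges = {_pair(*e) for e in self.pos_edges}
        self.neg_edges = {_pair(*e) for e in self.neg_edges}
        for u, v in list(self.pos_edges) + list(self.neg_edges):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
        if not self.allow_conflicts:
            conflicts = self.pos_edges & self.neg_edges
            if conflicts:
                u, v = sorted(conflicts)[0]
                raise ValidationError(
                    f"pair {u}-{v} appears with both positive and negative sign "
                    f"({len(conflicts)} conflicting pair(s)); pass allow_conflicts=True to keep both"
                )
        if self.context is not None:
            if not self.context or CONTEXT_SEP in self.context:
                raise ValidationError(
                    f"context label {self.context!r} is empty or contains {CONTEXT_SEP!r}"
                )
        self.nodes = {n for e in self.pos_edges | self.neg_edges for n in e}

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.pos_edges) + len(self.neg_edges)

    def signed_degree(self, u: str) -> tuple[int, int]:
        """The 2-vector [d+, d-] of positive/negative incident edge counts."""
        if u not in self.nodes:
            raise KeyError(f"unknown node {u!r}")
        dp = sum(1 for e in self.pos_edges if u in e)
        dn = sum(1 for e in self.neg_edges if u in e)
        return (dp, dn)

    def signed_degrees(self) -> dict[str, tuple[int, int]]:
        """Signed degree for every node (single pass over the edge sets)."""
        dp = {n: 0 for n in self.nodes}
        dn = {n: 0 for n in self.nodes}
        for u, v in self.pos_edges:
            dp[u] += 1
            dp[v] += 1
        for u, v in self.neg_edges:
            dn[u] += 1
            dn[v] += 1
        return {n: (dp[n], dn[n]) for n in self.nodes}

    def to_networkx(self, sign: str = "union"):
        """Export as a networkx Graph.

        ``sign`` selects the unsigned union ("union"), the positive subgraph
        ("pos") or the negative subgraph ("neg"); edge attribute ``sign`` is
        +1/-1 on the union graph.
        """
        import networkx as nx

        g = nx.Graph()
        if sign in ("union", "pos"):
            g.add_edges_from(self.pos_edges, sign=1)
        if sign in ("union", "neg"):
            g.add_edges_from(self.neg_edges, sign=-1)
        return g

    def relabel(self, mapping: Mapping[str, str]) -> "SignedNetwork":
        """Return a copy with node names replaced via ``mapping``."""
        m = lambda x: mapping.get(x, x)  # noqa: E731
        return SignedNetwork(
            pos_edges={_pair(m(u), m(v)) for u, v in self.pos_edges},
            neg_edges={_pair(m(u), m(v)) for u, v in self.neg_edges},
            context=self.context,
            allow_conflicts=self.allow_conflicts,
        )

    def with_context(self, context: str) -> "SignedNetwork":
        return SignedNetwork(
            pos_edges=set(self.pos_edges),
            neg_edges=set(self.neg_edges),
            context=context,
            weights=dict(self.weights) if self.weights else None,
            allow_conflicts=self.allow_conflicts,
        )


@dataclass
class MergedNetwork:
    """Disjoint union of signed networks from distinct contexts.

    Merged node identifiers are ``gene::context``.  No edge ever crosses
    contexts; proximity between contexts arises only later, through the
    structural-similarity layer weights.
    """

    networks: list[SignedNetwork]

    def __post_init__(self) -> None:
        if len(self.networks) < 2:
            raise ValidationError("need >=2 networks to merge")
        contexts = [n.context for n in self.networks]
        if any(c is None for c in contexts):
            raise ValidationError("every network needs a context label before merging")
        if len(set(contexts)) != len(contexts):
            raise ValidationError(f"duplicate context labels in {contexts}")

    @property
    def contexts(self) -> list[str]:
        return [n.context for n in self.networks]  # type: ignore[misc]

    def network(self, context: str) -> SignedNetwork:
        for n in self.networks:
            if n.context == context:
                return n
        raise KeyError(f"unknown context {context!r}")

    def gene_sets(self) -> dict[str, set[str]]:
        return {n.context: set(n.nodes) for n in self.networks}  # type: ignore[misc]

    def shared_genes(self, *contexts: str) -> set[str]:
        """Genes present (non-isolated) in every one of the given contexts;
        with no arguments, in every context."""
        cs = list(contexts) if contexts else self.contexts
        sets = [self.network(c).nodes for c in cs]
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return out

    @staticmethod
    def node_id(gene: str, context: str) -> str:
        return f"{gene}{CONTEXT_SEP}{context}"

    @staticmethod
    def split_id(node_id: str) -> tuple[str, str]:
        gene, _, context = node_id.rpartition(CONTEXT_SEP)
        return gene, context

    def merged_nodes(self) -> list[str]:
        out: list[str] = []
        for net in self.networks:
            out.extend(self.node_id(g, net.context) for g in sorted(net.nodes))  # type: ignore[arg-type]
        return out

    def merged_edges(self) -> tuple[set[Pair], set[Pair]]:
        pos: set[Pair] = set()
        neg: set[Pair] = set()
        for net in self.networks:
            c = net.context
            for u, v in net.pos_edges:
                pos.add(_pair(self.node_id(u, c), self.node_id(v, c)))  # type: ignore[arg-type]
            for u, v in net.neg_edges:
                neg.add(_pair(self.node_id(u, c), self.node_id(v, c)))  # type: ignore[arg-type]
        return pos, neg

    @property
    def n_nodes(self) -> int:
        return sum(n.n_nodes for n in self.networks)


def merge_networks(nets: Sequence[SignedNetwork]) -> MergedNetwork:
    """Merge >=2 signed networks with distinct context labels."""
    return MergedNetwork(list(nets))


# ----------------------------------------------------------------------
# Edge-list IO
# ----------------------------------------------------------------------

def _detect_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_edge_list(
    path: str | Path,
    sign_mode: str = "sign_column",
    context: str | None = None,
    allow_conflicts: bool = False,
) -> SignedNetwork:
    """Read a signed network from a delimited edge list.

    The file must have >=3 columns (source, target, value); the delimiter
    (tab or comma) and an optional header row are auto-detected.  Under
    ``sign_mode="sign_column"`` the value must be +/-1; under
    ``"weight_sign"`` any nonzero real, whose sign determines edge sign and
    whose magnitude is retained as an edge weight.  Duplicate identical rows
    collapse; rows assigning both signs to one pair raise unless
    ``allow_conflicts``.
    """
    if sign_mode not in ("sign_column", "weight_sign"):
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    pos: set[Pair] = set()
    neg: set[Pair] = set()
    weights: dict[Pair, float] = {}
    delim: str | None = None
    seen_rows: set[tuple[str, str, float]] = set()
    n_data = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None:
            delim = _detect_delimiter(line)
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 3:
            raise ValidationError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
        if n_data == 0 and not _is_number(parts[2]):
            continue  # header row
        u, v, tok = parts[0], parts[1], parts[2]
        if not _is_number(tok):
            raise ValidationError(f"{path}:{lineno}: non-numeric value {tok!r}")
        val = float(tok)
        if val == 0:
            raise ValidationError(f"{path}:{lineno}: zero value for pair {u}-{v} (sign undefined)")
        if sign_mode == "sign_column" and val not in (1.0, -1.0):
            raise ValidationError(
                f"{path}:{lineno}: sign column must be +1/-1, got {val}"
            )
        n_data += 1
        if u == v:
            warnings.warn(f"{path}:{lineno}: dropping self-loop on {u!r}")
            continue
        p = _pair(u, v)
        row = (*p, val if sign_mode == "weight_sign" else (1.0 if val > 0 else -1.0))
        if row in seen_rows:
            continue
        seen_rows.add(row)
        if val > 0:
            pos.add(p)
        else:
            neg.add(p)
        if sign_mode == "weight_sign":
            prev = weights.get(p)
            if prev is None or abs(val) > abs(prev):
                weights[p] = val
    net = SignedNetwork(
        pos_edges=pos,
        neg_edges=neg,
        context=context,
        weights=weights or None,
        allow_conflicts=allow_conflicts,
    )
    return net


def write_edge_list(net: SignedNetwork, path: str | Path) -> Path:
    """Write a three-column TSV ``source<TAB>target<TAB>sign`` with header.

    Round-trips with :func:`read_edge_list`: nodes-with-edges and both edge
    sets are recovered exactly.
    """
    if net.n_edges == 0:
        raise ValidationError("network has no edges; nothing to write")
    path = Path(path)
    rows = [(u, v, 1) for u, v in sorted(net.pos_edges)] + [
        (u, v, -1) for u, v in sorted(net.neg_edges)
    ]
    rows.sort()
    with path.open("w") as fh:
        fh.write("source\ttarget\tsign\n")
        for u, v, s in rows:
            fh.write(f"{u}\t{v}\t{s:+d}\n")
    return path


def read_manifest(path: str | Path) -> MergedNetwork:
    """Read a plain-text manifest of ``context<TAB-or-comma>path`` lines and
    merge the referenced edge lists."""
    path = Path(path)
    nets = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        delim = _detect_delimiter(line)
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2:
            raise ValidationError(f"{path}:{lineno}: expected 'context{delim}path'")
        ctx, edge_path = parts[0], parts[1]
        edge_file = Path(edge_path)
        if not edge_file.is_absolute():
            edge_file = path.parent / edge_file
        if not edge_file.exists():
            raise ValidationError(f"{path}:{lineno}: edge list {edge_file} not found")
        nets.append(read_edge_list(edge_file, context=ctx))
    return merge_networks(nets)
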