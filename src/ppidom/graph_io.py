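"""Network and gene-set I/O, and the closed-neighborhood matrix.

Protein-protein interaction networks are handled as simple undirected
graphs with free-text node identifiers. All dominating-set models in this
package operate on the *closed-neighborhood* matrix A, the adjacency
matrix with unit diagonal: ``A[i, j] = 1`` iff node i interacts with node
j or ``i == j``. A node set D dominates the graph exactly when ``A @ x >= 1``
for the indicator vector x of D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NeighborhoodMatrix",
    "GeneSet",
    "EdgeListError",
    "load_edge_list",
    "write_edge_list",
    "load_gene_set",
    "closed_neighborhood",
]


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass(frozen=True)
class Network:
    """An undirected graph with string node identifiers.

    Node identity is opaque and case-sensitive. Edges are stored as
    sorted 2-tuples; self-loops are never stored (the closed
    neighborhood adds the diagonal analytically). Isolated nodes are
    legal — they necessarily self-dominate and therefore belong to every
    minimum dominating set.
    """

    node_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.node_ids) == 0:
            raise ValueError("a network needs at least one node")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node IDs")
        known = set(self.node_ids)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop stored for node {u!r}")
            if u > v:
                raise ValueError(f"edge {(u, v)!r} not in sorted order")
            if u not in known or v not in known:
                raise ValueError(f"edge {(u, v)!r} references unknown node")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.node_ids)

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        allow_self_loops: bool = False,
    ) -> "Network":
        """Build a network from an edge iterable, deduplicating as needed.

        Duplicate edges (in either orientation) collapse to one; self-loops
        are dropped with a warning when ``allow_self_loops`` is set and
        rejected otherwise. ``extra_nodes`` admits singleton nodes that
        appear on no edge.
        """
        node_order: dict[str, None] = {}
        dedup: set[tuple[str, str]] = set()
        for u, v in edges:
            if u == v:
                if not allow_self_loops:
                    raise EdgeListError(
                        f"self-loop {u!r}-{v!r}; pass allow_self_loops=True to drop it"
                    )
                logger.warning("dropping self-loop on node %r", u)
                node_order.setdefault(u, None)
                continue
            node_order.setdefault(u, None)
            node_order.setdefault(v, None)
            dedup.add((u, v) if u < v else (v, u))
        for w in extra_nodes:
            node_order.setdefault(w, None)
        return cls(node_ids=tuple(node_order), edges=frozenset(dedup))


@dataclass(frozen=True)
class NeighborhoodMatrix:
    """Closed-neighborhood matrix: adjacency with unit diagonal.

    ``entries`` is a symmetric binary CSR matrix; row sums equal
    ``deg(v) + 1``. ``index_map`` sends each node ID to its 0-based
    row/column, following the network's node order.
    """

    entries: sparse.csr_matrix
    index_map: dict[str, int]

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.entries.todense(), dtype=np.int64)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of node identifiers (e.g. essential genes)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def restricted_to(self, net: Network) -> frozenset[str]:
        """Members that are actually present in the network."""
        return self.members & net.node_set


def _tokenize(line: str, delimiter: str | None) -> list[str]:
    if delimiter is not None and delimiter in line:
        return [t.strip() for t in line.split(delimiter)]
    return line.split()  # whitespace fallback


def load_edge_list(
    path: str | Path,
    delimiter: str | None = "\t",
    node_list: str | Path | None = None,
    allow_self_loops: bool = True,
    sif: bool = False,
) -> Network:
    """Read a two-column edge list (TSV by default) into a :class:`Network`.

    Lines starting with ``#`` are ignored. When the stated delimiter does
    not occur on a line, any whitespace is accepted instead. In SIF mode
    each line is ``node1 relation node2`` and the relation is ignored.
    ``node_list`` optionally names a file of one node ID per line, to admit
    singleton (edgeless) nodes. Input self-loops are dropped with a warning
    by default.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _tokenize(line, delimiter)
            if sif:
                if len(tokens) < 3:
                    raise EdgeListError(
                        f"{path}:{lineno}: SIF line needs 3 columns, got {len(tokens)}"
                    )
                edges.append((tokens[0], tokens[2]))
            else:
                if len(tokens) < 2:
                    raise EdgeListError(
                        f"{path}:{lineno}: expected 2 columns, got {len(tokens)}"
                    )
                edges.append((tokens[0], tokens[1]))
    extra: list[str] = []
    if node_list is not None:
        with Path(node_list).open() as fh:
            extra = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not edges and not extra:
        raise EdgeListError(f"{path}: no edges")
    return Network.from_edges(edges, extra_nodes=extra, allow_self_loops=allow_self_loops)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write a sorted, deterministic 2-column TSV edge list.

    Isolated nodes are recorded as trailing ``# node`` comments so a
    round-trip through :func:`load_edge_list` (with the same file passed
    as ``node_list`` after stripping comments) can reproduce them; the
    standard round-trip contract covers the edge-bearing subgraph.
    """
    path = Path(path)
    touched = {u for e in net.edges for u in e}
    with path.open("w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
        for w in net.node_ids:
            if w not in touched:
                fh.write(f"# singleton\t{w}\n")


def load_gene_set(path: str | Path, net: Network | None = None, name: str | None = None) -> GeneSet:
    """Read a gene set: one identifier per line, duplicates collapsed.

    When a network is given, members absent from it are kept but counted
    and logged — identifier conventions differ across annotation sources,
    and dropping silently would bias enrichment margins.
    """
    path = Path(path)
    members: set[str] = set()
    with path.open() as fh:
        for raw in fh:
            token = raw.strip()
            if token and not token.startswith("#"):
                members.add(token)
    if not members:
        raise EdgeListError(f"{path}: gene set is empty")
    gs = GeneSet(name=name or path.stem, members=frozenset(members))
    if net is not None:
        missing = len(gs.members - net.node_set)
        if missing:
            logger.warning(
                "gene set %r: %d of %d members absent from the network",
                gs.name, missing, len(gs.members),
            )
    return gs


def closed_neighborhood(net: Network) -> NeighborhoodMatrix:
    """Build the closed-neighborhood matrix of a network.

    Entry (i, j) is 1 iff i == j or {i, j} is an edge; the ordering
    follows ``net.node_ids``.
    """
    index = {v: i for i, v in enumerate(net.node_ids)}
    rows = list(range(net.n))
    cols = list(range(net.n))
    for u, v in net.edges:
        i, j = index[u], index[v]
        rows.extend((i, j))
        cols.extend((j, i))
    data = np.ones(len(rows), dtype=np.int64)
    mat = sparse.csr_matrix((data, (rows, cols)), shape=(net.n, net.n))
    return NeighborhoodMatrix(entries=mat, index_map=index)
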