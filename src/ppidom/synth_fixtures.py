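"""Seeded synthetic networks with known or oracle-computable structure.

Real interactome snapshots (HINT, BioPlex and kin) are sparse
undirected graphs with heavy-tailed degree distributions, thousands of
nodes, and domination numbers well under 20% of the node count. The
generators here emulate those structural roles at test scale:

* Erdős–Rényi graphs for unstructured random instances whose exact
  domination structure a brute-force oracle can certify;
* star forests as planted instances — the unique MDSet is the center
  set by construction, so critical/redundant labels are known exactly;
* preferential attachment for the hub-dominated degree structure
  characteristic of PPI networks.

All generators are pure functions of their explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .graph_io import Network

__all__ = ["FixtureSpec", "gen_erdos_renyi", "gen_star_forest", "gen_preferential", "generate"]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic network."""

    kind: Literal["er", "preferential", "star_forest", "toy"]
    n: int
    params: dict = field(default_factory=dict)
    seed: int = 0


def _node_names(n: int) -> list[str]:
    width = len(str(max(n - 1, 0)))
    return [f"v{str(i).zfill(width)}" for i in range(n)]


def gen_erdos_renyi(n: int, p: float, seed: int) -> Network:
    """G(n, p): each unordered pair is an edge independently with prob p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("edge probability must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = _node_names(n)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    edges = [(names[i], names[j]) for i, j in zip(iu[mask], ju[mask])]
    return Network.from_edges(edges, extra_nodes=names)


def gen_star_forest(centers: int, leaves_per_center: int, seed: int = 0) -> Network:
    """Disjoint stars: the center set is the unique MDSet by construction.

    Each center carries ``leaves_per_center >= 2`` leaves. Every leaf is
    dominated only by itself or its center, and with at least two
    leaves a star cannot be dominated by one leaf, so any dominating
    set needs its center (or >= 2 of its nodes); the centers alone are
    therefore the unique minimum. Hence critical = centers and
    redundant = leaves, exactly.
    """
    if centers < 1:
        raise ValueError("need at least one center")
    if leaves_per_center < 2:
        raise ValueError("need at least two leaves per center for MDSet uniqueness")
    edges = []
    for c in range(centers):
        for l in range(leaves_per_center):
            edges.append((f"c{c}", f"c{c}_l{l}"))
    return Network.from_edges(edges)


def star_forest_centers(centers: int) -> frozenset[str]:
    """The planted (unique) MDSet of :func:`gen_star_forest`."""
    return frozenset(f"c{c}" for c in range(centers))


def gen_preferential(n: int, m: int, seed: int) -> Network:
    """Preferential attachment starting from an m-clique, no multi-edges.

    Nodes m..n-1 arrive in turn; each attaches to m distinct existing
    nodes sampled with probability proportional to current degree
    (degree + 1 while the seed clique for m = 1 has no edges). Edge
    count is exactly C(m, 2) + m * (n - m). Connected and simple.
    """
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    rng = np.random.default_rng(seed)
    names = _node_names(n)
    edges: list[tuple[str, str]] = []
    degree = np.zeros(n, dtype=np.int64)
    for i in range(m):
        for j in range(i + 1, m):
            edges.append((names[i], names[j]))
            degree[i] += 1
            degree[j] += 1
    for new in range(m, n):
        weights = degree[:new].astype(np.float64) + 1.0  # +1 smooths the edgeless m=1 seed
        targets: set[int] = set()
        while len(targets) < m:
            w = weights.copy()
            w[list(targets)] = 0.0
            w /= w.sum()
            targets.add(int(rng.choice(new, p=w)))
        for t in sorted(targets):
            edges.append((names[t], names[new]))
            degree[t] += 1
            degree[new] += 1
    return Network.from_edges(edges, extra_nodes=names)


def er_validation_suite(n_instances: int = 200, seed: int = 0) -> list[Network]:
    """Seeded Erdős–Rényi instances small enough for exhaustive certification.

    Node counts cycle over 6..12 and edge probabilities over
    {0.15, 0.3, 0.5}, covering sparse through dense regimes while every
    instance stays within reach of the brute-force MDSet enumerator.
    """
    ps = (0.15, 0.3, 0.5)
    nets = []
    for i in range(n_instances):
        n = 6 + i % 7
        p = ps[i % len(ps)]
        nets.append(gen_erdos_renyi(n, p, seed=(seed * 100_003 + i) % 2**31))
    return nets


def generate(spec: FixtureSpec) -> Network:
    """Materialize a :class:`FixtureSpec`."""
    if spec.kind == "er":
        return gen_erdos_renyi(spec.n, spec.params["p"], spec.seed)
    if spec.kind == "star_forest":
        return gen_star_forest(spec.params["centers"], spec.params["leaves_per_center"], spec.seed)
    if spec.kind == "preferential":
        return gen_preferential(spec.n, spec.params["m"], spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
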