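"""Ground-truth procedures for validating the diversified models.

Two independent routes to the exact critical structure of a graph:

* the *traditional* per-node method — one baseline solve plus one
  constrained solve per MDSet member, forbidding each member in turn
  (a node is critical iff forbidding it raises the domination number);
* exhaustive enumeration of every minimum dominating set, feasible for
  small graphs, yielding the exact critical / intermittent / redundant
  partition by direct intersection and union.

The traditional method is the cost baseline the coupled two-set model
is designed to beat: it issues 1 + |MDSet| solver calls versus two.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .graph_io import Network, closed_neighborhood
from . import milp_engine
from .models import basic_problem, solve_basic
from .milp_engine import SolverError

__all__ = [
    "ExactClassification",
    "traditional_critical_set",
    "traditional_intermittent_test",
    "enumerate_all_mdsets",
]


@dataclass(frozen=True)
class ExactClassification:
    """Exact domination structure from full MDSet enumeration."""

    domination_number: int
    all_mdsets: tuple[frozenset[str], ...]
    node_set: frozenset[str]

    @property
    def critical(self) -> frozenset[str]:
        out = set(self.all_mdsets[0])
        for m in self.all_mdsets[1:]:
            out &= m
        return frozenset(out)

    @property
    def intermittent(self) -> frozenset[str]:
        union: set[str] = set()
        for m in self.all_mdsets:
            union |= m
        return frozenset(union) - self.critical

    @property
    def redundant(self) -> frozenset[str]:
        union: set[str] = set()
        for m in self.all_mdsets:
            union |= m
        return self.node_set - union


def traditional_critical_set(net: Network, backend: str = "highs", seed: int = 0) -> frozenset[str]:
    """Exact critical set by per-node forbidding.

    Finds one MDSet of size m, then for each of its members v re-solves
    with v forbidden (variable upper bound 0, equivalent to adding the
    constraint x_v = 0). If the optimum exceeds m — or the model becomes
    infeasible, as for an isolated node — no MDSet avoids v, so v is
    critical. Only members of the found MDSet need testing: a critical
    node belongs to every MDSet, in particular this one. Issues
    1 + m solver calls.
    """
    nm = closed_neighborhood(net)
    base = solve_basic(net, seed=seed, backend=backend, _nm=nm)
    m = base.size
    critical: set[str] = set()
    for v in base.members:
        prob = basic_problem(nm)
        prob.ux[nm.index_map[v]] = 0.0
        sol = milp_engine.solve(prob, seed=seed, backend=backend)
        if sol.status == "infeasible" or sol.objective > m:
            critical.add(v)
        elif sol.status != "optimal":
            raise SolverError(f"constrained solve failed for node {v!r}: {sol.status}")
    return frozenset(critical)


def traditional_intermittent_test(
    net: Network, v: str, backend: str = "highs", seed: int = 0
) -> bool:
    """True iff node v belongs to at least one MDSet.

    Forced-inclusion dual of the critical-set procedure: fix x_v = 1 and
    re-solve; v lies in some MDSet iff the optimum stays at the
    domination number.
    """
    nm = closed_neighborhood(net)
    if v not in nm.index_map:
        raise KeyError(f"node {v!r} not in network")
    m = solve_basic(net, seed=seed, backend=backend, _nm=nm).size
    prob = basic_problem(nm)
    prob.lx[nm.index_map[v]] = 1.0
    sol = milp_engine.solve(prob, seed=seed, backend=backend)
    if sol.status != "optimal":
        raise SolverError(f"forced-inclusion solve failed for node {v!r}: {sol.status}")
    return sol.objective <= m


def enumerate_all_mdsets(net: Network, n_cap: int = 15) -> ExactClassification:
    """All minimum dominating sets by exhaustive search (small graphs only).

    Closed neighborhoods are packed into bitmasks; candidate subsets of
    increasing size are scanned until the first dominating size is
    found, then every subset of that size is tested. Nodes whose closed
    neighborhood is covered by no other node (isolated nodes) are
    forced into every candidate, which prunes the search sharply on
    sparse graphs.
    """
    if net.n > n_cap:
        raise ValueError(f"enumeration refused for n={net.n} > cap {n_cap}")
    index = {v: i for i, v in enumerate(net.node_ids)}
    masks = [1 << i for i in range(net.n)]
    for u, v in net.edges:
        masks[index[u]] |= 1 << index[v]
        masks[index[v]] |= 1 << index[u]
    full = (1 << net.n) - 1
    # isolated nodes are dominated only by themselves: force them in
    forced = [i for i in range(net.n) if masks[i] == (1 << i)]
    free = [i for i in range(net.n) if masks[i] != (1 << i)]
    forced_cover = 0
    for i in forced:
        forced_cover |= masks[i]
    found: list[frozenset[str]] = []
    for extra in range(net.n - len(forced) + 1):
        for combo in combinations(free, extra):
            cover = forced_cover
            for i in combo:
                cover |= masks[i]
            if cover == full:
                found.append(
                    frozenset(net.node_ids[i] for i in forced)
                    | frozenset(net.node_ids[i] for i in combo)
                )
        if found:
            break
    gamma = len(forced) + extra
    return ExactClassification(
        domination_number=gamma,
        all_mdsets=tuple(found),
        node_set=net.node_set,
    )
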