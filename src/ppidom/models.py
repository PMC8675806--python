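"""The four dominating-set ILP models.

Writing x for the indicator vector of a node subset and A for the
closed-neighborhood matrix, a set dominates the network iff ``A x >= 1``
row-wise, and a *minimum* dominating set (MDSet) minimizes ``sum x``
subject to that cover. MDSets are far from unique, and which one a
solver returns is an artifact of its internals. The models here control
that degeneracy:

``solve_basic``
    One MDSet; establishes the domination number ``|MDSet|``.

``solve_two_most_different``
    Two MDSets x, y simultaneously, both of size ``|MDSet|``, with the
    number of differing nodes maximized. The XOR of two binaries is
    linearized with an auxiliary z per node via
    ``x + y + z <= 2`` and ``x + y - z >= 0``: maximizing ``sum z``
    drives z to 1 exactly where x and y disagree. The overlap of the
    pair is a tight upper envelope of the network's critical set.

``solve_iterative``
    Repeatedly finds an MDSet maximally different from the union of all
    MDSets generated so far (the union indicator enters as fixed data),
    stopping when a round contributes no new node. The resulting
    collection supports exact node classification at a handful of
    solver calls instead of one call per MDSet member.

``solve_user_defined``
    One MDSet that, at minimum size, avoids a designated node set as
    far as possible. Minimizing membership of a target set passes the
    targets as the avoid vector; maximizing passes their complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse

from .graph_io import GeneSet, Network, NeighborhoodMatrix, closed_neighborhood
from . import milp_engine
from .milp_engine import MilpProblem, MilpSolution, SolverError

__all__ = [
    "DominatingSet",
    "MdsetPair",
    "MdsetCollection",
    "UrdConstraint",
    "basic_problem",
    "two_most_different_problem",
    "diversified_problem",
    "solve_basic",
    "solve_two_most_different",
    "solve_iterative",
    "solve_user_defined",
]


@dataclass(frozen=True)
class DominatingSet:
    """A dominating node subset with solve provenance."""

    members: frozenset[str]
    model: Literal["basic", "2md", "itr", "urd"]
    solver_status: str
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class MdsetPair:
    """Two equal-size MDSets with maximal symmetric difference."""

    first: DominatingSet
    second: DominatingSet

    @property
    def overlap(self) -> frozenset[str]:
        return self.first.members & self.second.members

    @property
    def difference_count(self) -> int:
        return len(self.first.members ^ self.second.members)


@dataclass(frozen=True)
class MdsetCollection:
    """Ordered MDSets from one iterative run; the union drives strata."""

    mdsets: tuple[DominatingSet, ...]
    truncated: bool = False

    @property
    def k(self) -> int:
        return len(self.mdsets)

    @property
    def covered(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.mdsets:
            out |= m.members
        return frozenset(out)


@dataclass(frozen=True)
class UrdConstraint:
    """A target gene set plus the optimization direction over it."""

    targets: GeneSet
    mode: Literal["maximize", "minimize"]

    def __post_init__(self) -> None:
        if self.mode not in ("maximize", "minimize"):
            raise ValueError(f"mode must be maximize|minimize, got {self.mode!r}")


def _ones(n: int) -> np.ndarray:
    return np.ones(n, dtype=np.float64)


def _zeros(n: int) -> np.ndarray:
    return np.zeros(n, dtype=np.float64)


def basic_problem(nm: NeighborhoodMatrix) -> MilpProblem:
    """min sum(x) s.t. A x >= 1, x binary (upper row bound is the loose n)."""
    n = nm.n
    return MilpProblem(
        c=_ones(n),
        a=nm.entries,
        lc=_ones(n),
        uc=n * _ones(n),
        lx=_zeros(n),
        ux=_ones(n),
        sense="min",
    )


def two_most_different_problem(nm: NeighborhoodMatrix, mdset_size: int) -> MilpProblem:
    """The 3n-variable coupled system over blocks [x | y | z].

    Rows, in order: the two covering systems, the two size-equality
    rows pinning ``sum x = sum y = |MDSet|``, then the XOR-linearization
    blocks ``x + y + z in [0, 2]`` and ``x + y - z in [0, 2]``.
    """
    n = nm.n
    a = nm.entries
    eye = sparse.identity(n, dtype=np.int64, format="csr")
    zn = sparse.csr_matrix((n, n), dtype=np.int64)
    ones_row = sparse.csr_matrix(np.ones((1, n), dtype=np.int64))
    zrow = sparse.csr_matrix((1, n), dtype=np.int64)
    big_a = sparse.vstack(
        [
            sparse.hstack([a, zn, zn]),
            sparse.hstack([zn, a, zn]),
            sparse.hstack([ones_row, zrow, zrow]),
            sparse.hstack([zrow, ones_row, zrow]),
            sparse.hstack([eye, eye, eye]),
            sparse.hstack([eye, eye, -eye]),
        ],
        format="csr",
    )
    big_c = np.concatenate([_zeros(n), _zeros(n), _ones(n)])
    lc = np.concatenate([_ones(n), _ones(n), [mdset_size, mdset_size], _zeros(n), _zeros(n)])
    uc = np.concatenate(
        [n * _ones(n), n * _ones(n), [mdset_size, mdset_size], 2 * _ones(n), 2 * _ones(n)]
    )
    return MilpProblem(
        c=big_c, a=big_a, lc=lc, uc=uc,
        lx=_zeros(3 * n), ux=_ones(3 * n), sense="max",
    )


def diversified_problem(
    nm: NeighborhoodMatrix, mdset_size: int, avoid: np.ndarray
) -> MilpProblem:
    """The 2n-variable system over blocks [y | z] against a fixed avoid vector.

    ``avoid`` is the binary vector x of nodes the new MDSet y should
    steer clear of. Rows, in order: the covering system ``A y >= 1``,
    the size row ``sum y = |MDSet|``, then the coupled blocks
    ``y + z <= 2 - x`` and ``y - z >= -x``. With x fixed, maximizing
    ``sum z`` maximizes the Hamming distance between y and x at fixed
    ``sum y``, i.e. minimizes ``|y ∩ x|``.
    """
    n = nm.n
    x = np.asarray(avoid, dtype=np.float64)
    if x.shape != (n,):
        raise ValueError("avoid vector length must equal node count")
    eye = sparse.identity(n, dtype=np.int64, format="csr")
    zn = sparse.csr_matrix((n, n), dtype=np.int64)
    ones_row = sparse.csr_matrix(np.ones((1, n), dtype=np.int64))
    zrow = sparse.csr_matrix((1, n), dtype=np.int64)
    big_a = sparse.vstack(
        [
            sparse.hstack([nm.entries, zn]),
            sparse.hstack([ones_row, zrow]),
            sparse.hstack([eye, eye]),
            sparse.hstack([eye, -eye]),
        ],
        format="csr",
    )
    big_c = np.concatenate([_zeros(n), _ones(n)])
    lc = np.concatenate([_ones(n), [mdset_size], _zeros(n), -x])
    uc = np.concatenate([n * _ones(n), [mdset_size], 2.0 - x, _ones(n)])
    return MilpProblem(
        c=big_c, a=big_a, lc=lc, uc=uc,
        lx=_zeros(2 * n), ux=_ones(2 * n), sense="max",
    )


def _members_from(x: np.ndarray, net: Network) -> frozenset[str]:
    return frozenset(net.node_ids[i] for i in np.flatnonzero(x))


def _check_domination(net: Network, nm: NeighborhoodMatrix, members: frozenset[str]) -> None:
    x = np.zeros(net.n, dtype=np.int64)
    for v in members:
        x[nm.index_map[v]] = 1
    cover = sparse.csr_matrix(nm.entries).astype(np.int64) @ x
    if np.any(cover < 1):
        raise SolverError("returned set does not dominate the network")


def solve_basic(
    net: Network,
    seed: int = 0,
    backend: str = "highs",
    time_limit: float | None = None,
    _nm: NeighborhoodMatrix | None = None,
) -> DominatingSet:
    """Compute one minimum dominating set; its size is the domination number."""
    nm = _nm if _nm is not None else closed_neighborhood(net)
    sol = milp_engine.solve(basic_problem(nm), seed=seed, time_limit=time_limit, backend=backend)
    if sol.status != "optimal":
        raise SolverError(f"basic model did not reach optimality: {sol.status}")
    members = _members_from(sol.x, net)
    _check_domination(net, nm, members)
    return DominatingSet(
        members=members, model="basic", solver_status=sol.status,
        provenance={"solver": sol.solver_name, "seed": seed, "objective": sol.objective},
    )


def solve_two_most_different(
    net: Network,
    seed: int = 0,
    backend: str = "highs",
    time_limit: float | None = None,
    _nm: NeighborhoodMatrix | None = None,
    _mdset_size: int | None = None,
) -> MdsetPair:
    """Two equal-size MDSets with the maximum number of differing nodes."""
    nm = _nm if _nm is not None else closed_neighborhood(net)
    m = _mdset_size if _mdset_size is not None else solve_basic(net, seed, backend, time_limit, _nm=nm).size
    sol = milp_engine.solve(
        two_most_different_problem(nm, m), seed=seed, time_limit=time_limit, backend=backend
    )
    if sol.status != "optimal":
        raise SolverError(f"2MD model did not reach optimality: {sol.status}")
    n = net.n
    prov = {"solver": sol.solver_name, "seed": seed, "difference": sol.objective}
    first = DominatingSet(
        members=_members_from(sol.x[:n], net), model="2md",
        solver_status=sol.status, provenance=prov,
    )
    second = DominatingSet(
        members=_members_from(sol.x[n : 2 * n], net), model="2md",
        solver_status=sol.status, provenance=prov,
    )
    for ds in (first, second):
        _check_domination(net, nm, ds.members)
        if ds.size != m:
            raise SolverError("2MD set size deviates from the domination number")
    return MdsetPair(first=first, second=second)


def solve_iterative(
    net: Network,
    max_iter: int | None = None,
    seed: int = 0,
    backend: str = "highs",
    time_limit: float | None = None,
) -> MdsetCollection:
    """Generate MDSets until a round adds no node not already covered.

    Starts from the two-most-different pair; every further round solves
    for an MDSet maximally different from the running union X. The
    terminating MDSet (the one contributing nothing new) is retained in
    the collection. ``max_iter`` defaults to 2n as a safety bound; the
    union grows strictly every productive round, so at most n rounds can
    be productive.
    """
    nm = closed_neighborhood(net)
    if max_iter is None:
        max_iter = 2 * net.n
    if max_iter < 2:
        raise ValueError("max_iter must be at least 2")
    pair = solve_two_most_different(net, seed=seed, backend=backend, time_limit=time_limit, _nm=nm)
    m = pair.first.size
    mdsets: list[DominatingSet] = [
        DominatingSet(pair.first.members, "itr", pair.first.solver_status,
                      {**pair.first.provenance, "iteration": 1}),
        DominatingSet(pair.second.members, "itr", pair.second.solver_status,
                      {**pair.second.provenance, "iteration": 2}),
    ]
    covered: set[str] = set(pair.first.members | pair.second.members)
    # A zero-difference pair proves the MDSet unique (any second MDSet would
    # give a positive maximum difference), so no round can add a node.
    if pair.first.members == pair.second.members:
        return MdsetCollection(mdsets=tuple(mdsets), truncated=False)
    truncated = False
    while True:
        if len(mdsets) >= max_iter:
            truncated = True
            break
        avoid = np.zeros(net.n, dtype=np.float64)
        for v in covered:
            avoid[nm.index_map[v]] = 1.0
        sol = milp_engine.solve(
            diversified_problem(nm, m, avoid), seed=seed, time_limit=time_limit, backend=backend
        )
        if sol.status != "optimal":
            raise SolverError(f"iterative model did not reach optimality: {sol.status}")
        members = _members_from(sol.x[: net.n], net)
        _check_domination(net, nm, members)
        if len(members) != m:
            raise SolverError("iterative set size deviates from the domination number")
        mdsets.append(
            DominatingSet(members, "itr", sol.status,
                          {"solver": sol.solver_name, "seed": seed,
                           "iteration": len(mdsets) + 1,
                           "new_nodes": len(members - covered)})
        )
        new = members - covered
        if not new:
            break
        covered |= new
    return MdsetCollection(mdsets=tuple(mdsets), truncated=truncated)


def solve_user_defined(
    net: Network,
    constraint: UrdConstraint,
    seed: int = 0,
    backend: str = "highs",
    time_limit: float | None = None,
) -> DominatingSet:
    """One MDSet with the extreme target-set membership at minimum size.

    mode="minimize": the avoid vector marks the targets themselves, so
    the solver steers the MDSet away from them as far as domination at
    minimum size allows. mode="maximize": the avoid vector marks the
    complement of the targets — maximizing Hamming distance from the
    complement at fixed set size is the same as maximizing target
    membership.
    """
    nm = closed_neighborhood(net)
    m = solve_basic(net, seed=seed, backend=backend, time_limit=time_limit, _nm=nm).size
    targets = constraint.targets.restricted_to(net)
    avoid = np.zeros(net.n, dtype=np.float64)
    if constraint.mode == "minimize":
        for v in targets:
            avoid[nm.index_map[v]] = 1.0
    else:
        avoid[:] = 1.0
        for v in targets:
            avoid[nm.index_map[v]] = 0.0
    sol = milp_engine.solve(
        diversified_problem(nm, m, avoid), seed=seed, time_limit=time_limit, backend=backend
    )
    if sol.status != "optimal":
        raise SolverError(f"user-defined model did not reach optimality: {sol.status}")
    members = _members_from(sol.x[: net.n], net)
    _check_domination(net, nm, members)
    if len(members) != m:
        raise SolverError("user-defined set size deviates from the domination number")
    return DominatingSet(
        members=members, model="urd", solver_status=sol.status,
        provenance={"solver": sol.solver_name, "seed": seed,
                    "mode": constraint.mode, "target_set": constraint.targets.name,
                    "target_count": len(members & targets)},
    )
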