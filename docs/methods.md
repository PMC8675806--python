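# Methods

## Problem and model

Given an undirected graph G(V, E) with |V| = n — here a protein–protein
interaction (PPI) network with proteins as nodes — a set D ⊆ V *dominates*
G when every node is in D or adjacent to a member of D. Writing A for the
closed-neighborhood matrix (adjacency with unit diagonal, A_ij = 1 iff
i = j or {i, j} ∈ E) and x ∈ {0,1}^n for the indicator of D, domination is
the linear system A x ≥ 1 and a *minimum* dominating set (MDSet) solves

    min Σ x_j   s.t.  A x ≥ 1,  x binary.

All models in this package are binary integer programs in the canonical
two-sided form `optimize C'x s.t. Lc ≤ Ax ≤ Uc, Lx ≤ x ≤ Ux`, built by
`moia_models` and solved by `milp_engine`.

MDSets are highly non-unique; which one a solver returns is an artifact of
its internals. The package controls this degeneracy rather than ignoring
it:

* **Two most different MDSets.** A 3n-variable program over blocks
  [x | y | z] forces both x and y to be MDSets of the minimum size m
  (two equality rows Σx = Σy = m, with m from a fresh basic solve) and
  maximizes Σ z under the XOR linearization
  `x_i + y_i + z_i ≤ 2` and `x_i + y_i − z_i ≥ 0`: z_i can reach 1 exactly
  where x_i ≠ y_i. The pair's overlap is a tight superset of the critical
  set (nodes in *every* MDSet) at two solver calls instead of 1 + m.
* **Iterative diversification.** Starting from the pair's union X, the
  2n-variable variant fixes x := indicator(X) as data
  (`y_i + z_i ≤ 2 − x_i`, `y_i − z_i ≥ −x_i`, Σy = m) and maximizes Σ z,
  i.e. finds an MDSet with as many not-yet-covered nodes as possible.
  Rounds repeat until one adds no new node; that terminal set is kept in
  the collection so membership counts reflect every generated set. One
  exception is short-circuited: when the two-set solve returns a pair with
  zero difference, the MDSet is provably unique (any distinct second MDSet
  would make the maximal difference positive), no round can ever add a
  node, and the loop is skipped (k = 2).
* **User-constrained MDSets.** The same fixed-x system doubles as an
  avoid-vector model: maximizing the Hamming distance from a fixed
  indicator at fixed set size minimizes overlap with it. Minimizing
  membership of a target set passes the targets as the avoid vector;
  maximizing passes their complement. The latter mapping is this package's
  design choice — avoid semantics are the primitive, and complementation
  at fixed Σy = m makes max-membership exactly equivalent.

## Classification

For a collection of k generated MDSets, each node's membership count
j ∈ {0..k} yields a partition: k-critical (j = k), intermittent
(1 ≤ j ≤ k−1), redundant (j = 0); the (k−1)-critical set (j = k−1) is
reported separately because in PPI networks it is nearly as enriched in
essential genes, kinases and transcription factors as the critical set.
Two definitional choices keep the arithmetic consistent: intermittent
excludes the k-critical nodes (so the three categories partition V), and
(k−1)-critical means *exactly* k−1 memberships (disjoint from k-critical).
Strata are relative to the generated collection, not to the unenumerable
family of all MDSets; the iterative model's k-critical set is guaranteed
to be a superset of the true critical set, and its histogram over j/k
traces the bathtub-shaped criticalness profile.

## Oracles

Two independent ground-truth routes validate the models:

* `traditional_critical_set` — one baseline solve plus, for each member v
  of the found MDSet, a re-solve with v forbidden (variable upper bound
  Ux_v = 0, the same feasible set as adding x_v = 0); v is critical iff
  the optimum rises or the model becomes infeasible (isolated nodes).
  Only members of one MDSet need testing, since a critical node is in
  every MDSet. Cost: 1 + m solver calls — the baseline the coupled model
  is designed to beat.
* `enumerate_all_mdsets` — exhaustive enumeration for n ≤ 15 using
  bitmask closed neighborhoods, scanning subset sizes upward and forcing
  isolated nodes into every candidate; yields the exact critical /
  intermittent / redundant partition by direct intersection and union.

The forced-inclusion dual (`traditional_intermittent_test`, fix x_v = 1)
decides membership in *some* MDSet.

## Solver

The MILP backend is HiGHS via `scipy.optimize.milp`, run at zero
MIP gap: the critical-set logic ("did forbidding v raise the optimum?")
is only sound with proven optima. All model data are integers, so every
returned solution is re-validated post hoc in exact integer arithmetic
(rounding at 1e−6) against every constraint — backend feasibility reports
are never trusted. A second backend ("brute", exhaustive over binary
vectors, ≤ 18 free variables) provides solver-independent optima for
cross-checks in the test suite. Ties among optimal solutions are
solver-chosen; runs record solver name and seed, though HiGHS as driven
by scipy exposes no RNG control.

## Enrichment

Over-representation of an annotation set (essential genes, kinases,
transcription factors, drug targets, …) in a node set is tested
one-sided against the hypergeometric null: p = P(X ≥ overlap) with
X ~ Hypergeom(N = network size, K = annotation ∩ network,
n = node-set size), enriched at α = 0.05 by default. One-sided "greater"
is an explicit assumption — the scientific question is
over-representation. The universe is the network node count; annotation
members absent from the network are excluded from the margins. No
multiple-testing correction is applied across annotation sets; consumers
running many tests should correct downstream.

## Synthetic fixtures

Real interactome snapshots are external downloads and are deliberately
outside the build/test loop; the generators emulate their structural
roles at test scale:

* **Erdős–Rényi** G(n, p): unstructured instances whose full domination
  structure the enumerator can certify. The validation suite cycles
  n over 6–12 and p over {0.15, 0.3, 0.5} — sparse through dense — with
  200 instances per run; sizes are capped by the enumeration oracle, not
  by the models, which handle thousands of nodes.
* **Star forests**: planted instances with answers known by
  construction — with ≥ 2 leaves per center the center set is the unique
  MDSet, so critical = centers and redundant = leaves exactly.
* **Preferential attachment** (one fixed dialect: m-clique seed, m
  distinct degree-weighted targets per arriving node, weights degree + 1
  so the edgeless m = 1 seed is samplable; no multi-edges): the
  hub-dominated degree structure characteristic of PPI networks, with an
  assertable edge count C(m,2) + m(n−m).

All generators are pure functions of an explicit integer seed. What
passing tests do *not* show: synthetic graphs at this scale have no
protein-complex community structure, no degree-correlation profile of
real interactomes, and domination numbers of tens rather than thousands;
conclusions about specific biological networks require running the models
on those networks.

## Numerical and degenerate-input choices

* Integrality and constraint tolerance 1e−6; feasibility re-checked in
  exact integer arithmetic after rounding.
* Input self-loops are dropped (the diagonal is analytic); duplicate and
  reversed edges collapse; isolated nodes are legal and appear in every
  MDSet.
* `max_iter` for the iterative model defaults to 2n (the union grows
  strictly each productive round, so ≤ n rounds can be productive);
  exhaustion returns a collection flagged truncated rather than raising.
* Enumeration refuses n > 15 by default rather than silently running an
  exponential search.
* p-values are clamped to [0, 1] and p(overlap = 0) = 1 exactly.

## Known limitations

* The 2MD overlap can strictly exceed the true critical set; only the
  superset property is guaranteed (equality frequency is measured and, on
  the validation suite, is universal).
* No identifier mapping between annotation conventions: gene-set members
  absent from the network are counted and reported, never remapped.
* Weighted, connected or centrality-corrected domination variants are out
  of scope.
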