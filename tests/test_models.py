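from itertools import permutations

import pytest

from ppidom.graph_io import GeneSet, Network
from ppidom.models import (
    UrdConstraint,
    solve_basic,
    solve_iterative,
    solve_two_most_different,
    solve_user_defined,
)
from ppidom.oracles import enumerate_all_mdsets
from ppidom.synth_fixtures import er_validation_suite

from conftest import cycle_graph, path_graph


def _dominates(net: Network, members) -> bool:
    closed = {v: {v} for v in net.node_ids}
    for u, v in net.edges:
        closed[u].add(v)
        closed[v].add(u)
    return all(closed[v] & set(members) for v in net.node_ids)


class TestSolveBasic:
    def test_star_center(self, star5):
        assert solve_basic(star5).members == {"c"}

    # domination numbers frozen from exhaustive subset search:
    # path4 -> 2, cycle7 -> 3
    @pytest.mark.parametrize("net,gamma", [(path_graph(4), 2), (cycle_graph(7), 3)])
    def test_known_domination_numbers(self, net, gamma):
        ds = solve_basic(net)
        assert ds.size == gamma
        assert _dominates(net, ds.members)

    def test_isolated_node_always_selected(self):
        net = Network.from_edges([("A", "B")], extra_nodes=["Z"])
        assert "Z" in solve_basic(net).members

    def test_provenance_records_solver_and_seed(self, path4):
        ds = solve_basic(path4, seed=11)
        assert ds.provenance["solver"] == "highs"
        assert ds.provenance["seed"] == 11


class TestTwoMostDifferent:
    def test_cycle4_pair_is_disjoint(self, cycle4):
        # exhaustive check: C4 has disjoint size-2 MDSets ({0,2} vs {1,3})
        pair = solve_two_most_different(cycle4)
        assert pair.first.size == pair.second.size == 2
        assert pair.overlap == frozenset()
        assert pair.difference_count == 4

    def test_star_unique_mdset_forces_full_overlap(self, star5):
        pair = solve_two_most_different(star5)
        assert pair.first.members == pair.second.members == {"c"}
        assert pair.difference_count == 0

    def test_path4_pair_is_disjoint(self, path4):
        pair = solve_two_most_different(path4)
        assert pair.overlap == frozenset()

    def test_difference_count_identity(self, cycle4):
        pair = solve_two_most_different(cycle4)
        assert pair.difference_count == 2 * (pair.first.size - len(pair.overlap))

    def test_pair_attains_enumerated_maximum_hamming(self):
        """On small graphs the coupled solve must reach the exact maximum
        symmetric difference over all ordered MDSet pairs."""
        for net in er_validation_suite(12, seed=5):
            exact = enumerate_all_mdsets(net)
            best = max(
                len(a ^ b) for a, b in permutations(exact.all_mdsets, 2)
            ) if len(exact.all_mdsets) > 1 else 0
            pair = solve_two_most_different(net)
            assert pair.difference_count == best


class TestIterative:
    def test_star_terminates_at_k2(self, star5):
        coll = solve_iterative(star5)
        assert coll.k == 2
        assert coll.covered == {"c"}
        assert not coll.truncated

    def test_cycle4_covers_every_node(self, cycle4):
        # all six node-pairs of C4 are MDSets, so every node is attainable
        coll = solve_iterative(cycle4)
        assert coll.covered == cycle4.node_set
        assert coll.k <= 4

    def test_two_disjoint_stars_unique_mdset(self, two_stars):
        coll = solve_iterative(two_stars)
        assert coll.covered == {"c1", "c2"}
        assert all(m.members == {"c1", "c2"} for m in coll.mdsets)

    def test_union_grows_monotonically_and_terminal_set_kept(self, cycle4):
        coll = solve_iterative(cycle4)
        seen = set()
        for i, m in enumerate(coll.mdsets):
            new = m.members - seen
            if i < coll.k - 1 and i >= 2:
                assert new  # every non-terminal round past the pair adds nodes
            seen |= m.members
        assert not (coll.mdsets[-1].members - set().union(
            *(m.members for m in coll.mdsets[:-1])
        ))

    def test_all_sets_share_the_domination_number(self):
        for net in er_validation_suite(6, seed=9):
            gamma = enumerate_all_mdsets(net).domination_number
            coll = solve_iterative(net)
            assert {m.size for m in coll.mdsets} == {gamma}

    def test_max_iter_truncation_flagged(self, cycle4):
        coll = solve_iterative(cycle4, max_iter=2)
        assert coll.k == 2 and coll.truncated

    def test_max_iter_below_two_rejected(self, cycle4):
        with pytest.raises(ValueError):
            solve_iterative(cycle4, max_iter=1)


class TestUserDefined:
    def test_path4_maximize_endpoints(self, path4):
        # {0,3} is dominating, so 2 targets is attainable and maximal
        ds = solve_user_defined(path4, UrdConstraint(GeneSet("ends", frozenset({"0", "3"})), "maximize"))
        assert ds.members == {"0", "3"}
        assert ds.provenance["target_count"] == 2

    def test_path4_minimize_node0(self, path4):
        # exhaustive over size-2 MDSets: {1,3}, {1,2}... avoid 0 entirely
        ds = solve_user_defined(path4, UrdConstraint(GeneSet("g", frozenset({"0"})), "minimize"))
        assert "0" not in ds.members
        assert ds.size == 2

    def test_star_minimize_center_cannot_avoid_it(self, star5):
        ds = solve_user_defined(star5, UrdConstraint(GeneSet("g", frozenset({"c"})), "minimize"))
        assert ds.members == {"c"}
        assert ds.provenance["target_count"] == 1

    def test_ordering_min_le_basic_le_max(self):
        """Target membership is ordered min <= basic <= max for any gene set."""
        import random

        rnd = random.Random(3)
        for net in er_validation_suite(10, seed=2):
            targets = frozenset(rnd.sample(list(net.node_ids), max(1, net.n // 3)))
            gs = GeneSet("t", targets)
            lo = solve_user_defined(net, UrdConstraint(gs, "minimize"))
            hi = solve_user_defined(net, UrdConstraint(gs, "maximize"))
            base = solve_basic(net)
            assert (
                len(lo.members & targets)
                <= len(base.members & targets)
                <= len(hi.members & targets)
            )
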