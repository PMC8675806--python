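import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppidom.graph_io import (
    EdgeListError,
    Network,
    closed_neighborhood,
    load_edge_list,
    load_gene_set,
    write_edge_list,
)


def _write(tmp_path, name, lines):
    f = tmp_path / name
    f.write_text("\n".join(lines) + "\n")
    return f


class TestLoadEdgeList:
    def test_basic_parse(self, tmp_path):
        f = _write(tmp_path, "e.tsv", ["A\tB", "B\tC"])
        net = load_edge_list(f)
        assert net.n == 3
        assert len(net.edges) == 2

    def test_undirected_dedupe(self, tmp_path):
        f = _write(tmp_path, "e.tsv", ["A\tB", "B\tA", "A\tB"])
        net = load_edge_list(f)
        assert net.n == 2
        assert net.edges == frozenset({("A", "B")})

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        f = _write(tmp_path, "e.tsv", ["A\tA"])
        with caplog.at_level(logging.WARNING):
            net = load_edge_list(f)
        assert net.n == 1 and not net.edges
        assert any("self-loop" in r.message for r in caplog.records)

    def test_self_loop_rejected_in_strict_mode(self, tmp_path):
        f = _write(tmp_path, "e.tsv", ["A\tA"])
        with pytest.raises(EdgeListError, match="self-loop"):
            load_edge_list(f, allow_self_loops=False)

    def test_malformed_line_reports_number(self, tmp_path):
        f = _write(tmp_path, "e.tsv", ["A\tB", "lonely"])
        with pytest.raises(EdgeListError, match=":2:"):
            load_edge_list(f)

    def test_empty_file_is_error(self, tmp_path):
        f = _write(tmp_path, "e.tsv", ["# only a comment"])
        with pytest.raises(EdgeListError, match="no edges"):
            load_edge_list(f)

    def test_comments_and_whitespace_fallback(self, tmp_path):
        f = _write(tmp_path, "e.txt", ["# header", "A B", "B C"])
        assert load_edge_list(f).n == 3

    def test_sif_mode_ignores_relation(self, tmp_path):
        f = _write(tmp_path, "e.sif", ["A pp B", "B pp C"])
        net = load_edge_list(f, sif=True)
        assert net.node_set == {"A", "B", "C"}

    def test_node_list_admits_singletons(self, tmp_path):
        f = _write(tmp_path, "e.tsv", ["A\tB"])
        nl = _write(tmp_path, "n.txt", ["A", "Z"])
        net = load_edge_list(f, node_list=nl)
        assert "Z" in net.node_set and net.n == 3


class TestNetworkInvariants:
    def test_duplicate_nodes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Network(node_ids=("A", "A"), edges=frozenset())

    def test_edge_to_unknown_node_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            Network(node_ids=("A",), edges=frozenset({("A", "B")}))

    @given(
        st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 8)).filter(lambda e: e[0] != e[1]),
            min_size=1,
            max_size=25,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_preserves_node_and_edge_sets(self, tmp_path_factory, raw):
        net = Network.from_edges([(str(a), str(b)) for a, b in raw])
        path = tmp_path_factory.mktemp("rt") / "e.tsv"
        write_edge_list(net, path)
        back = load_edge_list(path)
        assert back.node_set == {u for e in net.edges for u in e}
        assert back.edges == net.edges


class TestClosedNeighborhood:
    def test_path_has_seven_ones(self):
        net = Network.from_edges([("A", "B"), ("B", "C")])
        nm = closed_neighborhood(net)
        assert nm.dense().sum() == 7
        assert np.all(np.diag(nm.dense()) == 1)

    def test_complete_graph_all_ones(self):
        nodes = ["A", "B", "C", "D"]
        net = Network.from_edges([(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]])
        assert np.all(closed_neighborhood(net).dense() == 1)

    def test_isolated_node_row_is_unit(self):
        net = Network.from_edges([("A", "B")], extra_nodes=["Z"])
        nm = closed_neighborhood(net)
        row = nm.dense()[nm.index_map["Z"]]
        assert row.sum() == 1 and row[nm.index_map["Z"]] == 1

    def test_row_sums_are_degree_plus_one(self, path4):
        nm = closed_neighborhood(path4)
        dense = nm.dense()
        for v in path4.node_ids:
            assert dense[nm.index_map[v]].sum() == path4.degree(v) + 1

    def test_symmetry_and_ordering_follow_node_ids(self, cycle4):
        nm = closed_neighborhood(cycle4)
        d = nm.dense()
        assert np.array_equal(d, d.T)
        assert list(nm.index_map) == list(cycle4.node_ids)

    def test_permuting_nodes_permutes_matrix_consistently(self, path4):
        perm = Network(node_ids=tuple(reversed(path4.node_ids)), edges=path4.edges)
        a, b = closed_neighborhood(path4), closed_neighborhood(perm)
        da, db = a.dense(), b.dense()
        for u in path4.node_ids:
            for v in path4.node_ids:
                assert da[a.index_map[u], a.index_map[v]] == db[b.index_map[u], b.index_map[v]]


class TestGeneSet:
    def test_load_and_restrict(self, tmp_path, path4):
        f = _write(tmp_path, "gs.txt", ["0", "2"])
        gs = load_gene_set(f, path4)
        assert gs.members == {"0", "2"}
        assert gs.restricted_to(path4) == {"0", "2"}

    def test_missing_members_kept_and_flagged(self, tmp_path, caplog):
        net = Network.from_edges([("A", "B")])
        f = _write(tmp_path, "gs.txt", ["A", "Z"])
        with caplog.at_level(logging.WARNING):
            gs = load_gene_set(f, net)
        assert len(gs.members) == 2
        assert any("absent" in r.message for r in caplog.records)

    def test_duplicates_collapse(self, tmp_path):
        f = _write(tmp_path, "gs.txt", ["A", "A"])
        assert len(load_gene_set(f).members) == 1

    def test_empty_set_is_error(self, tmp_path):
        f = _write(tmp_path, "gs.txt", ["# nothing"])
        with pytest.raises(EdgeListError, match="empty"):
            load_gene_set(f)
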