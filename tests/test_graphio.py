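"""Interaction parsing, network building and LCC extraction."""

from __future__ import annotations

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from hubnet import graphio
from hubnet.graphio import (DialectError, EmptyInputError, InteractionRecord,
                            InteractionTable, build_network,
                            largest_connected_component, parse_interactions,
                            read_graph_tsv, read_seeds, write_graph_tsv)


def _table(*pairs, scores=None):
    recs = [InteractionRecord(a, b, None if scores is None else scores[i])
            for i, (a, b) in enumerate(pairs)]
    return InteractionTable(records=recs)


class TestParseInteractions:
    def test_edgelist_dedups_exact_duplicates(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nB\tC\nA\tB\n")
        assert len(parse_interactions(p, "edgelist")) == 2

    def test_edgelist_dedups_reversed_pairs_and_case(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a\tB\nB\tA\n# comment\n\n")
        table = parse_interactions(p, "edgelist")
        assert [r.key() for r in table.records] == [("A", "B")]

    def test_string_links_score_threshold(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("protein1 protein2 combined_score\n"
                     "A B 950\nB C 400\n")
        table = parse_interactions(p, "string_links", score_min=700)
        assert len(table) == 1
        assert table.records[0].score == 950

    def test_biogrid_tab3_drops_self_interactions(self, tmp_path):
        p = tmp_path / "b.txt"
        header = ("#BioGRID Interaction ID\tOfficial Symbol Interactor A\t"
                  "Official Symbol Interactor B\tThroughput\n")
        rows = ["1\tA\tB\t-", "2\tB\tC\t-", "3\tA\tA\t-", "4\tC\tD\t-",
                "5\tD\tA\t-"]
        p.write_text(header + "\n".join(rows) + "\n")
        table = parse_interactions(p, "biogrid_tab3")
        assert len(table) == 4
        assert all(r.a != r.b for r in table.records)

    def test_malformed_rows_skipped_and_counted(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nonly_one_field\nC\tD\n")
        table = parse_interactions(p, "edgelist")
        assert len(table) == 2
        assert table.n_skipped == 1

    def test_unknown_dialect_is_configuration_error(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\n")
        with pytest.raises(DialectError):
            parse_interactions(p, "tab_separated")

    def test_zero_usable_rows_raises(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# nothing here\n")
        with pytest.raises(EmptyInputError):
            parse_interactions(p, "edgelist")


class TestBuildNetwork:
    def test_one_hop_adds_direct_partners_only(self):
        table = _table(("A", "B"), ("B", "C"), ("C", "D"))
        g = build_network(["A"], table, expand="one_hop")
        assert set(g.nodes()) == {"A", "B"}
        assert set(map(frozenset, g.edges())) == {frozenset({"A", "B"})}

    def test_one_hop_keeps_partner_partner_edges(self):
        table = _table(("A", "B"), ("A", "C"), ("B", "C"))
        g = build_network(["A"], table, expand="one_hop")
        assert g.number_of_edges() == 3  # B-C kept although neither is a seed

    def test_none_gives_induced_subgraph_on_seeds(self):
        g = build_network(["A", "B"], _table(("A", "B")), expand="none")
        assert (g.number_of_nodes(), g.number_of_edges()) == (2, 1)

    def test_seed_absent_from_table_is_isolated(self):
        g = build_network(["X"], _table(("A", "B")), expand="one_hop")
        assert set(g.nodes()) == {"X"}
        assert g.number_of_edges() == 0

    def test_empty_seed_list_raises(self):
        with pytest.raises(ValueError):
            build_network([], _table(("A", "B")))


class TestLargestConnectedComponent:
    def test_picks_largest(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"),
                      ("X", "Y"), ("Y", "Z")])
        assert set(largest_connected_component(g)) == {"A", "B", "C", "D", "E"}

    def test_connected_graph_is_identity(self):
        g = nx.path_graph(5)
        lcc = largest_connected_component(g)
        assert set(lcc) == set(g) and set(lcc.edges()) == set(g.edges())

    def test_tie_broken_by_smallest_label(self):
        g = nx.Graph([("D", "E"), ("E", "F"), ("A", "B"), ("B", "C")])
        assert set(largest_connected_component(g)) == {"A", "B", "C"}

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            largest_connected_component(nx.Graph())


@st.composite
def random_tables(draw):
    symbols = st.sampled_from(["A", "B", "C", "D", "E", "F"])
    pairs = draw(st.lists(st.tuples(symbols, symbols), min_size=1,
                          max_size=25))
    return InteractionTable(
        records=[InteractionRecord(a, b) for a, b in pairs])


@settings(derandomize=True, max_examples=60)
@given(table=random_tables(),
       seeds=st.lists(st.sampled_from(["A", "B", "C", "G"]), min_size=1,
                      max_size=3, unique=True))
def test_build_network_is_simple_graph(table, seeds):
    """No self-loop or duplicate edge survives, whatever the table."""
    g = build_network(seeds, table, expand="one_hop")
    assert all(u != v for u, v in g.edges())
    assert len(set(map(frozenset, g.edges()))) == g.number_of_edges()
    for u, v in g.edges():
        assert u in g and v in g


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 10 ** 6))
def test_lcc_is_connected_subgraph_of_input(seed):
    g = nx.gnp_random_graph(8, 0.2, seed=seed)
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g})
    lcc = largest_connected_component(g)
    assert nx.is_connected(lcc)
    assert set(lcc) <= set(g)
    assert set(map(frozenset, lcc.edges())) <= set(map(frozenset, g.edges()))


def test_graph_tsv_round_trip_preserves_sets(tmp_path):
    """Edge-list TSV round trip keeps node and edge sets, isolates included."""
    g = nx.Graph([("A", "B"), ("B", "C")])
    g.add_node("LONER")
    path = tmp_path / "g.tsv"
    write_graph_tsv(g, path)
    back = read_graph_tsv(path)
    assert set(back) == set(g)
    assert set(map(frozenset, back.edges())) == set(map(frozenset, g.edges()))


def test_read_seeds_normalizes_and_dedups(tmp_path):
    p = tmp_path / "seeds.txt"
    p.write_text("akt1\nTP53\n# note\nAKT1\n myc \n")
    assert read_seeds(p) == ["AKT1", "TP53", "MYC"]


def test_dialect_writers_round_trip(tmp_path):
    """All three dialect writers reparse to the same interaction set."""
    from hubnet import synthetic as syn
    table = InteractionTable(records=[
        InteractionRecord("A", "B", 900), InteractionRecord("B", "C", 800),
        InteractionRecord("C", "D", 700)])
    expected = {r.key() for r in table.records}
    syn.write_edgelist(table, tmp_path / "e.tsv")
    syn.write_biogrid_tab3(table, tmp_path / "b.txt")
    syn.write_string_links(table, tmp_path / "s.txt")
    for path, dialect in [(tmp_path / "e.tsv", "edgelist"),
                          (tmp_path / "b.txt", "biogrid_tab3"),
                          (tmp_path / "s.txt", "string_links")]:
        back = parse_interactions(path, dialect, score_min=0)
        assert {r.key() for r in back.records} == expected, dialect
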