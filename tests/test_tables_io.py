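import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.tables_io import (
    HERB_CODES,
    CompoundRecord,
    DiseaseTargetRecord,
    FormatError,
    GeneSetCollection,
    InteractionNetwork,
    TargetRecord,
    canonicalize_herb,
    read_compound_table,
    read_disease_table,
    read_edge_list,
    read_gmt,
    read_graphml,
    read_sif,
    read_target_table,
    write_compound_table,
    write_disease_table,
    write_edge_list,
    write_gmt,
    write_network,
    write_target_table,
)

from conftest import random_network


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


class TestFixtures:
    def test_table1_loads_77_entries(self, table1):
        assert len(table1) == 77

    def test_table1_invariants(self, table1):
        for r in table1:
            assert r.mw > 0
            assert r.hdon >= 0 and r.hacc >= 0
            assert 0.0 <= r.dl <= 1.0
            assert r.ob >= 0
            assert r.herb in HERB_CODES

    def test_table1_ob_may_exceed_100(self, table1):
        assert any(r.ob > 100 for r in table1)  # neobaicalein, 104.34

    def test_table2_loads_161_records(self, table2):
        assert len(table2) == 161

    def test_table2_invariants(self, table2):
        for r in table2:
            assert r.gene_symbol
            assert r.herbs and r.herbs <= set(HERB_CODES)

    def test_table2_alias_herb_code_is_canonicalized(self, table2):
        # the source table spells RERR as RRER; the reader canonicalizes
        assert not any("RRER" in r.herbs for r in table2)
        assert any("RERR" in r.herbs for r in table2)

    def test_table3_loads_38_records(self, table3):
        assert len(table3) == 38
        assert all(isinstance(r, DiseaseTargetRecord) for r in table3)
        assert all(r.inference_score is None for r in table3)


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------


def _mk_compound(i, herb="RB", **kw):
    base = dict(mol_id=f"MOL{i:06d}", name=f"c{i}", herb=herb, mw=300.0 + i,
                alogp=1.5, hdon=2, hacc=4, ob=45.0, dl=0.3)
    base.update(kw)
    return CompoundRecord(**base)


class TestCompoundTable:
    def test_round_trip_identity(self, tmp_path):
        records = [_mk_compound(i, herb=HERB_CODES[i % 8]) for i in range(10)]
        path = tmp_path / "c.tsv"
        write_compound_table(records, path)
        assert read_compound_table(path) == records

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("mol_id\tname\therb\tmw\talogp\thdon\thacc\tob\tdl\n")
        assert read_compound_table(path) == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("mol_id\tname\therb\tmw\talogp\thdon\thacc\tob\n")
        with pytest.raises(FormatError, match="dl"):
            read_compound_table(path)

    def test_unparseable_numeric_reports_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "mol_id\tname\therb\tmw\talogp\thdon\thacc\tob\tdl\n"
            "MOL1\tx\tRB\t300\t1.2\t2\t4\t45\t0.3\n"
            "MOL2\ty\tRB\tnot-a-number\t1.2\t2\t4\t45\t0.3\n"
        )
        with pytest.raises(FormatError, match="row 3"):
            read_compound_table(path)

    def test_unknown_herb_code_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "mol_id\tname\therb\tmw\talogp\thdon\thacc\tob\tdl\n"
            "MOL1\tx\tXX\t300\t1.2\t2\t4\t45\t0.3\n"
        )
        with pytest.raises(FormatError, match="herb"):
            read_compound_table(path)

    def test_csv_dialect(self, tmp_path):
        records = [_mk_compound(1)]
        path = tmp_path / "c.csv"
        write_compound_table(records, path, delimiter=",")
        assert read_compound_table(path, delimiter=",") == records

    @pytest.mark.parametrize("alias,canonical", [("RRER", "RERR"), ("rb", "RB")])
    def test_herb_aliases(self, alias, canonical):
        assert canonicalize_herb(alias) == canonical

    def test_record_invariant_violations(self):
        with pytest.raises(ValueError):
            _mk_compound(1, mw=-5.0)
        with pytest.raises(ValueError):
            _mk_compound(1, dl=1.5)
        with pytest.raises(ValueError):
            _mk_compound(1, hdon=-1)


class TestTargetAndDiseaseTables:
    def test_target_round_trip(self, tmp_path):
        records = [
            TargetRecord("P1", "protein one", "GENE1", frozenset({"RB", "JF"})),
            TargetRecord("P2", "protein two", "GENE2", frozenset({"SR"})),
        ]
        path = tmp_path / "t.tsv"
        write_target_table(records, path)
        assert read_target_table(path) == records

    def test_disease_round_trip_with_and_without_scores(self, tmp_path):
        records = [
            DiseaseTargetRecord("GENE1", 57.56),
            DiseaseTargetRecord("GENE2", None),
        ]
        path = tmp_path / "d.tsv"
        write_disease_table(records, path)
        assert read_disease_table(path) == records

    def test_empty_gene_symbol_rejected(self):
        with pytest.raises(ValueError):
            TargetRecord("P1", "x", "  ", frozenset({"RB"}))

    def test_empty_herb_set_rejected(self):
        with pytest.raises(ValueError):
            TargetRecord("P1", "x", "GENE1", frozenset())

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            DiseaseTargetRecord("GENE1", -1.0)


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


class TestEdgeList:
    def test_dedup_and_self_loop_rules(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("A\tB\t700\nB\tA\t700\nC\tC\t900\n")
        net = read_edge_list(path, score_scale="string1000")
        assert net.nodes == {"A", "B", "C"}
        assert net.edges() == [("A", "B", 0.700)]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("")
        net = read_edge_list(path)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_duplicate_rows_keep_max_confidence(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("A\tB\t0.4\nB\tA\t0.9\n")
        net = read_edge_list(path)
        assert net.confidence("A", "B") == 0.9

    def test_score_out_of_scale_reports_line(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("A\tB\t700\n")
        with pytest.raises(FormatError, match="line 1"):
            read_edge_list(path, score_scale="unit")

    def test_string1000_out_of_range(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("A\tB\t1500\n")
        with pytest.raises(FormatError, match="line 1"):
            read_edge_list(path, score_scale="string1000")

    def test_random_file_matches_set_oracle(self, tmp_path):
        rng = random.Random(7)
        rows = []
        for _ in range(50):
            u = f"n{rng.randrange(12)}"
            v = f"n{rng.randrange(12)}"
            rows.append((u, v, rng.randrange(1000)))
        path = tmp_path / "e.tsv"
        path.write_text("".join(f"{u}\t{v}\t{s}\n" for u, v, s in rows))
        net = read_edge_list(path, score_scale="string1000")
        expected_pairs = {frozenset((u, v)) for u, v, _ in rows if u != v}
        assert net.n_edges == len(expected_pairs)
        expected_nodes = {x for u, v, _ in rows for x in (u, v)}
        assert net.nodes == expected_nodes

    def test_round_trip(self, tmp_path):
        rng = random.Random(3)
        net = random_network(rng, 10, 0.3)
        net.add_node("isolated")
        path = tmp_path / "rt.tsv"
        write_edge_list(net, path)
        assert read_edge_list(path) == net

    @given(
        rows=st.lists(
            st.tuples(
                st.integers(0, 6), st.integers(0, 6),
                st.integers(0, 999),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_never_self_loops_or_duplicates(self, rows, tmp_path_factory):
        path = tmp_path_factory.mktemp("hyp") / "e.tsv"
        path.write_text("".join(f"a{u}\ta{v}\t{s}\n" for u, v, s in rows))
        net = read_edge_list(path, score_scale="string1000")
        seen = set()
        for u, v, c in net.edges():
            assert u != v
            assert 0.0 <= c <= 1.0
            pair = frozenset((u, v))
            assert pair not in seen
            seen.add(pair)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


class TestNetworkExport:
    def _path3(self):
        net = InteractionNetwork()
        for n in "ABC":
            net.add_node(n)
        net.add_edge("A", "B", 0.8)
        net.add_edge("B", "C", 0.9)
        return net

    def test_sif_path_graph_two_lines(self, tmp_path):
        written = write_network(self._path3(), tmp_path / "net", formats=("sif",))
        lines = written["sif"].read_text().splitlines()
        assert lines == ["A\tpp\tB", "B\tpp\tC"]

    def test_empty_network_exports(self, tmp_path):
        net = InteractionNetwork()
        written = write_network(net, tmp_path / "net")
        assert written["sif"].read_text() == ""
        assert read_graphml(written["graphml"]) == net

    def test_graphml_round_trip_random_graph(self, tmp_path):
        net = random_network(random.Random(11), 12, 0.4)
        written = write_network(net, tmp_path / "net", formats=("graphml",))
        again = read_graphml(written["graphml"])
        assert again.nodes == net.nodes
        assert again.edges() == net.edges()

    def test_sif_round_trip_node_and_edge_sets(self, tmp_path):
        net = random_network(random.Random(5), 8, 0.3)
        net.add_node("lonely")
        written = write_network(net, tmp_path / "net", formats=("sif",))
        again = read_sif(written["sif"])
        assert again.nodes == net.nodes
        assert [(u, v) for u, v, _ in again.edges()] == [
            (u, v) for u, v, _ in net.edges()
        ]

    def test_unknown_attr_node_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="unknown node"):
            write_network(self._path3(), tmp_path / "net",
                          node_attrs={"Z": {"x": 1}})

    def test_attribute_tables(self, tmp_path):
        written = write_network(
            self._path3(), tmp_path / "net",
            node_attrs={"A": {"kind": "herb"}, "B": {"kind": "compound"}},
            formats=("tables",),
        )
        node_lines = written["nodes"].read_text().splitlines()
        assert node_lines[0] == "node\tkind"
        assert "A\therb" in node_lines
        edge_lines = written["edges"].read_text().splitlines()
        assert edge_lines[0] == "source\ttarget\tconfidence"
        assert len(edge_lines) == 3


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


class TestGmt:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("")
        assert len(read_gmt(path)) == 0

    def test_two_set_file_exact_membership(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\tfirst\tA\tB\tC\nS2\tsecond\tB\tD\n")
        coll = read_gmt(path)
        assert coll.sets["S1"] == ("first", frozenset({"A", "B", "C"}))
        assert coll.sets["S2"] == ("second", frozenset({"B", "D"}))

    def test_duplicate_members_collapsed(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\tdesc\tA\tA\tB\n")
        assert read_gmt(path).sets["S1"][1] == frozenset({"A", "B"})

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\tfirst\tA\nS2\tonly-description\n")
        with pytest.raises(FormatError, match="line 2"):
            read_gmt(path)

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            sets={
                "S1": ("first", frozenset({"A", "B"})),
                "S2": ("second", frozenset({"C"})),
            }
        )
        path = tmp_path / "s.gmt"
        write_gmt(coll, path)
        assert read_gmt(path).sets == coll.sets

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSetCollection(sets={"S1": ("x", frozenset())})

    def test_member_outside_background_rejected(self):
        with pytest.raises(ValueError):
            GeneSetCollection(
                sets={"S1": ("x", frozenset({"A", "B"}))},
                background=frozenset({"A"}),
            )


# ---------------------------------------------------------------------------
# InteractionNetwork invariants
# ---------------------------------------------------------------------------


class TestInteractionNetwork:
    def test_self_loop_rejected(self):
        net = InteractionNetwork()
        net.add_node("A")
        with pytest.raises(ValueError):
            net.add_edge("A", "A", 0.9)

    def test_confidence_bounds(self):
        net = InteractionNetwork()
        with pytest.raises(ValueError):
            net.add_edge("A", "B", 1.2)

    def test_filter_confidence_keeps_nodes(self):
        net = InteractionNetwork()
        net.add_edge("A", "B", 0.5)
        net.add_edge("B", "C", 0.9)
        out = net.filter_confidence(0.7)
        assert out.nodes == {"A", "B", "C"}
        assert out.edges() == [("B", "C", 0.9)]

    def test_subgraph(self):
        net = random_network(random.Random(1), 8, 0.5)
        keep = {"n00", "n01", "n02"}
        sub = net.subgraph(keep)
        assert sub.nodes == keep & net.nodes
        for u, v, _ in sub.edges():
            assert u in keep and v in keep and net.has_edge(u, v)
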