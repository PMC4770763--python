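from __future__ import annotations

import logging

import pytest

from mirsubpath.pathway_io import (
    HIGH_THROUGHPUT,
    LOW_THROUGHPUT,
    InteractionRecord,
    PathwayParseError,
    deduplicate_interactions,
    filter_low_throughput,
    map_precursors,
    parse_kgml,
    read_exchange_tsv,
    read_interactions,
    read_precursor_map,
    write_exchange_tsv,
)

from conftest import make_pathway


KGML_ECREL = """<?xml version="1.0"?>
<pathway name="path:hsa00001" title="toy" org="hsa">
  <entry id="1" type="gene" name="A"/>
  <entry id="2" type="gene" name="B"/>
  <entry id="3" type="compound" name="cpd:C1"/>
  <relation entry1="1" entry2="2" type="ECrel">
    <subtype name="compound" value="3"/>
  </relation>
</pathway>
"""

KGML_REACTIONS = """<?xml version="1.0"?>
<pathway name="path:hsa00002" title="toy reactions" org="hsa">
  <entry id="1" type="gene" name="A" reaction="rn:R1"/>
  <entry id="2" type="gene" name="B" reaction="rn:R2"/>
  <entry id="3" type="gene" name="C" reaction="rn:R3"/>
  <reaction id="11" name="rn:R1" type="irreversible">
    <substrate id="21" name="cpd:X"/>
    <product id="22" name="cpd:Y"/>
  </reaction>
  <reaction id="12" name="rn:R2" type="irreversible">
    <substrate id="22" name="cpd:Y"/>
    <product id="23" name="cpd:Z"/>
  </reaction>
  <reaction id="13" name="rn:R3" type="irreversible">
    <substrate id="24" name="cpd:W"/>
    <product id="25" name="cpd:V"/>
  </reaction>
</pathway>
"""

KGML_EDGELESS = """<?xml version="1.0"?>
<pathway name="path:hsa00003" title="edgeless" org="hsa">
  <entry id="1" type="gene" name="A"/>
  <entry id="2" type="gene" name="B C"/>
</pathway>
"""


class TestParseKGML:
    def test_ecrel_relation_becomes_compound_labelled_edge(self):
        pg = parse_kgml(KGML_ECREL, "hsa")
        assert pg.genes == {"A", "B"}
        assert pg.edge_compounds("A", "B") == {"cpd:C1"}

    def test_consecutive_reactions_share_compound(self):
        pg = parse_kgml(KGML_REACTIONS, "hsa")
        assert pg.genes == {"A", "B", "C"}
        assert set(pg.graph.edges) == {("A", "B")}
        assert pg.edge_compounds("A", "B") == {"cpd:Y"}
        assert pg.graph.degree("C") == 0

    def test_document_without_relations_or_reactions_is_edgeless(self):
        pg = parse_kgml(KGML_EDGELESS, "hsa")
        # multi-gene entries split into one node per id
        assert pg.genes == {"A", "B", "C"}
        assert pg.graph.number_of_edges() == 0

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(PathwayParseError, match="malformed"):
            parse_kgml("<pathway><entry", "hsa")

    def test_wrong_root_element_raises(self):
        with pytest.raises(PathwayParseError, match="pathway"):
            parse_kgml("<notapathway/>", "hsa")

    def test_zero_gene_entries_warns_and_returns_empty_graph(self, caplog):
        doc = '<pathway name="path:hsa9" title="empty"><entry id="1" type="compound" name="cpd:C9"/></pathway>'
        with caplog.at_level(logging.WARNING):
            pg = parse_kgml(doc, "hsa")
        assert pg.graph.number_of_nodes() == 0
        assert any("no gene entries" in r.message for r in caplog.records)

    def test_deterministic(self):
        a, b = parse_kgml(KGML_REACTIONS, "hsa"), parse_kgml(KGML_REACTIONS, "hsa")
        assert set(a.graph.nodes) == set(b.graph.nodes)
        assert set(a.graph.edges) == set(b.graph.edges)


def _rec(mirna="miR-1", target="G1", species="hsa", evidence=LOW_THROUGHPUT, source="db1"):
    return InteractionRecord(mirna_id=mirna, target_gene=target, species=species,
                             evidence=evidence, source=source)


class TestInteractionTable:
    HEADER = "mirna\ttarget\tspecies\tevidence\tsource\n"

    def test_reads_valid_rows(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER + "miR-1\tG1\thsa\tlow_throughput\tdb\n"
                     "miR-2\tG2\thsa\thigh_throughput\tdb\n"
                     "miR-3\tG3\tmmu\tlow_throughput\tdb\n")
        assert len(read_interactions(p)) == 3

    def test_rows_missing_ids_dropped_and_logged(self, tmp_path, caplog):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER + "miR-1\tG1\thsa\tlow_throughput\tdb\n"
                     "miR-2\t\thsa\tlow_throughput\tdb\n"
                     "miR-3\tG3\thsa\tlow_throughput\tdb\n")
        with caplog.at_level(logging.INFO):
            records = read_interactions(p)
        assert len(records) == 2
        assert any("dropped 1" in r.message for r in caplog.records)

    def test_duplicates_pass_through_reader(self, tmp_path):
        p = tmp_path / "t.tsv"
        row = "miR-1\tG1\thsa\tlow_throughput\tdb\n"
        p.write_text(self.HEADER + row * 2)
        assert len(read_interactions(p)) == 2

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("mirna\ttarget\n" + "miR-1\tG1\n")
        with pytest.raises(KeyError, match="species"):
            read_interactions(p)

    def test_custom_column_names(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("miRNA_name\tTarget\tspecies\tevidence\tsource\nmiR-1\tG1\thsa\tlow_throughput\tdb\n")
        records = read_interactions(p, columns={"mirna": "miRNA_name", "target": "Target"})
        assert records[0].mirna_id == "miR-1"


class TestDeduplicate:
    def test_evidence_resolves_to_low_throughput_and_sources_concatenate(self):
        merged = deduplicate_interactions([
            _rec(target="PPAP2C", evidence=HIGH_THROUGHPUT, source="dbA"),
            _rec(target="PPAP2C", evidence=LOW_THROUGHPUT, source="dbB"),
        ])
        assert len(merged) == 1
        assert merged[0].evidence == LOW_THROUGHPUT
        assert merged[0].source == "dbA;dbB"

    def test_disjoint_keys_preserved(self):
        records = [_rec(mirna=f"miR-{i}") for i in range(5)]
        assert len(deduplicate_interactions(records)) == 5

    def test_planted_duplicates_counted_by_key_oracle(self):
        records = [_rec(mirna=f"miR-{i}", target=f"G{i}") for i in range(6)]
        records += [_rec(mirna="miR-0", target="G0", source=f"dup{j}") for j in range(4)]
        expected = len({(r.mirna_id, r.target_gene, r.species) for r in records})
        assert len(deduplicate_interactions(records)) == expected == 6

    def test_idempotent(self):
        records = [_rec(mirna=f"miR-{i % 3}", target=f"G{i % 2}",
                        evidence=LOW_THROUGHPUT if i % 2 else HIGH_THROUGHPUT)
                   for i in range(10)]
        once = deduplicate_interactions(records)
        twice = deduplicate_interactions(once)
        assert once == twice


class TestFilterLowThroughput:
    def test_keeps_only_low_throughput_of_species(self):
        records = [
            _rec(mirna="a"), _rec(mirna="b"),
            _rec(mirna="c", evidence=HIGH_THROUGHPUT),
            _rec(mirna="d", species="mmu"),
            _rec(mirna="e", evidence=HIGH_THROUGHPUT, species="mmu"),
        ]
        kept = filter_low_throughput(records, "hsa")
        assert {r.mirna_id for r in kept} == {"a", "b"}

    def test_all_high_throughput_yields_empty(self):
        records = [_rec(mirna=f"m{i}", evidence=HIGH_THROUGHPUT) for i in range(3)]
        assert filter_low_throughput(records, "hsa") == []

    def test_predicate_matches_hand_enumeration(self):
        records = [_rec(mirna=f"m{i}", species="hsa" if i % 2 else "rno",
                        evidence=LOW_THROUGHPUT if i % 3 else HIGH_THROUGHPUT)
                   for i in range(12)]
        expected = sum(1 for r in records if r.species == "hsa" and r.evidence == LOW_THROUGHPUT)
        assert len(filter_low_throughput(records, "hsa")) == expected

    def test_filtered_keys_subset_of_deduplicated(self):
        records = [_rec(mirna=f"m{i % 4}", target=f"G{i % 3}",
                        evidence=LOW_THROUGHPUT if i % 2 else HIGH_THROUGHPUT)
                   for i in range(20)]
        deduped = deduplicate_interactions(records)
        keys = {(r.mirna_id, r.target_gene, r.species) for r in deduped}
        filtered_keys = {(r.mirna_id, r.target_gene, r.species)
                         for r in filter_low_throughput(deduped, "hsa")}
        assert filtered_keys <= keys

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="species"):
            filter_low_throughput([], "xyz")


class TestPrecursorMap:
    def test_precursor_expands_to_matures(self):
        matures, unmapped = map_precursors({"pre-X"}, {"pre-X": frozenset({"X-3p", "X-5p"})})
        assert matures == {"X-3p", "X-5p"}
        assert unmapped == frozenset()

    def test_empty_input(self):
        matures, unmapped = map_precursors(set(), {"pre-X": frozenset({"X"})})
        assert matures == frozenset() and unmapped == frozenset()

    def test_unmapped_precursors_reported_and_union_counted(self):
        pmap = {
            "p1": frozenset({"a-3p", "a-5p"}),
            "p2": frozenset({"b-3p", "b-5p"}),
            "p3": frozenset({"c-3p", "a-5p"}),  # shares a mature with p1
            "p4": frozenset({"d-3p", "d-5p"}),
        }
        matures, unmapped = map_precursors({"p1", "p2", "p3", "p4", "p5"}, pmap)
        expected = set().union(*pmap.values())
        assert matures == expected and len(expected) == 7
        assert unmapped == {"p5"}

    def test_read_precursor_map(self, tmp_path):
        p = tmp_path / "pmap.tsv"
        p.write_text("pre-X\tX-3p\npre-X\tX-5p\npre-Y\tY-5p\n")
        pmap = read_precursor_map(p)
        assert pmap == {"pre-X": frozenset({"X-3p", "X-5p"}), "pre-Y": frozenset({"Y-5p"})}


class TestExchangeRoundTrip:
    def test_graphs_survive_write_read(self, tmp_path):
        pgs = [
            make_pathway("path:00001", [("A", "B", {"cpd:C1"}), ("B", "C", set())], nodes=["D"]),
            make_pathway("path:00002", [("X", "Y", {"cpd:C2", "cpd:C3"})]),
        ]
        path = tmp_path / "pathways.tsv"
        write_exchange_tsv(pgs, path)
        back = {p.pathway_id: p for p in read_exchange_tsv(path)}
        for pg in pgs:
            other = back[pg.pathway_id]
            assert set(other.graph.nodes) == set(pg.graph.nodes)
            assert set(map(frozenset, other.graph.edges)) == set(map(frozenset, pg.graph.edges))
            for a, b in pg.graph.edges:
                assert other.edge_compounds(a, b) == pg.edge_compounds(a, b)
            assert (other.name, other.species) == (pg.name, pg.species)
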