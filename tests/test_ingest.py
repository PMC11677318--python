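"""Ingest readers: dialects, filtering rules, de-duplication."""

import logging

import pytest

from amyloidnet import ingest
from amyloidnet.errors import ParseError, SchemaError, ValidationError
from amyloidnet.records import ScoredPPIEdge


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


DP_HEADER = "disease_id\tuniprot_ac\trole\n"
PPI_HEADER = "protein_a\tprotein_b\tcombined_score\torganism_tag\n"


class TestDiseaseProteinReader:
    def test_duplicate_rows_collapse_to_unique_pairs(self, tmp_path):
        rows = [
            ("d1", "P00001", "amyloidogenic"),
            ("d1", "P00002", "co_deposited"),
            ("d2", "P00001", "amyloidogenic"),
            ("d2", "P00003", "amyloidogenic"),
            ("d3", "P00002", "co_deposited"),
            ("d3", "P00003", "amyloidogenic"),
            ("d1", "P00001", "amyloidogenic"),  # duplicate
        ]
        path = write(tmp_path, "dp.tsv",
                     DP_HEADER + "".join("\t".join(r) + "\n" for r in rows))
        stats = {}
        edges, nodes = ingest.read_disease_protein_associations(
            path, stats=stats)
        assert len(edges) == 6
        assert stats == {"records_in": 7, "dropped_duplicate": 1,
                         "records_out": 6}
        # a protein amyloidogenic in one disease, co-deposited in another,
        # carries the union in its node record but per-edge tags stay local
        assert nodes["P00002"].protein_roles == frozenset({"co_deposited"})
        assert nodes["P00001"].protein_roles == frozenset({"amyloidogenic"})

    def test_xml_and_tsv_dialects_yield_identical_edges(self, tmp_path):
        tsv = write(tmp_path, "dp.tsv",
                    DP_HEADER + "diseaseX\tP02766\tamyloidogenic\n")
        xml = write(tmp_path, "dp.xml", """<?xml version="1.0"?>
<diseases>
  <disease id="diseaseX" name="Disease X">
    <protein ac="P02766" role="amyloidogenic"/>
  </disease>
</diseases>
""")
        e_tsv, _ = ingest.read_disease_protein_associations(tsv, dialect="tsv")
        e_xml, _ = ingest.read_disease_protein_associations(xml, dialect="xml")
        assert e_tsv == e_xml

    def test_unknown_role_rejected(self, tmp_path):
        path = write(tmp_path, "dp.tsv", DP_HEADER + "d1\tP00001\tmystery\n")
        with pytest.raises(ValidationError, match="mystery"):
            ingest.read_disease_protein_associations(path)

    def test_malformed_xml_names_position(self, tmp_path):
        path = write(tmp_path, "bad.xml", "<diseases><disease></diseases>")
        with pytest.raises(ParseError, match="line"):
            ingest.read_disease_protein_associations(path, dialect="xml")

    def test_missing_column_is_schema_error(self, tmp_path):
        path = write(tmp_path, "dp.tsv", "disease_id\tuniprot_ac\nd\tP1\n")
        with pytest.raises(SchemaError, match="role"):
            ingest.read_disease_protein_associations(path)


class TestPPIReader:
    def ppi(self, tmp_path, rows, **kw):
        text = PPI_HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows)
        return ingest.read_ppi_table(write(tmp_path, "ppi.tsv", text), **kw)

    def test_score_floor_is_inclusive(self, tmp_path):
        edges = self.ppi(tmp_path, [
            ("A", "B", 0.950, 9606),
            ("A", "C", 0.899, 9606),
            ("A", "D", 0.900, 9606),
        ])
        assert {e.pair for e in edges} == {("A", "B"), ("A", "D")}

    def test_thousand_scale_autodetected(self, tmp_path):
        edges = self.ppi(tmp_path, [("A", "B", 950, 9606),
                                    ("A", "C", 899, 9606)])
        assert [(e.pair, e.combined_score) for e in edges] == \
            [(("A", "B"), 0.950)]

    def test_nonhuman_rows_dropped(self, tmp_path):
        stats = {}
        edges = self.ppi(tmp_path, [("A", "B", 0.95, 9606),
                                    ("A", "C", 0.95, 10090)], stats=stats)
        assert {e.pair for e in edges} == {("A", "B")}
        assert stats["dropped_nonhuman"] == 1
        # and kept when the filter is off
        edges = self.ppi(tmp_path, [("A", "B", 0.95, 9606),
                                    ("A", "C", 0.95, 10090)],
                         human_only=False)
        assert len(edges) == 2

    def test_neighbor_cap_keeps_lexicographically_smallest_on_ties(
            self, tmp_path):
        rows = [("SEED", f"X{i:03d}", 0.950, 9606) for i in range(150)]
        edges = self.ppi(tmp_path, rows, max_neighbors=100)
        assert len(edges) == 100
        partners = sorted(
            e.protein_b if e.protein_a == "SEED" else e.protein_a
            for e in edges)
        assert partners == [f"X{i:03d}" for i in range(100)]

    def test_score_out_of_range_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="outside"):
            self.ppi(tmp_path, [("A", "B", 1500, 9606)])

    def test_missing_column_is_schema_error(self, tmp_path):
        path = write(tmp_path, "ppi.tsv",
                     "protein_a\tprotein_b\tcombined_score\nA\tB\t0.9\n")
        with pytest.raises(SchemaError, match="organism_tag"):
            ingest.read_ppi_table(path)

    def test_filter_chain_is_idempotent(self, tmp_path):
        rows = (
            [("A", f"B{i}", 0.90 + i / 1000, 9606) for i in range(5)]
            + [("B0", "A", 0.950, 9606), ("C", "D", 0.4, 9606),
               ("E", "F", 0.95, 10090)]
        )
        first = self.ppi(tmp_path, rows)
        text = PPI_HEADER + "".join(
            f"{e.protein_a}\t{e.protein_b}\t{e.combined_score}\t9606\n"
            for e in first)
        second = ingest.read_ppi_table(write(tmp_path, "again.tsv", text))
        assert first == second
        assert all(e.combined_score >= 0.900 for e in first)


class TestDedupePPI:
    def test_symmetric_duplicates_keep_max_score(self):
        out = ingest.dedupe_ppi([ScoredPPIEdge("A", "B", 0.91),
                                 ScoredPPIEdge("B", "A", 0.95)])
        assert out == [ScoredPPIEdge("A", "B", 0.95)]

    def test_idempotent_on_unique_input(self):
        edges = [ScoredPPIEdge("A", "B", 0.9), ScoredPPIEdge("A", "C", 0.95)]
        assert ingest.dedupe_ppi(edges) == edges
        assert ingest.dedupe_ppi(ingest.dedupe_ppi(edges)) == \
            ingest.dedupe_ppi(edges)

    def test_output_size_matches_unordered_pair_set(self):
        import random
        rnd = random.Random(7)
        names = [f"P{i}" for i in range(12)]
        edges = []
        for _ in range(120):
            a, b = rnd.sample(names, 2)
            edges.append(ScoredPPIEdge(a, b, round(rnd.uniform(0.9, 1), 3)))
        out = ingest.dedupe_ppi(edges)
        assert len(out) == len({e.pair for e in edges})
        assert out == sorted(out, key=lambda e: e.pair)


class TestDedupeProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st_

    pairs = st_.lists(
        st_.tuples(st_.sampled_from("ABCDEFGH"), st_.sampled_from("ABCDEFGH"),
                   st_.floats(min_value=0.0, max_value=1.0)).filter(
            lambda t: t[0] != t[1]),
        max_size=40)

    @given(pairs)
    @settings(deadline=None, derandomize=True)
    def test_pair_uniqueness_max_score_and_idempotence(self, raw):
        edges = [ScoredPPIEdge(a, b, s) for a, b, s in raw]
        out = ingest.dedupe_ppi(edges)
        assert len(out) == len({e.pair for e in edges})
        best = {}
        for e in edges:
            best[e.pair] = max(best.get(e.pair, 0.0), e.combined_score)
        assert {e.pair: e.combined_score for e in out} == best
        assert ingest.dedupe_ppi(out) == out


class TestDrugTables:
    def tables(self, tmp_path, targets, indications, **kw):
        t = write(tmp_path, "targets.tsv", "drugbank_id\tuniprot_ac\n"
                  + "".join("\t".join(r) + "\n" for r in targets))
        i = write(tmp_path, "ind.tsv", "drugbank_id\tdisease_id\n"
                  + "".join("\t".join(r) + "\n" for r in indications))
        return ingest.read_drug_tables(t, i, **kw)

    def test_metal_rows_excluded(self, tmp_path):
        pd_edges, dd = self.tables(
            tmp_path,
            [("DB01593", "P00441"), ("DB09221", "P00441")],
            [("DB01593", "als")],
        )
        assert [(e.source, e.target) for e in pd_edges] == \
            [("P00441", "DB09221")]
        assert dd == []

    def test_sod1_target_row_yields_one_edge(self, tmp_path):
        # Polaprezinc targeting superoxide dismutase [Cu-Zn]
        pd_edges, _ = self.tables(tmp_path, [("DB09221", "P00441")], [])
        assert len(pd_edges) == 1
        assert pd_edges[0].edge_type == "protein-drug"

    def test_duplicate_indications_collapse(self, tmp_path):
        _, dd = self.tables(tmp_path, [],
                            [("DB00988", "pd"), ("DB00988", "pd")])
        assert len(dd) == 1

    def test_bad_drug_id_kept_with_warning(self, tmp_path, caplog):
        with caplog.at_level(logging.WARNING):
            pd_edges, _ = self.tables(tmp_path, [("XX123", "P00001")], [])
        assert len(pd_edges) == 1
        assert any("XX123" in r.message for r in caplog.records)

    def test_empty_tables_are_not_an_error(self, tmp_path):
        pd_edges, dd = self.tables(tmp_path, [], [])
        assert pd_edges == [] and dd == []

    def test_custom_exclusion_list(self, tmp_path):
        pd_edges, _ = self.tables(tmp_path, [("DB00001", "P1")],
                                  [], excluded_drugs={"DB00001"})
        assert pd_edges == []


def test_generator_fixture_edge_counts_match_ground_truth(default_fixtures):
    outdir, paths, gt, _config = default_fixtures
    stats = {}
    edges, _ = ingest.read_disease_protein_associations(
        paths["disease_protein_tsv"], stats=stats)
    assert len(edges) == gt.n_dp_edges
    assert stats == gt.dp_drops
    # the XML dialect carries the same records
    xml_edges, _ = ingest.read_disease_protein_associations(
        paths["disease_protein_xml"], dialect="xml")
    assert xml_edges == edges
    ppi_stats = {}
    pp = ingest.read_ppi_table(paths["ppi_tsv"], stats=ppi_stats)
    assert ppi_stats == gt.ppi_drops
    assert all(e.combined_score >= 0.900 for e in pp)
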