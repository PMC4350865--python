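import pytest

from drugkb.ingest import (
    IngestReport,
    MappingConflictError,
    SchemaError,
    canonicalize_term,
    load_synonym_table,
    map_by_atc_and_id,
    map_by_name,
    merge_sources,
    parse_source,
)


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(c) for c in r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


DRUG_HEADER = ["native_id", "name", "synonyms", "atc_codes", "xrefs"]


def make_source(tmp_path, tag, drugs, interactions=(), side_effects=()):
    tmp_path.mkdir(parents=True, exist_ok=True)
    write_tsv(tmp_path / f"{tag}_drugs.tsv", DRUG_HEADER, drugs)
    if interactions:
        write_tsv(tmp_path / f"{tag}_interactions.tsv",
                  ["native_id_a", "native_id_b", "effect", "severity"], interactions)
    if side_effects:
        write_tsv(tmp_path / f"{tag}_side_effects.tsv",
                  ["native_id", "term", "frequency"], side_effects)
    return parse_source(tmp_path, tag)


class TestParseSource:
    def test_counts_preserved(self, tmp_path):
        rs = make_source(tmp_path, "PHARM", [
            ["P1", "Clonazepam", "", "N03AE01", ""],
            ["P2", "Aspirin", "ASS", "N02BA01", ""],
            ["P3", "Atenolol", "", "C07AB03", ""],
        ])
        assert len(rs.drugs) == 3
        assert rs.rejections == []

    def test_malformed_rows_are_skipped_and_reported(self, tmp_path):
        rows = [[f"P{i}", f"Drug{i}", "", "", ""] for i in range(9)]
        rows.insert(4, ["", "Nameless", "", "", ""])  # missing native_id
        rs = make_source(tmp_path, "PHARM", rows)
        assert len(rs.drugs) == 9
        assert len(rs.rejections) == 1
        assert rs.rejections[0].line == 6  # header is line 1

    def test_header_only_file_is_empty_not_an_error(self, tmp_path):
        rs = make_source(tmp_path, "PHARM", [])
        assert rs.drugs == {} and rs.rejections == []

    def test_missing_required_column_is_hard_error(self, tmp_path):
        (tmp_path / "PHARM_drugs.tsv").write_text(
            "native_id\tname\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="synonyms"):
            parse_source(tmp_path, "PHARM")

    def test_missing_drugs_table_is_hard_error(self, tmp_path):
        with pytest.raises(SchemaError):
            parse_source(tmp_path, "PHARM")

    def test_invalid_atc_code_dropped_not_fatal(self, tmp_path):
        rs = make_source(tmp_path, "PHARM",
                         [["P1", "Drug", "", "N03|N03AE01", ""]])
        assert rs.drugs["P1"].atc_codes == ["N03AE01"]
        assert any("N03" in r.reason for r in rs.rejections)

    def test_interaction_rows_referencing_unknown_drugs_rejected(self, tmp_path):
        rs = make_source(tmp_path, "PHARM",
                         [["P1", "A", "", "", ""], ["P2", "B", "", "", ""]],
                         interactions=[["P1", "P2", "x", ""],
                                       ["P1", "P9", "y", ""],
                                       ["P1", "P1", "z", ""]])
        assert len(rs.interactions) == 1
        assert len(rs.rejections) == 2


class TestMapping:
    def test_shared_identifier_link(self, tmp_path):
        a = make_source(tmp_path / "a", "PHARM",
                        [["P1", "Alpha", "", "", "MOLDB:DBX001"]])
        b = make_source(tmp_path / "b", "MOLDB", [["DBX001", "Alpha-renamed", "", "", ""]])
        m = map_by_atc_and_id(a, b)
        assert m.pairs == {("P1", "DBX001")}
        assert m.pair_methods[("P1", "DBX001")] == "shared_identifier"

    def test_atc_link_without_identifier(self, tmp_path):
        a = make_source(tmp_path / "a", "PHARM", [["P1", "Alpha", "", "N03AE01", ""]])
        b = make_source(tmp_path / "b", "MOLDB", [["DB1", "Beta", "", "N03AE01", ""]])
        m = map_by_atc_and_id(a, b)
        assert m.pairs == {("P1", "DB1")}
        assert m.pair_methods[("P1", "DB1")] == "atc_and_identifier"

    def test_atc_tie_break_links_smallest_pair(self, tmp_path):
        # oracle: candidates (P1,DB9) and (P2,DB9) both score shared-ATC;
        # the stated tie-break keeps the lexicographically smallest pair
        a = make_source(tmp_path / "a", "PHARM",
                        [["P1", "Alpha", "", "N02BA01", ""],
                         ["P2", "Beta", "", "N02BA01", ""]])
        b = make_source(tmp_path / "b", "MOLDB", [["DB9", "Gamma", "", "N02BA01", ""]])
        m = map_by_atc_and_id(a, b)
        assert m.pairs == {("P1", "DB9")}

    def test_identifier_outranks_atc(self, tmp_path):
        a = make_source(tmp_path / "a", "PHARM",
                        [["P1", "Alpha", "", "N02BA01", ""],
                         ["P2", "Beta", "", "N02BA01", "MOLDB:DB9"]])
        b = make_source(tmp_path / "b", "MOLDB", [["DB9", "Gamma", "", "N02BA01", ""]])
        m = map_by_atc_and_id(a, b)
        assert m.pairs == {("P2", "DB9")}

    def test_name_mapping_normalizes_and_uses_synonyms(self, tmp_path):
        a = make_source(tmp_path / "a", "MOLDB",
                        [["DB1", "Clonazepam", "", "", ""],
                         ["DB2", "Acetylsalicylic acid", "aspirin", "", ""],
                         ["DB3", "Clobazam", "", "", ""]])
        b = make_source(tmp_path / "b", "SEDB",
                        [["S1", "CLONAZEPAM ", "", "", ""],
                         ["S2", "Aspirin", "", "", ""]])
        m = map_by_name(a, b)
        assert m.pairs == {("DB1", "S1"), ("DB2", "S2")}

    def test_mapping_is_symmetric(self, tmp_path):
        a = make_source(tmp_path / "a", "PHARM",
                        [["P1", "Alpha", "", "N02BA01", ""],
                         ["P2", "Beta", "", "N03AE01", ""]])
        b = make_source(tmp_path / "b", "MOLDB",
                        [["DB1", "Gamma", "", "N02BA01", ""],
                         ["DB2", "Delta", "", "N03AE01", ""]])
        fwd = map_by_atc_and_id(a, b)
        rev = map_by_atc_and_id(b, a)
        assert {(y, x) for x, y in fwd.pairs} == rev.pairs


class TestCanonicalizeTerm:
    def test_synonym_lookup(self, tmp_path):
        write_tsv(tmp_path / "synonyms.tsv", ["raw_term", "canonical_term"],
                  [["emesis", "vomiting"]])
        table = load_synonym_table(tmp_path / "synonyms.tsv")
        assert canonicalize_term("emesis", table) == "vomiting"

    def test_canonical_is_fixed_point(self, tmp_path):
        write_tsv(tmp_path / "synonyms.tsv", ["raw_term", "canonical_term"],
                  [["emesis", "vomiting"]])
        table = load_synonym_table(tmp_path / "synonyms.tsv")
        assert canonicalize_term("vomiting", table) == "vomiting"

    def test_unknown_term_passes_through_normalized_and_flagged(self):
        report = IngestReport()
        assert canonicalize_term("Qwertyitis", {}, report) == "qwertyitis"
        assert "qwertyitis" in report.unmapped_terms


class TestMergeSources:
    def _two_sources(self, tmp_path):
        a = make_source(
            tmp_path / "a", "PHARM",
            [[f"P{i}", f"Drug{i}", "", f"N02BA0{i}", ""] for i in range(1, 6)],
            interactions=[["P1", "P2", "effect-x", "minor"]],
            side_effects=[["P1", "emesis", "common"]])
        b = make_source(
            tmp_path / "b", "MOLDB",
            [[f"DB{i}", f"Drug{i}", "", f"N02BA0{i}", ""] for i in range(3, 8)],
            interactions=[["DB3", "DB4", "effect-y", ""]])
        return a, b

    def test_fused_drug_count_matches_inclusion_exclusion(self, tmp_path):
        a, b = self._two_sources(tmp_path)
        mapping = map_by_atc_and_id(a, b)
        assert len(mapping.pairs) == 3  # Drug3..Drug5 shared
        kb = merge_sources([a, b], [mapping])
        assert len(kb.drugs) == 5 + 5 - 3 == 7

    def test_dual_provenance_after_fusion(self, tmp_path):
        a = make_source(tmp_path / "a", "PHARM",
                        [["P1", "Alpha", "", "N02BA01", ""],
                         ["P2", "Beta", "", "N02BA02", ""]],
                        interactions=[["P1", "P2", "pharm text", ""]])
        b = make_source(tmp_path / "b", "MOLDB",
                        [["DB1", "Alpha", "", "N02BA01", ""],
                         ["DB2", "Beta", "", "N02BA02", ""]],
                        interactions=[["DB2", "DB1", "mol text", ""]])
        kb = merge_sources([a, b], [map_by_atc_and_id(a, b)])
        assert len(kb.interactions) == 1
        assertion = next(iter(kb.interactions.values()))
        assert assertion.provenance == {"PHARM", "MOLDB"}
        assert assertion.effects == {"PHARM": "pharm text", "MOLDB": "mol text"}

    def test_empty_inputs_give_empty_kb(self, tmp_path):
        a = make_source(tmp_path / "a", "PHARM", [])
        kb = merge_sources([a], [])
        assert not kb.drugs and not kb.interactions

    def test_merge_is_order_independent(self, tmp_path):
        a, b = self._two_sources(tmp_path)
        mapping = map_by_atc_and_id(a, b)
        kb1 = merge_sources([a, b], [mapping])
        kb2 = merge_sources([b, a], [mapping])
        names = lambda kb: sorted(d.name for d in kb.drugs.values())
        assert names(kb1) == names(kb2)
        assert kb1.interactions.keys() == kb2.interactions.keys()
        assert {k: v.provenance for k, v in kb1.side_effects.items()} == \
               {k: v.provenance for k, v in kb2.side_effects.items()}

    def test_provenance_conservation_and_no_assertion_loss(self, tmp_path):
        a, b = self._two_sources(tmp_path)
        mapping = map_by_atc_and_id(a, b)
        kb = merge_sources([a, b], [mapping])
        # brute force: each source asserts exactly its raw rows
        raw_counts = len(a.interactions) + len(b.interactions)
        merged_multiset = sum(len(x.provenance) for x in kb.interactions.values())
        assert merged_multiset == raw_counts
        for assertion in kb.interactions.values():
            for tag in assertion.provenance:
                assert tag in ("PHARM", "MOLDB")

    def test_side_effect_canonicalized_on_merge(self, tmp_path):
        a, _ = self._two_sources(tmp_path)
        kb = merge_sources([a], [], synonym_table={"emesis": "vomiting",
                                                   "vomiting": "vomiting"})
        terms = {t for _, t in kb.side_effects}
        assert terms == {"vomiting"}

    def test_contradictory_mapping_is_hard_error(self, tmp_path):
        a, b = self._two_sources(tmp_path)
        m = map_by_atc_and_id(a, b)
        from drugkb.ingest import DrugMapping
        bad = DrugMapping(source_a="PHARM", source_b="MOLDB",
                          method="atc_and_identifier",
                          pairs={("P3", "DB4")})  # conflicts with ATC mapping P3-DB3
        with pytest.raises(MappingConflictError):
            merge_sources([a, b], [m, bad])

    def test_pathway_drug_refs_resolved_via_native_ids(self, tmp_path):
        from drugkb.ingest import parse_source as ps
        write_tsv(tmp_path / "PATHDB_drugs.tsv", DRUG_HEADER, [])
        write_tsv(tmp_path / "PATHDB_pathways.tsv",
                  ["pathway_id", "name", "member_molecules", "drugs", "diseases"],
                  [["PW1", "Test pathway", "CYP3A4", "DB3|DB4|NOPE", ""]])
        pathdb = ps(tmp_path, "PATHDB")
        a, b = self._two_sources(tmp_path)
        report = IngestReport()
        kb = merge_sources([a, b, pathdb], [map_by_atc_and_id(a, b)], report=report)
        pw = kb.pathways["PW1"]
        assert len(pw.linked_drug_ids) == 2
        assert all(d in kb.drugs for d in pw.linked_drug_ids)
        assert any("NOPE" in msg for msg in report.dropped_references)
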