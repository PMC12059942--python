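"""Entry-XML parsing, identifier reconciliation, and the early filters."""

import copy

import pytest

from allobench.annotation_ingest import (
    ActiveSiteRecord,
    RawAsdEntry,
    StaticIdResolver,
    filter_resolution,
    merge_active_sites,
    parse_asd_directory,
    parse_asd_xml,
    reconcile_identifiers,
    select_complete_entries,
)
from allobench.core_model import (
    AllostericEntry,
    ModulatorClass,
    ResidueRef,
    SiteAnnotation,
    SiteKind,
    SiteSource,
    StructureMeta,
)
from allobench.synthetic_fixtures import CorpusEntrySpec, make_asd_like_xml


@pytest.fixture
def resolver():
    return StaticIdResolver(
        pdb_updates={"9OLD": "1NEW"},
        chain_maps={"1NEW": {"A": "P00001"}, "1AAA": {"A": "P00002", "B": "P00003"}},
        accession_updates={"Q99OLD": "P00002"},
    )


class TestParseXml:
    def test_fields_extracted_verbatim(self):
        spec = CorpusEntrySpec(entry_id="E1", pdb_id="1ABC", accession="P12345",
                               pocket=(10, 11))
        entry = parse_asd_xml(make_asd_like_xml(spec))
        assert entry.entry_id == "E1"
        assert entry.pdb_id == "1ABC"
        assert entry.accessions == ["P12345"]
        assert entry.allosteric_residue_text == "A:10;A:11"
        assert entry.modulator_alias == "LIG"
        assert entry.modulator_class is ModulatorClass.SMALL_MOLECULE
        assert entry.flags == []

    def test_missing_site_element_flagged_not_dropped(self):
        spec = CorpusEntrySpec(entry_id="E2", pdb_id="1ABC", accession="P1",
                               defect="missing_site")
        entry = parse_asd_xml(make_asd_like_xml(spec))
        assert entry.allosteric_residue_text == ""
        assert "missing_site_annotation" in entry.flags
        assert entry.status == "kept"

    def test_malformed_xml_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_asd_xml("<entry><unclosed>")

    def test_batch_of_n_files(self, tmp_path):
        for i in range(5):
            spec = CorpusEntrySpec(entry_id=f"E{i}", pdb_id=f"1AB{i}", accession="P1")
            (tmp_path / f"e{i}.xml").write_text(make_asd_like_xml(spec))
        assert len(parse_asd_directory(tmp_path)) == 5

    def test_duplicate_entry_ids_rejected(self, tmp_path):
        spec = CorpusEntrySpec(entry_id="DUP", pdb_id="1ABC", accession="P1")
        (tmp_path / "a.xml").write_text(make_asd_like_xml(spec))
        (tmp_path / "b.xml").write_text(make_asd_like_xml(spec))
        with pytest.raises(ValueError, match="duplicate"):
            parse_asd_directory(tmp_path)


class TestReconcileIdentifiers:
    def test_obsolete_id_updated_and_kept(self, resolver):
        entry = RawAsdEntry(entry_id="e", pdb_id="9OLD", accessions=["P00001"])
        reconcile_identifiers(entry, resolver)
        assert entry.pdb_id == "1NEW"
        assert entry.status == "kept"

    def test_removed_structure_dropped(self, resolver):
        entry = RawAsdEntry(entry_id="e", pdb_id="4GON", accessions=["P00001"])
        reconcile_identifiers(entry, resolver)
        assert (entry.status, entry.drop_reason) == ("dropped", "pdb_removed")

    def test_accession_mismatch_dropped(self, resolver):
        entry = RawAsdEntry(entry_id="e", pdb_id="1AAA", accessions=["P99999"])
        reconcile_identifiers(entry, resolver)
        assert entry.drop_reason == "id_discrepancy"

    def test_superseded_accession_resolved_before_check(self, resolver):
        entry = RawAsdEntry(entry_id="e", pdb_id="1AAA", accessions=["Q99OLD"])
        reconcile_identifiers(entry, resolver)
        assert entry.status == "kept"
        assert entry.accessions == ["P00002"]

    def test_idempotent(self, resolver):
        entry = RawAsdEntry(entry_id="e", pdb_id="9OLD", accessions=["P00001"])
        reconcile_identifiers(entry, resolver)
        snapshot = copy.deepcopy(entry)
        reconcile_identifiers(entry, resolver)
        assert entry == snapshot

    def test_tsv_round_trip(self, tmp_path, resolver):
        path = tmp_path / "resolver.tsv"
        lines = ["pdb_update\t9OLD\t1NEW",
                 "chain\t1NEW:A\tP00001",
                 "chain\t1AAA:A\tP00002",
                 "chain\t1AAA:B\tP00003",
                 "accession_update\tQ99OLD\tP00002"]
        path.write_text("\n".join(lines) + "\n")
        loaded = StaticIdResolver.from_tsv(path)
        assert loaded.resolve_pdb("9OLD") == "1NEW"
        assert loaded.chain_map("1AAA") == {"A": "P00002", "B": "P00003"}
        assert loaded.resolve_accession("Q99OLD") == "P00002"


class TestMergeActiveSites:
    U = [ActiveSiteRecord("P1", 10, "UniProt"), ActiveSiteRecord("P1", 20, "UniProt")]
    M = [ActiveSiteRecord("P1", 20, "MCSA"), ActiveSiteRecord("P1", 30, "MCSA"),
         ActiveSiteRecord("P2", 5, "MCSA")]

    def test_union_with_provenance(self):
        merged = merge_active_sites(self.U, self.M)
        assert set(merged["P1"]) == {10, 20, 30}
        assert merged["P1"][20] == {"UniProt", "MCSA"}
        assert merged["P2"] == {5: {"MCSA"}}

    def test_commutative_and_idempotent(self):
        a = merge_active_sites(self.U, self.M)
        b = merge_active_sites(self.M, self.U)
        assert a == b
        assert merge_active_sites(self.U + self.M, []) == a

    def test_both_empty(self):
        assert merge_active_sites([], []) == {}


def _entry(eid, allo=True, active=True, resolution=2.0):
    site = SiteAnnotation(kind=SiteKind.ALLOSTERIC,
                          residues=frozenset({ResidueRef("A", 1)}),
                          source=SiteSource.ASD)
    act = SiteAnnotation(kind=SiteKind.ACTIVE,
                         residues=frozenset({ResidueRef("A", 9)}),
                         source=SiteSource.UNIPROT)
    return AllostericEntry(
        entry_id=eid, pdb_id="1ABC",
        allosteric_sites=[site] if allo else [],
        active_sites=[act] if active else [],
        structure_meta=StructureMeta(resolution=resolution))


class TestSelectComplete:
    def test_both_site_kinds_required(self):
        entries = [_entry("ok"), _entry("no_active", active=False),
                   _entry("no_allo", allo=False), _entry("ok2"),
                   _entry("neither", allo=False, active=False)]
        kept, dropped = select_complete_entries(entries)
        assert {e.entry_id for e in kept} == {"ok", "ok2"}
        assert all(e.drop_reason == "incomplete_annotation" for e in dropped)
        assert len(kept) + len(dropped) == len(entries)


class TestFilterResolution:
    @pytest.mark.parametrize("resolution,kept", [
        (3.9, True), (4.0, False), (4.1, False), (0.9, True),
    ])
    def test_strict_better_than_cutoff(self, resolution, kept):
        entries = [_entry("e", resolution=resolution)]
        kept_list, dropped = filter_resolution(entries, cutoff=4.0)
        assert bool(kept_list) is kept
        if not kept:
            assert dropped[0].drop_reason == "resolution"

    def test_no_resolution_kept_and_flagged(self):
        entries = [_entry("nmr", resolution=None)]
        kept, dropped = filter_resolution(entries)
        assert kept and not dropped
        assert "no_resolution" in kept[0].flags

    def test_partition_preserved(self):
        entries = [_entry(f"e{i}", resolution=r)
                   for i, r in enumerate([1.0, 3.99, 4.0, 5.0, None])]
        kept, dropped = filter_resolution(entries)
        assert len(kept) + len(dropped) == len(entries)
        assert all(e.drop_reason for e in dropped)
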