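"""Ingest allosteric-entry annotations and apply the early filters.

Entries arrive as one XML document per allosteric structure (entry ID,
PDB ID, UniProt accessions, allosteric-site residue list, modulator alias
and class).  Structure and accession identifiers in such curated databases
go stale, so every entry passes through an :class:`IdResolver` that
updates superseded PDB IDs, drops entries whose structures left the PDB,
and drops entries whose accessions disagree with the structure's
chain-to-accession mapping.

Active-site annotations come from two tabular sources keyed by accession
(UniProt-style and M-CSA-style, both in canonical sequence numbering) and
are merged by set union — the catalytic-site source covers few proteins,
so intersection would discard most annotations.

The XML element names are configurable because upstream schemas vary; the
defaults match the fixture schema emitted by
:mod:`allobench.synthetic_fixtures`.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

from .core_model import AllostericEntry, ModulatorClass

logger = logging.getLogger(__name__)

__all__ = [
    "RawAsdEntry",
    "XmlSchema",
    "IdResolver",
    "StaticIdResolver",
    "ActiveSiteRecord",
    "parse_asd_xml",
    "parse_asd_directory",
    "read_active_site_table",
    "merge_active_sites",
    "reconcile_identifiers",
    "select_complete_entries",
    "filter_resolution",
]


@dataclass
class RawAsdEntry:
    entry_id: str
    pdb_id: str
    accessions: list[str] = field(default_factory=list)
    allosteric_residue_text: str = ""
    modulator_alias: str = ""
    modulator_class: ModulatorClass = ModulatorClass.UNKNOWN
    flags: list[str] = field(default_factory=list)
    status: str = "kept"
    drop_reason: str = ""

    def drop(self, reason: str) -> None:
        self.status = "dropped"
        self.drop_reason = reason


@dataclass(frozen=True)
class XmlSchema:
    """Element names of the entry XML; override to match other dialects."""

    root: str = "entry"
    entry_id: str = "entry_id"
    pdb_id: str = "pdb_id"
    accessions: str = "uniprot_ids"
    accession_item: str = "id"
    allosteric_site: str = "allosteric_site"
    modulator: str = "modulator"
    modulator_alias: str = "alias"
    modulator_class: str = "class"


class IdResolver(Protocol):
    """Identifier-reconciliation backend (snapshot of the reference DBs)."""

    def resolve_pdb(self, pdb_id: str) -> str | None:
        """Current PDB ID, or None if the structure was removed."""
        ...

    def chain_map(self, pdb_id: str) -> dict[str, str]:
        """chain_id -> UniProt-style accession for the current structure."""
        ...

    def resolve_accession(self, accession: str) -> str:
        """Current accession for a possibly-superseded one."""
        ...


@dataclass
class StaticIdResolver:
    """Table-backed resolver (the fixture backend; deterministic).

    ``pdb_updates`` maps old -> new IDs; absence from ``chain_maps`` after
    update means the structure no longer exists.
    """

    pdb_updates: dict[str, str] = field(default_factory=dict)
    chain_maps: dict[str, dict[str, str]] = field(default_factory=dict)
    accession_updates: dict[str, str] = field(default_factory=dict)

    def resolve_pdb(self, pdb_id: str) -> str | None:
        current = pdb_id.upper()
        seen = {current}
        while current in self.pdb_updates:
            current = self.pdb_updates[current].upper()
            if current in seen:  # defensive: cyclic table
                break
            seen.add(current)
        return current if current in self.chain_maps else None

    def chain_map(self, pdb_id: str) -> dict[str, str]:
        return dict(self.chain_maps.get(pdb_id.upper(), {}))

    def resolve_accession(self, accession: str) -> str:
        return self.accession_updates.get(accession, accession)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StaticIdResolver":
        """Load from a 3-column TSV: kind<TAB>key<TAB>value, where kind is
        ``pdb_update`` (old,new), ``chain`` (pdb:chain,accession) or
        ``accession_update`` (old,new)."""
        resolver = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            kind, key, value = line.rstrip("\n").split("\t")
            if kind == "pdb_update":
                resolver.pdb_updates[key.upper()] = value.upper()
            elif kind == "chain":
                pdb_id, _, chain = key.partition(":")
                resolver.chain_maps.setdefault(pdb_id.upper(), {})[chain] = value
            elif kind == "accession_update":
                resolver.accession_updates[key] = value
            else:
                raise ValueError(f"unknown resolver record kind {kind!r}")
        return resolver


def parse_asd_xml(document: str | bytes, schema: XmlSchema | None = None) -> RawAsdEntry:
    """Parse one entry XML document.

    The allosteric residue text is kept verbatim for later parsing; a
    missing site element flags the entry ("missing_site_annotation") but
    does not drop it here — completeness is judged after residue
    synchronization.
    """
    sch = schema or XmlSchema()
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise ValueError(f"malformed entry XML: {exc}") from exc
    if root.tag != sch.root:
        raise ValueError(f"unexpected root element {root.tag!r} (want {sch.root!r})")

    def text_of(tag: str, parent: ET.Element = root) -> str:
        el = parent.find(tag)
        return (el.text or "").strip() if el is not None else ""

    entry = RawAsdEntry(
        entry_id=text_of(sch.entry_id),
        pdb_id=text_of(sch.pdb_id).upper(),
        allosteric_residue_text=text_of(sch.allosteric_site),
    )
    if not entry.entry_id:
        raise ValueError("entry XML lacks an entry id")
    acc_el = root.find(sch.accessions)
    if acc_el is not None:
        entry.accessions = [
            (item.text or "").strip() for item in acc_el.findall(sch.accession_item)
            if (item.text or "").strip()
        ]
    mod_el = root.find(sch.modulator)
    if mod_el is not None:
        entry.modulator_alias = text_of(sch.modulator_alias, mod_el)
        cls_text = text_of(sch.modulator_class, mod_el)
        try:
            entry.modulator_class = ModulatorClass(cls_text) if cls_text else ModulatorClass.UNKNOWN
        except ValueError:
            entry.modulator_class = ModulatorClass.OTHER
    if root.find(sch.allosteric_site) is None or not entry.allosteric_residue_text:
        entry.flags.append("missing_site_annotation")
    return entry


def parse_asd_directory(directory: str | Path, schema: XmlSchema | None = None) -> list[RawAsdEntry]:
    entries = []
    for path in sorted(Path(directory).glob("*.xml")):
        try:
            entries.append(parse_asd_xml(path.read_text(), schema))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    ids = [e.entry_id for e in entries]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate entry_id in batch")
    return entries


def reconcile_identifiers(entry: RawAsdEntry, resolver: IdResolver) -> RawAsdEntry:
    """Update superseded identifiers; drop removed or inconsistent entries.

    Idempotent for a fixed resolver snapshot.  Drop reasons:
    ``pdb_removed`` (structure no longer exists) and ``id_discrepancy``
    (none of the entry's accessions appears among the structure's chains).
    """
    if entry.status == "dropped":
        return entry
    current = resolver.resolve_pdb(entry.pdb_id)
    if current is None:
        entry.drop("pdb_removed")
        return entry
    if current != entry.pdb_id:
        logger.info("entry %s: PDB ID %s superseded by %s",
                    entry.entry_id, entry.pdb_id, current)
        entry.pdb_id = current
    entry.accessions = [resolver.resolve_accession(a) for a in entry.accessions]
    chain_accessions = set(resolver.chain_map(current).values())
    if entry.accessions and not set(entry.accessions) & chain_accessions:
        entry.drop("id_discrepancy")
    return entry


@dataclass(frozen=True)
class ActiveSiteRecord:
    accession: str
    position: int  # 1-based position in the canonical sequence
    source: str    # "UniProt" or "MCSA"


def read_active_site_table(path: str | Path) -> list[ActiveSiteRecord]:
    """Read a tab-delimited active-site table: accession, position, source."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        accession, position, source = line.rstrip("\n").split("\t")
        records.append(ActiveSiteRecord(accession, int(position), source))
    return records


def merge_active_sites(
    uniprot_records: Iterable[ActiveSiteRecord],
    mcsa_records: Iterable[ActiveSiteRecord],
) -> dict[str, dict[int, set[str]]]:
    """Union the two annotation sources per accession.

    Returns accession -> {position -> set of source names}; provenance per
    position is retained.  Commutative and idempotent.
    """
    merged: dict[str, dict[int, set[str]]] = {}
    for rec in list(uniprot_records) + list(mcsa_records):
        merged.setdefault(rec.accession, {}).setdefault(rec.position, set()).add(rec.source)
    return merged


def select_complete_entries(
    entries: list[AllostericEntry],
) -> tuple[list[AllostericEntry], list[AllostericEntry]]:
    """Keep entries with both site kinds present after synchronization.

    An entry needs at least one non-empty allosteric site and one non-empty
    mapped active site; others are dropped with reason
    ``incomplete_annotation``.
    """
    kept, dropped = [], []
    for entry in entries:
        if entry.status == "dropped":
            dropped.append(entry)
            continue
        if entry.allosteric_sites and entry.active_sites:
            kept.append(entry)
        else:
            entry.drop("incomplete_annotation")
            dropped.append(entry)
    return kept, dropped


def filter_resolution(
    entries: list[AllostericEntry], cutoff: float = 4.0
) -> tuple[list[AllostericEntry], list[AllostericEntry]]:
    """Keep structures with resolution strictly better than ``cutoff`` Å.

    Structures without a resolution record (e.g. NMR ensembles) are kept
    and flagged ``no_resolution`` — the criterion only excludes structures
    measured to be worse — so users can exclude them downstream.
    """
    kept, dropped = [], []
    for entry in entries:
        if entry.status == "dropped":
            dropped.append(entry)
            continue
        res = entry.structure_meta.resolution
        if res is None:
            if "no_resolution" not in entry.flags:
                entry.flags.append("no_resolution")
            kept.append(entry)
        elif res < cutoff:
            kept.append(entry)
        else:
            entry.drop("resolution")
            dropped.append(entry)
    return kept, dropped
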