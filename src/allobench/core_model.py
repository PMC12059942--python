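"""Shared domain types for the curation pipeline and benchmark harness.

The pipeline turns allosteric-protein annotations (database entries with
allosteric-site residues and a bound-modulator alias) plus PDB structures
into a tabular dataset of allosteric and active sites.  Everything down-
stream speaks in terms of the types defined here.

Residue identity is (chain, author number, insertion code): prediction
tools report residue numbers, not names, so the residue name is carried
for display/diagnostics only and never participates in equality.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ResidueRef",
    "SiteKind",
    "ModulatorClass",
    "SiteSource",
    "SiteAnnotation",
    "Atom",
    "Chain",
    "StructureModel",
    "StructureMeta",
    "AllostericEntry",
    "PredictionRecord",
    "BenchmarkResult",
    "PipelineConfig",
    "format_residue",
    "parse_residue_token",
    "serialize_residue_set",
    "parse_residue_set",
    "write_dataset_csv",
    "read_dataset_csv",
    "DatasetSchemaError",
]


@dataclass(frozen=True, order=True)
class ResidueRef:
    """One residue in author numbering.

    Equality and hashing use (chain_id, number, insertion_code) only;
    ``name`` is advisory.
    """

    chain_id: str
    number: int
    insertion_code: str = ""
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")


class SiteKind(str, enum.Enum):
    ALLOSTERIC = "allosteric"
    ACTIVE = "active"


class ModulatorClass(str, enum.Enum):
    SMALL_MOLECULE = "small_molecule"
    ION = "ion"
    PEPTIDE = "peptide"
    OTHER = "other"
    UNKNOWN = "unknown"


class SiteSource(str, enum.Enum):
    ASD = "ASD"
    UNIPROT = "UniProt"
    MCSA = "MCSA"
    DERIVED_GEOMETRIC = "derived_geometric"


@dataclass
class SiteAnnotation:
    """A set of residues forming one binding site."""

    kind: SiteKind
    residues: frozenset[ResidueRef]
    modulator_alias: str = ""
    modulator_class: ModulatorClass = ModulatorClass.UNKNOWN
    source: SiteSource = SiteSource.ASD

    def __post_init__(self) -> None:
        self.residues = frozenset(self.residues)
        if not self.residues:
            raise ValueError("a site must contain at least one residue")
        if self.kind is SiteKind.ACTIVE and self.modulator_alias:
            raise ValueError("active sites carry no modulator alias")


@dataclass(frozen=True)
class Atom:
    residue: ResidueRef
    name: str
    element: str
    x: float
    y: float
    z: float
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Chain:
    chain_id: str
    seqres: str  # 1-letter deposited sequence; may be "" if absent
    residues: list[ResidueRef]  # observed polymer residues, file order


@dataclass
class StructureModel:
    """Parsed coordinates plus the metadata the pipeline filters on.

    ``chains``/``atoms`` hold the first model; additional models of a
    multi-MODEL file live in ``extra_models`` until
    :func:`allobench.structure_ops.merge_models` folds them in.
    """

    pdb_id: str
    resolution: float | None
    chains: dict[str, Chain]
    atoms: list[Atom]
    chain_to_accession: dict[str, str] = field(default_factory=dict)
    extra_models: list[tuple[dict[str, Chain], list[Atom]]] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return 1 + len(self.extra_models)

    def n_protein_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains.values())


@dataclass
class StructureMeta:
    resolution: float | None = None
    method: str = ""
    oligomeric_state: str = ""


@dataclass
class AllostericEntry:
    """One record of the output dataset: an allosteric structure with both
    site kinds, carrying its keep/drop status and the reason for a drop."""

    entry_id: str
    pdb_id: str
    accessions: list[str] = field(default_factory=list)
    allosteric_sites: list[SiteAnnotation] = field(default_factory=list)
    active_sites: list[SiteAnnotation] = field(default_factory=list)
    structure_meta: StructureMeta = field(default_factory=StructureMeta)
    status: str = "kept"
    drop_reason: str = ""
    lddt: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.status not in ("kept", "dropped"):
            raise ValueError(f"invalid status {self.status!r}")
        if (self.status == "dropped") != bool(self.drop_reason):
            raise ValueError("status=dropped iff drop_reason is non-empty")
        if self.lddt is not None and not (0.0 <= self.lddt <= 1.0):
            raise ValueError("lddt must lie in [0, 1]")

    def drop(self, reason: str) -> None:
        if not reason:
            raise ValueError("a drop needs a reason")
        self.status = "dropped"
        self.drop_reason = reason


@dataclass
class PredictionRecord:
    """Ranked residue-set predictions from one tool for one protein.

    ``ranked_sites`` may be empty (tool failure); downstream scoring
    assigns such records a Jaccard index of 0.
    """

    tool: str
    protein_id: str
    ranked_sites: list[tuple[frozenset[ResidueRef], float | None]] = field(default_factory=list)


@dataclass
class BenchmarkResult:
    protein_id: str
    tool: str
    ji: float
    matched_known_site_index: int
    centroid_distance: float | None = None
    failed: bool = False  # tool produced no prediction; JI 0 assigned

    def __post_init__(self) -> None:
        if not (0.0 <= self.ji <= 1.0):
            raise ValueError("Jaccard index must lie in [0, 1]")
        if self.centroid_distance is not None and self.centroid_distance < 0:
            raise ValueError("centroid distance must be >= 0")

    @property
    def inverse_distance(self) -> float | None:
        """1/distance in 1/Å; None for coincident centroids or no distance."""
        if self.centroid_distance is None or self.centroid_distance == 0.0:
            return None
        return 1.0 / self.centroid_distance


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline in one place.

    Defaults are the published operating point: sites are residues within
    4 Å of the bound modulator, structures must diffract better than 4 Å,
    rebuilt models must score lDDT >= 0.8, and test-set structures may not
    exceed 8000 residues.
    """

    distance_cutoff_A: float = 4.0
    max_resolution_A: float = 4.0
    min_lddt: float = 0.8
    max_residues: int = 8000
    lddt_thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    lddt_inclusion_radius_A: float = 15.0
    min_alignment_identity: float = 0.30
    agreement_ji_threshold: float = 0.5

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a key=value config file; unknown keys are an error."""
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if key == "lddt_thresholds":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key == "max_residues":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name}={value}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Residue-set serialization
# ---------------------------------------------------------------------------

def format_residue(r: ResidueRef) -> str:
    """Serialize as ``chain:number[icode]``."""
    return f"{r.chain_id}:{r.number}{r.insertion_code}"


def parse_residue_token(token: str, default_chain: str | None = None) -> ResidueRef:
    """Parse ``chain:number[icode]`` or a bare number (needs default_chain)."""
    token = token.strip()
    if not token:
        raise ValueError("empty residue token")
    if ":" in token:
        chain, _, rest = token.rpartition(":")
    else:
        if default_chain is None:
            raise ValueError(f"bare residue number {token!r} without a chain")
        chain, rest = default_chain, token
    digits = rest
    icode = ""
    if digits and digits[-1].isalpha():
        icode = digits[-1]
        digits = digits[:-1]
    if not digits or not digits.lstrip("-").isdigit():
        raise ValueError(f"cannot parse residue token {token!r}")
    return ResidueRef(chain_id=chain, number=int(digits), insertion_code=icode)


def serialize_residue_set(residues: Iterable[ResidueRef]) -> str:
    """Semicolon-joined sorted tokens — deterministic for stable diffs."""
    return ";".join(sorted(format_residue(r) for r in residues))


def parse_residue_set(text: str) -> frozenset[ResidueRef]:
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(parse_residue_token(tok) for tok in text.split(";"))


# ---------------------------------------------------------------------------
# Dataset CSV (schema v1): one row per (entry, allosteric site);
# dropped entries appear as a single row with empty site columns.
# ---------------------------------------------------------------------------

DATASET_COLUMNS = [
    "entry_id",
    "pdb_id",
    "accessions",
    "status",
    "drop_reason",
    "resolution",
    "method",
    "oligomeric_state",
    "lddt",
    "site_index",
    "allosteric_residues",
    "allosteric_source",
    "modulator_alias",
    "modulator_class",
    "active_residues",
    "active_sources",
    "flags",
]


class DatasetSchemaError(ValueError):
    """Raised when a dataset CSV does not match the documented schema."""


def _fmt_float(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def write_dataset_csv(entries: Sequence[AllostericEntry], path: str | Path) -> int:
    """Write the dataset; returns the number of data rows written.

    Round-trips losslessly through :func:`read_dataset_csv` (residue names,
    which never participate in identity, are not preserved).
    """
    n_rows = 0
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=DATASET_COLUMNS)
        writer.writeheader()
        for entry in entries:
            entry.validate()
            base = {
                "entry_id": entry.entry_id,
                "pdb_id": entry.pdb_id,
                "accessions": ";".join(entry.accessions),
                "status": entry.status,
                "drop_reason": entry.drop_reason,
                "resolution": _fmt_float(entry.structure_meta.resolution),
                "method": entry.structure_meta.method,
                "oligomeric_state": entry.structure_meta.oligomeric_state,
                "lddt": _fmt_float(entry.lddt),
                "active_residues": "|".join(
                    serialize_residue_set(s.residues) for s in entry.active_sites
                ),
                "active_sources": "|".join(s.source.value for s in entry.active_sites),
                "flags": ";".join(entry.flags),
            }
            sites = entry.allosteric_sites
            if not sites:
                row = dict(base, site_index="", allosteric_residues="",
                           allosteric_source="", modulator_alias="", modulator_class="")
                writer.writerow(row)
                n_rows += 1
                continue
            for i, site in enumerate(sites):
                row = dict(
                    base,
                    site_index=str(i),
                    allosteric_residues=serialize_residue_set(site.residues),
                    allosteric_source=site.source.value,
                    modulator_alias=site.modulator_alias,
                    modulator_class=site.modulator_class.value,
                )
                writer.writerow(row)
                n_rows += 1
    return n_rows


def read_dataset_csv(path: str | Path) -> list[AllostericEntry]:
    """Inverse of :func:`write_dataset_csv`."""
    entries: dict[str, AllostericEntry] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in DATASET_COLUMNS if c not in header]
        if missing:
            raise DatasetSchemaError(f"missing required column(s): {', '.join(missing)}")
        for row in reader:
            eid = row["entry_id"]
            if eid not in entries:
                active_sites = []
                res_cells = row["active_residues"].split("|") if row["active_residues"] else []
                src_cells = row["active_sources"].split("|") if row["active_sources"] else []
                for cell, src in zip(res_cells, src_cells):
                    residues = parse_residue_set(cell)
                    if not residues:
                        raise DatasetSchemaError(
                            f"empty residue set in column 'active_residues' of entry {eid}"
                        )
                    active_sites.append(SiteAnnotation(
                        kind=SiteKind.ACTIVE, residues=residues, source=SiteSource(src)))
                entries[eid] = AllostericEntry(
                    entry_id=eid,
                    pdb_id=row["pdb_id"],
                    accessions=row["accessions"].split(";") if row["accessions"] else [],
                    active_sites=active_sites,
                    structure_meta=StructureMeta(
                        resolution=float(row["resolution"]) if row["resolution"] else None,
                        method=row["method"],
                        oligomeric_state=row["oligomeric_state"],
                    ),
                    status=row["status"],
                    drop_reason=row["drop_reason"],
                    lddt=float(row["lddt"]) if row["lddt"] else None,
                    flags=row["flags"].split(";") if row["flags"] else [],
                )
            entry = entries[eid]
            if row["site_index"] != "":
                residues = parse_residue_set(row["allosteric_residues"])
                if not residues and entry.status == "kept":
                    raise DatasetSchemaError(
                        f"empty residue set in column 'allosteric_residues' of kept entry {eid}"
                    )
                if residues:
                    entry.allosteric_sites.append(SiteAnnotation(
                        kind=SiteKind.ALLOSTERIC,
                        residues=residues,
                        modulator_alias=row["modulator_alias"],
                        modulator_class=ModulatorClass(row["modulator_class"]),
                        source=SiteSource(row["allosteric_source"]),
                    ))
    return list(entries.values())
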