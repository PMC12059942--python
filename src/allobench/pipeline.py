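"""End-to-end curation pipeline and benchmark entry points.

``run_pipeline`` wires the stages together with full drop-reason
accounting: parse entry XML -> reconcile identifiers -> merge active-site
sources -> parse structures (dropping mmCIF-only files) -> merge models ->
synchronize residue numbering -> completeness check -> resolution filter
-> gap detection (emitting target-template alignments for an external
modeling engine) -> lDDT gate -> modulator resolution -> geometric site
extraction -> CSV.  Every drop carries a reason; stage counts telescope
(what enters stage k+1 is exactly what stage k kept), and a rerun over
the same inputs is byte-identical.

Gap *filling* is delegated to a user-supplied modeling command taking a
template PDB and an alignment JSON; without one, gapped entries pass
through unmodeled and flagged.
"""

from __future__ import annotations

import json
import logging
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import annotation_ingest as ingest
from . import benchmark as bench
from . import model_qc
from . import site_extraction
from . import structure_ops
from .core_model import (
    AllostericEntry,
    PipelineConfig,
    PredictionRecord,
    SiteAnnotation,
    SiteKind,
    SiteSource,
    StructureMeta,
    StructureModel,
    parse_residue_token,
    write_dataset_csv,
)
from .residue_sync import UnalignableError, map_residue_numbers, remap_site

logger = logging.getLogger(__name__)

__all__ = ["PipelineInputs", "PipelineReport", "StageCount",
           "run_pipeline", "run_benchmark", "read_predictions_dir"]


@dataclass
class StageCount:
    name: str
    n_in: int
    n_kept: int
    drops: dict[str, int] = field(default_factory=dict)


@dataclass
class PipelineReport:
    stages: list[StageCount] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(self, name: str, entries_in, entries_kept) -> None:
        drops: dict[str, int] = {}
        kept_ids = {e.entry_id for e in entries_kept if e.status == "kept"}
        for e in entries_in:
            if e.entry_id not in kept_ids and e.status == "dropped":
                drops[e.drop_reason] = drops.get(e.drop_reason, 0) + 1
        self.stages.append(StageCount(name, len(entries_in), len(kept_ids), drops))

    def drop_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for stage in self.stages:
            for reason, n in stage.drops.items():
                tally[reason] = tally.get(reason, 0) + n
        return tally

    def check_telescoping(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_kept != nxt.n_in:
                raise AssertionError(
                    f"stage counts do not telescope: {prev.name} kept "
                    f"{prev.n_kept} but {nxt.name} saw {nxt.n_in}")


@dataclass
class PipelineInputs:
    """Paths of a corpus directory (the layout write_corpus emits)."""

    xml_dir: Path
    structures_dir: Path
    active_sites: Path
    sequences_fasta: Path
    resolver: Path | None = None
    clusters: Path | None = None

    @classmethod
    def from_corpus_dir(cls, corpus: str | Path) -> "PipelineInputs":
        corpus = Path(corpus)
        return cls(
            xml_dir=corpus / "xml",
            structures_dir=corpus / "structures",
            active_sites=corpus / "active_sites.tsv",
            sequences_fasta=corpus / "sequences.fasta",
            resolver=corpus / "resolver.tsv",
            clusters=corpus / "clusters.tsv",
        )


def _listed_site(raw: ingest.RawAsdEntry) -> frozenset:
    """Parse the annotation's allosteric residue text (author numbering).

    Accepts ``chain:number`` tokens and bare numbers; bare numbers go to
    the single annotated chain and are ambiguous otherwise.
    """
    text = raw.allosteric_residue_text
    if not text:
        return frozenset()
    tokens = [t for t in text.replace(",", ";").split(";") if t.strip()]
    if any(":" not in t for t in tokens) and "ambiguous_chain" not in raw.flags:
        raw.flags.append("bare_residue_numbers")
    return frozenset(parse_residue_token(t, default_chain="A") for t in tokens)


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    resolver: ingest.IdResolver | None = None,
    modeling_command: list[str] | None = None,
    output_csv: str | Path | None = None,
    alignments_dir: str | Path | None = None,
) -> tuple[list[AllostericEntry], dict[str, StructureModel], PipelineReport]:
    """Run the full curation pipeline over a corpus.

    Returns all entries (kept and dropped, no silent loss), the parsed
    structures keyed by PDB ID, and the stage-by-stage report.
    """
    cfg = config or PipelineConfig()
    report = PipelineReport()
    if resolver is None:
        if inputs.resolver is None:
            raise ValueError("an identifier resolver is required")
        resolver = ingest.StaticIdResolver.from_tsv(inputs.resolver)

    # --- parse annotation XML -------------------------------------------
    raw_entries = ingest.parse_asd_directory(inputs.xml_dir)
    raw_entries.sort(key=lambda e: e.entry_id)

    entries: list[AllostericEntry] = [
        AllostericEntry(entry_id=r.entry_id, pdb_id=r.pdb_id,
                        accessions=list(r.accessions), flags=list(r.flags))
        for r in raw_entries
    ]
    raw_by_id = {r.entry_id: r for r in raw_entries}
    report.record("parse_xml", entries, entries)

    # --- reconcile identifiers ------------------------------------------
    for entry in entries:
        raw = raw_by_id[entry.entry_id]
        raw.pdb_id, raw.accessions = entry.pdb_id, entry.accessions
        ingest.reconcile_identifiers(raw, resolver)
        entry.pdb_id, entry.accessions = raw.pdb_id, list(raw.accessions)
        if raw.status == "dropped":
            entry.drop(raw.drop_reason)
    live = [e for e in entries if e.status == "kept"]
    report.record("reconcile_ids", entries, live)

    # --- merge active-site annotation sources ---------------------------
    records = ingest.read_active_site_table(inputs.active_sites)
    active_map = ingest.merge_active_sites(
        [r for r in records if r.source == "UniProt"],
        [r for r in records if r.source == "MCSA"],
    )
    sequences = {rec.id: str(rec.seq)
                 for rec in SeqIO.parse(str(inputs.sequences_fasta), "fasta")}

    # --- parse structures ------------------------------------------------
    structures: dict[str, StructureModel] = {}
    for entry in live:
        if entry.pdb_id in structures:
            continue
        path = inputs.structures_dir / f"{entry.pdb_id}.pdb"
        if not path.exists():
            path = inputs.structures_dir / f"{entry.pdb_id.lower()}.pdb"
        if not path.exists():
            entry.drop("structure_missing")
            continue
        try:
            structures[entry.pdb_id] = structure_ops.parse_structure(
                path.read_text(), pdb_id=entry.pdb_id,
                chain_to_accession=resolver.chain_map(entry.pdb_id))
        except structure_ops.MmcifOnlyError:
            entry.drop("mmcif_only")
        except structure_ops.StructureParseError as exc:
            raise RuntimeError(
                f"stage parse_structures failed for entry {entry.entry_id}: {exc}"
            ) from exc
    live2 = [e for e in live if e.status == "kept"]
    report.record("parse_structures", live, live2)

    # --- merge multi-MODEL files -----------------------------------------
    for pdb_id in sorted(structures):
        structures[pdb_id] = structure_ops.merge_models(structures[pdb_id])
    for entry in live2:
        s = structures[entry.pdb_id]
        entry.structure_meta = StructureMeta(
            resolution=s.resolution,
            method="XRAY" if s.resolution is not None else "UNKNOWN",
            oligomeric_state=f"{len(s.chains)}-chain",
        )
    report.record("merge_models", live2, live2)

    # --- residue synchronization: map active sites into author numbering -
    for entry in live2:
        s = structures[entry.pdb_id]
        raw = raw_by_id[entry.entry_id]
        listed = _listed_site(raw)
        if listed:
            entry.allosteric_sites = [SiteAnnotation(
                kind=SiteKind.ALLOSTERIC, residues=listed,
                modulator_alias=raw.modulator_alias,
                modulator_class=raw.modulator_class, source=SiteSource.ASD)]
        try:
            for accession in entry.accessions:
                canonical = sequences.get(accession)
                positions = set(active_map.get(accession, {}))
                if not canonical or not positions:
                    continue
                for chain_id, chain in sorted(s.chains.items()):
                    if s.chain_to_accession.get(chain_id) != accession or not chain.residues:
                        continue
                    mapping = map_residue_numbers(
                        canonical, chain.residues,
                        min_identity=cfg.min_alignment_identity)
                    mapped, unmapped = remap_site(positions, mapping)
                    if unmapped:
                        report.warnings.append(
                            f"{entry.entry_id}: {len(unmapped)} active position(s) "
                            f"unmapped on chain {chain_id}")
                    if mapped:
                        sources = {src for pos in positions
                                   for src in active_map[accession].get(pos, set())}
                        entry.active_sites.append(SiteAnnotation(
                            kind=SiteKind.ACTIVE, residues=mapped,
                            source=(SiteSource.MCSA if sources == {"MCSA"}
                                    else SiteSource.UNIPROT)))
        except UnalignableError:
            entry.drop("unalignable")
    live3 = [e for e in live2 if e.status == "kept"]
    report.record("residue_sync", live2, live3)

    # --- completeness and resolution filters ----------------------------
    kept, _ = ingest.select_complete_entries(live3)
    report.record("select_complete", live3, kept)
    kept2, _ = ingest.filter_resolution(kept, cutoff=cfg.max_resolution_A)
    report.record("filter_resolution", kept, kept2)

    # --- gap detection + optional external modeling + lDDT gate ----------
    for entry in kept2:
        s = structures[entry.pdb_id]
        gaps = structure_ops.find_missing_residues(s)
        if not gaps:
            continue
        entry.flags.append("has_gaps")
        alignment = structure_ops.build_target_template_alignment(s, gaps)
        if alignments_dir is not None:
            path = Path(alignments_dir) / f"{entry.pdb_id}.json"
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text(structure_ops.alignment_to_json(alignment))
        if modeling_command:
            model = _run_modeling(modeling_command, inputs, entry, alignment)
            if model is None:
                entry.flags.append("unmodeled")
                continue
            entry.flags.append("modeled")
            result = model_qc.compute_lddt(
                s, model, thresholds=cfg.lddt_thresholds,
                inclusion_radius=cfg.lddt_inclusion_radius_A)
            entry.lddt = result.global_score
        else:
            entry.flags.append("unmodeled")
    kept3, _ = model_qc.qc_filter(kept2, min_lddt=cfg.min_lddt)
    report.record("lddt_gate", kept2, kept3)

    # --- modulator resolution + geometric site extraction ----------------
    for entry in kept3:
        s = structures[entry.pdb_id]
        raw = raw_by_id[entry.entry_id]
        if not raw.modulator_alias:
            entry.drop("no_modulator_alias")
            continue
        instances = site_extraction.resolve_modulator(raw.modulator_alias, s)
        if not instances:
            entry.flags.append("modulator_not_found")
            entry.drop("modulator_not_found")
            continue
        listed = entry.allosteric_sites[0].residues if entry.allosteric_sites else frozenset()
        derived_sites = []
        for inst in instances:
            site = site_extraction.extract_site(s, inst, cutoff=cfg.distance_cutoff_A)
            if not site:
                continue
            ji, verdict = site_extraction.validate_site_agreement(
                listed, site, ji_threshold=cfg.agreement_ji_threshold)
            if verdict == "discrepant" and "site_discrepant" not in entry.flags:
                entry.flags.append("site_discrepant")
            derived_sites.append(SiteAnnotation(
                kind=SiteKind.ALLOSTERIC, residues=site,
                modulator_alias=inst.chem_comp_id,
                modulator_class=raw.modulator_class,
                source=SiteSource.DERIVED_GEOMETRIC))
        if not derived_sites:
            entry.drop("empty_derived_site")
            continue
        # the geometrically derived sites are authoritative in the dataset
        entry.allosteric_sites = derived_sites
    final = [e for e in kept3 if e.status == "kept"]
    report.record("extract_sites", kept3, final)
    report.check_telescoping()

    if output_csv is not None:
        write_dataset_csv(entries, output_csv)
    return entries, structures, report


def _run_modeling(command, inputs, entry, alignment) -> StructureModel | None:
    """Invoke the external modeling engine: cmd TEMPLATE_PDB ALIGNMENT_JSON.

    The command must print a model PDB file path on stdout; failures leave
    the entry unmodeled (logged), never abort the pipeline.
    """
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".json", delete=False) as fh:
        fh.write(structure_ops.alignment_to_json(alignment))
        align_path = fh.name
    template = inputs.structures_dir / f"{entry.pdb_id}.pdb"
    try:
        proc = subprocess.run(
            list(command) + [str(template), align_path],
            capture_output=True, text=True, timeout=600, check=True)
        model_path = proc.stdout.strip().splitlines()[-1]
        return structure_ops.parse_structure_file(model_path, pdb_id=entry.pdb_id)
    except (subprocess.SubprocessError, OSError, IndexError,
            structure_ops.StructureParseError) as exc:
        logger.warning("modeling failed for %s: %s", entry.entry_id, exc)
        return None


# ---------------------------------------------------------------------------
# Benchmark entry point
# ---------------------------------------------------------------------------

def read_predictions_dir(directory: str | Path) -> list[PredictionRecord]:
    """Read prediction records from JSON files (one per tool × protein).

    Schema: ``{"tool": ..., "protein_id": ..., "ranked_sites":
    [{"residues": ["A:10", ...], "score": optional}, ...]}``.
    Duplicate (tool, protein) pairs are an error.
    """
    records: list[PredictionRecord] = []
    seen: set[tuple[str, str]] = set()
    for path in sorted(Path(directory).glob("*.json")):
        doc = json.loads(path.read_text())
        key = (doc["tool"], doc["protein_id"])
        if key in seen:
            raise ValueError(f"duplicate prediction file for {key}")
        seen.add(key)
        ranked = [
            (frozenset(parse_residue_token(t) for t in site["residues"]),
             site.get("score"))
            for site in doc.get("ranked_sites", [])
        ]
        records.append(PredictionRecord(tool=doc["tool"],
                                        protein_id=doc["protein_id"],
                                        ranked_sites=ranked))
    return records


def run_benchmark(
    entries: list[AllostericEntry],
    predictions: list[PredictionRecord],
    structures: dict[str, StructureModel] | None = None,
    cutoffs: tuple[float, ...] = bench.DEFAULT_CUTOFFS,
    best_of_k: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Score predictions against the curated known sites.

    Proteins are keyed by entry_id; predictions referencing unknown
    proteins are skipped with a warning.  Returns (per-protein results,
    per-tool summary, accuracy curve, warnings).
    """
    known: dict[str, list[frozenset]] = {}
    for entry in entries:
        if entry.status == "kept" and entry.allosteric_sites:
            known[entry.entry_id] = [s.residues for s in entry.allosteric_sites]
    warnings: list[str] = []
    results = []
    for p in predictions:
        if p.protein_id not in known:
            warnings.append(f"prediction for unknown protein {p.protein_id} skipped")
            continue
        s = None
        if structures:
            entry = next(e for e in entries if e.entry_id == p.protein_id)
            s = structures.get(entry.pdb_id)
        if s is not None:
            p, _ = bench.normalize_prediction(p, s)
        results.append(bench.score_prediction(p, known[p.protein_id], s,
                                              best_of_k=best_of_k))
    if not results:
        return (pd.DataFrame(), pd.DataFrame(), pd.DataFrame(),
                warnings + ["no predictions scored"])
    curve = bench.accuracy_curve(results, cutoffs)
    return (bench.results_to_frame(results), bench.summarize(results),
            curve.to_frame(), warnings)
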