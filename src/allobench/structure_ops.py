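"""PDB-format structure handling for the curation pipeline.

Parsing is delegated to gemmi; this module converts gemmi structures into
the pipeline's :class:`~allobench.core_model.StructureModel`, merges
multi-MODEL files into a single model with uniquely labeled chains,
detects missing residues against SEQRES, emits target-template alignments
for an external gap-modeling engine, and strips heteroatoms for test-set
preparation.

mmCIF input is not parsed: the benchmarked prediction tools only accept
PDB format, so mmCIF-only structures are flagged for dropping.
"""

from __future__ import annotations

import copy
import json
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi

from .core_model import Atom, Chain, ResidueRef, StructureModel
from .residue_sync import AlignmentParams, align_sequences, three_to_one

logger = logging.getLogger(__name__)

__all__ = [
    "GapReport",
    "MmcifOnlyError",
    "StructureParseError",
    "parse_structure",
    "parse_structure_file",
    "merge_models",
    "find_missing_residues",
    "build_target_template_alignment",
    "alignment_to_json",
    "strip_heteroatoms",
]

GAP_SYMBOL = "-"


class MmcifOnlyError(ValueError):
    """The input is mmCIF; the pipeline drops such structures ("mmcif_only")."""

    reason = "mmcif_only"


class StructureParseError(ValueError):
    pass


@dataclass
class GapReport:
    """Unobserved SEQRES ranges of one chain (1-based, inclusive)."""

    chain_id: str
    gaps: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, seq in self.gaps:
            if start <= prev_end:
                raise ValueError("gap ranges must be sorted and non-overlapping")
            if len(seq) != end - start + 1:
                raise ValueError("missing_sequence length must equal the range length")
            prev_end = end


def _looks_like_mmcif(text: str) -> bool:
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        return stripped.startswith("data_") or stripped.startswith("loop_") \
            or stripped.startswith("_")
    return False


def _select_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties -> lowest altloc ID."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
            continue
        if (atom.occ, -ord(atom.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
            chosen[atom.name] = atom
    return list(chosen.values())


def parse_structure(
    pdb_text: str,
    pdb_id: str = "",
    chain_to_accession: dict[str, str] | None = None,
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Extracts per-chain SEQRES sequences, resolution (REMARK 2), the model
    count, and all atoms with HETATM records flagged ``is_hetero``.
    Nonstandard residues that appear in SEQRES (e.g. MSE) are treated as
    protein, not heteroatoms, so that stripping heteroatoms does not
    create artificial gaps.
    """
    if _looks_like_mmcif(pdb_text):
        raise MmcifOnlyError("input is mmCIF; only PDB format is supported")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"unparseable PDB text: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError("no models found")
    st.setup_entities()

    # chain name -> SEQRES (1-letter and the raw 3-letter set)
    seqres1: dict[str, str] = {}
    seqres3: dict[str, set[str]] = {}
    for model in st:
        for ch in model:
            if ch.name in seqres1:
                continue
            ent = st.get_entity_of(ch.get_polymer())
            if ent is not None and ent.full_sequence:
                codes = [gemmi.Entity.first_mon(m) for m in ent.full_sequence]
                seqres1[ch.name] = "".join(three_to_one(c) for c in codes)
                seqres3[ch.name] = set(codes)

    def convert_model(model: gemmi.Model) -> tuple[dict[str, Chain], list[Atom]]:
        chains: dict[str, Chain] = {}
        atoms: list[Atom] = []
        for ch in model:
            observed: list[ResidueRef] = []
            in_seqres = seqres3.get(ch.name, set())
            for res in ch:
                is_water = res.name in ("HOH", "DOD", "WAT")
                hetero = is_water or (res.het_flag == "H" and res.name not in in_seqres)
                ref = ResidueRef(
                    chain_id=ch.name,
                    number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    name=res.name,
                )
                if not hetero:
                    observed.append(ref)
                for atom in _select_altloc(res):
                    atoms.append(Atom(
                        residue=ref,
                        name=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                        is_hetero=hetero,
                    ))
            if observed or any(a.residue.chain_id == ch.name for a in atoms):
                chains[ch.name] = Chain(
                    chain_id=ch.name,
                    seqres=seqres1.get(ch.name, ""),
                    residues=observed,
                )
        return chains, atoms

    first_chains, first_atoms = convert_model(st[0])
    extra = [convert_model(st[i]) for i in range(1, len(st))]
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return StructureModel(
        pdb_id=pdb_id or (st.name or "").strip().upper()[:4],
        resolution=resolution,
        chains=first_chains,
        atoms=first_atoms,
        chain_to_accession=dict(chain_to_accession or {}),
        extra_models=extra,
    )


def parse_structure_file(path: str | Path, **kwargs) -> StructureModel:
    path = Path(path)
    return parse_structure(path.read_text(), pdb_id=kwargs.pop("pdb_id", path.stem.upper()), **kwargs)


def _next_labels() -> list[str]:
    letters = string.ascii_uppercase
    singles = list(letters) + list(string.ascii_lowercase) + list(string.digits)
    doubles = [x + y for x in letters for y in letters]
    return singles + doubles


def merge_models(s: StructureModel) -> StructureModel:
    """Merge a multi-MODEL structure into a single model with unique chains.

    Models are processed in file order, chains alphabetically; each chain of
    model k>1 gets the first unused label (A-Z, a-z, 0-9, then two-letter
    codes).  Atom count and coordinates are preserved exactly.
    """
    if not s.extra_models:
        return s
    used = set(s.chains)
    pool = [lab for lab in _next_labels() if lab not in used]
    chains = dict(s.chains)
    atoms = list(s.atoms)
    accession = dict(s.chain_to_accession)
    for model_chains, model_atoms in s.extra_models:
        relabel: dict[str, str] = {}
        for old_id in sorted(model_chains):
            if not pool:
                raise ValueError("exhausted chain label space while merging models")
            new_id = pool.pop(0)
            relabel[old_id] = new_id
            used.add(new_id)
        for old_id, chain in sorted(model_chains.items()):
            new_id = relabel[old_id]
            chains[new_id] = Chain(
                chain_id=new_id,
                seqres=chain.seqres,
                residues=[ResidueRef(new_id, r.number, r.insertion_code, r.name)
                          for r in chain.residues],
            )
            if old_id in accession:
                accession[new_id] = accession[old_id]
        for a in model_atoms:
            new_id = relabel.get(a.residue.chain_id, a.residue.chain_id)
            atoms.append(Atom(
                residue=ResidueRef(new_id, a.residue.number,
                                   a.residue.insertion_code, a.residue.name),
                name=a.name, element=a.element,
                x=a.x, y=a.y, z=a.z, is_hetero=a.is_hetero,
            ))
    return StructureModel(
        pdb_id=s.pdb_id,
        resolution=s.resolution,
        chains=chains,
        atoms=atoms,
        chain_to_accession=accession,
        extra_models=[],
    )


def find_missing_residues(s: StructureModel) -> list[GapReport]:
    """Detect SEQRES ranges absent from the coordinates, per chain.

    SEQRES is aligned to the observed residue sequence; unobserved SEQRES
    positions form the gaps.  Chains without SEQRES are skipped with a
    warning.  If observed residues cannot be explained as a subsequence of
    SEQRES, the report carries a ``sequence_conflict`` gap-free marker via
    logging (the entry-level decision is the caller's).
    """
    reports: list[GapReport] = []
    for chain_id, chain in sorted(s.chains.items()):
        if not chain.seqres:
            logger.warning("chain %s has no SEQRES; skipping gap detection", chain_id)
            continue
        if not chain.residues:
            reports.append(GapReport(chain_id, [(1, len(chain.seqres), chain.seqres)]))
            continue
        observed_seq = "".join(three_to_one(r.name) for r in chain.residues)
        ga, gb, _ = align_sequences(chain.seqres, observed_seq, AlignmentParams())
        if any(x == "-" for x in ga):
            logger.warning("chain %s: observed residues not a subsequence of SEQRES "
                           "(sequence_conflict)", chain_id)
        gaps: list[tuple[int, int, str]] = []
        pos = 0
        run_start = None
        for x, y in zip(ga, gb):
            if x != "-":
                pos += 1
                if y == "-":
                    if run_start is None:
                        run_start = pos
                elif run_start is not None:
                    gaps.append((run_start, pos - 1, chain.seqres[run_start - 1:pos - 1]))
                    run_start = None
        if run_start is not None:
            gaps.append((run_start, pos, chain.seqres[run_start - 1:pos]))
        report = GapReport(chain_id, gaps)
        if gaps:
            reports.append(report)
    return reports


def build_target_template_alignment(
    s: StructureModel, gaps: list[GapReport]
) -> dict[str, dict[str, str]]:
    """Target-template alignment for an external modeling engine.

    Per chain: target = full SEQRES; template = SEQRES with gap symbols over
    the missing ranges, so that the structure serves as the template and the
    deposited sequence as the modeling target.  Strings are equal length.
    """
    by_chain = {g.chain_id: g for g in gaps}
    out: dict[str, dict[str, str]] = {}
    for chain_id, chain in sorted(s.chains.items()):
        if not chain.seqres:
            continue
        template = list(chain.seqres)
        report = by_chain.get(chain_id)
        if report is not None:
            for start, end, _seq in report.gaps:
                for i in range(start - 1, end):
                    template[i] = GAP_SYMBOL
        out[chain_id] = {"target": chain.seqres, "template": "".join(template)}
    return out


def alignment_to_json(alignment: dict[str, dict[str, str]]) -> str:
    return json.dumps(alignment, indent=2, sort_keys=True)


def strip_heteroatoms(s: StructureModel) -> StructureModel:
    """Remove all hetero atoms (ligands, ions, waters); drop emptied chains.

    Idempotent; protein chains and their coordinates are untouched.
    """
    atoms = [a for a in s.atoms if not a.is_hetero]
    chains = {cid: copy.deepcopy(c) for cid, c in s.chains.items() if c.residues}
    keep = set(chains)
    atoms = [a for a in atoms if a.residue.chain_id in keep]
    return StructureModel(
        pdb_id=s.pdb_id,
        resolution=s.resolution,
        chains=chains,
        atoms=atoms,
        chain_to_accession={c: a for c, a in s.chain_to_accession.items() if c in keep},
        extra_models=[],
    )
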