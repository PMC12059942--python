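"""Self-contained synthetic inputs for the pipeline and benchmark.

Real inputs to the pipeline are curated-database XML entries, PDB
structures, active-site tables, cluster tables, and prediction-tool
outputs — none of which can be fetched in a test.  This module fabricates
all of them with controllable, self-verified ground truth:

* structures are extended chains (Cα spacing 3.8 Å) so geometry is exactly
  controllable — no attempt at plausible folds;
* modulators are planted so that *exactly* a requested pocket lies within
  the distance cutoff, verified against a brute-force distance check
  before the fixture is emitted;
* corpus generation plants one defect per entry (obsolete ID, removed
  structure, ID discrepancy, missing annotation, numbering offset, low
  resolution, mmCIF-only file, coordinate gaps, ...) so each curation rule
  is independently testable;
* mock predictions overlap the known site by an exact fraction f, giving
  the closed-form Jaccard index m/(2|K|−m) with m = ⌊f·|K|⌋.

Every generator is deterministic under its (spec, seed) arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core_model import (
    Atom,
    ModulatorClass,
    PredictionRecord,
    ResidueRef,
    StructureModel,
)

__all__ = [
    "FixtureSpec",
    "CorpusEntrySpec",
    "make_sequence",
    "make_synthetic_structure",
    "plant_modulator",
    "make_asd_like_xml",
    "write_corpus",
    "make_mock_predictions",
    "perturb_model",
]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
CA_SPACING = 3.8  # Å, extended-chain Cα-Cα distance
CHAIN_SPACING = 40.0  # Å between parallel chains


@dataclass
class FixtureSpec:
    """Parameters of one synthetic structure."""

    seed: int = 0
    n_chains: int = 1
    n_residues: int = 20
    sequence: str | None = None  # default: seeded varied sequence
    gap_ranges: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    chain_ids: Sequence[str] | None = None
    resolution: float | None = 2.0
    n_models: int = 1
    author_offset: int = 0  # author number = position + offset


def make_sequence(n: int, seed: int = 0, window: int = 8) -> str:
    """Deterministic varied amino-acid sequence with all letters distinct
    within any sliding window of ``window + 1`` residues.

    Local non-repetition keeps SEQRES-to-observed alignments unambiguous:
    a deletion of length L can be slid along the sequence only where the
    flanking letters repeat within L+1 positions, so planted gaps up to
    ``window - 1`` residues are recovered at their exact positions.
    Homopolymers (or any repetitive sequence) would leave the gap
    placement degenerate.
    """
    rng = np.random.default_rng(seed)
    letters = sorted(ONE_TO_THREE)
    out: list[str] = []
    while len(out) < n:
        c = letters[rng.integers(len(letters))]
        if c in out[-window:]:
            continue
        out.append(c)
    return "".join(out)


def _residue_atoms(pos: int, chain_index: int, offset: int) -> list[tuple[str, str, float, float, float]]:
    x = CA_SPACING * (pos - 1)
    y = CHAIN_SPACING * chain_index
    return [
        ("N", "N", x - 1.2, y + 0.5, 0.0),
        ("CA", "C", x, y, 0.0),
        ("C", "C", x + 1.2, y + 0.5, 0.0),
        ("O", "O", x + 1.2, y + 1.7, 0.0),
    ]


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str, resnum: int,
                   x: float, y: float, z: float, element: str, hetero: bool) -> str:
    record = "HETATM" if hetero else "ATOM  "
    aname = name if len(name) == 4 else f" {name:<3}"
    return (f"{record}{serial:5d} {aname}{'':1}{resname:>3} {chain:1}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}")


def _seqres_lines_from_names(chain: str, names: list[str]) -> list[str]:
    lines = []
    for i in range(0, len(names), 13):
        chunk = " ".join(f"{n:>3}" for n in names[i:i + 13])
        lines.append(f"SEQRES {i // 13 + 1:3d} {chain:1} {len(names):4d}  {chunk}")
    return lines


def _seqres_lines(chain: str, sequence: str) -> list[str]:
    return _seqres_lines_from_names(chain, [ONE_TO_THREE[c] for c in sequence])


def make_synthetic_structure(spec: FixtureSpec) -> str:
    """Emit PDB text for an extended-backbone synthetic structure.

    Each residue contributes backbone atoms N/CA/C/O; Cα atoms sit 3.8 Å
    apart along x, chains 40 Å apart along y.  SEQRES covers the full
    sequence; residues inside ``gap_ranges`` (1-based, inclusive, per
    chain) are omitted from the coordinates.  Byte-identical output for
    identical specs.
    """
    if spec.n_residues < 1 or spec.n_chains < 1:
        raise ValueError("need at least one residue and one chain")
    chain_ids = list(spec.chain_ids or [chr(ord("A") + i) for i in range(spec.n_chains)])
    if len(chain_ids) != spec.n_chains:
        raise ValueError("chain_ids length must equal n_chains")
    sequence = spec.sequence or make_sequence(spec.n_residues, spec.seed)
    if len(sequence) != spec.n_residues:
        raise ValueError("sequence length must equal n_residues")
    for cid, ranges in spec.gap_ranges.items():
        for start, end in ranges:
            if not (1 <= start <= end <= spec.n_residues):
                raise ValueError(f"gap range ({start},{end}) outside chain {cid}")

    lines: list[str] = ["HEADER    SYNTHETIC FIXTURE"]
    if spec.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {spec.resolution:.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    for cid in chain_ids:
        lines.extend(_seqres_lines(cid, sequence))

    def missing(cid: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in spec.gap_ranges.get(cid, []))

    for model in range(1, spec.n_models + 1):
        if spec.n_models > 1:
            lines.append(f"MODEL     {model:4d}")
        serial = 1
        for ci, cid in enumerate(chain_ids):
            for pos in range(1, spec.n_residues + 1):
                if missing(cid, pos):
                    continue
                resname = ONE_TO_THREE[sequence[pos - 1]]
                for name, element, x, y, z in _residue_atoms(pos, ci, spec.author_offset):
                    z_off = z + (model - 1) * 0.0  # models share coordinates
                    lines.append(_pdb_atom_line(
                        serial, name, resname, cid, pos + spec.author_offset,
                        x, y, z_off, element, hetero=False))
                    serial += 1
            lines.append(f"TER   {serial:5d}      {ONE_TO_THREE[sequence[-1]]:>3} {cid:1}{spec.n_residues + spec.author_offset:4d}")
            serial += 1
        if spec.n_models > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _brute_force_site(structure_text: str, mod_resnum: int, cutoff: float) -> set[tuple[str, int]]:
    """Independent all-pairs distance check used to self-verify planting."""
    protein: list[tuple[str, int, float, float, float]] = []
    ligand: list[tuple[float, float, float]] = []
    for line in structure_text.splitlines():
        if line.startswith("ATOM  "):
            protein.append((line[21], int(line[22:26]),
                            float(line[30:38]), float(line[38:46]), float(line[46:54])))
        elif line.startswith("HETATM") and int(line[22:26]) == mod_resnum:
            ligand.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
    hits = set()
    for chain, num, x, y, z in protein:
        for lx, ly, lz in ligand:
            if math.dist((x, y, z), (lx, ly, lz)) <= cutoff:
                hits.add((chain, num))
                break
    return hits


def plant_modulator(
    structure_text: str,
    pockets: Sequence[Iterable[tuple[str, int]]],
    cutoff: float = 4.0,
    comp_id: str = "LIG",
) -> str:
    """Insert one hetero group per pocket so that *exactly* the pocket
    residues (given as (chain, author number)) have an atom within
    ``cutoff`` Å of the group.

    An empty pocket places the group far from every residue.  Placement is
    self-verified with a brute-force distance check before the text is
    returned; an unsatisfiable request raises.
    """
    ca: dict[tuple[str, int], tuple[float, float, float]] = {}
    max_serial = 0
    for line in structure_text.splitlines():
        if line.startswith(("ATOM  ", "HETATM", "TER")):
            max_serial = max(max_serial, int(line[6:11]))
        if line.startswith("ATOM  ") and line[12:16].strip() == "CA":
            ca[(line[21], int(line[22:26]))] = (
                float(line[30:38]), float(line[38:46]), float(line[46:54]))

    height = cutoff - 0.5
    if height <= 0:
        raise ValueError("cutoff too small to place a modulator")
    het_lines: list[str] = []
    serial = max_serial + 1
    seen_at: dict[tuple[str, int], int] = {}
    for k, pocket in enumerate(pockets):
        pocket = sorted(set(pocket))
        resnum = 901 + k
        chain = pocket[0][0] if pocket else "Z"
        atoms: list[tuple[float, float, float]] = []
        if pocket:
            for key in pocket:
                if key not in ca:
                    raise ValueError(f"pocket residue {key} not present in structure")
                x, y, z = ca[key]
                # alternate the z side for repeated plantings on the same residue
                side = 1 if seen_at.get(key, 0) % 2 == 0 else -1
                seen_at[key] = seen_at.get(key, 0) + 1
                atoms.append((x, y, z + side * height))
        else:
            atoms = [(0.0, -10.0 * (k + 1) - 100.0, 100.0),
                     (1.5, -10.0 * (k + 1) - 100.0, 100.0)]
        if len(atoms) == 1:  # keep the group multi-atom
            x, y, z = atoms[0]
            atoms.append((x, y, z + 1.0 * (1 if z >= 0 else -1)))
        for x, y, z in atoms:
            het_lines.append(_pdb_atom_line(serial, f"C{serial % 10}", comp_id,
                                            chain, resnum, x, y, z, "C", hetero=True))
            serial += 1

    body = structure_text.rstrip("\n").splitlines()
    assert body[-1] == "END"
    out = "\n".join(body[:-1] + het_lines + ["END"]) + "\n"

    for k, pocket in enumerate(pockets):
        want = set(pocket)
        got = _brute_force_site(out, 901 + k, cutoff)
        if got != want:
            raise ValueError(
                f"pocket {sorted(want)} is geometrically unsatisfiable: "
                f"placement yields {sorted(got)}")
    return out


# ---------------------------------------------------------------------------
# Corpus generation: XML entries + structures + annotation/cluster tables
# ---------------------------------------------------------------------------

#: Recognized defect knobs, one per entry, each exercising one curation rule.
DEFECTS = (
    "none", "obsolete_pdb", "pdb_removed", "id_discrepancy", "missing_site",
    "offset_numbering", "low_resolution", "mmcif_only", "gap",
    "ion_modulator", "peptide_modulator", "nucleic",
)


@dataclass
class CorpusEntrySpec:
    entry_id: str
    pdb_id: str
    accession: str
    cluster: str = "UniRef50_C1"
    n_residues: int = 20
    pocket: tuple[int, ...] = (5, 6, 7)  # canonical positions on chain A
    active_positions: tuple[int, ...] = (12, 13)
    defect: str = "none"
    resolution: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.defect not in DEFECTS:
            raise ValueError(f"unknown defect {self.defect!r}")


def make_asd_like_xml(spec: CorpusEntrySpec, pdb_id_in_xml: str | None = None) -> str:
    """One entry XML document in the fixture schema."""
    offset = 24 if spec.defect == "offset_numbering" else 0
    if spec.defect == "missing_site":
        site_el = ""
    else:
        tokens = ";".join(f"A:{p + offset}" for p in spec.pocket)
        site_el = f"  <allosteric_site>{tokens}</allosteric_site>\n"
    mod_class = {"ion_modulator": "ion", "peptide_modulator": "peptide"}.get(
        spec.defect, "small_molecule")
    alias = {"ion_modulator": "MG", "peptide_modulator": "PEP"}.get(spec.defect, "LIG")
    return (
        "<entry>\n"
        f"  <entry_id>{spec.entry_id}</entry_id>\n"
        f"  <pdb_id>{pdb_id_in_xml or spec.pdb_id}</pdb_id>\n"
        "  <uniprot_ids>\n"
        f"    <id>{spec.accession}</id>\n"
        "  </uniprot_ids>\n"
        f"{site_el}"
        "  <modulator>\n"
        f"    <alias>{alias}</alias>\n"
        f"    <class>{mod_class}</class>\n"
        "  </modulator>\n"
        "</entry>\n"
    )


def _entry_structure(spec: CorpusEntrySpec) -> str:
    offset = 24 if spec.defect == "offset_numbering" else 0
    gap_ranges = {"A": [(8, 10)]} if spec.defect == "gap" else {}
    resolution = 4.5 if spec.defect == "low_resolution" else spec.resolution
    fixture = FixtureSpec(
        seed=spec.seed,
        n_chains=1,
        n_residues=spec.n_residues,
        gap_ranges=gap_ranges,
        resolution=resolution,
        author_offset=offset,
    )
    text = make_synthetic_structure(fixture)
    pocket_authors = [("A", p + offset) for p in spec.pocket
                      if not any(s <= p <= e for s, e in gap_ranges.get("A", []))]
    text = plant_modulator(text, [pocket_authors], comp_id="LIG")
    if spec.defect == "ion_modulator":
        # a lone MG ion far from the chain
        body = text.rstrip("\n").splitlines()
        serial = 9000
        mg = _pdb_atom_line(serial, "MG", "MG", "A", 950, 0.0, -50.0, 50.0, "MG", True)
        text = "\n".join(body[:-1] + [mg, "END"]) + "\n"
    if spec.defect == "nucleic":
        body = text.rstrip("\n").splitlines()
        extra = _seqres_lines_from_names("N", ["DA", "DT"])
        serial = 9500
        for i, name in enumerate(("DA", "DT")):
            extra.append(_pdb_atom_line(serial + i, "C1'", name, "N", i + 1,
                                        0.0, -80.0, 3.8 * i, "C", False))
        text = "\n".join(body[:1] + extra + body[1:-1] + ["END"]) + "\n"
    return text


def write_corpus(specs: Sequence[CorpusEntrySpec], out_dir: str | Path) -> dict:
    """Write a cross-consistent fixture corpus.

    Layout: ``xml/<entry>.xml``, ``structures/<pdb>.pdb``,
    ``active_sites.tsv``, ``clusters.tsv``, ``resolver.tsv``,
    ``sequences.fasta``.  Returns a manifest describing the planted ground
    truth (expected drop reasons, pockets in author numbering).
    """
    out = Path(out_dir)
    (out / "xml").mkdir(parents=True, exist_ok=True)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    resolver_lines: list[str] = []
    active_lines: list[str] = []
    cluster_lines: list[str] = []
    fasta_lines: list[str] = []
    manifest: dict = {"entries": {}}
    seen_accessions: set[str] = set()

    for spec in specs:
        defect = spec.defect
        offset = 24 if defect == "offset_numbering" else 0
        xml_pdb_id = spec.pdb_id
        if defect == "obsolete_pdb":
            xml_pdb_id = "9" + spec.pdb_id[1:]
            resolver_lines.append(f"pdb_update\t{xml_pdb_id}\t{spec.pdb_id}")
        (out / "xml" / f"{spec.entry_id}.xml").write_text(
            make_asd_like_xml(spec, pdb_id_in_xml=xml_pdb_id))

        expected_reason = ""
        if defect == "pdb_removed":
            expected_reason = "pdb_removed"  # no chain map, no structure file
        else:
            mapped_accession = ("P99999" if defect == "id_discrepancy"
                                else spec.accession)
            resolver_lines.append(f"chain\t{spec.pdb_id}:A\t{mapped_accession}")
            if defect == "mmcif_only":
                (out / "structures" / f"{spec.pdb_id}.pdb").write_text(
                    f"data_{spec.pdb_id}\n_entry.id {spec.pdb_id}\n")
                expected_reason = "mmcif_only"
            else:
                (out / "structures" / f"{spec.pdb_id}.pdb").write_text(
                    _entry_structure(spec))
                expected_reason = {
                    "id_discrepancy": "id_discrepancy",
                    "missing_site": "incomplete_annotation",
                    "low_resolution": "resolution",
                }.get(defect, "")

        if spec.accession not in seen_accessions:
            seen_accessions.add(spec.accession)
            sequence = make_sequence(spec.n_residues, spec.seed)
            fasta_lines.append(f">{spec.accession}")
            fasta_lines.append(sequence)
            cluster_lines.append(f"{spec.accession}\t{spec.cluster}")
            for pos in spec.active_positions:
                active_lines.append(f"{spec.accession}\t{pos}\tUniProt")
            if spec.active_positions:
                active_lines.append(f"{spec.accession}\t{spec.active_positions[0]}\tMCSA")

        manifest["entries"][spec.entry_id] = {
            "pdb_id": spec.pdb_id,
            "defect": defect,
            "expected_drop_reason": expected_reason,
            "pocket_author": [["A", p + offset] for p in spec.pocket
                              if not (defect == "gap" and 8 <= p <= 10)],
            "active_author": [["A", p + offset] for p in spec.active_positions],
        }

    (out / "resolver.tsv").write_text("\n".join(resolver_lines) + "\n")
    (out / "active_sites.tsv").write_text("\n".join(active_lines) + "\n")
    (out / "clusters.tsv").write_text("\n".join(cluster_lines) + "\n")
    (out / "sequences.fasta").write_text("\n".join(fasta_lines) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Mock predictions and model perturbation
# ---------------------------------------------------------------------------

def make_mock_predictions(
    known_site: frozenset[ResidueRef] | set,
    f: float | Fraction,
    extra_spurious: int = 0,
    seed: int = 0,
    tool: str = "mock",
    protein_id: str = "synthetic",
    decoy_pool: Sequence[ResidueRef] | None = None,
) -> PredictionRecord:
    """A topmost prediction overlapping the known site by fraction ``f``.

    The predicted site has exactly ⌊f·|K|⌋ residues from K plus enough
    decoys to keep |P| = |K|, so the expected Jaccard index is the closed
    form m/(2|K|−m).  Decoys come from ``decoy_pool`` (residues that exist
    in the structure but not in K) or, absent a pool, are fabricated
    beyond the chain.  ``extra_spurious`` appends residues guaranteed not
    to exist (for spurious-residue-removal tests).
    """
    K = sorted(known_site)
    if not K:
        raise ValueError("known site must be non-empty")
    if not 0 <= float(f) <= 1:
        raise ValueError("overlap fraction must lie in [0, 1]")
    m = math.floor(float(f) * len(K))
    rng = np.random.default_rng(seed)
    picked = [K[i] for i in sorted(rng.choice(len(K), size=m, replace=False))]
    n_decoys = len(K) - m
    chain = K[0].chain_id
    if decoy_pool is not None:
        pool = [r for r in decoy_pool if r not in known_site]
        if len(pool) < n_decoys:
            raise ValueError("decoy pool too small")
        idx = sorted(rng.choice(len(pool), size=n_decoys, replace=False))
        decoys = [sorted(pool)[i] for i in idx]
    else:
        base = max(r.number for r in K) + 1000
        decoys = [ResidueRef(chain, base + i, name="ALA") for i in range(n_decoys)]
    spurious = [ResidueRef(chain, 99000 + i, name="ALA") for i in range(extra_spurious)]
    site = frozenset(picked + decoys + spurious)
    return PredictionRecord(tool=tool, protein_id=protein_id,
                            ranked_sites=[(site, None)])


def perturb_model(
    s: StructureModel,
    sigma: float = 0.0,
    rigid: bool = False,
    seed: int = 0,
) -> StructureModel:
    """Deterministically perturbed copy of a structure.

    ``rigid=True`` applies a random rotation + translation (all
    inter-atomic distances preserved exactly); ``sigma`` adds i.i.d.
    Gaussian noise (Å) to every coordinate.  Both may be combined.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray([(a.x, a.y, a.z) for a in s.atoms])
    if rigid and len(coords):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20.0, 20.0, size=3)
        coords = coords @ R.T + t
    if sigma > 0 and len(coords):
        coords = coords + rng.normal(0.0, sigma, size=coords.shape)
    atoms = [
        Atom(residue=a.residue, name=a.name, element=a.element,
             x=float(c[0]), y=float(c[1]), z=float(c[2]), is_hetero=a.is_hetero)
        for a, c in zip(s.atoms, coords)
    ]
    return StructureModel(
        pdb_id=s.pdb_id,
        resolution=s.resolution,
        chains={cid: Chain_copy for cid, Chain_copy in s.chains.items()},
        atoms=atoms,
        chain_to_accession=dict(s.chain_to_accession),
        extra_models=[],
    )
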