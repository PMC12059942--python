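"""Build an unbiased evaluation subset of the curated dataset.

Benchmarking prediction tools on proteins related to their training data
inflates their scores, so the test set drops every entry whose accession
falls in a UniRef50 cluster (>= 50% sequence identity) touched by any
tool's training set.  The remaining filters match what the benchmarked
tools can actually handle: small-molecule modulators only, no structures
over 8000 residues, no nucleic-acid-containing structures, and (via
``structure_ops.strip_heteroatoms``) protein chains only.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

from .core_model import AllostericEntry, ModulatorClass, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterTable",
    "NUCLEOTIDE_RESIDUES",
    "exclude_training_clusters",
    "filter_modulator_type",
    "filter_size",
    "filter_nucleic",
    "assemble_testset",
]

NUCLEOTIDE_RESIDUES = frozenset({"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DI"})


@dataclass
class ClusterTable:
    """accession -> UniRef50 cluster ID; unknown accessions are explicit."""

    clusters: dict[str, str] = field(default_factory=dict)

    def get(self, accession: str) -> str | None:
        return self.clusters.get(accession)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClusterTable":
        table = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            accession, cluster = line.rstrip("\n").split("\t")
            table.clusters[accession] = cluster
        return table


def _split(entries, keep_fn, reason):
    kept, dropped = [], []
    for entry in entries:
        if entry.status == "dropped":
            dropped.append(entry)
        elif keep_fn(entry):
            kept.append(entry)
        else:
            entry.drop(reason)
            dropped.append(entry)
    return kept, dropped


def exclude_training_clusters(
    entries: list[AllostericEntry],
    clusters: ClusterTable,
    training_accessions: set[str],
) -> tuple[list[AllostericEntry], list[AllostericEntry]]:
    """Drop entries related to any tool's training proteins.

    The excluded set is the UniRef50 clusters of the training accessions;
    an entry is dropped (reason ``training_overlap``) if ANY of its
    accessions maps into that set.  Accessions with unknown cluster are
    dropped conservatively and logged.
    """
    excluded = {clusters.get(a) for a in training_accessions} - {None}

    def keep(entry: AllostericEntry) -> bool:
        for accession in entry.accessions:
            cluster = clusters.get(accession)
            if cluster is None:
                logger.warning("entry %s: accession %s has no known cluster; "
                               "dropping conservatively", entry.entry_id, accession)
                return False
            if cluster in excluded:
                return False
        return True

    return _split(entries, keep, "training_overlap")


def filter_modulator_type(
    entries: list[AllostericEntry],
) -> tuple[list[AllostericEntry], list[AllostericEntry]]:
    """Keep only entries whose every allosteric site has a small-molecule
    modulator (reason ``modulator_class``) — the benchmarked tools were
    designed for small-molecule pockets."""
    return _split(
        entries,
        lambda e: all(s.modulator_class is ModulatorClass.SMALL_MOLECULE
                      for s in e.allosteric_sites),
        "modulator_class",
    )


def filter_size(
    entries: list[AllostericEntry],
    structures: dict[str, StructureModel],
    max_residues: int = 8000,
) -> tuple[list[AllostericEntry], list[AllostericEntry]]:
    """Drop enormous structures with more than ``max_residues`` observed
    protein residues (reason ``size``)."""

    def keep(entry: AllostericEntry) -> bool:
        s = structures.get(entry.pdb_id)
        return s is None or s.n_protein_residues() <= max_residues

    return _split(entries, keep, "size")


def filter_nucleic(
    entries: list[AllostericEntry],
    structures: dict[str, StructureModel],
) -> tuple[list[AllostericEntry], list[AllostericEntry]]:
    """Drop structures containing nucleic-acid polymer residues (reason
    ``nucleic``).  The rule is scoped to polymer chains: a single modified
    nucleotide bound as a hetero ligand does not trigger it."""

    def keep(entry: AllostericEntry) -> bool:
        s = structures.get(entry.pdb_id)
        if s is None:
            return True
        for chain in s.chains.values():
            if any(r.name.upper() in NUCLEOTIDE_RESIDUES for r in chain.residues):
                return False
        return True

    return _split(entries, keep, "nucleic")


def assemble_testset(
    entries: list[AllostericEntry],
    clusters: ClusterTable,
    n: int = 100,
    seed: int = 0,
    take_all: bool = False,
) -> list[AllostericEntry]:
    """Select the final test set from the filter survivors.

    If ``take_all`` or there are at most ``n`` survivors, all are returned.
    Otherwise a seeded uniform sample without replacement is drawn, keeping
    at most one structure per UniRef50 cluster (greedy in the shuffled
    order) — deterministic for a fixed seed.
    """
    if n <= 0:
        raise ValueError("test-set size must be positive")
    survivors = [e for e in entries if e.status == "kept"]
    if take_all or len(survivors) <= n:
        return survivors
    rng = random.Random(seed)
    order = sorted(survivors, key=lambda e: e.entry_id)
    rng.shuffle(order)
    chosen: list[AllostericEntry] = []
    used_clusters: set[str] = set()
    for entry in order:
        entry_clusters = {clusters.get(a) for a in entry.accessions} - {None}
        if entry_clusters & used_clusters:
            continue
        chosen.append(entry)
        used_clusters |= entry_clusters
        if len(chosen) == n:
            break
    return sorted(chosen, key=lambda e: e.entry_id)
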