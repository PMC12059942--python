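"""Synchronize canonical (UniProt-style) numbering with author numbering.

Active-site annotations come as 1-based positions in a protein's canonical
sequence, while structures use author residue numbers that frequently start
at an offset, skip gaps, or carry insertion codes.  The bridge is a global
pairwise alignment of the canonical sequence against the sequence observed
in the coordinates, from which a position -> ResidueRef mapping is read off.

Scoring: match +1, mismatch -1, gap open -5, gap extend -1 (first gapped
column costs -5, each further column -1).  An identity scheme rather than a
substitution matrix is appropriate because the two sequences are near-
identical variants of the same protein.  Traceback ties are broken
deterministically: match/mismatch first, then a gap in ``b``, then a gap
in ``a``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1_extended as _3TO1_EXTENDED

from .core_model import ResidueRef

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentParams",
    "ResidueMapping",
    "UnalignableError",
    "align_sequences",
    "alignment_identity",
    "map_residue_numbers",
    "remap_site",
    "three_to_one",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0   # score of the first column of a gap
    gap_extend: float = -1.0  # score of each subsequent column


@dataclass
class ResidueMapping:
    """Canonical position (1-based) -> residue in author numbering."""

    chain_id: str
    pairs: dict[int, ResidueRef] = field(default_factory=dict)
    coverage: float = 0.0
    identity: float = 0.0
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)


class UnalignableError(ValueError):
    """Alignment identity below the configured floor."""


def three_to_one(name: str) -> str:
    """3-letter -> 1-letter residue code; nonstandard residues translate via
    the PDB chemical-component table, unknown codes become 'X'."""
    code = _3TO1_EXTENDED.get(name.upper(), "X")
    return code if len(code) == 1 and code.isalpha() and code.isupper() else "X"


def align_sequences(a: str, b: str, params: AlignmentParams | None = None) -> tuple[str, str, float]:
    """Global (Needleman-Wunsch/Gotoh) alignment of two sequences.

    Returns ``(gapped_a, gapped_b, score)``.  Affine gap costs per
    :class:`AlignmentParams`; deterministic traceback (prefer the
    match/mismatch move, then a gap in ``b``, then a gap in ``a``).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    p = params or AlignmentParams()
    n, m = len(a), len(b)
    neg = -np.inf
    # M: a[i] aligned to b[j]; X: gap in b (consumes a); Y: gap in a (consumes b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = p.gap_open + (i - 1) * p.gap_extend
    for j in range(1, m + 1):
        Y[0, j] = p.gap_open + (j - 1) * p.gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = p.match if ai == b[j - 1] else p.mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + p.gap_open, X[i - 1, j] + p.gap_extend,
                          Y[i - 1, j] + p.gap_open)
            Y[i, j] = max(M[i, j - 1] + p.gap_open, Y[i, j - 1] + p.gap_extend,
                          X[i, j - 1] + p.gap_open)

    # traceback with the documented tie-break: M > X (gap in b) > Y (gap in a)
    i, j = n, m
    final = max(M[n, m], X[n, m], Y[n, m])
    if M[n, m] >= X[n, m] and M[n, m] >= Y[n, m]:
        state = "M"
    elif X[n, m] >= Y[n, m]:
        state = "X"
    else:
        state = "Y"
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:  # boundary: only gap states reach the edges
                state = "X" if j == 0 else "Y"
                continue
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            if M[i, j] == target:
                state = "M"
            elif X[i, j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + p.gap_open == here:
                state = "M"
            elif X[i, j] + p.gap_extend == here:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            out_a.append("-")
            out_b.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + p.gap_open == here:
                state = "M"
            elif Y[i, j] + p.gap_extend == here:
                state = "Y"
            else:
                state = "X"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(final)


def alignment_identity(gapped_a: str, gapped_b: str) -> float:
    """Fraction of alignment columns that are identical matches."""
    assert len(gapped_a) == len(gapped_b)
    matches = sum(1 for x, y in zip(gapped_a, gapped_b) if x == y and x != "-")
    return matches / len(gapped_a)


def map_residue_numbers(
    canonical_seq: str,
    observed: list[ResidueRef],
    min_identity: float = 0.30,
    params: AlignmentParams | None = None,
) -> ResidueMapping:
    """Align the canonical sequence to a chain's observed residues and map
    canonical positions onto author-numbered residues.

    Substitution columns (aligned but different letters) are mapped and
    logged; a global identity below ``min_identity`` raises
    :class:`UnalignableError` so the caller can drop the entry with a reason.
    """
    if not observed:
        raise ValueError("no observed residues to map onto")
    chain_id = observed[0].chain_id
    obs_seq = "".join(three_to_one(r.name) if r.name else "X" for r in observed)
    ga, gb, _ = align_sequences(canonical_seq, obs_seq, params)
    identity = alignment_identity(ga, gb)
    if identity < min_identity:
        raise UnalignableError(
            f"alignment identity {identity:.2f} below floor {min_identity:.2f} "
            f"for chain {chain_id}"
        )
    mapping = ResidueMapping(chain_id=chain_id, identity=identity)
    ci = 0  # canonical position (1-based after increment)
    oi = 0  # index into observed
    for x, y in zip(ga, gb):
        if x != "-":
            ci += 1
        if y != "-":
            oi += 1
        if x != "-" and y != "-":
            mapping.pairs[ci] = observed[oi - 1]
            if x != y:
                mapping.substitutions.append((ci, x, y))
                logger.debug("substitution at canonical %d: %s -> %s", ci, x, y)
    mapping.coverage = len(mapping.pairs) / len(canonical_seq)
    return mapping


def remap_site(
    positions: set[int], mapping: ResidueMapping
) -> tuple[frozenset[ResidueRef], frozenset[int]]:
    """Convert canonical positions to author-numbered residues.

    Positions without a mapped residue (e.g. inside a structural gap) are
    returned in the second element, never silently discarded.
    """
    mapped = frozenset(mapping.pairs[p] for p in positions if p in mapping.pairs)
    unmapped = frozenset(p for p in positions if p not in mapping.pairs)
    return mapped, unmapped
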