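"""lDDT quality gate for gap-filled structure models.

Structures with missing residues are rebuilt by an external modeling
engine; before a rebuilt model replaces the deposited structure in the
dataset it must score lDDT (Local Distance Difference Test) >= 0.8 against
the original.

lDDT is superposition-free: it considers every heavy-atom pair in
*different* residues of the reference that lies within an inclusion radius
(default 15 Å), and asks what fraction of those distances is preserved in
the model to within each of the thresholds 0.5, 1, 2 and 4 Å (strictly
less than the threshold).  The per-residue score is the mean preserved
fraction over the four thresholds for the pairs involving that residue;
the global score is the mean over residues that have at least one
reference distance.  Atoms present in the reference but absent from the
model count as non-preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_model import AllostericEntry, ResidueRef, StructureModel

__all__ = ["LddtResult", "compute_lddt", "qc_filter"]


@dataclass
class LddtResult:
    global_score: float
    per_residue: dict[ResidueRef, float] = field(default_factory=dict)
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    inclusion_radius: float = 15.0


def _atom_table(s: StructureModel):
    keys, residues, coords = [], [], []
    for a in s.atoms:
        if a.is_hetero or not a.is_heavy:
            continue
        keys.append((a.residue.chain_id, a.residue.number,
                     a.residue.insertion_code, a.name))
        residues.append(a.residue)
        coords.append((a.x, a.y, a.z))
    return keys, residues, np.asarray(coords, dtype=float)


def compute_lddt(
    reference: StructureModel,
    model: StructureModel,
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    inclusion_radius: float = 15.0,
) -> LddtResult:
    """Score ``model`` against ``reference`` (both in author numbering).

    Atoms correspond by (chain, residue number, insertion code, atom name).
    Only inter-residue heavy-atom distances are counted.  Raises if the two
    structures share no residues.
    """
    ref_keys, ref_res, ref_xyz = _atom_table(reference)
    if len(ref_keys) == 0:
        raise ValueError("no_correspondence: reference has no protein atoms")
    mod_keys, _, mod_xyz = _atom_table(model)
    mod_index = {k: i for i, k in enumerate(mod_keys)}
    if not any(k in mod_index for k in ref_keys):
        raise ValueError("no_correspondence: no atoms shared with the model")

    n = len(ref_keys)
    ref_d = squareform(pdist(ref_xyz))
    uniq: dict[ResidueRef, int] = {}
    res_ids = np.asarray([uniq.setdefault(r, len(uniq)) for r in ref_res])
    within = (ref_d < inclusion_radius) & (res_ids[:, None] != res_ids[None, :])
    iu = np.triu_indices(n, k=1)
    pair_mask = within[iu]
    ii, jj = iu[0][pair_mask], iu[1][pair_mask]

    # model distances; pairs with a missing atom are never preserved
    mod_pos = np.asarray([mod_index.get(k, -1) for k in ref_keys])
    have = (mod_pos[ii] >= 0) & (mod_pos[jj] >= 0)
    delta = np.full(ii.shape, np.inf)
    if have.any():
        d_model = np.linalg.norm(
            mod_xyz[mod_pos[ii[have]]] - mod_xyz[mod_pos[jj[have]]], axis=1)
        delta[have] = np.abs(d_model - ref_d[ii[have], jj[have]])

    # per-pair preserved fraction over thresholds, then accumulate per residue
    thr = np.asarray(thresholds)
    preserved = (delta[:, None] < thr[None, :]).mean(axis=1)
    per_res_sum: dict[ResidueRef, float] = {}
    per_res_n: dict[ResidueRef, int] = {}
    for a, b, frac in zip(ii, jj, preserved):
        for r in (ref_res[a], ref_res[b]):
            per_res_sum[r] = per_res_sum.get(r, 0.0) + float(frac)
            per_res_n[r] = per_res_n.get(r, 0) + 1
    per_residue = {r: per_res_sum[r] / per_res_n[r] for r in per_res_sum}
    if not per_residue:
        raise ValueError("no_correspondence: no reference distances within radius")
    global_score = float(np.mean(list(per_residue.values())))
    return LddtResult(global_score=global_score, per_residue=per_residue,
                      thresholds=tuple(thresholds), inclusion_radius=inclusion_radius)


def qc_filter(
    entries: list[AllostericEntry], min_lddt: float = 0.8
) -> tuple[list[AllostericEntry], list[AllostericEntry]]:
    """Gate modeled entries at lDDT >= ``min_lddt``; drop reason "low_lddt".

    Entries that were never modeled (no lddt value, no "modeled" flag) pass
    through untouched; a modeled entry without a score is an error.
    """
    kept, dropped = [], []
    for entry in entries:
        modeled = "modeled" in entry.flags
        if modeled and entry.lddt is None:
            raise ValueError(f"entry {entry.entry_id} was modeled but has no lDDT score")
        if entry.lddt is not None and entry.lddt < min_lddt:
            entry.drop("low_lddt")
            dropped.append(entry)
        else:
            kept.append(entry)
    return kept, dropped
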