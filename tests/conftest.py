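import numpy as np
import pytest

from allobench.core_model import Atom, Chain, ResidueRef, StructureModel


def build_structure(
    protein_atoms, ligand_atoms=(), pdb_id="1XYZ", seqres="", resolution=2.0
) -> StructureModel:
    """Assemble a StructureModel directly from (chain, resnum, name, xyz) tuples.

    ``protein_atoms``: iterable of (chain_id, resnum, atom_name, (x, y, z));
    ``ligand_atoms``: same but flagged hetero with residue name LIG.
    """
    chains: dict[str, Chain] = {}
    atoms: list[Atom] = []
    for chain_id, resnum, atom_name, (x, y, z) in protein_atoms:
        ref = ResidueRef(chain_id, resnum, name="ALA")
        chain = chains.setdefault(chain_id, Chain(chain_id, seqres, []))
        if ref not in chain.residues:
            chain.residues.append(ref)
        element = atom_name[0]
        atoms.append(Atom(ref, atom_name, element, x, y, z, is_hetero=False))
    for chain_id, resnum, atom_name, (x, y, z) in ligand_atoms:
        ref = ResidueRef(chain_id, resnum, name="LIG")
        chains.setdefault(chain_id, Chain(chain_id, "", []))
        atoms.append(Atom(ref, atom_name, atom_name[0], x, y, z, is_hetero=True))
    return StructureModel(pdb_id=pdb_id, resolution=resolution,
                          chains=chains, atoms=atoms)


def random_structure(rng: np.random.Generator, n_residues=10, atoms_per_res=3,
                     box=20.0) -> StructureModel:
    """Random atom cloud grouped into residues (for oracle comparisons)."""
    protein = []
    for i in range(1, n_residues + 1):
        for j in range(atoms_per_res):
            xyz = tuple(rng.uniform(0, box, size=3))
            name = "CA" if j == 0 else f"C{j}"
            protein.append(("A", i, name, xyz))
    return build_structure(protein)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
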