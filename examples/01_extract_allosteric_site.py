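"""Derive an allosteric site geometrically from a bound modulator.

Builds a synthetic 30-residue chain, plants a ligand against residues
6-9, then locates the modulator by its chemical-component alias and
extracts every residue with a heavy atom within 4 Å — the operational
definition of the allosteric site.
"""

from allobench.site_extraction import extract_site, resolve_modulator
from allobench.structure_ops import parse_structure
from allobench.synthetic_fixtures import (
    FixtureSpec,
    make_synthetic_structure,
    plant_modulator,
)

pdb_text = make_synthetic_structure(FixtureSpec(seed=11, n_residues=30))
pdb_text = plant_modulator(pdb_text, [[("A", 6), ("A", 7), ("A", 8), ("A", 9)]])

structure = parse_structure(pdb_text, pdb_id="1SYN")
(modulator,) = resolve_modulator("LIG", structure)
site = extract_site(structure, modulator, cutoff=4.0)

print(f"modulator: {modulator.chem_comp_id} with {len(modulator.atoms)} atoms")
print("derived allosteric site:",
      sorted(f"{r.chain_id}:{r.number}" for r in site))
# The site is exactly the planted pocket: every residue with a heavy atom
# within 4 Å of the ligand, and nothing else.
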