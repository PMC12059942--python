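"""Score a rebuilt structure model with lDDT.

lDDT is superposition-free: a rigidly moved copy still scores 1.0, while
coordinate noise degrades the score.  The pipeline drops rebuilt models
scoring below 0.8.
"""

from allobench.model_qc import compute_lddt
from allobench.structure_ops import parse_structure
from allobench.synthetic_fixtures import (
    FixtureSpec,
    make_synthetic_structure,
    perturb_model,
)

reference = parse_structure(make_synthetic_structure(
    FixtureSpec(seed=5, n_residues=15)))

rigid = perturb_model(reference, rigid=True, seed=1)
noisy = perturb_model(reference, sigma=1.0, seed=1)
bad = perturb_model(reference, sigma=4.0, seed=1)

for label, model in [("rigid motion", rigid), ("sigma=1.0 A", noisy),
                     ("sigma=4.0 A", bad)]:
    score = compute_lddt(reference, model).global_score
    verdict = "pass" if score >= 0.8 else "FAIL (< 0.8 gate)"
    print(f"{label:14s} lDDT = {score:.3f}  {verdict}")
# Rigid motions preserve all inter-residue distances (score 1.0); noise at
# the Angstrom level erodes the preserved fraction until the QC gate trips.
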