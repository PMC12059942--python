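# Methods

This note documents the models, conventions and numerical choices behind
`allobench`, and what the synthetic test conditions do and do not show
about real data.

## Residue identity

A residue is identified by *(chain ID, author number, insertion code)*.
The residue name is carried for diagnostics but never participates in
equality: prediction tools report residue numbers, not names, and name
mismatches between annotation sources are common and benign. Name
disagreements are logged, never fatal.

Residue sets serialize as semicolon-joined `chain:number[icode]` tokens
in lexicographic order, so dataset CSVs diff deterministically.

## Geometric site definition

The allosteric site of a structure is defined operationally as **every
protein residue with at least one heavy atom at Euclidean distance
≤ 4.0 Å from any heavy atom of the bound modulator**. Choices within
that definition:

- *Inclusive cutoff, heavy atoms only.* Hydrogens are rarely present in
  crystal structures; including them would make the site definition
  depend on deposition practice rather than chemistry. ≤ vs < matters
  only on a measure-zero set; ≤ is the standard contact convention.
- The modulator is located by its chemical-component alias,
  case-insensitively, over hetero residues. Waters and a documented
  blocklist of buffer/cryo components (GOL, EDO, SO4, ...) are never
  accepted as modulators even if an annotation aliases them.
- Each bound copy of the modulator yields its own site annotation;
  duplicate sites across protomers are all retained, which is why a
  dataset can contain more sites than structures.
- When the listed annotation and the derived site disagree, the derived
  site is authoritative for the output dataset; the agreement Jaccard
  index and an `agree`/`discrepant` verdict (threshold 0.5) are recorded
  for audit.

The k-d-tree implementation is required by tests to agree exactly with a
brute-force all-pairs distance computation, and is monotone in the
cutoff by construction.

## Numbering synchronization

Active sites are annotated as 1-based positions on the canonical
sequence; structures use author numbering. The bridge is a global
Needleman–Wunsch/Gotoh alignment of the canonical sequence against the
observed chain sequence with **match +1, mismatch −1, gap open −5, gap
extend −1** (first gapped column −5, each further column −1). Identity
scoring rather than a substitution matrix is appropriate because the two
sequences are near-identical variants of the same protein, not homologs.
Traceback ties break deterministically: match/mismatch first, then a gap
in the observed sequence, then a gap in the canonical one. Alignments
with identity below a configurable floor (default 0.30) mark the entry
`unalignable` and drop it with that reason. Substitution columns are
mapped but logged. Nonstandard residues translate through the PDB
chemical-component 3→1 table (MSE→M, ...); unknown codes become `X`,
which matches nothing.

For homomers the mapping is computed per matching chain and the active
site instantiated on every chain that carries the accession — multimeric
proteins have the same sites on all identical chains.

## Missing residues and the lDDT gate

Gaps are detected by aligning each chain's SEQRES sequence to its
observed residues; unobserved SEQRES ranges form the gap report, and the
target–template alignment (target = full SEQRES, template = SEQRES with
`-` over missing ranges) is emitted as JSON for an external modeling
engine. Gap *filling* itself is a pluggable shell command; without one,
gapped entries pass through flagged `unmodeled`. Note an intrinsic limit
of alignment-based gap detection: two deletions separated by one or two
observed residues can merge into a single gap with equal or better
alignment score (the gap-open/extend difference of 4 vs 2 points per
converted match), so such configurations are not uniquely recoverable.

Rebuilt models are scored with **lDDT** (Local Distance Difference
Test), superposition-free: all heavy-atom pairs in *different* residues
of the reference within a 15 Å inclusion radius are collected, and a
pair is preserved at threshold t ∈ {0.5, 1, 2, 4} Å if the model
reproduces the reference distance to within strictly less than t. The
per-residue score is the mean preserved fraction over the four
thresholds for pairs involving that residue; the global score is the
mean over residues with at least one reference distance. Atoms missing
from the model count as non-preserved. Stereochemistry checks of the
full published lDDT protocol are omitted: the gate is applied to
template-copied coordinates, where covalent geometry is inherited from
the deposited structure. Models score against the *whole* original
structure, not only the rebuilt regions. The gate keeps models with
lDDT ≥ 0.8.

## Curation filters

- **Identifier reconciliation** is a snapshot-backed interface
  (`IdResolver`); the shipped backend is a static table
  (old→new PDB IDs, chain→accession maps, accession updates) so runs are
  deterministic and offline. A live backend can implement the same
  three-method protocol.
- **Resolution**: kept iff resolution < 4.0 Å, strictly — "better than"
  excludes a structure measured at exactly 4.0 Å. Structures without a
  resolution record (NMR ensembles) are kept and flagged
  `no_resolution`: the criterion excludes structures measured to be
  worse, not structures without the measurement. Users can exclude the
  flag downstream.
- **Active-site merging** is a set union of the two sources with
  per-position provenance. Union, not intersection: the catalytic-atlas
  source covers few proteins, and intersecting would discard most
  annotations.
- **Test-set filters**: drop entries whose accessions fall in UniRef50
  clusters (≥ 50% identity) of any training accession (any-match over an
  entry's accessions; unknown clusters drop conservatively); keep only
  small-molecule modulators; drop structures with more than 8000
  observed protein residues (8000 itself is kept); drop structures with
  nucleic-acid *polymer* residues ({A,C,G,U,I,DA,DC,DG,DT,DI}) — a lone
  modified nucleotide bound as a hetero ligand does not trigger the
  rule. Heteroatoms are stripped before the set is emitted. Final
  selection is a seeded uniform sample without replacement, at most one
  structure per cluster, greedy in shuffled order; `take_all` disables
  sampling. Filter order does not affect the surviving set (each filter
  is a pointwise predicate); the canonical order above only decides
  which reason a doubly-defective entry records.

All thresholds live in one `PipelineConfig` object (distance cutoff
4.0 Å, resolution 4.0 Å, lDDT 0.8 with thresholds 0.5/1/2/4 Å and 15 Å
radius, 8000 residues, alignment-identity floor 0.30), serializable as a
key=value file.

## Benchmark conventions

- Only the **topmost-ranked** site per tool and protein is scored, so
  tools returning different numbers of predictions are compared
  uniformly; `best_of_k` scores all ranked sites and keeps the best, for
  tools that do not rank their output. Reported probabilities/scores are
  carried but never re-rank predictions.
- Multimeric proteins: the topmost prediction is compared against every
  known site copy and the highest Jaccard index is used (ties to the
  lowest site index).
- Spurious residues — identifiers absent from the structure given to the
  predictor — are removed before scoring while valid residues are kept;
  fully spurious or empty predictions score 0 and remain in medians and
  means, so central tendencies reflect tool reliability too. The JI
  distributions are strongly right-skewed, so the median is the primary
  summary; the mean is reported alongside.
- The accuracy curve reports, per tool and cutoff c, the percentage of
  proteins with topmost JI strictly greater than c; it is non-increasing
  in c by construction.
- As a 3D-proximity cross-check, the distance between the unweighted Cα
  centroids of the predicted and matched known site is reported with its
  inverse; coincident centroids store the inverse as absent. On
  ensembles where a predicted site slides away from the known site, JI
  and inverse distance correlate positively in rank.

## Synthetic test conditions

The fixture generator emulates the pipeline's input universe at desk
scale and is itself first-class, tested code:

- **Structures** are extended chains (Cα spacing 3.8 Å along x, chains
  40 Å apart, backbone N/CA/C/O per residue), not plausible folds:
  geometry must be exactly controllable. Sequences are deterministic
  varied strings with all letters distinct inside any 9-residue window,
  so SEQRES↔observed alignments are unambiguous and planted gaps are
  recovered at their exact positions (a design requirement the
  alignment-ambiguity limit above makes necessary).
- **Planted modulators** place one atom 3.5 Å above the Cα of each
  pocket residue (empty pockets place the group far away); at the chain
  geometry above this puts every non-pocket atom beyond 4 Å. Every
  planting is self-verified against an independent brute-force distance
  check before the fixture is emitted.
- **Corpora** carry one defect per entry (obsolete ID, removed
  structure, accession mismatch, missing annotation, +24 numbering
  offset, sub-threshold resolution, mmCIF-only file, coordinate gaps,
  ion/peptide modulators, nucleic chains) with the expected drop reason
  recorded in a manifest, so every curation rule is independently
  testable and end-to-end drop tallies have exact expectations.
- **Mock predictions** contain exactly ⌊f·|K|⌋ residues of the known
  site K plus decoys to size |K|, giving the closed-form JI m/(2|K|−m).

Consequently, passing tests demonstrate the *correctness of the
machinery* — parsing, bookkeeping, geometry, scoring — under exactly
known ground truth. They do not demonstrate curation quality on real
databases: real annotation errors, sequence polymorphism, crystal
packing, alternate conformations beyond altloc selection, and genuinely
ambiguous modulator chemistry are outside what the generator emulates.
Dataset-scale figures from real snapshots (thousands of sites and
structures) depend on live database state and are not computed here.

## Numerical and degenerate-input choices

- Altloc handling: the highest-occupancy conformer per atom name wins;
  ties break toward the lowest altloc ID.
- Nonstandard amino acids present in SEQRES (e.g. MSE) are protein, not
  heteroatoms — stripping them would create artificial gaps.
- Chain relabeling when merging multi-MODEL files: models in file order,
  chains alphabetically, first unused label from A–Z, a–z, 0–9, then
  two-letter codes; exhausting the label space is an error. Atom count
  and coordinates are preserved exactly.
- Jaccard index: an empty known site is an error (`empty_known_site`);
  an empty prediction scores 0.
- Coincident site centroids: distance 0, inverse stored as absent.
- Every filter partitions its input into kept ∪ dropped with a reason on
  each drop; stage counts telescope and reruns are byte-identical.

## Problem sizes

Tests and the acceptance script run on chains of 5–80 residues, corpora
of ~10 entries, 200 randomized site-extraction trials, 1000+ random set
pairs for the Jaccard oracle, and 20-seed rigid-motion checks for lDDT —
sizes at which every oracle comparison is exact and the full suite
completes in well under a minute of compute per module.
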