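# Methods

This note documents the models, rules and numerical choices behind
`complexeval`, and what the synthetic fixtures do and do not establish.

## Scope and data model

The unit of evaluation is a structure of chains → residues → atoms. Every
non-polymer component is carried as its own single-residue chain of kind
`ligand`; waters are dropped on read and oligosaccharide components are
dropped with a warning. Models are required to be numbered on the target
sequence (1-based); insertion codes are rejected in models and accepted in
references, which can be renumbered against the entity sequence by global
alignment (`renumber_chain_to_sequence`). Alternate conformers keep the
highest-occupancy altloc. PDB files lacking element columns get elements
inferred from atom names (digit-prefix stripping; two-letter elements only
for hetero atoms, so `CA` stays carbon in polymers and calcium as a ligand).

Reference eligibility: NMR and X-ray entries qualify; EM only at resolution
≤ 4.0 Å; entries with > 200 polymer chains or > 100 copies of one entity
are excluded as computationally unreasonable. The rule is monotone —
worsening resolution or growing the complex never regains eligibility.

Canonical sequences derive from non-canonical component lists through a
parent map. A small table of common modified residues (MSE→MET, SEP→SER,
PSU→U, …) ships with the package; a full component-dictionary table can be
supplied as any mapping. Entities are invalid when a component has no
parent, is marked unknown or non-linking, or when parents mix amino and
nucleic classes — such targets are excluded from classification upstream.

## Difficulty classification

Sequence clustering is greedy and incremental, longest sequence first, with
identity computed as matches over the shorter sequence length (the
convention of incremental clustering tools); proteins cluster at 99%,
peptides and nucleic acids at 100%. Cluster representatives are the
alphabetically first members. Complexes sharing the same *set* of sequence
clusters cluster together — set, not multiset, so stoichiometry variants of
the same components share a cluster; this is the literal reading of the
rule and is deliberate.

Per-template sequence labels follow the stated thresholds exactly
(≥ 85% identity, ≥ 70% coverage, < 45 uncovered residues applying only to
targets strictly longer than 250 residues; medium needs identity < 85% and
e-value ≤ 1e-4 with the same coverage). Complex labels quantify over single
templates: easy requires one template easy for every entity; entities
without a hit against a template are implicitly hard for it. The ligand
flag compares exact ligand component-ID sets between the target and its
easy templates, ignoring a configurable exclusion list (default: water).

The internal aligner (Biopython `PairwiseAligner`, local, BLOSUM62 with
gap open −11 / extend −1 for proteins) produces identity over aligned
columns and coverage over the target length but no e-value: the medium rule
is therefore only reachable through external hit tables (12-column
BLAST-tabular dialect). Multiple local alignments of one query–template
pair are merged by interval union on the query; merged identity is the
alignment-length-weighted mean and the e-value the minimum. Union is the
permissive reading; an implementation that required a single alignment to
satisfy coverage alone would label some multi-domain hits harder.

## Chain mapping

Model chains may only pair with reference chains of the same entity
(explicit entity labels when present, else ≥ 95% component agreement at
shared target-sequence positions). Among entity-compatible assignments the
mapping maximizes the complex backbone LDDT — backbone-only for speed; all
reported scores are recomputed all-atom afterwards. Up to 6 interchangeable
copies per entity the search is exhaustive over joint assignments; beyond
that, greedy seeding plus pairwise-swap hill climbing. Ties are broken by
lexicographic pair order, which makes outputs deterministic; note that for
an exactly symmetric homo-oligomer *every* assignment yields the same LDDT
(the score is distance-based), so the tie-break, not geometry, decides.

Ligands pair only with chemically identical reference ligands — same
component ID, or element-and-bond graph isomorphism when IDs are absent —
under the assignment maximizing summed LDDT-PLI (Hungarian algorithm;
undefined pose scores enter as 0). Reference ligands without a partner stay
unmapped and count as failures downstream.

## Scores

**LDDT.** Reference distance set: all polymer heavy-atom pairs within
15 Å, excluding same-residue pairs. Per distance, the score is the fraction
of thresholds {0.5, 1, 2, 4} Å the model error stays within; distances with
either atom absent from the model count zero at every threshold — this is
the stoichiometry penalty. The reported score is the unweighted mean over
distances; a per-residue profile averages over the distances touching each
residue. An empty distance set gives an undefined (None) score.

**Stereochemistry filter** (on by default): model atoms in backbone bonds
deviating more than 12 standard deviations from ideal lengths, or in
non-bonded inter-residue contacts closer than 1.5 Å, are removed before
scoring and hence score zero. This is a simplified screen; full
dictionary-based geometry checking is out of scope, and the C-alpha-trace
fixtures never trigger the bond branch.

**iLDDT** restricts the distance set to pairs spanning different polymer
chains and is undefined (never zero) when no inter-chain contact exists —
monomers have no interface to get wrong. **Mapped** variants rebuild the
reference from the mapped chains only and rescore, removing the
missing-chain penalty; mapped iLDDT is undefined for monomeric predictions
of oligomers. Because removed distances all scored zero, mapped ≥ unmapped
holds identically.

**TM-score.** Backbone representative is CA (C4′/P fallback for nucleic
acids). Normalization is by the total reference backbone length L with
d₀ = max(0.5, 1.24·(L−15)^⅓ − 1.8); the single global superposition is
searched by Kabsch fits seeded on the full alignment and on sliding
fragments (L, L/2, L/4, 4), each refined by iteratively re-fitting on
residues within max(d₀, 4.5) Å until the inlier set stabilizes. This is the
standard heuristic; it is exact on the fixtures used in tests (identity or
single-cluster optima) but, like all TM-score implementations, not a
certified global optimum.

**LDDT-PLI.** Distance set: reference polymer-atom ↔ ligand-atom pairs
within 4.0 Å (configurable; deliberately tighter than the 15 Å polymer
radius — it is a contact definition, not a neighborhood). Threshold logic
as LDDT; the ligand atom correspondence is chosen over graph automorphisms
to maximize the score. Undefined when the reference ligand touches no
polymer atom.

**BiSyRMSD.** The binding site is every reference polymer residue with an
atom within 4.0 Å of the ligand. The model is superposed onto the reference
on the site backbone atoms (≥ 3 required, else undefined), and the ligand
heavy-atom RMSD is minimized over graph automorphisms. Automorphisms are
enumerated by element- and degree-pruned backtracking, capped at 10,000
with a truncation flag; bond orders are ignored (aromatic/Kekulé ambiguity
across SMILES dialects would otherwise split identical ligands). Model
ligand correspondence falls back to atom-name matching when geometric bond
perception on a distorted pose breaks isomorphism.

## Aggregation

Models are scored against every biological assembly. Polymer scores are
reported against the assembly with the highest LDDT; ligand scores against
the assembly scoring the most ligands, ties broken by higher ΣLDDT-PLI,
then lower ΣBiSyRMSD, then lowest assembly ID. Weighted-mean LDDT-PLI uses
ligand heavy-atom counts as weights so single-atom ions cannot dominate.
Pose success is strict (`BiSyRMSD < threshold`) at 1, 2 and 5 Å with 2 Å as
the headline rule, divided by the *total* number of reference ligands.
Best-pose-per-entity keeps the lowest-RMSD copy (ties: highest PLI) and
removes the multi-copy penalty. Undefined scores serialize as explicit
nulls with reason codes; common-subset summaries exclude them from means
and medians rather than zeroing them, and report both mean and median per
server on the intersection of predicted target sets. Success fractions are
computed per target; cross-target summaries macro-average them.

## Synthetic fixtures

Chains are ideal α-helical C-alpha traces (radius 2.3 Å, rise 1.5 Å, twist
100°/residue) placed on a circle with 9 Å between neighboring helix axes,
which guarantees inter-chain contacts (iLDDT defined) without clashes.
Ligands are embedded from SMILES (seeded ETKDG) and parked in the shallow
pocket equidistant (3–4 Å) from the face residues k, k+3, k+4, oriented
with their thinnest principal axis outward; placement retries anchors until
≥ 3 residues lie within 4 Å and no atom is closer than 2.2 Å. Perturbations
are exact: rigid shifts (whole complex or one chain), seeded isotropic
Gaussian noise, chain/ligand deletion, label swaps. All randomness flows
from one seed; identical specs produce byte-identical mmCIF.

What a green fixture test does *not* establish: the traces have no side
chains, no realistic packing, no experimental artifacts (partial occupancy,
unresolved loops beyond what perturbations emulate), and single-conformer
ligands. The fixtures pin down the *arithmetic* of the scores and rules,
not robustness to real crystallographic pathology.

The TM-score closed-form fixture deserves a note: a straight 640-residue
chain displaced by d along z in a +,−,−,+ block pattern has zero net
translation and zero net torque, and 640 residues make d₀ ≈ 8.9 Å so the
per-residue term stays concave up to d = 5 Å; both together make the
identity superposition globally optimal and the score exactly
1/(1+(d/d₀)²). With shorter chains or unbalanced patterns the optimizer
would legitimately beat the closed form.

## Known limitations

- e-value computation is not implemented; medium labels require external
  hit tables.
- Geometric bond perception uses covalent radii + 0.45 Å slack; unusual
  coordination geometries may mis-perceive, which only affects inputs
  without component IDs.
- The classification of entities relies on the bundled parent-map excerpt
  unless a full dictionary table is supplied.
- Assembly handling expects assemblies as separate structures; generating
  assemblies from symmetry operators is out of scope.
- PDB occurrence counts for the drug-like rule are a static user-supplied
  table (a small illustrative one is bundled), not a live query.
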