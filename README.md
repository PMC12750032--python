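# complexeval

Stoichiometry-aware evaluation of predicted macromolecular complexes.

Blind benchmarking of structure prediction servers compares predicted
complexes — proteins, nucleic acids and small-molecule ligands together —
against newly released experimental structures. Two problems make this
harder than single-chain assessment. First, at prediction time only the
entity sequences and ligand identifiers are known, not the stoichiometry of
the biological assembly, so the evaluation must decide which model chain
corresponds to which reference chain and must penalize (or, in mapped
variants, forgive) missing copies. Second, target *difficulty* must be
assessed from sequence alone, before any structure is public.

`complexeval` implements both halves as a Python library:

- **Target classification** — polymer entities are typed (protein ≥ 30
  residues, peptide, DNA, RNA), clustered (proteins at 99% identity,
  everything else at 100%), aggregated to complex clusters, and labelled
  from template hits. A protein sequence is *easy* for a template at
  identity ≥ 85% with coverage ≥ 70% (and, for targets > 250 residues,
  < 45 residues uncovered); *medium* below 85% identity with e-value ≤ 1e-4
  and the same coverage; peptides and nucleic acids are easy only at 100%
  identity with full coverage. A complex is easy/medium only if a *single*
  template qualifies for *all* its entities; easy complexes whose ligand set
  no easy template reproduces are flagged *ligand* targets.
- **Scoring** — all-atom LDDT (fraction of reference inter-atomic distances
  within an inclusion radius R₀ = 15 Å reproduced within thresholds
  {0.5, 1, 2, 4} Å; superposition-free; missing chains score zero), interface
  LDDT (inter-chain distances only; undefined for monomers), complex
  TM-score (1/L · Σ 1/(1+(dᵢ/d₀)²) with d₀ = 1.24·(L−15)^⅓ − 1.8), LDDT-PLI
  (polymer–ligand contacts, correspondence optimized over ligand graph
  automorphisms), and BiSyRMSD (ligand heavy-atom RMSD after binding-site
  superposition, minimized over automorphisms — symmetry correction).
- **Aggregation** — assembly selection (polymer scores against the assembly
  with highest LDDT; ligand scores against the assembly scoring most
  ligands, ties by ΣLDDT-PLI then ΣBiSyRMSD), mapped-chain rescoring,
  heavy-atom-weighted mean LDDT-PLI, pose success fractions at 1/2/5 Å
  (strict `< 2 Å` headline rule, unpredicted copies count as failures),
  best-pose-per-entity reduction, and common-subset server comparison.
- **Ligand categorization** — drug-like (Lipinski's Rule of Five and fewer
  than 100 PDB entries), cofactor, ion, artifact, other.
- **Synthetic fixtures** — deterministic helical-trace complexes with
  pocket-placed ligands and exactly specified perturbations, so every score
  relation is testable offline.

## Worked example

`examples/score_complex.py` builds a benzene- and ethanol-bound homodimer
and scores three models against it:

```
--- perfect copy
  LDDT          1.000   (penalizes missing chains)
  mapped LDDT   1.000   (mapped chains only)
  ...
--- one chain missing
  LDDT          0.269   (penalizes missing chains)
  mapped LDDT   1.000   (mapped chains only)
  iLDDT         0.000   (interface contacts only)
  mapped iLDDT  undefined
  TM-score      0.500
  weighted PLI  0.606   (heavy-atom weighted)
  ligand success @1/2/5 A: 0.50 / 0.50 / 0.50
```

The monomeric model's chain is perfect — mapped LDDT 1.0 — but the complex
LDDT collapses to 0.269 because every distance touching the unpredicted
copy scores zero; its interface score is 0 and its *mapped* interface score
is undefined (a monomer has no mapped interface), which is reported as
`null`, never conflated with 0. The ethanol sat on the dropped chain, so
its pose cannot be scored and counts as a failure in the success fractions.

Other examples: `classify_targets.py` (difficulty rules on boundary cases),
`categorize_ligands.py`, `summarize_servers.py` (common-subset comparison),
`simulate_fixtures.py`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on synthetic fixtures: the
48-target classification boundary battery (written to disk and re-parsed
through the BLAST-tabular reader), scoring of perturbed models of a
ligand-bearing homodimer (including the file-based mmCIF path), and ligand
categorization, then writes the result summary JSON to `--out`.
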