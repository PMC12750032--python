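"""Deterministic synthetic fixtures with known expected labels and scores.

Structures are idealized — helical C-alpha traces arranged on a circle so
that neighboring chains are in contact, with ligands embedded from SMILES
and parked against a chain face — because every score in this package is
geometric; no physics is needed.  Model structures derive from the
reference by exactly specified perturbations, each with documented score
consequences (e.g. a dropped chain lowers LDDT but leaves mapped LDDT at
1.0).  The classification generator emits boundary targets for every
difficulty rule together with expected labels computed by an independent,
literal transcription of those rules.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classify import TemplateHit
from .structio import (
    AMINO_ONE_LETTER,
    Atom,
    Chain,
    PolymerEntity,
    NonPolymerEntity,
    Residue,
    Structure,
    TargetComplex,
    THREE_LETTER,
    ValidationError,
    write_target_record,
    write_structure,
)

__all__ = [
    "FixtureSpec",
    "make_complex",
    "make_model",
    "make_classification_set",
    "make_displacement_pair",
    "ClassificationSet",
]

_AMINO_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

# alpha-helical C-alpha trace parameters
_HELIX_RADIUS = 2.3     # A
_HELIX_RISE = 1.5       # A per residue
_HELIX_TWIST = 100.0    # degrees per residue
_CHAIN_SPACING = 9.0    # A between neighboring helix axes


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic complex."""

    seed: int = 0
    n_entities: int = 1
    copies_per_entity: tuple[int, ...] = (1,)
    chain_length: int = 40
    ligands: tuple[str, ...] = ()
    perturbation: object = "none"

    def __post_init__(self) -> None:
        if len(self.copies_per_entity) != self.n_entities:
            raise ValidationError("copies_per_entity must match n_entities")


def _helix_trace(n: int, phase: float = 0.0) -> np.ndarray:
    i = np.arange(n)
    angle = np.deg2rad(_HELIX_TWIST * i) + phase
    return np.stack(
        [
            _HELIX_RADIUS * np.cos(angle),
            _HELIX_RADIUS * np.sin(angle),
            _HELIX_RISE * i,
        ],
        axis=1,
    )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AMINO_LETTERS), size=length))


def _embed_smiles(smiles: str, seed: int) -> tuple[list[str], np.ndarray]:
    """Heavy-atom names/elements and 3D coordinates for a SMILES, seeded."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValidationError(f"embedding failed for {smiles!r}")
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    elements, coords = [], []
    for atom in mol.GetAtoms():
        elements.append(atom.GetSymbol())
        coords.append(list(conf.GetAtomPosition(atom.GetIdx())))
    return elements, np.array(coords)


def make_complex(spec: FixtureSpec) -> tuple[Structure, TargetComplex]:
    """Build a reference complex and its pre-release-style target record.

    Chains are helical C-alpha traces placed on a circle (neighboring chains
    in contact, so homo-oligomers have a defined interface LDDT); each
    ligand is embedded from its SMILES and placed with at least 3 polymer
    residues within 4 A.  Output is fully deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_chains = sum(spec.copies_per_entity)
    circle_r = (
        0.0 if n_chains == 1 else _CHAIN_SPACING / (2.0 * math.sin(math.pi / n_chains))
    )

    polymers: list[PolymerEntity] = []
    chains: list[Chain] = []
    chain_index = 0
    for e_idx in range(spec.n_entities):
        seq = _random_sequence(rng, spec.chain_length)
        entity_id = f"E{e_idx + 1}"
        polymers.append(
            PolymerEntity(
                entity_id=entity_id,
                noncanonical_seq=[THREE_LETTER[c] for c in seq],
                canonical_seq=seq,
                kind="protein" if len(seq) >= 30 else "peptide",
                copy_count=spec.copies_per_entity[e_idx],
            )
        )
        for _ in range(spec.copies_per_entity[e_idx]):
            angle = 2.0 * math.pi * chain_index / n_chains
            center = np.array(
                [circle_r * math.cos(angle), circle_r * math.sin(angle), 0.0]
            )
            trace = _helix_trace(spec.chain_length, phase=angle) + center
            residues = [
                Residue(
                    number=i + 1,
                    component_id=THREE_LETTER[seq[i]],
                    atoms=[Atom(name="CA", element="C", position=trace[i])],
                )
                for i in range(spec.chain_length)
            ]
            chains.append(
                Chain(
                    chain_id=chr(ord("A") + chain_index),
                    entity_ref=entity_id,
                    residues=residues,
                    kind=polymers[-1].kind,
                )
            )
            chain_index += 1

    nonpolymers: list[NonPolymerEntity] = []
    comp_of_smiles: dict[str, str] = {}
    for j, smiles in enumerate(spec.ligands):
        if smiles not in comp_of_smiles:
            comp = f"L{len(comp_of_smiles):02d}"
            comp_of_smiles[smiles] = comp
            elements, _ = _embed_smiles(smiles, seed=spec.seed)
            nonpolymers.append(
                NonPolymerEntity(
                    entity_id=comp,
                    component_id=comp,
                    smiles=smiles,
                    copy_count=sum(1 for s in spec.ligands if s == smiles),
                    heavy_atom_count=len(elements),
                )
            )
        comp = comp_of_smiles[smiles]
        host = chains[j % len(chains)]
        placed = _place_ligand(host, smiles, comp, j, seed=spec.seed + j)
        chains.append(placed)

    reference = Structure(structure_id=f"synth{spec.seed}", chains=chains)
    target = TargetComplex(
        target_id=f"synth{spec.seed}", polymers=polymers, nonpolymers=nonpolymers
    )
    return reference, target


def _place_ligand(
    host: Chain, smiles: str, comp: str, index: int, seed: int
) -> Chain:
    """Park a ligand against 3 consecutive residues of the host chain."""
    elements, coords = _embed_smiles(smiles, seed=seed)
    coords = coords - coords.mean(axis=0)
    ca = np.array([r.atoms[0].position for r in host.residues])
    axis_xy = ca[:, :2].mean(axis=0)
    n = len(host.residues)
    for attempt in range(n - 4):
        # residues k, k+3, k+4 share a helix face; sit the ligand in the
        # shallow pocket equidistant from their C-alphas
        k = (5 + 7 * index + attempt) % (n - 4)
        tri = (ca[k], ca[k + 3], ca[k + 4])
        tri_xy = np.mean([t[:2] for t in tri], axis=0)
        for radius in np.arange(3.0, 4.01, 0.2):
            for P in _trilaterate(*tri, radius):
                if np.linalg.norm(P[:2] - axis_xy) < np.linalg.norm(tri_xy - axis_xy):
                    continue  # inward solution, inside the helix
                outward = P - np.mean(tri, axis=0)
                outward /= np.linalg.norm(outward)
                placed = _orient_flat(coords, outward) + P
                d = np.linalg.norm(ca[None, :, :] - placed[:, None, :], axis=2)
                n_close_res = int(np.sum(np.any(d <= 4.0, axis=0)))
                if n_close_res >= 3 and d.min() > 2.2:
                    atoms = [
                        Atom(
                            name=f"{el}{i + 1}",
                            element=el,
                            position=placed[i],
                            is_hetero=True,
                        )
                        for i, el in enumerate(elements)
                    ]
                    return Chain(
                        chain_id=f"{host.chain_id}.{900 + index}",
                        entity_ref=comp,
                        residues=[Residue(number=1, component_id=comp, atoms=atoms)],
                        kind="ligand",
                    )
    raise ValidationError(f"could not place ligand {smiles!r} without clashes")


def _trilaterate(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                 r: float) -> list[np.ndarray]:
    """Points at distance ``r`` from all three anchors (0, 1 or 2 solutions)."""
    ex = (p2 - p1) / np.linalg.norm(p2 - p1)
    i = float(ex @ (p3 - p1))
    ey = p3 - p1 - i * ex
    ey = ey / np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    d = float(np.linalg.norm(p2 - p1))
    j = float(ey @ (p3 - p1))
    x = d / 2.0
    y = (i * i + j * j) / (2.0 * j) - i * x / j
    z2 = r * r - x * x - y * y
    if z2 < 0:
        return []
    z = math.sqrt(z2)
    base = p1 + x * ex + y * ey
    return [base + z * ez, base - z * ez]


def _orient_flat(coords: np.ndarray, outward: np.ndarray) -> np.ndarray:
    """Rotate centred coordinates so their thinnest axis points outward."""
    if len(coords) == 1:
        return coords
    cov = coords.T @ coords
    eigval, eigvec = np.linalg.eigh(cov)
    normal = eigvec[:, 0]  # smallest-variance axis
    v = np.cross(normal, outward)
    s, c = np.linalg.norm(v), float(normal @ outward)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return coords @ R.T


# ---------------------------------------------------------------------------
# model perturbations
# ---------------------------------------------------------------------------


def make_model(reference: Structure, perturbation: object = "none",
               seed: int = 0) -> Structure:
    """Derive a model from the reference by an exactly specified perturbation.

    Supported perturbations (``"none"`` or ``(name, kwargs)`` tuples):

    - ``("rigid_shift", {"d": x})`` — translate the whole complex (scores
      that are superposition-free stay perfect);
    - ``("rigid_shift", {"d": x, "chain": cid})`` — translate one chain;
    - ``("per_atom_noise", {"sigma": s})`` — iid Gaussian coordinate noise;
    - ``("drop_chain", {"k": i})`` — remove the i-th polymer chain (LDDT
      drops, mapped LDDT stays 1.0);
    - ``("drop_ligand", {"k": i})`` — remove the i-th ligand chain;
    - ``("swap_chain_labels", {})`` — swap the ids of the first two chains
      of the same entity (chain mapping must undo this).
    """
    model = copy.deepcopy(reference)
    model.structure_id = reference.structure_id + "_model"
    if perturbation == "none":
        return model
    if not (isinstance(perturbation, tuple) and len(perturbation) == 2):
        raise ValidationError(f"unknown perturbation {perturbation!r}")
    name, kwargs = perturbation
    if name == "rigid_shift":
        d = float(kwargs["d"])
        direction = np.array(kwargs.get("direction", (1.0, 0.0, 0.0)), float)
        direction = direction / np.linalg.norm(direction)
        cids = (
            [kwargs["chain"]] if "chain" in kwargs
            else [c.chain_id for c in model.chains]
        )
        for chain in model.chains:
            if chain.chain_id in cids:
                for res in chain.residues:
                    for atom in res.atoms:
                        atom.position = atom.position + d * direction
    elif name == "per_atom_noise":
        sigma = float(kwargs["sigma"])
        rng = np.random.default_rng(seed)
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = atom.position + rng.normal(0.0, sigma, size=3)
    elif name == "drop_chain":
        k = int(kwargs["k"])
        polymer_ids = [c.chain_id for c in model.polymer_chains]
        drop = polymer_ids[k]
        model.chains = [c for c in model.chains if c.chain_id != drop]
    elif name == "drop_ligand":
        k = int(kwargs["k"])
        ligand_ids = [c.chain_id for c in model.ligand_chains]
        drop = ligand_ids[k]
        model.chains = [c for c in model.chains if c.chain_id != drop]
    elif name == "swap_chain_labels":
        by_entity: dict[str, list[Chain]] = {}
        for c in model.polymer_chains:
            by_entity.setdefault(c.entity_ref, []).append(c)
        for chains in by_entity.values():
            if len(chains) >= 2:
                chains[0].chain_id, chains[1].chain_id = (
                    chains[1].chain_id, chains[0].chain_id,
                )
                break
        else:
            raise ValidationError("no entity with 2+ copies to swap")
        model.chains.sort(key=lambda c: c.chain_id)
    else:
        raise ValidationError(f"unknown perturbation {name!r}")
    return model


def make_displacement_pair(
    d: float, n_residues: int = 640
) -> tuple[Structure, Structure]:
    """Reference/model pair where every residue sits exactly ``d`` A off.

    A straight C-alpha chain with displacements along z in a +,-,-,+ block
    pattern: zero net translation and zero net torque, so the identity
    superposition is optimal and the TM-score has the closed form
    ``1 / (1 + (d/d0)^2)``.  ``n_residues`` defaults to 640 so that d0 is
    large enough for the closed form to hold up to d = 5 A.
    """
    if n_residues % 4:
        raise ValidationError("n_residues must be a multiple of 4")
    signs = np.tile([1.0, -1.0, -1.0, 1.0], n_residues // 4)

    def build(offset: np.ndarray) -> Structure:
        residues = [
            Residue(
                number=i + 1,
                component_id="GLY",
                atoms=[
                    Atom(
                        name="CA", element="C",
                        position=np.array([3.8 * i, 0.0, offset[i]]),
                    )
                ],
            )
            for i in range(n_residues)
        ]
        return Structure(
            structure_id="disp",
            chains=[Chain(chain_id="A", entity_ref="E1", residues=residues,
                          kind="protein")],
        )

    return build(np.zeros(n_residues)), build(signs * d)


# ---------------------------------------------------------------------------
# classification boundary set
# ---------------------------------------------------------------------------


@dataclass
class ClassificationSet:
    """Targets plus template data spanning every difficulty-rule branch."""

    targets: list[TargetComplex]
    hits: list[TemplateHit]
    entity_kind: dict[str, str]           # "<target>:<entity>" -> kind
    template_sequences: dict[str, str]    # FASTA payload
    template_ligand_sets: dict[str, frozenset[str]]
    target_ligand_sets: dict[str, frozenset[str]]
    expected: dict[str, str]              # target_id -> expected label
    target_lengths: dict[str, int]

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for target in self.targets:
            write_target_record(target, directory / f"{target.target_id}.json")
        with open(directory / "templates.fasta", "w") as fh:
            for tid, seq in sorted(self.template_sequences.items()):
                fh.write(f">{tid}\n{seq}\n")
        with open(directory / "hits.tsv", "w") as fh:
            for h in self.hits:
                covered = h.target_length - h.uncovered
                fh.write(
                    "\t".join(
                        str(x) for x in [
                            h.target_entity, h.template_id, f"{h.identity:.2f}",
                            covered, 0, 0, 1, covered, 1, covered,
                            "1e-30" if h.evalue is None else f"{h.evalue:g}",
                            100.0,
                        ]
                    )
                    + "\n"
                )
        with open(directory / "target_lengths.tsv", "w") as fh:
            for k, v in sorted(self.target_lengths.items()):
                fh.write(f"{k}\t{v}\n")
        import json

        (directory / "expected.json").write_text(
            json.dumps(self.expected, indent=1, sort_keys=True) + "\n"
        )


# --- independent literal transcription of the difficulty rules -------------


def _literal_sequence_label(kind, identity, coverage, length, uncovered, evalue):
    if kind in ("peptide", "dna", "rna"):
        return "easy" if (identity == 100.0 and coverage == 100.0) else "hard"
    coverage_ok = coverage >= 70.0
    if length > 250:
        coverage_ok = coverage_ok and (uncovered < 45)
    if identity >= 85.0 and coverage_ok:
        return "easy"
    if identity < 85.0 and evalue is not None and evalue <= 1e-4 and coverage_ok:
        return "medium"
    return "hard"


def _literal_complex_label(entities, labels_by_template):
    for labels in labels_by_template.values():
        if all(labels.get(e, "hard") == "easy" for e in entities):
            return "easy"
    for labels in labels_by_template.values():
        if all(labels.get(e, "hard") in ("easy", "medium") for e in entities):
            return "medium"
    return "hard"


@dataclass
class _Case:
    """One boundary scenario: entities with per-template hit parameters."""

    name: str
    entities: list[tuple[str, str, int]]  # (entity_id, kind, length)
    # hits[(entity_id, template_id)] = (identity, coverage%, uncovered, evalue)
    hits: dict[tuple[str, str], tuple[float, float, int, float | None]]
    target_ligands: frozenset[str] = frozenset()
    template_ligands: dict[str, frozenset[str]] = field(default_factory=dict)


def _boundary_cases() -> list[_Case]:
    E = "e1"
    cases = [
        _Case("id85_cov70", [(E, "protein", 200)],
              {(E, "t1"): (85.0, 70.0, 60, 1e-20)}),
        _Case("id84.9_eval1e-4", [(E, "protein", 200)],
              {(E, "t1"): (84.9, 70.0, 60, 1e-4)}),
        _Case("id84.9_eval2e-4", [(E, "protein", 200)],
              {(E, "t1"): (84.9, 70.0, 60, 2e-4)}),
        _Case("id84.9_eval10", [(E, "protein", 200)],
              {(E, "t1"): (84.9, 90.0, 20, 10.0)}),
        _Case("cov69.5", [(E, "protein", 200)],
              {(E, "t1"): (99.0, 69.5, 61, 1e-30)}),
        _Case("len300_unc44", [(E, "protein", 300)],
              {(E, "t1"): (90.0, 85.3, 44, 1e-30)}),
        _Case("len300_unc45", [(E, "protein", 300)],
              {(E, "t1"): (90.0, 85.0, 45, 1e-30)}),
        _Case("len300_unc46", [(E, "protein", 300)],
              {(E, "t1"): (90.0, 84.7, 46, 1e-30)}),
        _Case("len250_unc60", [(E, "protein", 250)],
              {(E, "t1"): (90.0, 76.0, 60, 1e-30)}),
        _Case("len251_unc60", [(E, "protein", 251)],
              {(E, "t1"): (90.0, 76.1, 60, 1e-30)}),
        _Case("pep100_full", [(E, "peptide", 20)],
              {(E, "t1"): (100.0, 100.0, 0, None)}),
        _Case("pep100_partial", [(E, "peptide", 20)],
              {(E, "t1"): (100.0, 95.0, 1, None)}),
        _Case("pep99", [(E, "peptide", 20)],
              {(E, "t1"): (95.0, 100.0, 0, None)}),
        _Case("rna_full", [(E, "rna", 40)],
              {(E, "t1"): (100.0, 100.0, 0, None)}),
        _Case("dna_partial", [(E, "dna", 40)],
              {(E, "t1"): (100.0, 97.5, 1, None)}),
        _Case("nohit", [(E, "protein", 150)], {}),
        _Case("two_easy_one_template", [("e1", "protein", 100), ("e2", "protein", 120)],
              {("e1", "t1"): (95.0, 100.0, 0, 1e-30),
               ("e2", "t1"): (95.0, 100.0, 0, 1e-30)}),
        _Case("split_templates", [("e1", "protein", 100), ("e2", "protein", 120)],
              {("e1", "t1"): (95.0, 100.0, 0, 1e-30),
               ("e2", "t2"): (95.0, 100.0, 0, 1e-30)}),
        _Case("easy_plus_medium", [("e1", "protein", 100), ("e2", "protein", 120)],
              {("e1", "t1"): (95.0, 100.0, 0, 1e-30),
               ("e2", "t1"): (60.0, 100.0, 0, 1e-9),
               ("e1", "t2"): (95.0, 100.0, 0, 1e-30)}),
        _Case("medium_then_hard", [("e1", "protein", 100), ("e2", "protein", 120)],
              {("e1", "t1"): (60.0, 100.0, 0, 1e-9),
               ("e2", "t1"): (40.0, 50.0, 60, 0.5)}),
        _Case("ligand_match", [(E, "protein", 100)],
              {(E, "t1"): (95.0, 100.0, 0, 1e-30)},
              target_ligands=frozenset({"ATP"}),
              template_ligands={"t1": frozenset({"ATP"})}),
        _Case("ligand_mismatch", [(E, "protein", 100)],
              {(E, "t1"): (95.0, 100.0, 0, 1e-30)},
              target_ligands=frozenset({"GTP"}),
              template_ligands={"t1": frozenset({"ATP"})}),
        _Case("ligand_empty_sets", [(E, "protein", 100)],
              {(E, "t1"): (95.0, 100.0, 0, 1e-30)},
              target_ligands=frozenset(),
              template_ligands={"t1": frozenset()}),
        _Case("ligand_water_ignored", [(E, "protein", 100)],
              {(E, "t1"): (95.0, 100.0, 0, 1e-30)},
              target_ligands=frozenset({"ATP", "HOH"}),
              template_ligands={"t1": frozenset({"ATP"})}),
    ]
    return cases


_LIGAND_SMILES = {
    "ATP": "Nc1ncnc2n(cnc12)C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O",
    "GTP": "Nc1nc2n(cnc2c(=O)[nH]1)C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O",
}


def make_classification_set(seed: int, n_targets: int = 48) -> ClassificationSet:
    """Emit >= ``n_targets`` boundary targets covering every rule branch.

    Expected labels come from a literal, self-contained transcription of the
    difficulty rules (above), independent of the classify module.
    """
    rng = np.random.default_rng(seed)
    base_cases = _boundary_cases()
    cases: list[_Case] = []
    rep = 0
    while len(cases) < max(n_targets, len(base_cases)):
        for case in base_cases:
            if len(cases) >= max(n_targets, len(base_cases)) and rep > 0:
                break
            suffix = "" if rep == 0 else f"_r{rep}"
            cases.append(
                _Case(
                    name=case.name + suffix,
                    entities=case.entities,
                    hits=case.hits,
                    target_ligands=case.target_ligands,
                    template_ligands=case.template_ligands,
                )
            )
        rep += 1

    targets, hits = [], []
    entity_kind: dict[str, str] = {}
    template_sequences: dict[str, str] = {}
    template_ligand_sets: dict[str, frozenset[str]] = {}
    target_ligand_sets: dict[str, frozenset[str]] = {}
    expected: dict[str, str] = {}
    target_lengths: dict[str, int] = {}

    for idx, case in enumerate(cases):
        tid = f"T{idx:03d}_{case.name}"
        polymers = []
        for eid, kind, length in case.entities:
            if kind in ("protein", "peptide"):
                seq = _random_sequence(rng, length)
                noncanon = [THREE_LETTER[c] for c in seq]
            elif kind == "dna":
                seq = "".join(rng.choice(list("ACGT"), size=length))
                noncanon = ["D" + c for c in seq]
            else:
                seq = "".join(rng.choice(list("ACGU"), size=length))
                noncanon = list(seq)
            polymers.append(
                PolymerEntity(
                    entity_id=eid, noncanonical_seq=noncanon, canonical_seq=seq,
                    kind=kind, copy_count=1,
                )
            )
            entity_kind[f"{tid}:{eid}"] = kind
            target_lengths[f"{tid}:{eid}"] = length
        nonpolymers = [
            NonPolymerEntity(
                entity_id=comp, component_id=comp,
                smiles=_LIGAND_SMILES.get(comp, "O"),
                copy_count=1,
                heavy_atom_count=max(
                    1, _LIGAND_SMILES.get(comp, "O").count("C") or 1
                ),
            )
            for comp in sorted(case.target_ligands)
        ]
        targets.append(
            TargetComplex(target_id=tid, polymers=polymers, nonpolymers=nonpolymers)
        )
        target_ligand_sets[tid] = case.target_ligands

        labels_by_template: dict[str, dict[str, str]] = {}
        for (eid, tpl), (identity, coverage, uncovered, evalue) in case.hits.items():
            tpl_id = f"{tid}_{tpl}"
            length = target_lengths[f"{tid}:{eid}"]
            hits.append(
                TemplateHit(
                    target_entity=f"{tid}:{eid}", template_id=tpl_id,
                    identity=identity, coverage=coverage, uncovered=uncovered,
                    target_length=length, evalue=evalue,
                )
            )
            template_sequences.setdefault(tpl_id, _random_sequence(rng, 60))
            template_ligand_sets[tpl_id] = case.template_ligands.get(
                tpl, frozenset()
            )
            kind = entity_kind[f"{tid}:{eid}"]
            labels_by_template.setdefault(tpl_id, {})[eid] = _literal_sequence_label(
                kind, identity, coverage, length, uncovered, evalue
            )
        entity_ids = [eid for eid, _, _ in case.entities]
        label = _literal_complex_label(entity_ids, labels_by_template)
        if label == "easy":
            easy_templates = [
                t for t, labels in labels_by_template.items()
                if all(labels.get(e, "hard") == "easy" for e in entity_ids)
            ]
            tset = case.target_ligands - {"HOH"}
            if not any(
                template_ligand_sets.get(t, frozenset()) - {"HOH"} == tset
                for t in easy_templates
            ):
                label = "ligand"
        expected[tid] = label

    return ClassificationSet(
        targets=targets,
        hits=hits,
        entity_kind=entity_kind,
        template_sequences=template_sequences,
        template_ligand_sets=template_ligand_sets,
        target_ligand_sets=target_ligand_sets,
        expected=expected,
        target_lengths=target_lengths,
    )
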