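"""Structure similarity scores.

All scores compare a model against a reference under a chain mapping:

* ``lddt`` — all-atom local distance difference test: the fraction of
  reference inter-atomic distances (within an inclusion radius, excluding
  same-residue pairs) reproduced by the model within a set of tolerance
  thresholds.  Superposition-free; distances touching atoms the model did
  not predict score zero, which is what penalizes wrong stoichiometry.
* ``ilddt`` — the same restricted to inter-chain (interface) distances;
  undefined for monomers.
* ``tm_score`` — superposition-based backbone score with the standard
  length-dependent scaling constant d0.
* ``lddt_pli`` — LDDT restricted to polymer-ligand contacts, with the ligand
  atom correspondence chosen over graph automorphisms.
* ``bisy_rmsd`` — ligand heavy-atom RMSD after superposing on the binding
  site, minimized over ligand graph automorphisms (symmetry correction).

Undefined scores are returned as ``None``, never 0: a monomer has no
interface to get wrong, and a ligand without polymer contacts has no pose
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import LDDTParams
from .mapping import ChainMapping, LigandGraph, graph_isomorphisms, ligand_automorphisms
from .structio import BACKBONE_ATOMS, Chain, Structure

__all__ = [
    "lddt",
    "ilddt",
    "tm_score",
    "lddt_pli",
    "bisy_rmsd",
    "superpose",
    "SuperpositionResult",
    "PoseScore",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class PoseScore:
    """Scores of one reference ligand (chain id) under the ligand mapping."""

    ligand_ref: str
    lddt_pli: float | None
    bisy_rmsd: float | None
    heavy_atoms: int
    model_ligand: str | None = None
    entity_id: str | None = None


def superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of ``moving`` onto ``fixed``."""
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    moved = moving @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


# ---------------------------------------------------------------------------
# atom bookkeeping
# ---------------------------------------------------------------------------


class _AtomTable:
    """Flat view of a structure's atoms for vectorized scoring."""

    def __init__(self, structure: Structure, polymer_only: bool = True,
                 backbone_only: bool = False):
        coords, keys = [], []
        self.chain_of: list[str] = []
        self.res_uid: list[int] = []
        self.res_key: list[tuple[str, int]] = []
        uid = -1
        last = None
        for chain in structure.chains:
            if polymer_only and not chain.is_polymer:
                continue
            for res in chain.residues:
                for atom in res.atoms:
                    if backbone_only and atom.name not in BACKBONE_ATOMS:
                        continue
                    if atom.element == "H":
                        continue
                    if (chain.chain_id, res.number) != last:
                        uid += 1
                        last = (chain.chain_id, res.number)
                    coords.append(atom.position)
                    keys.append((chain.chain_id, res.number, atom.name))
                    self.chain_of.append(chain.chain_id)
                    self.res_uid.append(uid)
                    self.res_key.append((chain.chain_id, res.number))
        self.coords = np.array(coords) if coords else np.zeros((0, 3))
        self.keys = keys
        self.index = {k: i for i, k in enumerate(keys)}
        self.res_uid = np.array(self.res_uid, dtype=int) if keys else np.zeros(0, int)

    def __len__(self) -> int:
        return len(self.keys)


def _model_lookup(
    model: Structure, mapping: ChainMapping, removed: set | None = None
) -> dict[tuple[str, int, str], np.ndarray]:
    """Reference-keyed model coordinates: (ref_chain, res_number, atom_name)."""
    removed = removed or set()
    ref_chain_of = {m: r for m, r in mapping.pairs}
    lookup: dict[tuple[str, int, str], np.ndarray] = {}
    for chain in model.chains:
        if not chain.is_polymer:
            continue
        ref_cid = ref_chain_of.get(chain.chain_id)
        if ref_cid is None:
            continue
        for res in chain.residues:
            for atom in res.atoms:
                if (chain.chain_id, res.number, atom.name) in removed:
                    continue
                lookup[(ref_cid, res.number, atom.name)] = atom.position
    return lookup


# ---------------------------------------------------------------------------
# stereochemistry filter
# ---------------------------------------------------------------------------

# ideal backbone bond lengths (A) with standard deviations
_IDEAL_BONDS = {
    ("N", "CA"): (1.458, 0.019),
    ("CA", "C"): (1.525, 0.021),
    ("C", "O"): (1.231, 0.020),
}
_PEPTIDE_BOND = (1.329, 0.014)  # C(i) - N(i+1)


def stereo_violating_atoms(model: Structure, params: LDDTParams) -> set:
    """Model atoms failing the simplified stereochemistry screen.

    Bond lengths more than ``bond_tolerance_sigmas`` standard deviations from
    ideal, or non-bonded inter-residue contacts below ``clash_distance``,
    mark the involved atoms for removal (they then score zero).
    """
    bad: set = set()
    k = params.bond_tolerance_sigmas
    for chain in model.polymer_chains:
        prev_c = None
        prev_key = None
        prev_number = None
        for res in chain.residues:
            by_name = {a.name: a for a in res.atoms}
            for (a_name, b_name), (ideal, sigma) in _IDEAL_BONDS.items():
                a, b = by_name.get(a_name), by_name.get(b_name)
                if a is None or b is None:
                    continue
                d = float(np.linalg.norm(a.position - b.position))
                if abs(d - ideal) > k * sigma:
                    bad.add((chain.chain_id, res.number, a_name))
                    bad.add((chain.chain_id, res.number, b_name))
            n = by_name.get("N")
            if prev_c is not None and n is not None and res.number == prev_number + 1:
                ideal, sigma = _PEPTIDE_BOND
                d = float(np.linalg.norm(prev_c.position - n.position))
                if abs(d - ideal) > k * sigma:
                    bad.add(prev_key)
                    bad.add((chain.chain_id, res.number, "N"))
            prev_c = by_name.get("C")
            prev_key = (chain.chain_id, res.number, "C")
            prev_number = res.number
    # steric clashes between non-bonded (different-residue) atom pairs
    table = _AtomTable(model, polymer_only=True)
    if len(table) > 1:
        tree = cKDTree(table.coords)
        for i, j in tree.query_pairs(params.clash_distance):
            if table.res_uid[i] == table.res_uid[j]:
                continue
            ci, ri, ai = table.keys[i]
            cj, rj, aj = table.keys[j]
            # consecutive-residue peptide/phosphodiester bonds are bonded pairs
            if ci == cj and abs(ri - rj) == 1 and {ai, aj} in ({"C", "N"}, {"P", "O3'"}):
                continue
            bad.add(table.keys[i])
            bad.add(table.keys[j])
    return bad


# ---------------------------------------------------------------------------
# LDDT family
# ---------------------------------------------------------------------------


def _lddt_core(
    ref_table: _AtomTable,
    pairs: np.ndarray,
    model_coords: np.ndarray,
    model_present: np.ndarray,
    thresholds: tuple[float, ...],
):
    """Score a list of reference atom-index pairs against model coordinates."""
    if len(pairs) == 0:
        return None, {}
    i, j = pairs[:, 0], pairs[:, 1]
    d_ref = np.linalg.norm(ref_table.coords[i] - ref_table.coords[j], axis=1)
    both = model_present[i] & model_present[j]
    d_model = np.full(len(pairs), np.nan)
    if both.any():
        d_model[both] = np.linalg.norm(
            model_coords[i[both]] - model_coords[j[both]], axis=1
        )
    err = np.abs(d_model - d_ref)
    fracs = np.zeros(len(pairs))
    for t in thresholds:
        fracs += (err <= t) & both
    fracs /= len(thresholds)
    score = float(fracs.mean())
    per_res_sum: dict[tuple[str, int], list[float]] = {}
    for idx in range(len(pairs)):
        for atom_idx in (i[idx], j[idx]):
            key = ref_table.res_key[atom_idx]
            per_res_sum.setdefault(key, []).append(fracs[idx])
    per_residue = {k: float(np.mean(v)) for k, v in per_res_sum.items()}
    return score, per_residue


def _prepare(model, reference, mapping, params, backbone_only):
    ref_table = _AtomTable(reference, polymer_only=True, backbone_only=backbone_only)
    removed = (
        stereo_violating_atoms(model, params) if params.stereo_check else set()
    )
    lookup = _model_lookup(model, mapping, removed)
    model_coords = np.zeros((len(ref_table), 3))
    model_present = np.zeros(len(ref_table), dtype=bool)
    for idx, key in enumerate(ref_table.keys):
        pos = lookup.get(key)
        if pos is not None:
            model_coords[idx] = pos
            model_present[idx] = True
    if len(ref_table) > 1:
        tree = cKDTree(ref_table.coords)
        raw = np.array(sorted(tree.query_pairs(params.inclusion_radius)))
    else:
        raw = np.zeros((0, 2), int)
    if len(raw):
        keep = ref_table.res_uid[raw[:, 0]] != ref_table.res_uid[raw[:, 1]]
        raw = raw[keep]
    return ref_table, raw, model_coords, model_present


def lddt(
    model: Structure,
    reference: Structure,
    mapping: ChainMapping,
    params: LDDTParams = LDDTParams(),
    backbone_only: bool = False,
) -> tuple[float | None, dict[tuple[str, int], float]]:
    """All-atom LDDT of the model against the full reference complex.

    Returns ``(score, per_residue)``; the score is ``None`` when the
    reference defines no distances.  Reference distances whose atoms the
    model does not provide (missing residues, chains, or atoms removed by
    the stereochemistry filter) count zero at every threshold.
    """
    ref_table, pairs, mc, mp = _prepare(model, reference, mapping, params, backbone_only)
    return _lddt_core(ref_table, pairs, mc, mp, params.thresholds)


def ilddt(
    model: Structure,
    reference: Structure,
    mapping: ChainMapping,
    params: LDDTParams = LDDTParams(),
    backbone_only: bool = False,
) -> float | None:
    """Interface LDDT: only distances between atoms of different polymer
    chains. ``None`` (undefined) when the reference has no inter-chain
    contact — monomers have no interface to score."""
    ref_table, pairs, mc, mp = _prepare(model, reference, mapping, params, backbone_only)
    if len(pairs):
        chain_arr = np.array(ref_table.chain_of)
        pairs = pairs[chain_arr[pairs[:, 0]] != chain_arr[pairs[:, 1]]]
    if len(pairs) == 0:
        return None
    score, _ = _lddt_core(ref_table, pairs, mc, mp, params.thresholds)
    return score


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------


def tm_d0(n_residues: int) -> float:
    """Length-dependent scaling constant, floored at 0.5 A."""
    if n_residues <= 15:
        return 0.5
    return max(0.5, 1.24 * (n_residues - 15) ** (1.0 / 3.0) - 1.8)


def _backbone_positions(chain: Chain) -> dict[int, np.ndarray]:
    out = {}
    for res in chain.residues:
        for name in ("CA", "C4'", "P"):
            a = res.atom(name)
            if a is not None:
                out[res.number] = a.position
                break
    return out


def tm_score(
    model: Structure,
    reference: Structure,
    mapping: ChainMapping,
) -> float | None:
    """Complex TM-score in a single global superposition frame.

    Normalized by the total reference backbone length; unmapped reference
    residues contribute zero.  The superposition maximizing the score is
    searched with Kabsch fits seeded on the full alignment and on sliding
    fragments, each refined by iterative inclusion of close residues.
    """
    model_for = mapping.model_for
    ref_bb: list[np.ndarray] = []
    mod_bb: list[np.ndarray] = []
    l_ref = 0
    for chain in reference.polymer_chains:
        ref_pos = _backbone_positions(chain)
        l_ref += len(ref_pos)
        mcid = model_for.get(chain.chain_id)
        if mcid is None:
            continue
        mod_pos = _backbone_positions(model.chain(mcid))
        for number, pos in ref_pos.items():
            if number in mod_pos:
                ref_bb.append(pos)
                mod_bb.append(mod_pos[number])
    n = len(ref_bb)
    if n < 3 or l_ref == 0:
        return None
    P = np.array(mod_bb)
    Q = np.array(ref_bb)
    d0 = tm_d0(l_ref)

    def tm_of(sup: SuperpositionResult) -> float:
        d = np.linalg.norm(sup.apply(P) - Q, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)

    best = -1.0
    seeds: list[np.ndarray] = [np.arange(n)]
    for frag in {n, max(4, n // 2), max(4, n // 4), 4}:
        if frag > n:
            continue
        step = max(1, frag // 2)
        for start in range(0, n - frag + 1, step):
            seeds.append(np.arange(start, start + frag))
    d_cut = max(d0, 4.5)
    for seed in seeds:
        subset = seed
        prev: np.ndarray | None = None
        for _ in range(20):
            if len(subset) < 3:
                break
            sup = superpose(P[subset], Q[subset])
            best = max(best, tm_of(sup))
            d = np.linalg.norm(sup.apply(P) - Q, axis=1)
            cut = d_cut
            new = np.flatnonzero(d < cut)
            while len(new) < 3:
                cut += 0.5
                new = np.flatnonzero(d < cut)
            if prev is not None and len(new) == len(prev) and np.array_equal(new, prev):
                break
            prev, subset = subset, new
    return best


# ---------------------------------------------------------------------------
# ligand scores
# ---------------------------------------------------------------------------


def _ligand_chain(structure: Structure, chain_id: str) -> Chain:
    chain = structure.chain(chain_id)
    if chain.kind != "ligand":
        raise ValueError(f"chain {chain_id} is not a ligand")
    return chain


def _heavy_atoms(chain: Chain) -> tuple[list[str], np.ndarray]:
    atoms = [a for a in chain.residues[0].atoms if a.element != "H"]
    return [a.name for a in atoms], np.array([a.position for a in atoms])


def _ligand_correspondences(
    ref_chain: Chain,
    model_chain: Chain,
    automorphisms: list[tuple[int, ...]] | None,
    cap: int = 10_000,
) -> list[tuple[int, ...]]:
    """All candidate maps ref-ligand-atom-index -> model-ligand-atom-index."""
    ref_graph = LigandGraph.from_chain(ref_chain)
    model_graph = LigandGraph.from_chain(model_chain)
    base_list = graph_isomorphisms(ref_graph, model_graph, cap=1)
    if base_list:
        base = base_list[0]
    else:
        # distorted model poses can defeat geometric bond perception; fall
        # back to atom-name correspondence when names agree
        ref_names, _ = _heavy_atoms(ref_chain)
        model_names, _ = _heavy_atoms(model_chain)
        if sorted(ref_names) != sorted(model_names):
            raise ValueError(
                f"ligands {ref_chain.chain_id} and {model_chain.chain_id} "
                "are neither graph-isomorphic nor name-matched"
            )
        index_of = {name: i for i, name in enumerate(model_names)}
        base = tuple(index_of[name] for name in ref_names)
    if automorphisms is None:
        automorphisms, _ = ligand_automorphisms(ref_graph, cap=cap)
    return [tuple(base[s[i]] for i in range(len(s))) for s in automorphisms]


def lddt_pli(
    model: Structure,
    reference: Structure,
    ligand_pair: tuple[str, str],
    mapping: ChainMapping,
    params: LDDTParams = LDDTParams(),
    inclusion_radius: float = 4.0,
    automorphisms: list[tuple[int, ...]] | None = None,
) -> float | None:
    """LDDT over polymer-ligand contacts for one mapped ligand pair.

    The reference distance set holds polymer-atom to ligand-atom pairs within
    ``inclusion_radius``; the ligand atom correspondence is the one among the
    graph automorphisms that maximizes the score.  ``None`` when the
    reference ligand has no polymer contact.
    """
    model_cid, ref_cid = ligand_pair
    ref_lig = _ligand_chain(reference, ref_cid)
    model_lig = _ligand_chain(model, model_cid)
    _, ref_lig_coords = _heavy_atoms(ref_lig)
    _, model_lig_coords = _heavy_atoms(model_lig)

    poly_table = _AtomTable(reference, polymer_only=True)
    removed = stereo_violating_atoms(model, params) if params.stereo_check else set()
    lookup = _model_lookup(model, mapping, removed)

    # contacts: polymer atom p, ligand atom l with d_ref <= radius
    contacts: list[tuple[int, int, float]] = []
    if len(poly_table):
        tree = cKDTree(poly_table.coords)
        for l_idx, l_pos in enumerate(ref_lig_coords):
            for p_idx in sorted(tree.query_ball_point(l_pos, inclusion_radius)):
                d = float(np.linalg.norm(poly_table.coords[p_idx] - l_pos))
                contacts.append((p_idx, l_idx, d))
    if not contacts:
        return None

    model_poly = [lookup.get(poly_table.keys[p]) for p, _, _ in contacts]
    best: float | None = None
    for corr in _ligand_correspondences(ref_lig, model_lig, automorphisms):
        total = 0.0
        for (p_idx, l_idx, d_ref), m_pos in zip(contacts, model_poly):
            if m_pos is None:
                continue
            d_model = float(np.linalg.norm(m_pos - model_lig_coords[corr[l_idx]]))
            err = abs(d_model - d_ref)
            total += sum(err <= t for t in params.thresholds) / len(params.thresholds)
        score = total / len(contacts)
        if best is None or score > best:
            best = score
    return best


def bisy_rmsd(
    model: Structure,
    reference: Structure,
    ligand_pair: tuple[str, str],
    mapping: ChainMapping,
    automorphisms: list[tuple[int, ...]] | None = None,
    site_radius: float = 4.0,
) -> float | None:
    """Binding-site superposed, symmetry-corrected ligand RMSD.

    The binding site is every reference polymer residue with an atom within
    ``site_radius`` of the ligand; the model is superposed onto the reference
    on the site backbone atoms, and the ligand heavy-atom RMSD is minimized
    over graph automorphisms.  ``None`` when fewer than 3 site backbone atoms
    can be paired.
    """
    model_cid, ref_cid = ligand_pair
    ref_lig = _ligand_chain(reference, ref_cid)
    model_lig = _ligand_chain(model, model_cid)
    _, ref_lig_coords = _heavy_atoms(ref_lig)
    _, model_lig_coords = _heavy_atoms(model_lig)

    poly_table = _AtomTable(reference, polymer_only=True)
    if not len(poly_table):
        return None
    tree = cKDTree(poly_table.coords)
    site_residues: set[tuple[str, int]] = set()
    for l_pos in ref_lig_coords:
        for p_idx in tree.query_ball_point(l_pos, site_radius):
            site_residues.add(poly_table.res_key[p_idx])

    lookup = _model_lookup(model, mapping)
    ref_site, model_site = [], []
    for idx, key in enumerate(poly_table.keys):
        cid, number, name = key
        if (cid, number) in site_residues and name in BACKBONE_ATOMS:
            m_pos = lookup.get(key)
            if m_pos is not None:
                ref_site.append(poly_table.coords[idx])
                model_site.append(m_pos)
    if len(ref_site) < 3:
        return None
    sup = superpose(np.array(model_site), np.array(ref_site))
    moved = sup.apply(model_lig_coords)
    best = None
    for corr in _ligand_correspondences(ref_lig, model_lig, automorphisms):
        rmsd = float(
            np.sqrt(np.mean(np.sum((moved[list(corr)] - ref_lig_coords) ** 2, axis=1)))
        )
        if best is None or rmsd < best:
            best = rmsd
    return best
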