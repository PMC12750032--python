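"""Chain and ligand mapping, and ligand graph symmetry.

Model chains are assigned to reference chains among entity-compatible
candidates so that the total complex score (backbone LDDT by default) is
maximal; reference chains left without a partner carry the stoichiometry
penalty downstream.  Ligands are matched only to reference ligands with an
identical component graph (element- and bond-preserving isomorphism), and
the automorphism group of that graph drives the symmetry correction of
RMSD-based pose scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .structio import Chain, Structure, ValidationError

__all__ = [
    "ChainMapping",
    "LigandMapping",
    "LigandGraph",
    "ligand_automorphisms",
    "graph_isomorphisms",
    "map_chains",
    "map_ligands",
]

# single-bond covalent radii (A) for distance-based bond perception
_COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
    "Si": 1.11, "As": 1.19,
}
_BOND_SLACK = 0.45  # bonded when d <= r1 + r2 + slack


@dataclass
class ChainMapping:
    """Injective assignment of model polymer chains to reference chains."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    unmapped_model: list[str] = field(default_factory=list)
    unmapped_reference: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ms = [m for m, _ in self.pairs]
        rs = [r for _, r in self.pairs]
        if len(set(ms)) != len(ms) or len(set(rs)) != len(rs):
            raise ValidationError("chain mapping is not injective")

    @property
    def model_for(self) -> dict[str, str]:
        """reference chain id -> model chain id"""
        return {r: m for m, r in self.pairs}

    @property
    def reference_for(self) -> dict[str, str]:
        return {m: r for m, r in self.pairs}

    @classmethod
    def identity(cls, structure: Structure) -> "ChainMapping":
        ids = [c.chain_id for c in structure.polymer_chains]
        return cls(pairs=[(i, i) for i in ids])


@dataclass
class LigandMapping:
    """Injective assignment of model ligands to reference ligands (chain ids)."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    unmapped_reference: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ms = [m for m, _ in self.pairs]
        rs = [r for _, r in self.pairs]
        if len(set(ms)) != len(ms) or len(set(rs)) != len(rs):
            raise ValidationError("ligand mapping is not injective")


@dataclass
class LigandGraph:
    """A ligand as an element-labelled graph over heavy atoms.

    Bond orders are deliberately ignored: aromatic/Kekule ambiguity across
    SMILES dialects would otherwise split identical ligands.
    """

    elements: list[str]
    bonds: set[frozenset[int]]

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.elements]
        for bond in self.bonds:
            i, j = tuple(bond)
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return False
        if self.n_atoms == 1:
            return True
        adj = self.neighbors()
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_atoms

    @classmethod
    def from_chain(cls, chain: Chain) -> "LigandGraph":
        """Perceive bonds geometrically from a single-residue ligand chain."""
        if chain.kind != "ligand" or len(chain.residues) != 1:
            raise ValidationError(f"chain {chain.chain_id} is not a ligand chain")
        atoms = [a for a in chain.residues[0].atoms if a.element != "H"]
        coords = np.array([a.position for a in atoms])
        elements = [a.element for a in atoms]
        bonds: set[frozenset[int]] = set()
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                cutoff = (
                    _COVALENT_RADIUS.get(elements[i], 1.5)
                    + _COVALENT_RADIUS.get(elements[j], 1.5)
                    + _BOND_SLACK
                )
                if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                    bonds.add(frozenset((i, j)))
        return cls(elements=elements, bonds=bonds)

    @classmethod
    def from_smiles(cls, smiles: str) -> "LigandGraph":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValidationError(f"unparseable SMILES: {smiles!r}")
        elements = [atom.GetSymbol() for atom in mol.GetAtoms()]
        bonds = {
            frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in mol.GetBonds()
        }
        return cls(elements=elements, bonds=bonds)


def graph_isomorphisms(
    g1: LigandGraph, g2: LigandGraph, cap: int | None = None
) -> list[tuple[int, ...]]:
    """All element- and bond-preserving maps ``g1 -> g2`` (backtracking).

    Returned as tuples ``m`` with ``m[i]`` the g2 index of g1 atom ``i``.
    """
    n = g1.n_atoms
    if n != g2.n_atoms or len(g1.bonds) != len(g2.bonds):
        return []
    if sorted(g1.elements) != sorted(g2.elements):
        return []
    adj1, adj2 = g1.neighbors(), g2.neighbors()
    deg1 = [len(a) for a in adj1]
    deg2 = [len(a) for a in adj2]
    # assign high-degree, rare-element atoms first; keep connectivity to the
    # already-assigned set so neighbor constraints prune immediately
    order: list[int] = []
    remaining = set(range(n))
    while remaining:
        frontier = [i for i in remaining if any(j in order for j in adj1[i])]
        pool = frontier or list(remaining)
        nxt = max(pool, key=lambda i: (deg1[i], g1.elements[i], -i))
        order.append(nxt)
        remaining.discard(nxt)
    results: list[tuple[int, ...]] = []
    mapping: dict[int, int] = {}
    used = [False] * n

    def backtrack(pos: int) -> bool:
        if cap is not None and len(results) >= cap:
            return True  # truncated
        if pos == n:
            full = tuple(mapping[i] for i in range(n))
            results.append(full)
            return False
        i = order[pos]
        for j in range(n):
            if used[j] or g2.elements[j] != g1.elements[i] or deg2[j] != deg1[i]:
                continue
            ok = True
            for k in adj1[i]:
                if k in mapping and mapping[k] not in adj2[j]:
                    ok = False
                    break
            if ok:
                for k in mapping:
                    if k not in adj1[i] and mapping[k] in adj2[j]:
                        ok = False
                        break
            if ok:
                mapping[i] = j
                used[j] = True
                if backtrack(pos + 1):
                    return True
                used[j] = False
                del mapping[i]
        return False

    backtrack(0)
    return sorted(results)


def ligand_automorphisms(
    graph: LigandGraph, cap: int = 10_000
) -> tuple[list[tuple[int, ...]], bool]:
    """All atom permutations preserving elements and bonds, up to ``cap``.

    Returns ``(permutations, truncated)``; the identity is always included
    and the group is closed under composition when not truncated.
    """
    if not graph.is_connected():
        raise ValidationError("ligand graph is disconnected")
    perms = graph_isomorphisms(graph, graph, cap=cap)
    truncated = len(perms) >= cap
    identity = tuple(range(graph.n_atoms))
    if identity not in perms:  # only possible under truncation
        perms = [identity] + perms[: cap - 1]
    return perms, truncated


# ---------------------------------------------------------------------------
# chain mapping
# ---------------------------------------------------------------------------


def _chains_compatible(model_chain: Chain, ref_chain: Chain) -> bool:
    """Same entity: explicit entity_ref when both carry one, else sequence."""
    if not model_chain.is_polymer or not ref_chain.is_polymer:
        return False
    if model_chain.entity_ref and ref_chain.entity_ref:
        return model_chain.entity_ref == ref_chain.entity_ref
    if model_chain.kind != ref_chain.kind and {model_chain.kind, ref_chain.kind} != {
        "protein", "peptide",
    }:
        return False
    # model residues are numbered on the target sequence: compare shared positions
    ref_by_number = {r.number: r.component_id for r in ref_chain.residues}
    shared = [
        r for r in model_chain.residues if r.number in ref_by_number
    ]
    if not shared:
        return False
    same = sum(1 for r in shared if ref_by_number[r.number] == r.component_id)
    return same / len(shared) >= 0.95


def _enumerate_assignments(
    groups: list[tuple[list[str], list[str]]]
) -> Iterable[list[tuple[str, str]]]:
    """All joint injective assignments across compatibility groups."""
    per_group: list[list[list[tuple[str, str]]]] = []
    for model_ids, ref_ids in groups:
        k = min(len(model_ids), len(ref_ids))
        options: list[list[tuple[str, str]]] = []
        for model_subset in itertools.combinations(sorted(model_ids), k):
            for ref_perm in itertools.permutations(sorted(ref_ids), k):
                options.append(list(zip(model_subset, ref_perm)))
        per_group.append(options)
    for combo in itertools.product(*per_group):
        yield [pair for group in combo for pair in group]


def map_chains(
    model: Structure,
    reference: Structure,
    score_fn: Callable[[list[tuple[str, str]]], float] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> ChainMapping:
    """Assign model chains to reference chains, maximizing the complex score.

    ``score_fn`` receives a candidate pair list and returns a real score;
    the default is the backbone LDDT of the model against the reference
    under that candidate mapping (complex context).  Exhaustive for up to
    ``config.exhaustive_copy_limit`` interchangeable copies per entity,
    greedy with local swaps beyond.
    """
    model_chains = model.polymer_chains
    ref_chains = reference.polymer_chains

    if score_fn is None:
        from .scores import lddt

        def score_fn(pairs: list[tuple[str, str]]) -> float:
            cand = ChainMapping(
                pairs=pairs,
                unmapped_model=[],
                unmapped_reference=[],
            )
            value, _ = lddt(
                model, reference, cand, params=config.lddt, backbone_only=True
            )
            return value if value is not None else 0.0

    # build compatibility groups (connected components of the bipartite graph)
    compat: dict[str, set[str]] = {
        mc.chain_id: {
            rc.chain_id for rc in ref_chains if _chains_compatible(mc, rc)
        }
        for mc in model_chains
    }
    groups: list[tuple[list[str], list[str]]] = []
    unassigned_model = [c.chain_id for c in model_chains]
    unassigned_ref = {c.chain_id for c in ref_chains}
    while unassigned_model:
        seed = unassigned_model[0]
        group_m, group_r = {seed}, set(compat[seed])
        changed = True
        while changed:
            changed = False
            for m in unassigned_model:
                if m not in group_m and compat[m] & group_r:
                    group_m.add(m)
                    group_r |= compat[m]
                    changed = True
        if group_r:
            groups.append((sorted(group_m), sorted(group_r)))
        unassigned_model = [m for m in unassigned_model if m not in group_m]
        unassigned_ref -= group_r

    if not groups:
        return ChainMapping(
            pairs=[],
            unmapped_model=sorted(c.chain_id for c in model_chains),
            unmapped_reference=sorted(c.chain_id for c in ref_chains),
        )

    max_copies = max(max(len(m), len(r)) for m, r in groups)
    if max_copies <= config.exhaustive_copy_limit:
        best_pairs, best_score = None, -np.inf
        for pairs in _enumerate_assignments(groups):
            pairs = sorted(pairs)
            s = score_fn(pairs)
            if s > best_score + 1e-12:
                best_pairs, best_score = pairs, s
            elif best_pairs is not None and abs(s - best_score) <= 1e-12:
                if pairs < best_pairs:  # deterministic tie-break
                    best_pairs = pairs
        pairs = best_pairs or []
    else:
        pairs = _greedy_with_swaps(groups, score_fn)

    mapped_m = {m for m, _ in pairs}
    mapped_r = {r for _, r in pairs}
    return ChainMapping(
        pairs=pairs,
        unmapped_model=sorted(c.chain_id for c in model_chains if c.chain_id not in mapped_m),
        unmapped_reference=sorted(
            c.chain_id for c in ref_chains if c.chain_id not in mapped_r
        ),
    )


def _greedy_with_swaps(groups, score_fn) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for model_ids, ref_ids in groups:
        free_refs = sorted(ref_ids)
        for m in sorted(model_ids):
            if not free_refs:
                break
            best_r = max(
                free_refs, key=lambda r: (score_fn(sorted(pairs + [(m, r)])), r)
            )
            pairs.append((m, best_r))
            free_refs.remove(best_r)
    pairs = sorted(pairs)
    current = score_fn(pairs)
    improved = True
    while improved:
        improved = False
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                (ma, ra), (mb, rb) = pairs[a], pairs[b]
                swapped = sorted(
                    [p for i, p in enumerate(pairs) if i not in (a, b)]
                    + [(ma, rb), (mb, ra)]
                )
                s = score_fn(swapped)
                if s > current + 1e-12:
                    pairs, current, improved = swapped, s, True
                    break
            if improved:
                break
    return sorted(pairs)


# ---------------------------------------------------------------------------
# ligand mapping
# ---------------------------------------------------------------------------


def map_ligands(
    model_ligands: Sequence[Chain],
    reference_ligands: Sequence[Chain],
    pose_score_fn: Callable[[str, str], float | None],
    graphs: dict[str, LigandGraph] | None = None,
) -> LigandMapping:
    """Optimal assignment among graph-isomorphic ligand pairs.

    ``pose_score_fn(model_chain_id, reference_chain_id)`` returns the pose
    score to maximize in sum (undefined scores count as zero for the
    assignment).  Reference ligands with no isomorphic model ligand are left
    unmapped and count as failures downstream.
    """
    from scipy.optimize import linear_sum_assignment

    graphs = graphs or {}
    _cache: dict[int, LigandGraph] = {}

    def graph_of(chain: Chain) -> LigandGraph:
        # model and reference ligands may share chain ids; cache by object
        if id(chain) not in _cache:
            _cache[id(chain)] = graphs.get(chain.chain_id) or LigandGraph.from_chain(chain)
        return _cache[id(chain)]

    model_ligands = sorted(model_ligands, key=lambda c: c.chain_id)
    reference_ligands = sorted(reference_ligands, key=lambda c: c.chain_id)
    if not model_ligands or not reference_ligands:
        return LigandMapping(
            pairs=[], unmapped_reference=[c.chain_id for c in reference_ligands]
        )
    INCOMPATIBLE = -1e9
    cost = np.full((len(model_ligands), len(reference_ligands)), INCOMPATIBLE)
    for i, mc in enumerate(model_ligands):
        for j, rc in enumerate(reference_ligands):
            # identical component ids are chemically identical by definition;
            # geometric graph isomorphism covers renamed/unnamed components
            same_component = (
                mc.residues[0].component_id == rc.residues[0].component_id
            )
            if same_component or graph_isomorphisms(
                graph_of(mc), graph_of(rc), cap=1
            ):
                s = pose_score_fn(mc.chain_id, rc.chain_id)
                cost[i, j] = 0.0 if s is None else s
    rows, cols = linear_sum_assignment(cost, maximize=True)
    pairs = [
        (model_ligands[i].chain_id, reference_ligands[j].chain_id)
        for i, j in zip(rows, cols)
        if cost[i, j] > INCOMPATIBLE / 2
    ]
    mapped_r = {r for _, r in pairs}
    return LigandMapping(
        pairs=sorted(pairs),
        unmapped_reference=sorted(
            c.chain_id for c in reference_ligands if c.chain_id not in mapped_r
        ),
    )
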