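"""LDDT family, TM-score and ligand pose scores."""

import copy
import math

import numpy as np
import pytest

from complexeval.config import LDDTParams
from complexeval.mapping import ChainMapping, LigandGraph, ligand_automorphisms, map_chains
from complexeval.scores import (
    bisy_rmsd,
    ilddt,
    lddt,
    lddt_pli,
    superpose,
    tm_d0,
    tm_score,
)
from complexeval.structio import Structure
from complexeval.synthgen import (
    FixtureSpec,
    make_complex,
    make_displacement_pair,
    make_model,
)
from tests.conftest import NO_STEREO, random_rotation, rigid_transform, single_atom_chain


def one_chain_structure(xs, chain_id="A"):
    return Structure(
        structure_id="s", chains=[single_atom_chain(chain_id, xs)]
    )


def naive_lddt(model, reference, mapping, params, interface_only=False):
    """Independent O(n^2) oracle over all reference atom pairs."""
    ref_atoms = []
    for chain in reference.polymer_chains:
        for res in chain.residues:
            for atom in res.atoms:
                ref_atoms.append((chain.chain_id, res.number, atom.name, atom.position))
    model_pos = {}
    ref_of = {m: r for m, r in mapping.pairs}
    for chain in model.polymer_chains:
        if chain.chain_id not in ref_of:
            continue
        for res in chain.residues:
            for atom in res.atoms:
                model_pos[(ref_of[chain.chain_id], res.number, atom.name)] = atom.position
    fractions = []
    for i in range(len(ref_atoms)):
        for j in range(i + 1, len(ref_atoms)):
            ci, ri, ni, pi = ref_atoms[i]
            cj, rj, nj, pj = ref_atoms[j]
            if (ci, ri) == (cj, rj):
                continue
            if interface_only and ci == cj:
                continue
            d_ref = math.dist(pi, pj)
            if d_ref > params.inclusion_radius:
                continue
            mi = model_pos.get((ci, ri, ni))
            mj = model_pos.get((cj, rj, nj))
            if mi is None or mj is None:
                fractions.append(0.0)
                continue
            err = abs(math.dist(mi, mj) - d_ref)
            fractions.append(
                sum(err <= t for t in params.thresholds) / len(params.thresholds)
            )
    if not fractions:
        return None
    return sum(fractions) / len(fractions)


class TestLDDT:
    def test_identical_is_one(self, homodimer):
        ref, _ = homodimer
        model = make_model(ref, "none")
        mapping = ChainMapping.identity(ref)
        score, per_residue = lddt(model, ref, mapping)
        assert score == 1.0
        assert all(v == 1.0 for v in per_residue.values())

    def test_three_atom_worked_case(self):
        # distances 4, 8, 4 -> model errors {0, 1.5, 1.5}
        ref = one_chain_structure([[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        model = one_chain_structure([[0, 0, 0], [4, 0, 0], [9.5, 0, 0]])
        mapping = ChainMapping(pairs=[("A", "A")])
        score, _ = lddt(model, ref, mapping, NO_STEREO)
        assert score == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_superposition_invariance(self, homodimer):
        ref, _ = homodimer
        model = make_model(ref, ("per_atom_noise", {"sigma": 0.4}), seed=8)
        mapping = ChainMapping.identity(ref)
        base, _ = lddt(model, ref, mapping, NO_STEREO)
        rng = np.random.default_rng(1)
        moved = rigid_transform(
            model, rotation=random_rotation(rng), translation=(5.0, -3.0, 11.0)
        )
        score, _ = lddt(moved, ref, mapping, NO_STEREO)
        assert score == pytest.approx(base, abs=1e-12)

    def test_missing_chain_penalty(self, homodimer):
        ref, _ = homodimer
        model = make_model(ref, ("drop_chain", {"k": 1}))
        mapping = map_chains(model, ref)
        score, _ = lddt(model, ref, mapping)
        assert score is not None and score < 1.0
        # oracle agreement on the penalized case
        assert score == pytest.approx(
            naive_lddt(model, ref, mapping, LDDTParams()), abs=1e-9
        )

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            ref, _ = make_complex(
                FixtureSpec(
                    seed=100 + trial, n_entities=1,
                    copies_per_entity=(2 if trial % 2 else 1,),
                    chain_length=int(rng.integers(15, 30)),
                )
            )
            model = make_model(
                ref, ("per_atom_noise", {"sigma": float(rng.uniform(0.2, 1.5))}),
                seed=trial,
            )
            mapping = ChainMapping.identity(ref)
            score, _ = lddt(model, ref, mapping, NO_STEREO)
            assert score == pytest.approx(
                naive_lddt(model, ref, mapping, NO_STEREO), abs=1e-9
            )

    def test_dropping_model_chain_never_raises_score(self, homodimer):
        ref, _ = homodimer
        model = make_model(ref, ("per_atom_noise", {"sigma": 0.5}), seed=4)
        full_mapping = ChainMapping.identity(ref)
        full, _ = lddt(model, ref, full_mapping, NO_STEREO)
        dropped = make_model(model, ("drop_chain", {"k": 1}))
        part_mapping = ChainMapping(pairs=[("A", "A")])
        part, _ = lddt(dropped, ref, part_mapping, NO_STEREO)
        assert part <= full + 1e-12

    def test_empty_distance_set_undefined(self):
        ref = one_chain_structure([[0, 0, 0]])
        model = one_chain_structure([[0, 0, 0]])
        score, per_residue = lddt(model, ref, ChainMapping(pairs=[("A", "A")]), NO_STEREO)
        assert score is None

    def test_stereo_filter_removes_clashing_atoms(self):
        ref = one_chain_structure([[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        # model: residues 2 and 3 collapse onto each other (0.5 A apart)
        model = one_chain_structure([[0, 0, 0], [4, 0, 0], [4.5, 0, 0]])
        mapping = ChainMapping(pairs=[("A", "A")])
        with_check, _ = lddt(model, ref, mapping, LDDTParams(stereo_check=True))
        without, _ = lddt(model, ref, mapping, NO_STEREO)
        # the clashing pair is removed and scores 0 at every distance it touches
        assert with_check < without


class TestILDDT:
    def test_monomer_undefined(self):
        ref = one_chain_structure([[0, 0, 0], [4, 0, 0]])
        model = one_chain_structure([[0, 0, 0], [4, 0, 0]])
        assert ilddt(model, ref, ChainMapping(pairs=[("A", "A")]), NO_STEREO) is None

    def test_identical_dimer_is_one(self, homodimer):
        ref, _ = homodimer
        model = make_model(ref, "none")
        assert ilddt(model, ref, ChainMapping.identity(ref)) == 1.0

    def test_shifted_chain_zeroes_interface(self, homodimer):
        ref, _ = homodimer
        # pull chain B straight away from A, far enough that every interface
        # distance grows by more than the largest threshold
        model = make_model(
            ref, ("rigid_shift", {"d": 15.0, "chain": "B", "direction": (-1, 0, 0)})
        )
        score = ilddt(model, ref, ChainMapping.identity(ref), NO_STEREO)
        assert score == pytest.approx(0.0, abs=1e-12)
        # intra-chain geometry is intact, so complex LDDT stays well above 0
        full, _ = lddt(model, ref, ChainMapping.identity(ref), NO_STEREO)
        assert full > 0.3

    def test_oracle_equivalence(self, homodimer):
        ref, _ = homodimer
        model = make_model(ref, ("per_atom_noise", {"sigma": 0.8}), seed=9)
        mapping = ChainMapping.identity(ref)
        assert ilddt(model, ref, mapping, NO_STEREO) == pytest.approx(
            naive_lddt(model, ref, mapping, NO_STEREO, interface_only=True), abs=1e-9
        )


class TestTMScore:
    def test_rigid_transform_scores_one(self, homodimer):
        ref, _ = homodimer
        rng = np.random.default_rng(2)
        model = rigid_transform(
            make_model(ref, "none"), rotation=random_rotation(rng),
            translation=(20.0, 5.0, -7.0),
        )
        score = tm_score(model, ref, ChainMapping.identity(ref))
        assert score == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("d", [1.0, 2.0, 5.0])
    def test_uniform_displacement_closed_form(self, d):
        ref, model = make_displacement_pair(d)
        score = tm_score(model, ref, ChainMapping(pairs=[("A", "A")]))
        d0 = tm_d0(640)
        assert score == pytest.approx(1.0 / (1.0 + (d / d0) ** 2), abs=1e-6)

    def test_missing_residues_bound(self):
        # half the reference residues absent: their terms contribute 0
        n = 40
        xs = [[3.8 * i, 0.0, 0.0] for i in range(n)]
        ref = one_chain_structure(xs)
        model = one_chain_structure(xs[: n // 2])
        score = tm_score(model, ref, ChainMapping(pairs=[("A", "A")]))
        assert score == pytest.approx(0.5, abs=1e-9)

    def test_monotone_under_deletion(self):
        n = 30
        rng = np.random.default_rng(6)
        xs = [[3.8 * i, float(rng.normal(0, 0.5)), 0.0] for i in range(n)]
        ref = one_chain_structure(xs)
        model = one_chain_structure(xs)
        mapping = ChainMapping(pairs=[("A", "A")])
        prev = tm_score(model, ref, mapping)
        for keep in (25, 18, 10):
            smaller = one_chain_structure(xs[:keep])
            score = tm_score(smaller, ref, mapping)
            assert score <= prev + 1e-9
            prev = score

    def test_too_few_positions_undefined(self):
        ref = one_chain_structure([[0, 0, 0], [3.8, 0, 0]])
        model = one_chain_structure([[0, 0, 0], [3.8, 0, 0]])
        assert tm_score(model, ref, ChainMapping(pairs=[("A", "A")])) is None


class TestSuperpose:
    def test_recovers_random_rigid_transform(self):
        rng = np.random.default_rng(12)
        P = rng.normal(size=(20, 3))
        R = random_rotation(rng)
        Q = P @ R.T + np.array([1.0, -2.0, 3.0])
        sup = superpose(P, Q)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


class TestLDDTPLI:
    def test_identical_pose_is_one(self, benzene_complex):
        ref, _ = benzene_complex
        model = make_model(ref, "none")
        mapping = ChainMapping.identity(ref)
        pair = (ref.ligand_chains[0].chain_id,) * 2
        assert lddt_pli(model, ref, pair, mapping) == 1.0

    def test_displaced_ligand_scores_zero(self, benzene_complex):
        ref, _ = benzene_complex
        model = make_model(
            ref, ("rigid_shift", {"d": 20.0, "chain": ref.ligand_chains[0].chain_id})
        )
        mapping = ChainMapping.identity(ref)
        pair = (ref.ligand_chains[0].chain_id,) * 2
        assert lddt_pli(model, ref, pair, mapping) == pytest.approx(0.0, abs=1e-12)

    def test_automorphism_permuted_pose_is_one(self, benzene_complex):
        ref, _ = benzene_complex
        model = make_model(ref, "none")
        lig = model.ligand_chains[0]
        graph = LigandGraph.from_chain(lig)
        perms, _ = ligand_automorphisms(graph)
        nontrivial = perms[5]
        positions = [a.position.copy() for a in lig.residues[0].atoms]
        for i, atom in enumerate(lig.residues[0].atoms):
            atom.position = positions[nontrivial[i]]
        mapping = ChainMapping.identity(ref)
        pair = (lig.chain_id, lig.chain_id)
        assert lddt_pli(model, ref, pair, mapping) == pytest.approx(1.0, abs=1e-12)

    def test_no_contacts_undefined(self):
        ref, _ = make_complex(
            FixtureSpec(seed=31, n_entities=1, copies_per_entity=(1,),
                        chain_length=40, ligands=("O",))
        )
        # push the reference ligand far out: no polymer contact remains
        far = copy.deepcopy(ref)
        for atom in far.ligand_chains[0].residues[0].atoms:
            atom.position = atom.position + np.array([100.0, 0, 0])
        model = make_model(far, "none")
        pair = (far.ligand_chains[0].chain_id,) * 2
        assert lddt_pli(model, far, pair, ChainMapping.identity(far)) is None


class TestBiSyRMSD:
    def test_identical_complex_zero(self, benzene_complex):
        ref, _ = benzene_complex
        model = make_model(ref, "none")
        pair = (ref.ligand_chains[0].chain_id,) * 2
        assert bisy_rmsd(model, ref, pair, ChainMapping.identity(ref)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_translated_ligand_equals_translation(self, benzene_complex):
        ref, _ = benzene_complex
        lig_id = ref.ligand_chains[0].chain_id
        model = make_model(ref, ("rigid_shift", {"d": 2.5, "chain": lig_id}))
        pair = (lig_id, lig_id)
        value = bisy_rmsd(model, ref, pair, ChainMapping.identity(ref))
        assert value == pytest.approx(2.5, abs=1e-9)

    def test_symmetry_correction_beats_identity_correspondence(self, benzene_complex):
        ref, _ = benzene_complex
        model = make_model(ref, "none")
        lig = model.ligand_chains[0]
        graph = LigandGraph.from_chain(lig)
        perms, _ = ligand_automorphisms(graph)
        positions = [a.position.copy() for a in lig.residues[0].atoms]
        for i, atom in enumerate(lig.residues[0].atoms):
            atom.position = positions[perms[3][i]]
        pair = (lig.chain_id, lig.chain_id)
        corrected = bisy_rmsd(model, ref, pair, ChainMapping.identity(ref))
        identity_only = bisy_rmsd(
            model, ref, pair, ChainMapping.identity(ref),
            automorphisms=[tuple(range(6))],
        )
        assert corrected == pytest.approx(0.0, abs=1e-9)
        assert corrected <= identity_only

    def test_asymmetric_ligand_equals_identity_rmsd(self):
        ref, _ = make_complex(
            FixtureSpec(seed=33, n_entities=1, copies_per_entity=(1,),
                        chain_length=40, ligands=("CCO",))
        )
        model = make_model(ref, ("per_atom_noise", {"sigma": 0.3}), seed=1)
        lig_id = ref.ligand_chains[0].chain_id
        pair = (lig_id, lig_id)
        mapping = ChainMapping.identity(ref)
        corrected = bisy_rmsd(model, ref, pair, mapping)
        identity_only = bisy_rmsd(model, ref, pair, mapping,
                                  automorphisms=[(0, 1, 2)])
        assert corrected == pytest.approx(identity_only, abs=1e-12)
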