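"""Assembly selection, score aggregation and per-target reports.

A reference entry may define several biological assemblies; the model is
scored against all of them.  Polymer scores are reported against the
assembly with the highest complex LDDT; ligand scores against the assembly
scoring the most ligands (ties: higher summed LDDT-PLI, then lower summed
BiSyRMSD, then lowest assembly id).  Mapped-score variants recompute LDDT
and iLDDT on the mapped reference chains only, removing the missing-chain
penalty.  Undefined scores stay ``None`` with a reason code — averaging
them in as zero would conflate "wrong" with "not defined".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, LDDTParams, RunConfig
from .mapping import ChainMapping, LigandMapping, map_chains, map_ligands
from .scores import PoseScore, bisy_rmsd, ilddt, lddt, lddt_pli, tm_score
from .structio import Structure

__all__ = [
    "AssemblyChoice",
    "AssemblyResult",
    "ScoreReport",
    "score_against_assembly",
    "select_assembly",
    "choose_assemblies",
    "mapped_scores",
    "weighted_pli",
    "success_fraction",
    "best_pose_per_entity",
    "common_subset",
    "evaluate_model",
]


@dataclass
class AssemblyChoice:
    polymer_assembly: str
    ligand_assembly: str
    rationale: str


@dataclass
class AssemblyResult:
    """All scores of one model against one reference assembly."""

    assembly_id: str
    mapping: ChainMapping
    lddt: float | None
    per_residue: dict
    ilddt: float | None
    tm: float | None
    ligand_mapping: LigandMapping
    per_ligand: list[PoseScore] = field(default_factory=list)

    @property
    def n_ligands_scored(self) -> int:
        return sum(
            1 for p in self.per_ligand
            if p.lddt_pli is not None or p.bisy_rmsd is not None
        )

    @property
    def sum_pli(self) -> float:
        return sum(p.lddt_pli for p in self.per_ligand if p.lddt_pli is not None)

    @property
    def sum_bisy(self) -> float:
        return sum(p.bisy_rmsd for p in self.per_ligand if p.bisy_rmsd is not None)


def score_against_assembly(
    model: Structure,
    reference: Structure,
    config: RunConfig = DEFAULT_CONFIG,
) -> AssemblyResult:
    """Map chains and ligands, then compute every per-assembly score."""
    mapping = map_chains(model, reference, config=config)
    lddt_val, per_res = lddt(model, reference, mapping, config.lddt)
    ilddt_val = ilddt(model, reference, mapping, config.lddt)
    tm_val = tm_score(model, reference, mapping)

    def pose_score(model_cid: str, ref_cid: str) -> float | None:
        return lddt_pli(
            model, reference, (model_cid, ref_cid), mapping,
            params=config.lddt, inclusion_radius=config.pli_inclusion_radius,
        )

    lig_mapping = map_ligands(model.ligand_chains, reference.ligand_chains, pose_score)
    per_ligand: list[PoseScore] = []
    model_for = dict((r, m) for m, r in lig_mapping.pairs)
    for ref_lig in sorted(reference.ligand_chains, key=lambda c: c.chain_id):
        heavy = sum(1 for a in ref_lig.residues[0].atoms if a.element != "H")
        mcid = model_for.get(ref_lig.chain_id)
        if mcid is None:
            per_ligand.append(
                PoseScore(
                    ligand_ref=ref_lig.chain_id, lddt_pli=None, bisy_rmsd=None,
                    heavy_atoms=heavy, model_ligand=None,
                    entity_id=ref_lig.entity_ref,
                )
            )
            continue
        pair = (mcid, ref_lig.chain_id)
        per_ligand.append(
            PoseScore(
                ligand_ref=ref_lig.chain_id,
                lddt_pli=pose_score(*pair),
                bisy_rmsd=bisy_rmsd(
                    model, reference, pair, mapping, site_radius=config.site_radius
                ),
                heavy_atoms=heavy,
                model_ligand=mcid,
                entity_id=ref_lig.entity_ref,
            )
        )
    return AssemblyResult(
        assembly_id=reference.assembly_id or reference.structure_id,
        mapping=mapping,
        lddt=lddt_val,
        per_residue=per_res,
        ilddt=ilddt_val,
        tm=tm_val,
        ligand_mapping=lig_mapping,
        per_ligand=per_ligand,
    )


def select_assembly(
    model: Structure,
    assemblies: Sequence[Structure],
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[AssemblyChoice, dict[str, AssemblyResult]]:
    """Choose the reporting assemblies after scoring the model against all.

    Polymer choice: highest complex LDDT.  Ligand choice: most ligands
    scored, ties broken by higher summed LDDT-PLI, then lower summed
    BiSyRMSD, then lowest assembly id.
    """
    if not assemblies:
        raise ValueError("at least one assembly required")
    results = {}
    for asm in assemblies:
        res = score_against_assembly(model, asm, config)
        results[res.assembly_id] = res
    return choose_assemblies(results), results


def choose_assemblies(results: Mapping[str, AssemblyResult]) -> AssemblyChoice:
    """Apply the assembly-selection rules to per-assembly results."""
    if len(results) == 1:
        only = next(iter(results))
        return AssemblyChoice(only, only, "only assembly")

    def polymer_key(aid: str):
        r = results[aid]
        return (-(r.lddt if r.lddt is not None else -1.0), aid)

    def ligand_key(aid: str):
        r = results[aid]
        return (-r.n_ligands_scored, -r.sum_pli, r.sum_bisy, aid)

    polymer_aid = min(results, key=polymer_key)
    ligand_aid = min(results, key=ligand_key)
    return AssemblyChoice(
        polymer_aid,
        ligand_aid,
        f"polymer: highest LDDT ({polymer_aid}); "
        f"ligand: most ligands scored with tie-breaks ({ligand_aid})",
    )


def mapped_scores(
    model: Structure,
    reference: Structure,
    mapping: ChainMapping,
    params: LDDTParams = LDDTParams(),
) -> tuple[float | None, float | None]:
    """LDDT / iLDDT recomputed on initially mapped reference chains only.

    Both are ``None`` for an empty mapping; mapped iLDDT is ``None`` when
    the mapped substructure has no inter-chain contact (e.g., a monomeric
    prediction of an oligomer).
    """
    if not mapping.pairs:
        return None, None
    mapped_ref_ids = [r for _, r in mapping.pairs]
    sub = reference.subset(
        mapped_ref_ids + [c.chain_id for c in reference.ligand_chains]
    )
    m_lddt, _ = lddt(model, sub, mapping, params)
    m_ilddt = ilddt(model, sub, mapping, params)
    return m_lddt, m_ilddt


def weighted_pli(per_ligand: Sequence[PoseScore]) -> float | None:
    """Heavy-atom-weighted mean LDDT-PLI — keeps ions from dominating."""
    pairs = [
        (p.heavy_atoms, p.lddt_pli) for p in per_ligand if p.lddt_pli is not None
    ]
    if not pairs:
        return None
    total_w = sum(w for w, _ in pairs)
    return sum(w * s for w, s in pairs) / total_w


def success_fraction(
    per_ligand: Sequence[PoseScore],
    n_reference_ligands: int,
    threshold: float,
) -> float | None:
    """Fraction of reference ligands with BiSyRMSD strictly below threshold.

    Unpredicted ligands (undefined RMSD) count as failures: the denominator
    is the total number of ligands in the target.
    """
    if n_reference_ligands < 1:
        return None
    ok = sum(
        1 for p in per_ligand if p.bisy_rmsd is not None and p.bisy_rmsd < threshold
    )
    return ok / n_reference_ligands


def best_pose_per_entity(
    per_ligand: Sequence[PoseScore],
    entity_of: Mapping[str, str] | None = None,
) -> list[PoseScore]:
    """Best-scored pose per ligand entity (no multi-copy penalty).

    Keeps the pose with the lowest BiSyRMSD per entity (ties: highest
    LDDT-PLI); entities with no scored copy are absent from the result and
    count as failures downstream.
    """
    best: dict[str, PoseScore] = {}
    for pose in per_ligand:
        if pose.bisy_rmsd is None and pose.lddt_pli is None:
            continue
        entity = (
            entity_of[pose.ligand_ref] if entity_of is not None else pose.entity_id
        ) or pose.ligand_ref
        cur = best.get(entity)
        if cur is None:
            best[entity] = pose
            continue
        key = (
            np.inf if pose.bisy_rmsd is None else pose.bisy_rmsd,
            -(pose.lddt_pli if pose.lddt_pli is not None else -np.inf),
        )
        cur_key = (
            np.inf if cur.bisy_rmsd is None else cur.bisy_rmsd,
            -(cur.lddt_pli if cur.lddt_pli is not None else -np.inf),
        )
        if key < cur_key:
            best[entity] = pose
    return [best[k] for k in sorted(best)]


def common_subset(
    results: Mapping[str, Mapping[str, Mapping[str, float | None]]],
    selected: Sequence[str],
) -> pd.DataFrame:
    """Compare servers on the intersection of their predicted target sets.

    ``results[server][target][metric]`` holds per-target scores.  Returns a
    long-format table (server, metric, n, mean, median) over the common
    subset; undefined scores are excluded from the statistics, not zeroed.
    """
    if not selected:
        raise ValueError("at least one server required")
    common: set[str] | None = None
    for server in selected:
        targets = set(results.get(server, {}))
        common = targets if common is None else common & targets
    common = common or set()
    rows = []
    for server in selected:
        metrics: dict[str, list[float]] = {}
        for tid in common:
            for metric, value in results[server][tid].items():
                if value is not None:
                    metrics.setdefault(metric, []).append(value)
        for metric in sorted(metrics):
            vals = metrics[metric]
            rows.append(
                {
                    "server": server,
                    "metric": metric,
                    "n_targets": len(common),
                    "n_defined": len(vals),
                    "mean": float(np.mean(vals)),
                    "median": float(np.median(vals)),
                }
            )
        if not metrics:
            rows.append(
                {
                    "server": server, "metric": "", "n_targets": len(common),
                    "n_defined": 0, "mean": np.nan, "median": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=[
        "server", "metric", "n_targets", "n_defined", "mean", "median",
    ])


# ---------------------------------------------------------------------------
# per-target report
# ---------------------------------------------------------------------------

_REASONS = {
    "ilddt": "no_interchain_contacts",
    "mapped_ilddt": "no_interchain_contacts_in_mapped_subset",
    "lddt_pli_weighted": "no_ligand_with_defined_pli",
    "tm": "fewer_than_3_mapped_backbone_positions",
}


@dataclass
class ScoreReport:
    """All per-target scores of one submitted model."""

    target_id: str
    server_id: str
    model_rank: int
    assembly_choice: AssemblyChoice
    lddt: float | None
    mapped_lddt: float | None
    ilddt: float | None
    mapped_ilddt: float | None
    tm: float | None
    lddt_pli_weighted: float | None
    success_fracs: dict[float, float | None]
    per_ligand: list[PoseScore]
    best_per_entity: list[PoseScore]
    oligo_state_predicted: int
    oligo_state_reference: int

    def to_dict(self) -> dict:
        def pose(p: PoseScore) -> dict:
            return {
                "ligand_ref": p.ligand_ref,
                "model_ligand": p.model_ligand,
                "entity_id": p.entity_id,
                "lddt_pli": p.lddt_pli,
                "bisy_rmsd": p.bisy_rmsd,
                "heavy_atoms": p.heavy_atoms,
            }

        doc = {
            "target_id": self.target_id,
            "server_id": self.server_id,
            "model_rank": self.model_rank,
            "assembly": {
                "polymer": self.assembly_choice.polymer_assembly,
                "ligand": self.assembly_choice.ligand_assembly,
                "rationale": self.assembly_choice.rationale,
            },
            "scores": {
                "lddt": self.lddt,
                "mapped_lddt": self.mapped_lddt,
                "ilddt": self.ilddt,
                "mapped_ilddt": self.mapped_ilddt,
                "tm": self.tm,
                "lddt_pli_weighted": self.lddt_pli_weighted,
            },
            "success_fractions": {
                f"{thr:g}A": val for thr, val in sorted(self.success_fracs.items())
            },
            "per_ligand": [pose(p) for p in self.per_ligand],
            "best_per_entity": [pose(p) for p in self.best_per_entity],
            "oligo_state": {
                "predicted": self.oligo_state_predicted,
                "reference": self.oligo_state_reference,
            },
            "undefined_reasons": {
                name: _REASONS.get(name, "undefined")
                for name, value in (
                    ("lddt", self.lddt),
                    ("mapped_lddt", self.mapped_lddt),
                    ("ilddt", self.ilddt),
                    ("mapped_ilddt", self.mapped_ilddt),
                    ("tm", self.tm),
                    ("lddt_pli_weighted", self.lddt_pli_weighted),
                )
                if value is None
            },
        }
        return doc

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def evaluate_model(
    model: Structure,
    assemblies: Sequence[Structure],
    config: RunConfig = DEFAULT_CONFIG,
    target_id: str = "",
    server_id: str = "",
    model_rank: int = 1,
) -> ScoreReport:
    """Score one model against all assemblies and assemble the report."""
    choice, results = select_assembly(model, assemblies, config)
    poly = results[choice.polymer_assembly]
    lig = results[choice.ligand_assembly]
    poly_ref = next(
        a for a in assemblies
        if (a.assembly_id or a.structure_id) == choice.polymer_assembly
    )
    m_lddt, m_ilddt = mapped_scores(model, poly_ref, poly.mapping, config.lddt)
    n_ref_ligands = len(lig.per_ligand)
    fracs = {
        thr: success_fraction(lig.per_ligand, n_ref_ligands, thr)
        if n_ref_ligands else None
        for thr in config.success_thresholds
    }
    return ScoreReport(
        target_id=target_id or poly_ref.structure_id,
        server_id=server_id,
        model_rank=model_rank,
        assembly_choice=choice,
        lddt=poly.lddt,
        mapped_lddt=m_lddt,
        ilddt=poly.ilddt,
        mapped_ilddt=m_ilddt,
        tm=poly.tm,
        lddt_pli_weighted=weighted_pli(lig.per_ligand),
        success_fracs=fracs,
        per_ligand=lig.per_ligand,
        best_per_entity=best_pose_per_entity(lig.per_ligand),
        oligo_state_predicted=len(model.polymer_chains),
        oligo_state_reference=len(poly_ref.polymer_chains),
    )
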