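"""High-level entry points mirroring the benchmark's workflows.

These are thin orchestration wrappers over the library modules, used by the
scripts in examples/ (the package is used from Python; there is no shell
command).  All outputs are deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from .aggregate import ScoreReport, common_subset, evaluate_model
from .classify import classify_targets, parse_hit_table
from .config import DEFAULT_CONFIG, RunConfig
from .ligcat import categorize_table
from .structio import Structure, read_structure, read_target_record
from .synthgen import FixtureSpec, make_classification_set, make_complex, make_model

__all__ = [
    "run_classify",
    "run_score",
    "run_summarize",
    "run_ligcat",
    "run_simulate",
]


def run_classify(
    target_paths: Sequence[str | Path],
    hits_path: str | Path,
    lengths_path: str | Path,
    entity_kind: Mapping[str, str],
    template_ligand_sets: Mapping[str, frozenset[str]] | None = None,
    out_path: str | Path | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict:
    """Classify target records against an external hit table."""
    targets = [read_target_record(p) for p in target_paths]
    lengths: dict[str, int] = {}
    for line in Path(lengths_path).read_text().splitlines():
        if line.strip():
            key, value = line.split("\t")
            lengths[key] = int(value)
    hits = parse_hit_table(hits_path, lengths)
    report = classify_targets(
        targets, hits, entity_kind, template_ligand_sets, config=config
    )
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report


def run_score(
    model_path: str | Path,
    assembly_paths: Sequence[str | Path],
    out_path: str | Path | None = None,
    config: RunConfig = DEFAULT_CONFIG,
    server_id: str = "",
) -> ScoreReport:
    """Score one model file against all reference assemblies of its entry."""
    model = read_structure(model_path, role="model")
    assemblies = []
    for i, p in enumerate(assembly_paths):
        asm = read_structure(p, role="reference")
        asm.assembly_id = asm.assembly_id or f"assembly_{i + 1}"
        assemblies.append(asm)
    report = evaluate_model(model, assemblies, config=config, server_id=server_id)
    if out_path is not None:
        Path(out_path).write_text(report.to_json() + "\n")
    return report


def run_summarize(
    report_paths: Mapping[str, Sequence[str | Path]],
    servers: Sequence[str],
    out_path: str | Path | None = None,
):
    """Common-subset comparison table from per-target report files.

    ``report_paths[server]`` lists that server's JSON reports (one per
    target, as written by :func:`run_score`).
    """
    results: dict[str, dict[str, dict[str, float | None]]] = {}
    for server, paths in report_paths.items():
        per_target = {}
        for p in paths:
            doc = json.loads(Path(p).read_text())
            per_target[doc["target_id"]] = doc["scores"]
        results[server] = per_target
    table = common_subset(results, servers)
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table


def run_ligcat(
    smiles_table_path: str | Path,
    lists_dir: str | Path | None = None,
    occurrence_path: str | Path | None = None,
    out_path: str | Path | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, str]:
    """Categorize a TSV of component_id<TAB>SMILES rows."""
    from .ligcat import load_category_lists, load_occurrence_table

    smiles: dict[str, str] = {}
    for line in Path(smiles_table_path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            comp, smi = line.split("\t")
            smiles[comp] = smi
    table = categorize_table(
        smiles,
        lists=load_category_lists(lists_dir),
        occurrence=load_occurrence_table(occurrence_path),
        config=config,
    )
    if out_path is not None:
        lines = ["component_id,category"] + [f"{k},{v}" for k, v in sorted(table.items())]
        Path(out_path).write_text("\n".join(lines) + "\n")
    return table


def run_simulate(spec: FixtureSpec, out_dir: str | Path) -> None:
    """Write a synthetic reference, perturbed model, and target record."""
    from .structio import write_structure, write_target_record

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference, target = make_complex(spec)
    model = make_model(reference, spec.perturbation, seed=spec.seed)
    write_structure(reference, out_dir / "reference.cif")
    write_structure(model, out_dir / "model.cif")
    write_target_record(target, out_dir / "target.json")
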