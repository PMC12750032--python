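"""Ligand categorization: drug-like / cofactor / ion / artifact / other.

Ions, cofactors and crystallization artifacts are recognized from curated
component-ID lists; what remains is *drug-like* when it satisfies Lipinski's
Rule of Five and occurs in fewer than 100 PDB entries (occurrence counts are
a user-supplied table, not a live query), and *other* otherwise (mostly
metabolites, sugars and lipids).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .config import DEFAULT_CONFIG, RunConfig
from .structio import ValidationError

__all__ = [
    "LigandDescriptors",
    "CategoryLists",
    "descriptors_from_smiles",
    "lipinski_pass",
    "categorize",
    "load_category_lists",
    "load_occurrence_table",
]

CATEGORIES = ("drug_like", "cofactor", "ion", "artifact", "other")


@dataclass
class LigandDescriptors:
    component_id: str
    mol_weight: float
    hbd: int
    hba: int
    logp: float
    heavy_atoms: int
    pdb_occurrence: int | None = None

    def __post_init__(self) -> None:
        if self.hbd < 0 or self.hba < 0 or self.heavy_atoms < 0:
            raise ValidationError("descriptor counts must be non-negative")


@dataclass
class CategoryLists:
    ions: frozenset[str]
    cofactors: frozenset[str]
    artifacts: frozenset[str]

    def __post_init__(self) -> None:
        overlap = (self.ions & self.cofactors) | (self.ions & self.artifacts) | (
            self.cofactors & self.artifacts
        )
        if overlap:
            raise ValidationError(f"category lists overlap: {sorted(overlap)}")


def load_category_lists(directory: str | Path | None = None) -> CategoryLists:
    """Load ion/cofactor/artifact component-ID lists (one ID per line).

    Without a directory, the small bundled example lists are used.
    """

    def read(name: str) -> frozenset[str]:
        if directory is None:
            text = resources.files("complexeval.data").joinpath(name).read_text()
        else:
            text = (Path(directory) / name).read_text()
        return frozenset(
            line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        )

    return CategoryLists(
        ions=read("ions.txt"),
        cofactors=read("cofactors.txt"),
        artifacts=read("artifacts.txt"),
    )


def load_occurrence_table(path: str | Path | None = None) -> dict[str, int]:
    """Component-ID -> number of PDB entries containing it (TSV)."""
    if path is None:
        text = resources.files("complexeval.data").joinpath("occurrence.tsv").read_text()
    else:
        text = Path(path).read_text()
    out: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        comp, count = line.split("\t")
        out[comp] = int(count)
    return out


def descriptors_from_smiles(smiles: str, component_id: str = "") -> LigandDescriptors:
    """Compute Lipinski descriptors with RDKit (occurrence left unset)."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    return LigandDescriptors(
        component_id=component_id,
        mol_weight=float(Descriptors.MolWt(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NumHAcceptors(mol)),
        logp=float(Crippen.MolLogP(mol)),
        heavy_atoms=int(mol.GetNumHeavyAtoms()),
    )


def lipinski_pass(
    d: LigandDescriptors, allow_one_violation: bool = False
) -> bool:
    """Rule of Five: MW < 500 Da, HBD <= 5, HBA <= 10, logP <= 5.

    The strict reading requires all four; the classic "at most one
    violation" variant is available as a switch.
    """
    violations = sum(
        (d.mol_weight >= 500.0, d.hbd > 5, d.hba > 10, d.logp > 5.0)
    )
    return violations <= (1 if allow_one_violation else 0)


def categorize(
    d: LigandDescriptors,
    lists: CategoryLists,
    config: RunConfig = DEFAULT_CONFIG,
) -> str:
    """Assign exactly one category with precedence ion > cofactor > artifact
    > drug-like > other.

    Drug-like additionally requires a known occurrence below
    ``config.drug_like_max_occurrence`` ("fewer than 100 PDB entries").
    """
    if d.component_id in lists.ions:
        return "ion"
    if d.component_id in lists.cofactors:
        return "cofactor"
    if d.component_id in lists.artifacts:
        return "artifact"
    if (
        lipinski_pass(d, config.lipinski_allow_one_violation)
        and d.pdb_occurrence is not None
        and d.pdb_occurrence < config.drug_like_max_occurrence
    ):
        return "drug_like"
    return "other"


def categorize_table(
    smiles_by_component: Mapping[str, str],
    lists: CategoryLists | None = None,
    occurrence: Mapping[str, int] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, str]:
    """Categorize a table of component-ID -> SMILES in one call."""
    lists = lists if lists is not None else load_category_lists()
    occurrence = occurrence if occurrence is not None else load_occurrence_table()
    out: dict[str, str] = {}
    for comp, smiles in sorted(smiles_by_component.items()):
        d = descriptors_from_smiles(smiles, component_id=comp)
        d.pdb_occurrence = occurrence.get(comp)
        out[comp] = categorize(d, lists, config)
    return out
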