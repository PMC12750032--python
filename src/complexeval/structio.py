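"""Structures, target records, sequence derivation and reference eligibility.

The unit of evaluation is a :class:`Structure`: chains of residues of atoms,
where every non-polymer (ligand) component is carried as its own
single-residue chain of kind ``ligand``.  Model structures are expected to be
numbered according to the target sequence (1-based); reference structures
read from the wet lab may carry author numbering and insertion codes and can
be renumbered against the entity sequence by alignment.

Target records mirror the pre-release data that precedes a coordinate
release: per-entity polymer sequences with copy counts, and ligand component
IDs with SMILES — no coordinates.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ExperimentMeta",
    "PolymerEntity",
    "NonPolymerEntity",
    "TargetComplex",
    "FormatError",
    "ValidationError",
    "read_structure",
    "write_structure",
    "read_target_record",
    "write_target_record",
    "derive_canonical",
    "sequence_alphabet",
    "classify_entity_kind",
    "reference_eligible",
    "default_parent_map",
    "renumber_chain_to_sequence",
    "infer_element",
]


class FormatError(ValueError):
    """A file could not be parsed in the named dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# chemical vocabulary
# ---------------------------------------------------------------------------

ELEMENTS = frozenset(
    "H HE LI BE B C N O F NE NA MG AL SI P S CL AR K CA SC TI V CR MN FE CO NI "
    "CU ZN GA GE AS SE BR KR RB SR Y ZR NB MO TC RU RH PD AG CD IN SN SB TE I "
    "XE CS BA LA CE PR ND PM SM EU GD TB DY HO ER TM YB LU HF TA W RE OS IR PT "
    "AU HG TL PB BI PO AT RN FR RA AC TH PA U NP PU AM CM BK CF ES FM MD NO LR "
    "RF DB SG BH HS MT DS RG CN NH FL MC LV TS OG D".split()
)

AMINO_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
DNA_ONE_LETTER = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "DI": "I", "DU": "U"}
RNA_ONE_LETTER = {"A": "A", "C": "C", "G": "G", "U": "U", "I": "I"}

THREE_LETTER = {v: k for k, v in AMINO_ONE_LETTER.items()}

#: Sentinel parent classes used in parent maps.
UNKNOWN = "unknown"
NON_LINKING = "non-linking"
ORPHAN = "orphan"

WATER_COMPONENTS = frozenset({"HOH", "DOD", "WAT"})
# common mono-saccharides; chains made of these are oligosaccharide entities
SACCHARIDE_COMPONENTS = frozenset(
    {"NAG", "NDG", "MAN", "BMA", "GAL", "GLA", "GLC", "BGC", "FUC", "FUL",
     "SIA", "XYS", "RIB", "A2G", "GCU", "IDS"}
)

BACKBONE_ATOMS = frozenset({"CA", "C4'", "P"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """One atom: name, element symbol and Cartesian position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.name}: non-finite position")
        if self.element.upper() not in ELEMENTS:
            raise ValidationError(f"atom {self.name}: unknown element {self.element!r}")


@dataclass
class Residue:
    """A residue numbered by its 1-based position in the target sequence."""

    number: int
    component_id: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValidationError(
                f"residue {self.component_id} {self.number}: duplicate atom names"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    entity_ref: str
    residues: list[Residue] = field(default_factory=list)
    kind: str = "protein"  # protein | peptide | dna | rna | ligand

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValidationError(
                f"chain {self.chain_id}: residue numbers not strictly increasing"
            )

    @property
    def is_polymer(self) -> bool:
        return self.kind != "ligand"

    def one_letter_sequence(self) -> str:
        out = []
        for r in self.residues:
            c = AMINO_ONE_LETTER.get(r.component_id) or DNA_ONE_LETTER.get(
                r.component_id
            ) or RNA_ONE_LETTER.get(r.component_id)
            out.append(c or "X")
        return "".join(out)


@dataclass
class ExperimentMeta:
    method: str = "other"  # xray | nmr | em | other
    resolution: float | None = None
    n_polymer_chains: int = 0
    max_copies_single_entity: int = 0

    def __post_init__(self) -> None:
        if self.method in {"xray", "em"} and self.resolution is None:
            raise ValidationError(f"method {self.method} requires a resolution")


@dataclass
class Structure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    assembly_id: str = ""
    metadata: ExperimentMeta | None = None

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"structure {self.structure_id}: duplicate chain ids")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_polymer]

    @property
    def ligand_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.kind == "ligand"]

    def subset(self, chain_ids: Iterable[str], structure_id: str | None = None) -> "Structure":
        keep = set(chain_ids)
        return Structure(
            structure_id=structure_id or self.structure_id,
            chains=[c for c in self.chains if c.chain_id in keep],
            assembly_id=self.assembly_id,
            metadata=self.metadata,
        )


@dataclass
class PolymerEntity:
    entity_id: str
    noncanonical_seq: list[str]
    canonical_seq: str
    kind: str  # protein | peptide | dna | rna
    copy_count: int = 1

    def __post_init__(self) -> None:
        if self.copy_count < 1:
            raise ValidationError("copy_count must be >= 1")
        if len(self.canonical_seq) != len(self.noncanonical_seq):
            raise ValidationError(
                f"entity {self.entity_id}: canonical/non-canonical length mismatch"
            )


@dataclass
class NonPolymerEntity:
    entity_id: str
    component_id: str
    smiles: str
    copy_count: int = 1
    heavy_atom_count: int = 1

    def __post_init__(self) -> None:
        if self.copy_count < 1 or self.heavy_atom_count < 1:
            raise ValidationError("copy_count and heavy_atom_count must be >= 1")


@dataclass
class TargetComplex:
    target_id: str
    polymers: list[PolymerEntity] = field(default_factory=list)
    nonpolymers: list[NonPolymerEntity] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.polymers:
            raise ValidationError(f"target {self.target_id}: at least one polymer required")

    def polymer(self, entity_id: str) -> PolymerEntity:
        for e in self.polymers:
            if e.entity_id == entity_id:
                return e
        raise KeyError(entity_id)

    @property
    def ligand_component_set(self) -> frozenset[str]:
        return frozenset(e.component_id for e in self.nonpolymers)


# ---------------------------------------------------------------------------
# canonical sequence derivation and entity typing
# ---------------------------------------------------------------------------


def default_parent_map() -> dict[str, str]:
    """Bundled table of common modified residues (component -> parent).

    A full chemical-component-dictionary lookup can be supplied instead by
    passing any mapping with the same shape; sentinel parents are
    ``unknown``, ``non-linking`` and ``orphan``.
    """
    text = resources.files("complexeval.data").joinpath("modified_residues.tsv").read_text()
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        comp, parent = line.split("\t")
        out[comp] = parent
    return out


def _component_class(comp: str, parent_map: Mapping[str, str]) -> tuple[str, str]:
    """Resolve a component to (one_letter, class); raises nothing.

    Returns class in {amino, nucleic-dna, nucleic-rna} or a sentinel reason.
    """
    if comp in AMINO_ONE_LETTER:
        return AMINO_ONE_LETTER[comp], "amino"
    if comp in DNA_ONE_LETTER:
        return DNA_ONE_LETTER[comp], "nucleic-dna"
    if comp in RNA_ONE_LETTER:
        return RNA_ONE_LETTER[comp], "nucleic-rna"
    parent = parent_map.get(comp)
    if parent is None:
        return "", ORPHAN
    if parent in (UNKNOWN, NON_LINKING, ORPHAN):
        return "", parent
    # one level of indirection: parents must be standard components
    if parent in AMINO_ONE_LETTER:
        return AMINO_ONE_LETTER[parent], "amino"
    if parent in DNA_ONE_LETTER:
        return DNA_ONE_LETTER[parent], "nucleic-dna"
    if parent in RNA_ONE_LETTER:
        return RNA_ONE_LETTER[parent], "nucleic-rna"
    return "", ORPHAN


def derive_canonical(
    noncanonical_seq: list[str],
    parent_map: Mapping[str, str] | None = None,
) -> tuple[str, bool, str]:
    """Derive the canonical one-letter sequence of a polymer entity.

    Modified residues are substituted by their parent component.  The entity
    is invalid (``valid=False`` with a reason) when any component has no
    parent, is marked unknown or non-linking, or when the parents mix amino
    and nucleic acid classes.
    """
    if not noncanonical_seq:
        raise ValidationError("empty non-canonical sequence")
    parent_map = default_parent_map() if parent_map is None else parent_map
    letters: list[str] = []
    classes: set[str] = set()
    for comp in noncanonical_seq:
        letter, cls = _component_class(comp, parent_map)
        if cls == ORPHAN:
            return "", False, f"component {comp} has no parent in the dictionary"
        if cls == UNKNOWN:
            return "", False, f"component {comp} is marked unknown"
        if cls == NON_LINKING:
            return "", False, f"component {comp} is non-linking"
        letters.append(letter)
        classes.add("amino" if cls == "amino" else "nucleic")
    if len(classes) > 1:
        return "", False, "mix of nucleic and amino acid residues"
    return "".join(letters), True, ""


def sequence_alphabet(
    noncanonical_seq: list[str],
    parent_map: Mapping[str, str] | None = None,
) -> str:
    """Return ``amino``, ``nucleic-dna`` or ``nucleic-rna`` for a valid entity.

    Raises :class:`ValidationError` when the alphabet cannot be unambiguously
    assigned (e.g., a DNA/RNA hybrid).
    """
    parent_map = default_parent_map() if parent_map is None else parent_map
    classes = {_component_class(c, parent_map)[1] for c in noncanonical_seq}
    classes -= {ORPHAN, UNKNOWN, NON_LINKING}
    if classes == {"amino"}:
        return "amino"
    if classes == {"nucleic-dna"}:
        return "nucleic-dna"
    if classes == {"nucleic-rna"}:
        return "nucleic-rna"
    raise ValidationError(f"alphabet cannot be unambiguously assigned: {sorted(classes)}")


def classify_entity_kind(canonical: str, alphabet_class: str) -> str:
    """Protein (>= 30 aa), peptide (< 30 aa), DNA or RNA."""
    if alphabet_class == "amino":
        return "protein" if len(canonical) >= 30 else "peptide"
    if alphabet_class == "nucleic-dna":
        return "dna"
    if alphabet_class == "nucleic-rna":
        return "rna"
    raise ValidationError(f"unrecognized alphabet class {alphabet_class!r}")


def reference_eligible(
    meta: ExperimentMeta,
    em_resolution_cutoff: float = 4.0,
    max_polymer_chains: int = 200,
    max_copies_single_entity: int = 100,
) -> tuple[bool, str]:
    """Decide whether an experimental structure may serve as reference.

    Solution NMR and X-ray structures qualify unconditionally; EM only at
    high resolution.  Very large complexes are excluded regardless of method.
    """
    if meta.method == "em":
        if meta.resolution is None or meta.resolution > em_resolution_cutoff:
            res = "absent" if meta.resolution is None else f"{meta.resolution:g} A"
            return False, f"EM resolution {res} exceeds {em_resolution_cutoff:g} A"
    elif meta.method not in {"nmr", "xray"}:
        return False, f"method {meta.method!r} not accepted as reference"
    if meta.n_polymer_chains > max_polymer_chains:
        return False, f"{meta.n_polymer_chains} polymer chains exceed {max_polymer_chains}"
    if meta.max_copies_single_entity > max_copies_single_entity:
        return False, (
            f"{meta.max_copies_single_entity} copies of a single entity exceed "
            f"{max_copies_single_entity}"
        )
    return True, ""


# ---------------------------------------------------------------------------
# coordinate file I/O (biotite-backed)
# ---------------------------------------------------------------------------


def infer_element(atom_name: str, is_hetero: bool) -> str:
    """Infer the element from a PDB atom name when the element column is blank.

    Follows the v3.3 alignment convention: names starting with a digit are
    remoteness-prefixed (``1HB``); two-letter elements (ions, metals) occupy
    the full name of a hetero atom.
    """
    name = atom_name.strip()
    if not name:
        raise ValidationError("empty atom name")
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    if is_hetero and name[:2].upper() in ELEMENTS and len(name) >= 2 and name[1].isalpha():
        return name[:2].capitalize()
    return name[0].upper()


def _kind_from_components(component_ids: list[str]) -> str:
    classes = set()
    pm = default_parent_map()
    for comp in component_ids:
        _, cls = _component_class(comp, pm)
        classes.add(cls)
    if classes <= {"amino"}:
        return "protein" if len(component_ids) >= 30 else "peptide"
    if classes <= {"nucleic-dna"}:
        return "dna"
    if classes <= {"nucleic-rna"}:
        return "rna"
    return "ligand"


_LIGAND_CHAIN_SEP = "."


def ligand_chain_id(author_chain: str, res_id: int) -> str:
    return f"{author_chain}{_LIGAND_CHAIN_SEP}{res_id}"


def _from_atom_array(arr, structure_id: str, role: str) -> Structure:
    import biotite.structure as struc

    pm = default_parent_map()
    chains: list[Chain] = []
    for cid in np.unique(arr.chain_id):
        sub = arr[arr.chain_id == cid]
        polymer_residues: list[Residue] = []
        entity_components: list[str] = []
        ligand_chains: list[Chain] = []
        for (res_id, ins, res_name), lo, hi in _iter_residues(sub):
            res_atoms = sub[lo:hi]
            hetero = bool(res_atoms.hetero[0])
            if res_name in WATER_COMPONENTS:
                continue
            is_polymer_comp = _component_class(res_name, pm)[1] in (
                "amino", "nucleic-dna", "nucleic-rna",
            )
            if res_name in SACCHARIDE_COMPONENTS:
                warnings.warn(
                    f"dropping oligosaccharide component {res_name} in chain {cid}",
                    stacklevel=3,
                )
                continue
            atoms = [
                Atom(
                    name=str(a.atom_name),
                    element=(str(a.element).capitalize()
                             if str(a.element).strip()
                             else infer_element(str(a.atom_name), bool(a.hetero))),
                    position=np.array(a.coord, float),
                    is_hetero=bool(a.hetero),
                )
                for a in res_atoms
            ]
            if hetero and not is_polymer_comp:
                ligand_chains.append(
                    Chain(
                        chain_id=ligand_chain_id(str(cid), int(res_id)),
                        entity_ref=res_name,
                        residues=[Residue(number=1, component_id=res_name, atoms=atoms)],
                        kind="ligand",
                    )
                )
                continue
            if ins.strip() and role == "model":
                raise ValidationError(
                    f"chain {cid} residue {res_id}{ins}: insertion codes are not "
                    "allowed in model files (1-based target numbering required)"
                )
            number = int(res_id)
            if ins.strip():
                # reference with insertion codes: shift to keep strict ordering;
                # call renumber_chain_to_sequence for exact entity numbering
                number = (polymer_residues[-1].number + 1) if polymer_residues else number
            if polymer_residues and number <= polymer_residues[-1].number:
                number = polymer_residues[-1].number + 1
            polymer_residues.append(Residue(number=number, component_id=res_name, atoms=atoms))
            entity_components.append(res_name)
        if polymer_residues:
            chains.append(
                Chain(
                    chain_id=str(cid),
                    entity_ref="",
                    residues=polymer_residues,
                    kind=_kind_from_components(entity_components),
                )
            )
        chains.extend(ligand_chains)
    return Structure(structure_id=structure_id, chains=chains)


def _iter_residues(sub):
    """Yield ((res_id, ins_code, res_name), start, stop) contiguous blocks."""
    seen: list = []
    have_ins = "ins_code" in sub.get_annotation_categories()
    n = sub.array_length()
    start = 0
    while start < n:
        key = (
            int(sub.res_id[start]),
            str(sub.ins_code[start]) if have_ins else "",
            str(sub.res_name[start]),
        )
        stop = start
        while stop < n and (
            int(sub.res_id[stop]),
            str(sub.ins_code[stop]) if have_ins else "",
            str(sub.res_name[stop]),
        ) == key:
            stop += 1
        if key in seen:
            raise FormatError(
                f"residue {key[0]}{key[1]} ({key[2]}) appears twice non-contiguously"
            )
        seen.append(key)
        yield key, start, stop
        start = stop


def read_structure(path, fmt: str | None = None, role: str = "model") -> Structure:
    """Read a coordinate file into a :class:`Structure`.

    Parameters
    ----------
    fmt
        ``mmcif`` or ``pdb``; inferred from the suffix when omitted.
    role
        ``model`` enforces 1-based target numbering (insertion codes are an
        error); ``reference`` accepts author numbering and insertion codes.

    Ligand components become single-residue chains of kind ``ligand``; the
    highest-occupancy alternate conformer is kept.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "mmcif":
            from biotite.structure.io import pdbx

            f = pdbx.CIFFile.read(str(path))
            arr = pdbx.get_structure(
                f, model=1, altloc="occupancy", extra_fields=["occupancy"]
            )
        elif fmt == "pdb":
            from biotite.structure.io import pdb

            f = pdb.PDBFile.read(str(path))
            arr = f.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (ValidationError, ValueError):
        raise
    except Exception as exc:  # biotite raises a zoo of parse errors
        raise FormatError(f"cannot parse {path.name} as {fmt}: {exc}") from exc
    return _from_atom_array(arr, structure_id=path.stem, role=role)


def _to_atom_array(structure: Structure):
    import biotite.structure as struc

    n = sum(len(r.atoms) for c in structure.chains for r in c.residues)
    arr = struc.AtomArray(n)
    i = 0
    for chain in structure.chains:
        if chain.kind == "ligand":
            base, _, res_id = chain.chain_id.rpartition(_LIGAND_CHAIN_SEP)
            cid = base or chain.chain_id
            rid = int(res_id) if res_id.isdigit() else 1
        else:
            cid, rid = chain.chain_id, None
        for res in chain.residues:
            for atom in res.atoms:
                arr.chain_id[i] = cid
                arr.res_id[i] = rid if rid is not None else res.number
                arr.res_name[i] = res.component_id
                arr.atom_name[i] = atom.name
                arr.element[i] = atom.element.upper()
                arr.hetero[i] = atom.is_hetero or chain.kind == "ligand"
                arr.coord[i] = atom.position
                i += 1
    return arr


def write_structure(structure: Structure, path, fmt: str | None = None) -> None:
    """Write a structure as mmCIF or PDB (dialect inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    arr = _to_atom_array(structure)
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    if fmt == "mmcif":
        from biotite.structure.io import pdbx

        f = pdbx.CIFFile()
        pdbx.set_structure(f, arr, data_block=structure.structure_id)
        f.write(str(path))
    elif fmt == "pdb":
        from biotite.structure.io import pdb

        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def renumber_chain_to_sequence(chain: Chain, canonical_seq: str) -> Chain:
    """Renumber a reference chain to 1-based entity-sequence positions.

    Aligns the chain's observed one-letter sequence globally against the full
    entity sequence and assigns each observed residue the matched position.
    Residues that do not align (rare author artifacts) are dropped.
    """
    observed = chain.one_letter_sequence()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(canonical_seq, observed)[0]
    new_residues = []
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for offset in range(t1 - t0):
            res = chain.residues[q0 + offset]
            new_residues.append(
                Residue(number=t0 + offset + 1, component_id=res.component_id,
                        atoms=res.atoms)
            )
    return Chain(chain_id=chain.chain_id, entity_ref=chain.entity_ref,
                 residues=new_residues, kind=chain.kind)


# ---------------------------------------------------------------------------
# target records (pre-release JSON schema)
# ---------------------------------------------------------------------------


def write_target_record(target: TargetComplex, path) -> None:
    doc = {
        "target_id": target.target_id,
        "polymers": [
            {
                "entity_id": e.entity_id,
                "noncanonical_seq": e.noncanonical_seq,
                "canonical_seq": e.canonical_seq,
                "kind": e.kind,
                "copy_count": e.copy_count,
            }
            for e in target.polymers
        ],
        "nonpolymers": [
            {
                "entity_id": e.entity_id,
                "component_id": e.component_id,
                "smiles": e.smiles,
                "copy_count": e.copy_count,
                "heavy_atom_count": e.heavy_atom_count,
            }
            for e in target.nonpolymers
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_target_record(path) -> TargetComplex:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse target record {path}: {exc}") from exc
    return TargetComplex(
        target_id=doc["target_id"],
        polymers=[PolymerEntity(**p) for p in doc["polymers"]],
        nonpolymers=[NonPolymerEntity(**p) for p in doc["nonpolymers"]],
    )
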