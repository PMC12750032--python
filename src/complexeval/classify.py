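"""Target novelty classification from sequences.

Individual polymer sequences are clustered (proteins at 99% identity,
peptides and nucleic acids at 100%), complexes sharing the same set of
sequence clusters are clustered together, and each complex is labelled
easy / medium / hard from template hits:

* a protein sequence is *easy* for a template at >= 85% identity with >= 70%
  of the target covered and, for targets longer than 250 residues, fewer
  than 45 residues uncovered;
* *medium* for a template at < 85% identity but e-value <= 1e-4 with the
  same coverage requirements;
* peptides, DNA and RNA are easy only at 100% identity with full coverage;
* a complex is easy when one template is easy for every entity, medium when
  one template is easy-or-medium for every entity, hard otherwise (including
  when no single template covers the whole complex).

Easy complexes whose ligand set matches no easy template's ligand set are
flagged as *ligand* targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .config import DEFAULT_CONFIG, RunConfig
from .structio import TargetComplex, ValidationError

__all__ = [
    "TemplateHit",
    "Cluster",
    "LABEL_ORDER",
    "cluster_sequences",
    "cluster_complexes",
    "align_and_measure",
    "parse_hit_table",
    "label_sequence",
    "label_complex",
    "detect_ligand_target",
    "classify_targets",
]

#: total order for monotonicity: easy < medium < hard
LABEL_ORDER = {"easy": 0, "medium": 1, "hard": 2}


@dataclass
class TemplateHit:
    """Summary of one target-sequence-vs-template alignment.

    ``coverage`` is the percentage of target residues inside the alignment;
    ``uncovered = target_length - covered`` counts target residues outside it.
    """

    target_entity: str
    template_id: str
    identity: float          # % in [0, 100]
    coverage: float          # % in [0, 100]
    uncovered: int
    target_length: int
    evalue: float | None = None

    def __post_init__(self) -> None:
        covered = self.target_length - self.uncovered
        if abs(self.coverage - 100.0 * covered / self.target_length) > 0.51:
            raise ValidationError(
                f"hit {self.target_entity}->{self.template_id}: coverage "
                f"{self.coverage:.1f}% inconsistent with uncovered={self.uncovered}"
            )


@dataclass
class Cluster:
    members: list[str]
    representative: str = ""

    def __post_init__(self) -> None:
        if not self.representative:
            self.representative = min(self.members)
        if self.representative not in self.members:
            raise ValidationError("representative must be a member")


# ---------------------------------------------------------------------------
# alignment and identity
# ---------------------------------------------------------------------------


def _make_aligner(kind: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if kind in ("protein", "peptide"):
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    return aligner


def _alignment_stats(aln, target_seq: str, template_seq: str) -> tuple[int, int, int]:
    """(matches, aligned_columns, covered_target_residues) of a local alignment."""
    matches = aligned_cols = covered = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        covered += t1 - t0
        aligned_cols += t1 - t0
        for k in range(t1 - t0):
            if target_seq[t0 + k] == template_seq[q0 + k]:
                matches += 1
    return matches, aligned_cols, covered


def align_and_measure(
    target_seq: str,
    template_seq: str,
    kind: str = "protein",
    target_entity: str = "",
    template_id: str = "",
) -> TemplateHit:
    """Local alignment summary of a target sequence against one template.

    Identity is computed over aligned columns (gaps excluded); coverage over
    the full target length.  No e-value is produced — e-values come only
    from external hit tables.
    """
    if not target_seq or not template_seq:
        raise ValidationError("empty sequence")
    aligner = _make_aligner(kind)
    alignments = aligner.align(target_seq, template_seq)
    try:
        aln = alignments[0]
    except IndexError:
        aln = None
    if aln is None or len(aln.aligned[0]) == 0:
        return TemplateHit(
            target_entity=target_entity,
            template_id=template_id,
            identity=0.0,
            coverage=0.0,
            uncovered=len(target_seq),
            target_length=len(target_seq),
        )
    matches, cols, covered = _alignment_stats(aln, target_seq, template_seq)
    return TemplateHit(
        target_entity=target_entity,
        template_id=template_id,
        identity=100.0 * matches / cols if cols else 0.0,
        coverage=100.0 * covered / len(target_seq),
        uncovered=len(target_seq) - covered,
        target_length=len(target_seq),
    )


def _identity_over_shorter(seq_a: str, seq_b: str, kind: str) -> float:
    """Clustering identity: matches divided by the shorter sequence length."""
    if seq_a == seq_b:
        return 100.0
    shorter = min(len(seq_a), len(seq_b))
    if shorter == 0:
        return 0.0
    aligner = _make_aligner(kind)
    alignments = aligner.align(seq_a, seq_b)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0
    matches, _, _ = _alignment_stats(aln, seq_a, seq_b)
    return 100.0 * matches / shorter


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_sequences(
    seqs: Sequence[tuple[str, str, str]],
    identity_threshold: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[Cluster]:
    """Greedy incremental clustering, longest sequence first.

    ``seqs`` are ``(id, canonical_sequence, kind)`` of one kind.  A sequence
    joins the first existing cluster whose seed it matches at or above the
    threshold (identity over the shorter length, the CD-HIT convention);
    proteins default to 99%, everything else to 100%.  The stored
    representative is the alphabetically first member.
    """
    if not seqs:
        return []
    kinds = {k for _, _, k in seqs}
    if len(kinds) > 1:
        raise ValidationError(f"sequences of mixed kinds: {sorted(kinds)}")
    kind = kinds.pop()
    if identity_threshold is None:
        identity_threshold = (
            config.protein_cluster_identity
            if kind == "protein"
            else config.other_cluster_identity
        )
    ordered = sorted(seqs, key=lambda s: (-len(s[1]), s[0]))
    clusters: list[tuple[str, list[str]]] = []  # (seed sequence, member ids)
    for sid, seq, _ in ordered:
        for seed_seq, members in clusters:
            if _identity_over_shorter(seq, seed_seq, kind) >= identity_threshold - 1e-9:
                members.append(sid)
                break
        else:
            clusters.append((seq, [sid]))
    return [Cluster(members=sorted(members)) for _, members in clusters]


def cluster_complexes(
    targets: Sequence[TargetComplex],
    seq_clusters: Sequence[Cluster],
    entity_seq_id: Callable[[TargetComplex, str], str] | None = None,
) -> list[Cluster]:
    """Cluster complexes that contain the same *set* of sequence clusters.

    Set semantics: targets differing only in copy number of identical
    sequences fall in the same cluster.  Representatives are the
    alphabetically first target ids.
    """
    if entity_seq_id is None:
        entity_seq_id = lambda t, e: f"{t.target_id}:{e}"
    member_cluster: dict[str, int] = {}
    for idx, cluster in enumerate(seq_clusters):
        for m in cluster.members:
            member_cluster[m] = idx
    by_key: dict[frozenset[int], list[str]] = {}
    for target in targets:
        key_items = set()
        for entity in target.polymers:
            sid = entity_seq_id(target, entity.entity_id)
            if sid not in member_cluster:
                raise ValidationError(
                    f"entity {sid} not assigned to any sequence cluster"
                )
            key_items.add(member_cluster[sid])
        by_key.setdefault(frozenset(key_items), []).append(target.target_id)
    return [
        Cluster(members=sorted(members))
        for _, members in sorted(by_key.items(), key=lambda kv: sorted(kv[1]))
    ]


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def parse_hit_table(path, target_lengths: Mapping[str, int]) -> list[TemplateHit]:
    """Parse a 12-column tab-separated hit table into template hits.

    Multiple local alignments (HSPs) of one query-template pair are merged:
    coverage is the union of their query intervals, identity the
    alignment-length-weighted mean, and the e-value the minimum.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_HIT_COLUMNS,
            dtype={"query": str, "subject": str},
        )
    except pd.errors.EmptyDataError:
        return []
    except Exception as exc:
        raise ValidationError(f"cannot parse hit table {path.name}: {exc}") from exc
    if df.isnull().any().any():
        row = int(df.isnull().any(axis=1).idxmax()) + 1
        raise ValidationError(f"{path.name}: malformed row {row}")
    hits: list[TemplateHit] = []
    for (query, subject), rows in df.groupby(["query", "subject"], sort=True):
        if query not in target_lengths:
            raise ValidationError(f"{path.name}: no target length for {query!r}")
        length = int(target_lengths[query])
        intervals = sorted(
            (min(int(r.qstart), int(r.qend)), max(int(r.qstart), int(r.qend)))
            for r in rows.itertuples()
        )
        covered = 0
        cur_lo, cur_hi = intervals[0]
        for lo, hi in intervals[1:]:
            if lo <= cur_hi + 1:
                cur_hi = max(cur_hi, hi)
            else:
                covered += cur_hi - cur_lo + 1
                cur_lo, cur_hi = lo, hi
        covered += cur_hi - cur_lo + 1
        weights = rows["length"].astype(float)
        identity = float((rows["pident"] * weights).sum() / weights.sum())
        hits.append(
            TemplateHit(
                target_entity=str(query),
                template_id=str(subject),
                identity=identity,
                coverage=100.0 * covered / length,
                uncovered=length - covered,
                target_length=length,
                evalue=float(rows["evalue"].min()),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# difficulty labels
# ---------------------------------------------------------------------------


def label_sequence(
    hit: TemplateHit | None,
    kind: str,
    config: RunConfig = DEFAULT_CONFIG,
) -> str:
    """Easy/medium/hard of one sequence for one template hit (None -> hard)."""
    if hit is None:
        return "hard"
    if kind in ("protein",):
        coverage_ok = hit.coverage >= config.easy_coverage - 1e-9 and (
            hit.target_length <= config.long_target_length
            or hit.uncovered < config.max_uncovered
        )
        if hit.identity >= config.easy_identity - 1e-9 and coverage_ok:
            return "easy"
        if (
            hit.identity < config.easy_identity
            and hit.evalue is not None
            and hit.evalue <= config.medium_evalue
            and coverage_ok
        ):
            return "medium"
        return "hard"
    # peptides, DNA, RNA: easy only at full identity and full coverage
    if hit.identity >= 100.0 - 1e-9 and hit.coverage >= 100.0 - 1e-9:
        return "easy"
    return "hard"


def label_complex(
    target: TargetComplex,
    per_template_labels: Mapping[str, Mapping[str, str]],
) -> str:
    """Aggregate per-(template, entity) labels to one complex label.

    A template must cover *all* entities; entities without a hit against a
    template are implicitly hard for it.
    """
    entity_ids = [e.entity_id for e in target.polymers]
    best = "hard"
    for labels in per_template_labels.values():
        template_labels = [labels.get(eid, "hard") for eid in entity_ids]
        if all(l == "easy" for l in template_labels):
            return "easy"
        if all(l in ("easy", "medium") for l in template_labels):
            best = "medium"
    return best


def detect_ligand_target(
    label: str,
    target_ligands: Iterable[str],
    easy_template_ligand_sets: Mapping[str, Iterable[str]],
    exclude: frozenset[str] = DEFAULT_CONFIG.ligand_set_exclude,
) -> bool:
    """True when no easy template carries the target's exact ligand set."""
    if label != "easy":
        raise ValueError("ligand detection applies to easy targets only")
    target_set = frozenset(target_ligands) - exclude
    for ligands in easy_template_ligand_sets.values():
        if frozenset(ligands) - exclude == target_set:
            return False
    return True


def classify_targets(
    targets: Sequence[TargetComplex],
    hits: Sequence[TemplateHit],
    entity_kind: Mapping[str, str],
    template_ligand_sets: Mapping[str, Iterable[str]] | None = None,
    target_ligand_sets: Mapping[str, Iterable[str]] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, dict]:
    """Full classification report for a set of targets.

    ``hits`` carry ``target_entity`` ids of the form ``"<target>:<entity>"``;
    ``entity_kind`` maps those ids to protein/peptide/dna/rna.  Returns, per
    target: per-entity best labels, the complex label, and the ligand flag.
    """
    template_ligand_sets = template_ligand_sets or {}
    by_target: dict[str, dict[str, dict[str, str]]] = {}
    for hit in hits:
        tid, _, eid = hit.target_entity.partition(":")
        label = label_sequence(hit, entity_kind.get(hit.target_entity, "protein"), config)
        tpl = by_target.setdefault(tid, {}).setdefault(hit.template_id, {})
        prev = tpl.get(eid)
        if prev is None or LABEL_ORDER[label] < LABEL_ORDER[prev]:
            tpl[eid] = label
    report: dict[str, dict] = {}
    for target in targets:
        per_template = by_target.get(target.target_id, {})
        label = label_complex(target, per_template)
        entry: dict = {"label": label, "base_label": label, "per_template": {
            t: dict(sorted(d.items())) for t, d in sorted(per_template.items())
        }}
        if label == "easy":
            easy_templates = {
                t: template_ligand_sets.get(t, frozenset())
                for t, labels in per_template.items()
                if all(
                    labels.get(e.entity_id, "hard") == "easy"
                    for e in target.polymers
                )
            }
            ligands = (
                target_ligand_sets[target.target_id]
                if target_ligand_sets is not None
                else target.ligand_component_set
            )
            if detect_ligand_target(
                label, ligands, easy_templates, config.ligand_set_exclude
            ):
                entry["label"] = "ligand"
                entry["ligand_flag"] = True
            else:
                entry["ligand_flag"] = False
        report[target.target_id] = entry
    return report
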