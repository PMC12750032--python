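"""Clustering, template evaluation and difficulty labelling."""

import numpy as np
import pytest

from complexeval.classify import (
    Cluster,
    LABEL_ORDER,
    TemplateHit,
    align_and_measure,
    cluster_complexes,
    cluster_sequences,
    detect_ligand_target,
    label_complex,
    label_sequence,
    parse_hit_table,
)
from complexeval.structio import PolymerEntity, TargetComplex, ValidationError


def hit(identity, coverage, uncovered, length, evalue=None):
    return TemplateHit(
        target_entity="t:e1", template_id="tpl", identity=identity,
        coverage=coverage, uncovered=uncovered, target_length=length,
        evalue=evalue,
    )


class TestLabelSequence:
    @pytest.mark.parametrize(
        "h,kind,expected",
        [
            # boundary: >= 85% identity and >= 70% coverage qualify
            (hit(85.0, 70.0, 60, 200), "protein", "easy"),
            (hit(84.99, 70.0, 60, 200, evalue=1e-5), "protein", "medium"),
            (hit(84.99, 70.0, 60, 200, evalue=2e-4), "protein", "hard"),
            (hit(60.0, 80.0, 40, 200, evalue=1e-5), "protein", "medium"),
            # 45-uncovered rule bites only above 250 residues
            (hit(90.0, 85.0, 45, 300), "protein", "hard"),
            (hit(90.0, 85.3, 44, 300), "protein", "easy"),
            (hit(90.0, 76.0, 60, 250), "protein", "easy"),
            (hit(90.0, 76.1, 60, 251), "protein", "hard"),
            # high identity but poor coverage is neither easy nor medium
            (hit(90.0, 60.0, 80, 200, evalue=1e-30), "protein", "hard"),
            # peptides and nucleic acids: exact full-length match or nothing
            (hit(100.0, 100.0, 0, 20), "peptide", "easy"),
            (hit(100.0, 98.0, 1, 50), "peptide", "hard"),
            (hit(99.0, 100.0, 0, 20), "rna", "hard"),
            (hit(100.0, 100.0, 0, 40), "dna", "easy"),
        ],
    )
    def test_rule_boundaries(self, h, kind, expected):
        assert label_sequence(h, kind) == expected

    def test_no_hit_is_hard(self):
        assert label_sequence(None, "protein") == "hard"

    def test_monotone_toward_easy(self):
        # raising identity or coverage never moves a protein label toward hard
        rng = np.random.default_rng(42)
        for _ in range(300):
            length = int(rng.integers(50, 400))
            uncovered = int(rng.integers(0, length))
            coverage = 100.0 * (length - uncovered) / length
            identity = float(rng.uniform(0, 100))
            evalue = float(10 ** rng.uniform(-30, 1))
            base = label_sequence(
                hit(identity, coverage, uncovered, length, evalue), "protein"
            )
            bump_unc = max(0, uncovered - int(rng.integers(0, 20)))
            better = hit(
                min(100.0, identity + float(rng.uniform(0, 10))),
                100.0 * (length - bump_unc) / length,
                bump_unc, length, evalue,
            )
            upgraded = label_sequence(better, "protein")
            # identity may cross 85% and leave the medium path, but never
            # drops below the base label unless base was medium (easy>medium path)
            if base == "easy":
                assert upgraded == "easy"


class TestLabelComplex:
    def t(self, entities):
        return TargetComplex(
            target_id="T",
            polymers=[
                PolymerEntity(
                    entity_id=e, noncanonical_seq=["ALA"], canonical_seq="A",
                    kind="peptide",
                )
                for e in entities
            ],
        )

    def test_single_template_all_easy(self):
        assert label_complex(self.t(["e1", "e2"]),
                             {"t1": {"e1": "easy", "e2": "easy"}}) == "easy"

    def test_split_easy_templates_are_hard(self):
        labels = {"t1": {"e1": "easy"}, "t2": {"e2": "easy"}}
        assert label_complex(self.t(["e1", "e2"]), labels) == "hard"

    def test_easy_plus_medium_is_medium(self):
        labels = {"t1": {"e1": "easy", "e2": "medium"}}
        assert label_complex(self.t(["e1", "e2"]), labels) == "medium"

    def test_matches_bruteforce_enumeration(self):
        # oracle: literal quantifier evaluation over all templates
        rng = np.random.default_rng(7)
        names = ["easy", "medium", "hard"]
        for _ in range(300):
            n_entities = int(rng.integers(1, 5))
            entities = [f"e{i}" for i in range(n_entities)]
            n_templates = int(rng.integers(0, 5))
            labels = {
                f"t{j}": {
                    e: names[rng.integers(0, 3)]
                    for e in entities
                    if rng.random() < 0.8
                }
                for j in range(n_templates)
            }
            got = label_complex(self.t(entities), labels)
            full = {
                t: [d.get(e, "hard") for e in entities] for t, d in labels.items()
            }
            if any(all(l == "easy" for l in ls) for ls in full.values()):
                expected = "easy"
            elif any(all(l != "hard" for l in ls) for ls in full.values()):
                expected = "medium"
            else:
                expected = "hard"
            assert got == expected


class TestDetectLigandTarget:
    def test_same_set_present(self):
        assert detect_ligand_target("easy", {"ATP"}, {"t1": {"ATP"}}) is False

    def test_no_template_has_set(self):
        assert detect_ligand_target("easy", {"GTP"}, {"t1": {"ATP"}, "t2": set()}) is True

    def test_empty_sets_match(self):
        assert detect_ligand_target("easy", set(), {"t1": set()}) is False

    def test_water_excluded_by_default(self):
        assert detect_ligand_target("easy", {"ATP", "HOH"}, {"t1": {"ATP"}}) is False

    def test_non_easy_rejected(self):
        with pytest.raises(ValueError):
            detect_ligand_target("medium", set(), {})


class TestClusterSequences:
    def test_identical_sequences_cluster(self):
        seqs = [("a", "MKV" * 20, "protein"), ("b", "MKV" * 20, "protein")]
        clusters = cluster_sequences(seqs)
        assert len(clusters) == 1
        assert clusters[0].representative == "a"

    def test_threshold_splits(self):
        s = "ACDEFGHIKLMNPQRSTVWY" * 5  # 100 residues
        s2 = s[:-2] + "AA"  # 98% identity
        clusters = cluster_sequences([("a", s, "protein"), ("b", s2, "protein")])
        assert len(clusters) == 2

    def test_peptides_cluster_at_100(self):
        clusters = cluster_sequences(
            [("a", "ACDEFGHIKL", "peptide"), ("b", "ACDEFGHIKV", "peptide")]
        )
        assert len(clusters) == 2
        identical = cluster_sequences(
            [("a", "ACDEFGHIKL", "peptide"), ("b", "ACDEFGHIKL", "peptide")]
        )
        assert len(identical) == 1

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        base = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
                for _ in range(6)]
        seqs = [(f"s{i}", s, "protein") for i, s in enumerate(base)]
        ref = cluster_sequences(seqs)
        for _ in range(5):
            perm = list(seqs)
            rng.shuffle(perm)
            got = cluster_sequences(perm)
            assert [c.members for c in got] == [c.members for c in ref]

    def test_empty_input(self):
        assert cluster_sequences([]) == []

    def test_mixed_kinds_rejected(self):
        with pytest.raises(ValidationError):
            cluster_sequences([("a", "ACGT", "dna"), ("b", "MKV", "protein")])


class TestClusterComplexes:
    def make_target(self, tid, entity_ids):
        return TargetComplex(
            target_id=tid,
            polymers=[
                PolymerEntity(entity_id=e, noncanonical_seq=["ALA"],
                              canonical_seq="A", kind="peptide")
                for e in entity_ids
            ],
        )

    def test_same_cluster_sets_merge(self):
        ta = self.make_target("A", ["e1", "e2"])
        tb = self.make_target("B", ["e1", "e2"])
        clusters = [
            Cluster(members=["A:e1", "B:e2"]),
            Cluster(members=["A:e2", "B:e1"]),
        ]
        out = cluster_complexes([ta, tb], clusters)
        assert len(out) == 1
        assert out[0].representative == "A"

    def test_set_semantics_ignores_copy_structure(self):
        ta = self.make_target("A", ["e1"])
        tb = self.make_target("B", ["e1", "e2"])
        clusters = [Cluster(members=["A:e1", "B:e1", "B:e2"])]
        out = cluster_complexes([ta, tb], clusters)
        assert len(out) == 1

    def test_disjoint_sets_stay_separate(self):
        ta = self.make_target("A", ["e1"])
        tb = self.make_target("B", ["e1"])
        clusters = [Cluster(members=["A:e1"]), Cluster(members=["B:e1"])]
        out = cluster_complexes([ta, tb], clusters)
        assert len(out) == 2

    def test_unassigned_entity_errors(self):
        ta = self.make_target("A", ["e1"])
        with pytest.raises(ValidationError):
            cluster_complexes([ta], [])


class TestAlignAndMeasure:
    def test_identical_sequences(self):
        s = "ACDEFGHIKLMNPQRSTVWY" * 5
        h = align_and_measure(s, s)
        assert h.identity == 100.0
        assert h.coverage == 100.0
        assert h.uncovered == 0

    def test_prefix_template_coverage(self):
        target = "ACDEFGHIKLMNPQRSTVWY" * 10  # 200-mer
        h = align_and_measure(target, target[:140])
        assert h.coverage == pytest.approx(70.0)
        assert h.uncovered == 60

    def test_single_mismatch_identity(self):
        h = align_and_measure("ACDEFGHIK", "ACDEFGHIR", kind="peptide")
        assert h.identity == pytest.approx(100.0 * 8 / 9)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValidationError):
            align_and_measure("", "ACD")


class TestParseHitTable:
    def write(self, tmp_path, rows):
        path = tmp_path / "hits.tsv"
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return path

    def test_coverage_from_interval(self, tmp_path):
        path = self.write(
            tmp_path, [["q1", "t1", 90.0, 140, 10, 0, 1, 140, 1, 140, 1e-30, 200.0]]
        )
        hits = parse_hit_table(path, {"q1": 200})
        assert hits[0].coverage == pytest.approx(70.0)
        assert hits[0].uncovered == 60

    def test_hsp_union_merges(self, tmp_path):
        path = self.write(
            tmp_path,
            [
                ["q1", "t1", 90.0, 100, 0, 0, 1, 100, 1, 100, 1e-30, 200.0],
                ["q1", "t1", 90.0, 100, 0, 0, 101, 200, 101, 200, 1e-20, 180.0],
            ],
        )
        hits = parse_hit_table(path, {"q1": 200})
        assert len(hits) == 1
        assert hits[0].coverage == pytest.approx(100.0)
        assert hits[0].uncovered == 0
        assert hits[0].evalue == pytest.approx(1e-30)

    def test_hsp_union_oracle(self, tmp_path):
        # interval-union oracle on random HSP sets
        rng = np.random.default_rng(5)
        for trial in range(20):
            length = 300
            rows = []
            intervals = []
            for _ in range(rng.integers(1, 6)):
                a = int(rng.integers(1, length - 10))
                b = int(a + rng.integers(5, 80))
                b = min(b, length)
                intervals.append((a, b))
                rows.append(["q", "t", 80.0, b - a + 1, 0, 0, a, b, a, b, 1e-9, 50.0])
            path = self.write(tmp_path, rows)
            hits = parse_hit_table(path, {"q": length})
            covered_oracle = len(
                {i for a, b in intervals for i in range(a, b + 1)}
            )
            assert hits[0].uncovered == length - covered_oracle

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert parse_hit_table(path, {}) == []

    def test_malformed_row_reports_position(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\tt1\t90.0\n")
        with pytest.raises(ValidationError):
            parse_hit_table(path, {"q1": 100})
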