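"""Annotation parsing, overlap resolution, pairwise identity, family clustering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import mutate_interior, random_dna, smith_waterman_score
from tedepth.annotate import (
    _ALIGNER,
    ConsensusElement,
    TEFamily,
    cluster_families,
    consolidate_classification,
    deduplicate_annotations,
    pairwise_identity,
    read_repeatmasker_out,
)
from tedepth.model import TEAnnotation

RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat         class/family         begin  end (left)   ID\n"
    "\n"
)


def _ann(scaffold, start, end, repeat_id, identity, score=0, superfamily="Gypsy"):
    return TEAnnotation(scaffold, start, end, "+", repeat_id, superfamily, (), identity, score)


class TestRepeatMaskerReader:
    def test_header_only_yields_empty_set(self, tmp_path):
        p = tmp_path / "empty.out"
        p.write_text(RM_HEADER)
        assert read_repeatmasker_out(p) == []

    def test_coordinates_strand_and_identity_conversion(self, tmp_path):
        p = tmp_path / "two.out"
        p.write_text(
            RM_HEADER
            + "  463   8.5  0.0  0.0  scf1      101     200  (800)    + rep1   LTR/Gypsy    1  100  (0)   1\n"
            + "  250  12.0  0.0  0.0  scf1      501     700  (300)    C rep2   LINE/L1      1  200  (0)   2\n"
        )
        a, b = read_repeatmasker_out(p)
        assert (a.start, a.end, a.length) == (100, 200, 100)
        assert a.pct_identity == pytest.approx(91.5)
        assert a.score == 463
        assert a.classification_path == ("LTR", "Gypsy")
        assert b.strand == "-"
        assert b.superfamily == "L1"

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text(RM_HEADER + "garbage row\n")
        with pytest.raises(ValueError, match="line 4"):
            read_repeatmasker_out(p)


class TestDeduplicate:
    def test_non_overlapping_pass_through(self):
        anns = [_ann("s", 0, 100, "A", 90.0), _ann("s", 200, 300, "B", 80.0)]
        out = deduplicate_annotations(anns)
        assert [(a.repeat_id, a.start, a.end) for a in out] == [("A", 0, 100), ("B", 200, 300)]

    def test_loser_is_trimmed_to_remainder(self):
        a = _ann("s", 100, 500, "A", 85.0)
        b = _ann("s", 300, 700, "B", 92.0)
        out = deduplicate_annotations([a, b])
        assert [(x.repeat_id, x.start, x.end) for x in out] == [("A", 100, 300), ("B", 300, 700)]

    def test_short_remainder_is_dropped(self):
        a = _ann("s", 100, 500, "A", 85.0)
        b = _ann("s", 150, 700, "B", 92.0)  # remainder of A is 50 bp < 80
        out = deduplicate_annotations([a, b])
        assert [(x.repeat_id, x.start, x.end) for x in out] == [("B", 150, 700)]

    def test_drop_loser_mode_discards_partial_overlaps_whole(self):
        a = _ann("s", 100, 500, "A", 85.0)
        b = _ann("s", 300, 700, "B", 92.0)
        out = deduplicate_annotations([a, b], trim=False)
        assert [(x.repeat_id, x.start, x.end) for x in out] == [("B", 300, 700)]

    def test_tie_break_ladder(self):
        # same interval, same identity: higher score wins
        a = _ann("s", 0, 200, "A", 90.0, score=100)
        b = _ann("s", 0, 200, "B", 90.0, score=300)
        assert [x.repeat_id for x in deduplicate_annotations([a, b])] == ["B"]
        # equal score: lexicographic repeat_id, exactly one survivor
        a = _ann("s", 0, 200, "zeta", 90.0)
        b = _ann("s", 0, 200, "alpha", 90.0)
        out = deduplicate_annotations([a, b])
        assert [x.repeat_id for x in out] == ["alpha"]

    def test_idempotent(self, rng):
        anns = [
            _ann("s", int(s), int(s) + int(l), f"r{i}", float(rng.integers(70, 100)))
            for i, (s, l) in enumerate(zip(rng.integers(0, 5000, 60), rng.integers(100, 800, 60)))
        ]
        once = deduplicate_annotations(anns)
        assert deduplicate_annotations(once) == once


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = random_dna(1000, rng)
        assert pairwise_identity(s, s) == (1.0, 1.0, 1000)

    def test_constructed_ten_percent_mutant(self, rng):
        s = random_dna(1000, rng)
        m = mutate_interior(s, 100, rng)
        ident, cov, length = pairwise_identity(s, m)
        assert ident == pytest.approx(0.90, abs=0.005)
        assert cov == pytest.approx(1.0, abs=0.01)
        assert length >= 990

    def test_random_pair_has_low_coverage(self, rng):
        a, b = random_dna(1000, rng), random_dna(1000, rng)
        res = pairwise_identity(a, b)
        assert res.coverage_of_shorter < 0.8

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_identity("", "ACGT")

    def test_local_score_matches_dp_oracle(self, rng):
        for _ in range(15):
            a = random_dna(int(rng.integers(8, 30)), rng)
            b = random_dna(int(rng.integers(8, 30)), rng)
            expected = smith_waterman_score(a, b)
            assert _ALIGNER.align(a, b).score == pytest.approx(expected)


class TestClusterFamilies:
    def test_singleton(self):
        fams = cluster_families([ConsensusElement("e1", "ACGT" * 30)])
        assert len(fams) == 1
        assert fams[0].member_ids == ["e1"]
        assert fams[0].representative_id == "e1"

    def test_mutant_joins_random_does_not(self, rng):
        s1 = random_dna(1000, rng)
        s2 = mutate_interior(s1, 100, rng)  # 90% identity
        s3 = random_dna(1000, rng)
        fams = cluster_families(
            [ConsensusElement("S1", s1), ConsensusElement("S2", s2), ConsensusElement("S3", s3)]
        )
        members = sorted(tuple(sorted(f.member_ids)) for f in fams)
        assert members == [("S1", "S2"), ("S3",)]

    def test_reverse_complement_matches_join(self, rng):
        s = random_dna(500, rng)
        rc = s[::-1].translate(str.maketrans("ACGT", "TGCA"))
        fams = cluster_families([ConsensusElement("fwd", s), ConsensusElement("rev", rc)])
        assert len(fams) == 1

    def test_literal_80bp_floor(self, rng):
        e = random_dna(79, rng)
        fams = cluster_families([ConsensusElement("a", e), ConsensusElement("b", e)])
        assert len(fams) == 2  # 79 aligned bp fails the literal >= 80 bp rule

    def test_order_invariance_of_membership(self, rng):
        seqs = [random_dna(300, rng) for _ in range(3)]
        seqs.append(mutate_interior(seqs[0], 30, rng))
        elements = [ConsensusElement(f"e{i}", s) for i, s in enumerate(seqs)]
        def membership(els):
            return sorted(tuple(sorted(f.member_ids)) for f in cluster_families(els))
        assert membership(elements) == membership(elements[::-1])

    def test_representative_is_longest_member(self, rng):
        long = random_dna(600, rng)
        short = long[50:550]  # contained, ~100% identical
        fams = cluster_families([ConsensusElement("short", short), ConsensusElement("long", long)])
        assert len(fams) == 1
        assert fams[0].representative_id == "long"


class TestConsolidateClassification:
    @pytest.mark.parametrize(
        "paths,expected",
        [
            ([("ClassI", "LTR", "Gypsy")] * 3, ("ClassI", "LTR", "Gypsy")),
            ([("ClassI", "LTR", "Gypsy"), ("ClassI", "LTR", "Copia")], ("ClassI", "LTR")),
            ([("ClassI", "LTR", "Gypsy"), ("ClassII", "TIR", "Tc1")], ()),
        ],
    )
    def test_examples(self, paths, expected):
        fam = TEFamily("f", [f"m{i}" for i in range(len(paths))], "m0")
        assert consolidate_classification(fam, {f"m{i}": p for i, p in enumerate(paths)}) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.lists(st.sampled_from(["A", "B", "C"]), max_size=4), min_size=1, max_size=5))
    def test_result_is_maximal_shared_prefix(self, paths):
        fam = TEFamily("f", [f"m{i}" for i in range(len(paths))], "m0")
        result = consolidate_classification(fam, {f"m{i}": tuple(p) for i, p in enumerate(paths)})
        for p in paths:
            assert tuple(p[: len(result)]) == result
        if all(len(p) > len(result) for p in paths):
            assert len({p[len(result)] for p in paths}) > 1
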