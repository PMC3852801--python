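"""Column taxonomy, gap-context extraction and error tallies."""

import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from pyroerr.ace import PairwiseAlignment
from pyroerr.errors import (
    ColumnLabel,
    ErrorSummary,
    classify_columns,
    context_gap_ratio,
    count_substitutions,
    extract_gaps,
    reverse_complement_alignment,
    summarize,
    tally_exact_homopolymer_matches,
)

M, S, I, D, A = (
    ColumnLabel.MATCH,
    ColumnLabel.SUBSTITUTION,
    ColumnLabel.INSERTION,
    ColumnLabel.DELETION,
    ColumnLabel.AMBIGUOUS,
)


class TestClassifyColumns:
    def test_worked_alignment(self):
        # the two G's read as one copy, the final T misread as C
        aln = PairwiseAlignment("AGGCT", "AG-CC")
        assert classify_columns(aln) == [M, M, D, M, S]

    def test_identical_rows_all_match(self):
        aln = PairwiseAlignment("ACGT", "ACGT")
        assert classify_columns(aln) == [M, M, M, M]

    def test_deletion_then_insertion(self):
        aln = PairwiseAlignment("A-", "-A")
        assert classify_columns(aln) == [D, I]

    def test_n_is_ambiguous(self):
        aln = PairwiseAlignment("AN-", "ANC")
        assert classify_columns(aln) == [M, A, I]

    def test_gap_only_column_rejected(self):
        with pytest.raises(ValueError, match="gap-only"):
            classify_columns(PairwiseAlignment("A-", "A-"))


class TestExtractGaps:
    def test_paper_context_example(self, context_example):
        gaps = extract_gaps(context_example)
        contexts = [g.base * g.context_length for g in gaps]
        assert contexts == ["AA", "CCCCC", "AA", "T", "GG", "T"]
        assert [g.kind for g in gaps] == [
            "deletion", "deletion", "deletion", "deletion", "insertion", "deletion",
        ]
        assert [g.length for g in gaps] == [1, 2, 2, 1, 1, 1]

    def test_perfect_alignment_no_gaps(self):
        assert extract_gaps(PairwiseAlignment("ACGT", "ACGT")) == []

    def test_flanks_extend_context(self):
        (gap,) = extract_gaps(PairwiseAlignment("AAAA", "A--A"))
        assert (gap.kind, gap.base, gap.length, gap.context_length) == (
            "deletion", "A", 2, 4,
        )

    def test_substitution_breaks_flank(self):
        # read shows A at the flank position but as a mismatch partner of C
        (gap,) = extract_gaps(PairwiseAlignment("CAAA", "A-AA"))
        assert gap.context_length == 3  # the C/A substitution is not a flank

    def test_mixed_base_run_splits_per_base(self):
        gaps = extract_gaps(PairwiseAlignment("AAT", "---"))
        assert [(g.base, g.length, g.context_length) for g in gaps] == [
            ("A", 2, 2),
            ("T", 1, 1),
        ]

    def test_template_positions_are_unpadded(self):
        aln = PairwiseAlignment("AAG-CC", "A-GGCC", contig_start=10)
        by_kind = {g.kind: g for g in extract_gaps(aln)}
        assert by_kind["deletion"].template_pos == 11
        assert by_kind["insertion"].template_pos == 13  # next template base


class TestTallyExactHomopolymerMatches:
    def test_direct_enumeration(self):
        aln = PairwiseAlignment("AACCT", "AACCT")
        tally = tally_exact_homopolymer_matches(aln, [])
        assert tally == Counter({("A", 2): 1, ("C", 2): 1, ("T", 1): 1})

    def test_paper_example_leaves_single_t(self, context_example):
        gaps = extract_gaps(context_example)
        tally = tally_exact_homopolymer_matches(context_example, gaps)
        assert tally == Counter({("T", 1): 1})

    def test_empty_alignment(self):
        aln = PairwiseAlignment("", "")
        assert tally_exact_homopolymer_matches(aln, []) == Counter()

    def test_substituted_homopolymer_not_counted(self):
        aln = PairwiseAlignment("AAT", "ATT")
        gaps = extract_gaps(aln)
        # AA contains a substitution column and is excluded; the matched T counts
        assert tally_exact_homopolymer_matches(aln, gaps) == Counter({("T", 1): 1})


class TestCountSubstitutions:
    def test_worked_alignment_t_to_c(self):
        counts = count_substitutions(PairwiseAlignment("AGGCT", "AG-CC"))
        assert counts[("T", "C")] == 1 and counts.total == 1

    def test_context_example_a_to_g(self, context_example):
        counts = count_substitutions(context_example)
        assert counts[("A", "G")] == 1 and counts.total == 1

    def test_identical_rows_zero_matrix(self):
        assert count_substitutions(PairwiseAlignment("ACGT", "ACGT")).total == 0


class TestSummarize:
    def test_empty_input(self):
        summary = summarize([])
        assert summary.aligned_positions == 0 and summary.n_alignments == 0

    def test_additivity(self, context_example):
        one = summarize([context_example])
        two = summarize([context_example, context_example])
        assert two.aligned_positions == 2 * one.aligned_positions
        assert two.substitutions.total == 2 * one.substitutions.total
        assert len(two.gaps) == 2 * len(one.gaps)
        assert two.tally == one.tally + one.tally

    def test_labels_partition_columns(self, context_example):
        summary = summarize([context_example])
        summary.check()  # raises if the partition identity fails
        assert summary.aligned_positions == len(context_example)

    def test_gap_lengths_sum_to_gap_columns(self, context_example):
        summary = summarize([context_example])
        del_len = sum(g.length for g in summary.gaps if g.kind == "deletion")
        ins_len = sum(g.length for g in summary.gaps if g.kind == "insertion")
        assert del_len == summary.deletion_columns
        assert ins_len == summary.insertion_columns


class TestContextGapRatio:
    def test_arithmetic(self):
        summary = summarize(
            [PairwiseAlignment("AAA" + "T" * 4, "A-A" + "T" * 4)]
            + [PairwiseAlignment("AAAC", "AAAC")] * 95
        )
        ratios = context_gap_ratio(summary)
        assert ratios[("A", 3)] == pytest.approx(1 / 95)

    def test_never_a_context_is_zero(self):
        summary = summarize([PairwiseAlignment("GG", "GG")])
        assert context_gap_ratio(summary)[("G", 2)] == 0.0

    def test_no_exact_matches_is_missing(self):
        summary = summarize([PairwiseAlignment("AA", "A-")])
        assert math.isnan(context_gap_ratio(summary)[("A", 2)])


COLUMN_POOL = [
    ("A", "A"), ("T", "T"), ("G", "G"), ("C", "C"),
    ("A", "G"), ("C", "T"),
    ("A", "-"), ("T", "-"), ("-", "C"), ("-", "G"),
]


@st.composite
def normalized_alignments(draw):
    cols = draw(st.lists(st.sampled_from(COLUMN_POOL), min_size=1, max_size=40))
    return PairwiseAlignment(
        template="".join(c[0] for c in cols), read="".join(c[1] for c in cols)
    )


@settings(derandomize=True, max_examples=300)
@given(normalized_alignments())
def test_label_counts_partition_columns(aln):
    labels = classify_columns(aln)
    assert len(labels) == len(aln)
    counts = Counter(labels)
    assert sum(counts.values()) == len(aln)


@settings(derandomize=True, max_examples=300)
@given(normalized_alignments())
def test_gap_record_lengths_partition_gap_columns(aln):
    labels = classify_columns(aln)
    gaps = extract_gaps(aln, labels)
    for kind, label in (("deletion", ColumnLabel.DELETION), ("insertion", ColumnLabel.INSERTION)):
        assert sum(g.length for g in gaps if g.kind == kind) == sum(
            1 for l in labels if l is label
        )


@settings(derandomize=True, max_examples=300)
@given(normalized_alignments())
def test_context_extraction_is_strand_symmetric(aln):
    flipped = reverse_complement_alignment(aln)
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    fwd = Counter(
        (g.kind, complement[g.base], g.length, g.context_length) for g in extract_gaps(aln)
    )
    rev = Counter((g.kind, g.base, g.length, g.context_length) for g in extract_gaps(flipped))
    assert fwd == rev
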