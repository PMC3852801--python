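"""Column classification, homopolymer gap-context extraction, error tallies.

Each column of a normalized read-contig alignment is one of: a match, a
substitution, a deletion (template base over a read gap), an insertion (the
converse), or ambiguous (an ``N`` in either row).  Runs of gap columns are
decomposed into per-base sub-gaps, and each sub-gap is annotated with its
*homopolymer context*: the gapped bases together with the maximal flanking
runs of matched columns of the same base on either side.  Pyrosequencing
reads one homopolymer per nucleotide flow, so that context — not the single
column — is the natural unit of its indel errors.

Example (template over read)::

    AACCCCCAATG-TAT
    -AC--CC---GGTG-

yields six gaps whose contexts, left to right, are AA, CCCCC, AA, T, GG
and T — note the deleted run ``AAT`` splits into an A-gap and a T-gap, each
with its own context.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .ace import GAP, PairwiseAlignment

__all__ = [
    "ColumnLabel",
    "GapRecord",
    "SubstitutionCounts",
    "HomopolymerMatchTally",
    "ErrorSummary",
    "classify_columns",
    "extract_gaps",
    "tally_exact_homopolymer_matches",
    "count_substitutions",
    "summarize",
    "context_gap_ratio",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


class ColumnLabel(Enum):
    MATCH = "match"
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class GapRecord:
    """One homopolymer indel: a per-base sub-gap plus its context.

    ``length`` counts the gapped bases; ``context_length`` counts the whole
    context homopolymer (gapped bases plus matched flanks), so
    ``context_length >= length`` always.  ``template_pos`` is the 1-based
    unpadded template coordinate of the first gap column (for insertions,
    of the next template base).  ``col_start``/``ctx_span`` locate the gap
    and its context in alignment-column coordinates (0-based), which later
    tallies use to exclude context homopolymers from exact-match counts.
    """

    kind: str  # "insertion" | "deletion"
    base: str
    length: int
    context_length: int
    template_pos: int = 0
    alignment_id: str = ""
    col_start: int = field(default=0, compare=False)
    ctx_span: tuple[int, int] = field(default=(0, 0), compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad gap kind {self.kind!r}")
        if self.base not in BASES:
            raise ValueError(f"bad gap base {self.base!r}")
        if self.length < 1:
            raise ValueError("gap length must be >= 1")
        if self.context_length < self.length:
            raise ValueError("context_length must be >= length")

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.kind, self.base, self.length, self.context_length)


@dataclass
class SubstitutionCounts:
    """4x4 substitution matrix indexed (template base, read base), A,C,G,T.

    The diagonal is structurally zero.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=np.int64))

    def __getitem__(self, pair: tuple[str, str]) -> int:
        return int(self.matrix[_BASE_INDEX[pair[0]], _BASE_INDEX[pair[1]]])

    def add(self, template_base: str, read_base: str, n: int = 1) -> None:
        if template_base == read_base:
            raise ValueError("diagonal of a substitution matrix is structurally zero")
        self.matrix[_BASE_INDEX[template_base], _BASE_INDEX[read_base]] += n

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def __iadd__(self, other: "SubstitutionCounts") -> "SubstitutionCounts":
        self.matrix += other.matrix
        return self

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SubstitutionCounts) and bool(
            (self.matrix == other.matrix).all()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(BASES), columns=list(BASES))


HomopolymerMatchTally = Counter  # keys (base, length) -> count


@dataclass
class ErrorSummary:
    """Pooled per-column and per-gap tallies over a set of alignments."""

    aligned_positions: int = 0
    match_positions: int = 0
    ambiguous_positions: int = 0
    insertion_columns: int = 0
    deletion_columns: int = 0
    substitutions: SubstitutionCounts = field(default_factory=SubstitutionCounts)
    gaps: list[GapRecord] = field(default_factory=list)
    tally: Counter = field(default_factory=Counter)
    n_alignments: int = 0

    @property
    def substitution_positions(self) -> int:
        return self.substitutions.total

    def check(self) -> None:
        """Column labels must partition the aligned positions."""
        parts = (
            self.match_positions
            + self.substitution_positions
            + self.insertion_columns
            + self.deletion_columns
            + self.ambiguous_positions
        )
        if parts != self.aligned_positions:
            raise AssertionError(
                f"column labels do not partition positions: {parts} != {self.aligned_positions}"
            )


# ---------------------------------------------------------------------------


def classify_columns(aln: PairwiseAlignment) -> list[ColumnLabel]:
    """Label every column of a normalized alignment.

    Gap-only columns are a precondition violation (they belong to the
    pre-normalization representation).
    """
    labels: list[ColumnLabel] = []
    for i, (x, y) in enumerate(aln.columns()):
        if x == GAP and y == GAP:
            raise ValueError(
                f"gap-only column {i} in {aln.alignment_id or 'alignment'}; normalize first"
            )
        if x == "N" or y == "N":
            labels.append(ColumnLabel.AMBIGUOUS)
        elif x == GAP:
            labels.append(ColumnLabel.INSERTION)
        elif y == GAP:
            labels.append(ColumnLabel.DELETION)
        elif x == y:
            labels.append(ColumnLabel.MATCH)
        else:
            labels.append(ColumnLabel.SUBSTITUTION)
    return labels


def _template_positions(aln: PairwiseAlignment) -> list[int]:
    """Unpadded template coordinate each column maps to (next base for gaps)."""
    pos = aln.contig_start
    out = []
    for x in aln.template:
        out.append(pos)
        if x != GAP:
            pos += 1
    return out


def extract_gaps(aln: PairwiseAlignment, labels: list[ColumnLabel] | None = None) -> list[GapRecord]:
    """Decompose indel runs of a normalized alignment into contextful gaps.

    Every maximal run of deletion (resp. insertion) columns is split into
    per-base sub-gaps by template (resp. read) base; each sub-gap's context is
    its gapped bases plus the maximal flanking runs of *matched* columns of
    the same base on both sides.  A substitution — even of the same base —
    breaks a flank.  Records are ordered by first gap column.
    """
    if labels is None:
        labels = classify_columns(aln)
    n = len(labels)
    tpos = _template_positions(aln)
    records: list[GapRecord] = []

    def emit(kind: str, row: str, start: int, end: int) -> None:
        # [start, end) is a maximal run of columns with this gap label;
        # split by the base carried on `row` (template for deletions, read
        # for insertions).
        i = start
        while i < end:
            base = row[i]
            j = i
            while j < end and row[j] == base:
                j += 1
            if base in BASES:
                left = i
                while left > 0 and labels[left - 1] is ColumnLabel.MATCH and row[left - 1] == base:
                    left -= 1
                right = j
                while right < n and labels[right] is ColumnLabel.MATCH and row[right] == base:
                    right += 1
                records.append(
                    GapRecord(
                        kind=kind,
                        base=base,
                        length=j - i,
                        context_length=right - left,
                        template_pos=tpos[i],
                        alignment_id=aln.alignment_id,
                        col_start=i,
                        ctx_span=(left, right),
                    )
                )
            i = j

    i = 0
    while i < n:
        lab = labels[i]
        if lab in (ColumnLabel.DELETION, ColumnLabel.INSERTION):
            j = i
            while j < n and labels[j] is lab:
                j += 1
            row = aln.template if lab is ColumnLabel.DELETION else aln.read
            emit("deletion" if lab is ColumnLabel.DELETION else "insertion", row, i, j)
            i = j
        else:
            i += 1
    records.sort(key=lambda r: r.col_start)
    return records


def tally_exact_homopolymer_matches(
    aln: PairwiseAlignment, gaps: list[GapRecord], labels: list[ColumnLabel] | None = None
) -> Counter:
    """Count template homopolymers aligned as exact matches, context-free.

    A maximal template homopolymer increments ``(base, length)`` iff every
    alignment column it spans is a match and none of its columns lies inside
    any gap's context span.  Homopolymers that serve as (part of) a gap
    context are the error-bearing occurrences; this tally is their error-free
    complement, the denominator of the per-context gap ratio.
    """
    if labels is None:
        labels = classify_columns(aln)
    covered = np.zeros(len(labels), dtype=bool)
    for g in gaps:
        covered[g.ctx_span[0] : g.ctx_span[1]] = True

    tally: Counter = Counter()
    t = aln.template
    n = len(t)
    i = 0
    while i < n:
        if t[i] == GAP or t[i] not in BASES:
            i += 1
            continue
        base = t[i]
        # maximal template homopolymer in unpadded terms: consecutive template
        # bases equal to `base`, possibly interrupted by insertion columns
        j = i
        last_base_col = i
        while j < n:
            if t[j] == base:
                last_base_col = j
                j += 1
            elif t[j] == GAP:  # insertion column inside the homopolymer span
                j += 1
            else:
                break
        span_end = last_base_col + 1
        length = sum(1 for k in range(i, span_end) if t[k] == base)
        all_match = all(labels[k] is ColumnLabel.MATCH for k in range(i, span_end))
        in_context = covered[i:span_end].any()
        if all_match and not in_context:
            tally[(base, length)] += 1
        i = span_end

    return tally


def count_substitutions(aln: PairwiseAlignment, labels: list[ColumnLabel] | None = None) -> SubstitutionCounts:
    if labels is None:
        labels = classify_columns(aln)
    counts = SubstitutionCounts()
    for lab, (x, y) in zip(labels, aln.columns()):
        if lab is ColumnLabel.SUBSTITUTION:
            counts.add(x, y)
    return counts


def summarize(alignments: list[PairwiseAlignment]) -> ErrorSummary:
    """Pool per-column and per-gap tallies over normalized alignments."""
    summary = ErrorSummary()
    for aln in alignments:
        labels = classify_columns(aln)
        gaps = extract_gaps(aln, labels)
        summary.aligned_positions += len(labels)
        summary.match_positions += sum(1 for l in labels if l is ColumnLabel.MATCH)
        summary.ambiguous_positions += sum(1 for l in labels if l is ColumnLabel.AMBIGUOUS)
        summary.insertion_columns += sum(1 for l in labels if l is ColumnLabel.INSERTION)
        summary.deletion_columns += sum(1 for l in labels if l is ColumnLabel.DELETION)
        summary.substitutions += count_substitutions(aln, labels)
        summary.gaps.extend(gaps)
        summary.tally += tally_exact_homopolymer_matches(aln, gaps, labels)
        summary.n_alignments += 1
    summary.check()
    return summary


def context_gap_ratio(summary: ErrorSummary) -> dict[tuple[str, int], float]:
    """Per-homopolymer odds of erring: context occurrences / exact matches.

    For each ``(base, context length)`` the ratio of the number of gaps with
    that context homopolymer to the number of its exact-match occurrences.
    NaN marks homopolymers never seen as an exact match (undefined ratio).
    """
    numer: Counter = Counter(((g.base, g.context_length) for g in summary.gaps))
    keys = set(numer) | set(summary.tally)
    out: dict[tuple[str, int], float] = {}
    for key in sorted(keys):
        denom = summary.tally.get(key, 0)
        out[key] = numer.get(key, 0) / denom if denom else float("nan")
    return out


def reverse_complement_alignment(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Reverse-complement both rows (a strand-symmetry helper for checks)."""
    from dataclasses import replace

    return replace(
        aln,
        template=aln.template.translate(_COMPLEMENT)[::-1],
        read=aln.read.translate(_COMPLEMENT)[::-1],
    )
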