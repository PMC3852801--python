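"""Homology filtering of read-contig alignments against a related genome.

A normalized read-contig alignment is only trusted (*bona fide*) when the
contig piece it covers has a BLASTN hit in the reference genome of a closely
related species passing an identity floor ``i_min`` and an e-value ceiling
``e_max`` (defaults 0.8 and 0.01).  BLAST itself is consumed as tabular
``-outfmt 6`` input; invoking it is deliberately outside this module.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ace import GAP, PairwiseAlignment

__all__ = [
    "BlastHit",
    "FilterParams",
    "read_blast_tab",
    "write_blast_tab",
    "passes_filter",
    "query_id",
    "select_bona_fide",
]


@dataclass(frozen=True)
class BlastHit:
    """One line of BLAST tabular output (outfmt 6)."""

    query_id: str
    subject_id: str
    pident: float  # percent identity, 0-100
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if self.qstart > self.qend:
            raise ValueError(f"qstart {self.qstart} > qend {self.qend}")


@dataclass(frozen=True)
class FilterParams:
    """Cutoffs for the homology filter.

    ``i_min`` — minimum identity as a fraction; ``e_max`` — maximum e-value;
    ``min_qcov`` — minimum query coverage fraction (no coverage requirement by
    default: only identity and e-value gate a hit).
    """

    i_min: float = 0.8
    e_max: float = 0.01
    min_qcov: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.i_min <= 1.0):
            raise ValueError("i_min must be in [0, 1]")
        if not (0.0 <= self.min_qcov <= 1.0):
            raise ValueError("min_qcov must be in [0, 1]")
        if self.e_max < 0:
            raise ValueError("e_max must be non-negative")


_N_COLUMNS = 12


def read_blast_tab(path) -> list[BlastHit]:
    """Read a BLAST ``-outfmt 6`` tabular file (12 columns, one hit per line)."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != _N_COLUMNS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_N_COLUMNS} columns, got {len(fields)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pident=float(fields[2]),
                        aln_len=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_blast_tab(hits: list[BlastHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.2f}\t{h.aln_len}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart}\t{h.qend}\t{h.sstart}\t"
                f"{h.send}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


def passes_filter(hits: list[BlastHit], query_len: int, params: FilterParams) -> bool:
    """True iff *some* hit clears identity, e-value and coverage cutoffs.

    A single qualifying hit suffices; hits are never combined.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    for h in hits:
        if h.pident / 100.0 < params.i_min:
            continue
        if h.evalue > params.e_max:
            continue
        if params.min_qcov > 0 and (h.qend - h.qstart + 1) / query_len < params.min_qcov:
            continue
        return True
    return False


def query_id(aln: PairwiseAlignment) -> str:
    """Canonical id of the contig piece spanned by an alignment.

    The piece is the unpadded contig substring under the alignment, identified
    as ``contig:start-end`` (1-based inclusive).  Alignments sharing a span
    share a query, so BLAST queries are naturally deduplicated.
    """
    n_bases = len(aln.template) - aln.template.count(GAP)
    end = aln.contig_start + max(n_bases, 1) - 1
    return f"{aln.contig_id}:{aln.contig_start}-{end}"


def select_bona_fide(
    alignments: list[PairwiseAlignment],
    hits_by_query: dict[str, list[BlastHit]],
    params: FilterParams = FilterParams(),
) -> list[PairwiseAlignment]:
    """Retain alignments whose contig piece passes the homology filter.

    ``hits_by_query`` maps :func:`query_id` strings to BLAST hits.  A query
    absent from the map has no hits, and an alignment with no hits is always
    rejected: passing requires at least one qualifying hit.  Output order
    follows the input.
    """
    kept: list[PairwiseAlignment] = []
    for aln in alignments:
        qid = query_id(aln)
        qlen = len(aln.template) - aln.template.count(GAP)
        hits = hits_by_query.get(qid, [])
        if hits and passes_filter(hits, max(qlen, 1), params):
            kept.append(aln)
    return kept
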