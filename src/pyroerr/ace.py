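"""ACE assembly I/O and pairwise read-contig alignment extraction.

An ACE file (consed dialect) stores padded contigs (``CO`` records, pad
character ``*``) together with the placement (``AF``), sequence (``RD``) and
quality clipping (``QA``) of every assembled read.  This module parses such
files into plain dataclasses, writes them back, and projects each read onto
its contig as an equal-length pairwise alignment — the raw material for
sequencing-error extraction.

Internally pads are represented as ``-`` (the usual gap symbol); the ``*``
convention is confined to the ACE files themselves.  Coordinates are 1-based
inclusive throughout, as in ACE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

from Bio.Sequencing import Ace as _BioAce

__all__ = [
    "PaddedRead",
    "PaddedContig",
    "Assembly",
    "PairwiseAlignment",
    "AceParseError",
    "read_ace",
    "write_ace",
    "extract_pairwise",
    "normalize",
]

GAP = "-"
_ALPHABET = set("ACGTN-")


class AceParseError(ValueError):
    """Raised when an ACE file is malformed; the message names the record."""


@dataclass(frozen=True)
class PaddedRead:
    """One read as placed in a padded contig.

    ``contig_offset`` is the 1-based padded-consensus position of the read's
    first character; ACE allows it to be < 1 (read overhanging the contig
    start).  ``clip_range`` is the 1-based inclusive high-quality segment
    within ``padded_seq`` (the QA quality clip).
    """

    read_id: str
    padded_seq: str
    contig_offset: int
    orientation: str = "forward"  # or "reverse" (already complemented, per ACE)
    clip_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.padded_seq:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"read {self.read_id!r}: bad orientation {self.orientation!r}")
        bad = set(self.padded_seq.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id!r}: illegal characters {sorted(bad)}")
        if self.clip_range is not None:
            lo, hi = self.clip_range
            if not (1 <= lo <= hi <= len(self.padded_seq)):
                raise ValueError(
                    f"read {self.read_id!r}: clip_range {self.clip_range} outside "
                    f"[1, {len(self.padded_seq)}]"
                )


@dataclass(frozen=True)
class PaddedContig:
    contig_id: str
    padded_consensus: str
    reads: tuple[PaddedRead, ...] = ()

    def __post_init__(self) -> None:
        if not self.padded_consensus:
            raise ValueError(f"contig {self.contig_id!r}: empty consensus")
        object.__setattr__(self, "reads", tuple(self.reads))

    @property
    def unpadded_consensus(self) -> str:
        return self.padded_consensus.replace(GAP, "")


@dataclass(frozen=True)
class Assembly:
    contigs: tuple[PaddedContig, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "contigs", tuple(self.contigs))
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids in assembly")

    @property
    def n_reads(self) -> int:
        return sum(len(c.reads) for c in self.contigs)


@dataclass(frozen=True)
class PairwiseAlignment:
    """An equal-length gapped template/read pair in contig orientation.

    ``contig_start`` is the 1-based *unpadded* contig coordinate that the
    first alignment column maps to.
    """

    template: str
    read: str
    contig_id: str = ""
    read_id: str = ""
    contig_start: int = 1

    def __post_init__(self) -> None:
        if len(self.template) != len(self.read):
            raise ValueError(
                f"alignment {self.contig_id!r}/{self.read_id!r}: row lengths differ "
                f"({len(self.template)} vs {len(self.read)})"
            )

    def __len__(self) -> int:
        return len(self.template)

    @property
    def alignment_id(self) -> str:
        return f"{self.contig_id}/{self.read_id}"

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.template, self.read)


# ---------------------------------------------------------------------------
# reading / writing


def read_ace(path) -> Assembly:
    """Parse an ACE assembly file.

    One :class:`PaddedContig` per CO record; every AF-placed read must have a
    matching RD record.  ``*`` pads become ``-``.  Raises
    :class:`AceParseError` naming the offending record on malformed input.
    """
    try:
        with open(path) as fh:
            record = _BioAce.read(fh)
    except ValueError as exc:
        raise AceParseError(f"{path}: {exc}") from exc

    contigs = []
    for contig in record.contigs:
        if contig.sequence is None or not contig.sequence:
            raise AceParseError(f"CO {contig.name}: missing consensus sequence")
        consensus = contig.sequence.upper().replace("*", GAP)
        if contig.nbases is not None and len(consensus) != contig.nbases:
            raise AceParseError(
                f"CO {contig.name}: declared {contig.nbases} bases, "
                f"sequence has {len(consensus)}"
            )
        rd_by_name: dict[str, object] = {}
        for rd_entry in contig.reads:
            if rd_entry.rd is None:
                continue
            rd_by_name[rd_entry.rd.name] = rd_entry
        reads = []
        for af in contig.af:
            entry = rd_by_name.get(af.name)
            if entry is None:
                raise AceParseError(f"AF {af.name}: no matching RD record")
            rd = entry.rd
            seq = rd.sequence.upper().replace("*", GAP)
            if rd.padded_bases is not None and len(seq) != rd.padded_bases:
                raise AceParseError(
                    f"RD {rd.name}: declared {rd.padded_bases} bases, "
                    f"sequence has {len(seq)}"
                )
            clip = None
            if entry.qa is not None and entry.qa.qual_clipping_start not in (None, -1):
                clip = (entry.qa.qual_clipping_start, entry.qa.qual_clipping_end)
            reads.append(
                PaddedRead(
                    read_id=af.name,
                    padded_seq=seq,
                    contig_offset=af.padded_start,
                    orientation="reverse" if af.coru == "C" else "forward",
                    clip_range=clip,
                )
            )
        contigs.append(PaddedContig(contig.name, consensus, tuple(reads)))
    return Assembly(tuple(contigs), source=str(path))


def write_ace(assembly: Assembly, path) -> None:
    """Write ``assembly`` as a consed-style ACE file (pads re-encoded as ``*``).

    ``read_ace(write_ace(a)) == a`` up to the ``source`` label.  A uniform
    placeholder BQ section is emitted for each contig (quality values are
    parsed but ignored on the way back in).
    """
    lines: list[str] = [f"AS {len(assembly.contigs)} {assembly.n_reads}", ""]
    for contig in assembly.contigs:
        padded = contig.padded_consensus.replace(GAP, "*")
        lines.append(f"CO {contig.contig_id} {len(padded)} {len(contig.reads)} 0 U")
        lines.extend(_wrap(padded))
        lines.append("")
        lines.append("BQ")
        n_unpadded = len(contig.unpadded_consensus)
        lines.extend(_wrap_tokens(["20"] * n_unpadded, per_line=50))
        lines.append("")
        for read in contig.reads:
            flag = "C" if read.orientation == "reverse" else "U"
            lines.append(f"AF {read.read_id} {flag} {read.contig_offset}")
        lines.append("")
        for read in contig.reads:
            seq = read.padded_seq.replace(GAP, "*")
            lines.append(f"RD {read.read_id} {len(seq)} 0 0")
            lines.extend(_wrap(seq))
            lines.append("")
            if read.clip_range is None:
                qa = (-1, -1)
            else:
                qa = read.clip_range
            lines.append(f"QA {qa[0]} {qa[1]} 1 {len(seq)}")
            lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        fh.write("\n")


def _wrap(seq: str, width: int = 50) -> list[str]:
    return [seq[i : i + width] for i in range(0, len(seq), width)] or [""]


def _wrap_tokens(tokens: list[str], per_line: int) -> list[str]:
    return [
        " ".join(tokens[i : i + per_line]) for i in range(0, len(tokens), per_line)
    ] or [""]


# ---------------------------------------------------------------------------
# pairwise extraction and normalization


def extract_pairwise(assembly: Assembly, honor_clip: bool = True) -> list[PairwiseAlignment]:
    """Project each placed read onto its contig as a pairwise alignment.

    The template row is the padded-consensus substring under the read's span
    (quality-clipped when ``honor_clip``); the read row is the corresponding
    padded-read substring.  Overhanging read prefixes/suffixes are trimmed to
    the consensus span.  Reads whose span falls entirely outside the consensus
    are skipped with a warning.  Reverse-orientation reads are already stored
    complemented (ACE convention), so all output is in contig orientation.
    """
    out: list[PairwiseAlignment] = []
    for contig in assembly.contigs:
        cons = contig.padded_consensus
        for read in contig.reads:
            o = read.contig_offset
            if honor_clip and read.clip_range is not None:
                r1, r2 = read.clip_range
            else:
                r1, r2 = 1, len(read.padded_seq)
            # clamp the read-column window [r1, r2] to the consensus span
            r1 = max(r1, 2 - o)
            r2 = min(r2, len(cons) - o + 1)
            if r1 > r2:
                warnings.warn(
                    f"read {read.read_id} lies outside contig {contig.contig_id}; skipped"
                )
                continue
            p1 = o + r1 - 1  # 1-based padded consensus start
            template = cons[p1 - 1 : p1 - 1 + (r2 - r1 + 1)]
            read_row = read.padded_seq[r1 - 1 : r2]
            contig_start = len(cons[: p1 - 1].replace(GAP, "")) + 1
            out.append(
                PairwiseAlignment(
                    template=template,
                    read=read_row,
                    contig_id=contig.contig_id,
                    read_id=read.read_id,
                    contig_start=contig_start,
                )
            )
    return out


def normalize(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Drop gap-only columns (pad positions contributed by *other* reads).

    Multi-read padding projects onto a pairwise alignment as columns gapped in
    both rows; removing exactly those columns yields the normalized alignment.
    Idempotent; preserves column order and every non-gap symbol.
    """
    keep = [i for i, (x, y) in enumerate(zip(aln.template, aln.read)) if not (x == GAP and y == GAP)]
    if len(keep) == len(aln.template):
        return aln
    template = "".join(aln.template[i] for i in keep)
    read = "".join(aln.read[i] for i in keep)
    return replace(aln, template=template, read=read)
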