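"""Synthetic pyrosequencing-style assemblies with a ground-truth error ledger.

The generator emulates the situation the extraction pipeline assumes: a known
reference sequence, reads drawn from uniformly placed windows, rare uniform
substitutions, and homopolymer-context indels whose per-homopolymer
probability grows with homopolymer length and whose lengths follow a
configurable law (geometric or truncated Zipf).  Reads are assembled into a
padded consensus exactly as an assembler would lay them out — the consensus
equals the reference padded with ``-`` wherever *any* read carries an
insertion, so reads without that insertion acquire the gap-only columns that
alignment normalization must remove.  Every injected event is recorded in a
:class:`GroundTruth` ledger, the oracle for end-to-end recovery tests.

Design constraints that keep ledger <-> extraction equality exact:

* at most one gap per homopolymer occurrence per read;
* deletions are capped at the homopolymer length (over-draws resampled);
* gaps sit canonical-left within their homopolymer / pad slot;
* no substitutions inside a homopolymer that received a gap;
* the first and last (possibly window-truncated) homopolymers of a read
  receive no gaps, so no event is lost to read-edge trimming.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from .ace import GAP, Assembly, PaddedContig, PaddedRead
from .gapfit import GeometricParams, ZipfParams
from .homology import BlastHit, query_id, write_blast_tab
from . import ace as _ace
from . import homology as _homology

__all__ = [
    "SimulationParams",
    "InjectedGap",
    "InjectedSubstitution",
    "SimulatedRead",
    "GroundTruth",
    "default_indel_rate",
    "generate_reference",
    "simulate_reads",
    "build_assembly",
    "emit_blast_hits",
    "write_fasta",
    "simulate_assembly",
]

BASES = "ACGT"


def default_indel_rate(length: int) -> float:
    """Per-homopolymer gap probability, increasing with homopolymer length.

    Doubles per extra base from 0.007 at length 1, capped at 0.9 — the
    qualitative shape of observed per-context gap ratios (the flow-signal
    ambiguity grows with homopolymer length) at an overall yield of roughly
    1.2 gaps per hundred homopolymer occurrences, which puts indels and
    substitutions at comparable abundance under the default rates.
    """
    return min(0.9, 0.007 * 2.0 ** (length - 1))


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic assembly.

    Defaults emulate a 100 kb slice of a bacterial genome sequenced at 20x
    with 250 +/- 30 nt reads, a 0.8% per-base substitution rate, indels
    confined to homopolymer contexts at :func:`default_indel_rate`, gap
    lengths from a truncated Zipf (sigma = 1.6, L = 10), and 57% of gaps
    being insertions.
    """

    genome_length: int = 100_000
    max_run: int = 8
    homopolymer_spectrum: dict | None = None  # (base, length) -> min count
    run_length_decay: float = 0.3  # P(run length = l) ~ decay^(l-1), l <= max_run
    coverage: float = 20.0
    read_length_mean: float = 250.0
    read_length_sd: float = 30.0
    substitution_rate: float = 0.008
    indel_context_rate: Callable[[int], float] = default_indel_rate
    gap_model: Union[GeometricParams, ZipfParams] = ZipfParams(sigma=1.6, L=10)
    insertion_fraction: float = 0.57
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be a probability")
        if not (0.0 <= self.insertion_fraction <= 1.0):
            raise ValueError("insertion_fraction must be a probability")


@dataclass(frozen=True)
class InjectedGap:
    read_id: str
    kind: str  # "insertion" | "deletion"
    base: str
    length: int
    context_length: int
    template_pos: int  # 1-based reference coordinate of the first gap column

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.kind, self.base, self.length, self.context_length)


@dataclass(frozen=True)
class InjectedSubstitution:
    read_id: str
    template_pos: int  # 1-based
    template_base: str
    read_base: str


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    start: int  # 0-based reference offset of the window
    template_row: str  # true pairwise alignment, reference on top
    read_row: str

    @property
    def sequence(self) -> str:
        return self.read_row.replace(GAP, "")


@dataclass
class GroundTruth:
    """Ledger of every injected event plus the true pairwise alignments."""

    gaps: list[InjectedGap] = field(default_factory=list)
    substitutions: list[InjectedSubstitution] = field(default_factory=list)

    def gap_key_multiset(self) -> Counter:
        return Counter(g.key for g in self.gaps)

    def to_json(self, path) -> None:
        payload = {
            "gaps": [vars(g) for g in self.gaps],
            "substitutions": [vars(s) for s in self.substitutions],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            gaps=[InjectedGap(**g) for g in payload["gaps"]],
            substitutions=[InjectedSubstitution(**s) for s in payload["substitutions"]],
        )


# ---------------------------------------------------------------------------
# reference generation


def _runs_of(seq: str) -> list[tuple[str, int]]:
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        runs.append((seq[i], j - i))
        i = j
    return runs


def generate_reference(params: SimulationParams, rng: np.random.Generator) -> str:
    """Random reference honoring the max-run constraint and optional spectrum.

    The sequence is built as a list of homopolymer runs (base differing from
    its neighbour, length from a truncated geometric law).  When a spectrum
    of minimum ``(base, length) -> count`` targets is given, randomly chosen
    runs are replaced until each target is met; an unsatisfiable spectrum
    raises.
    """
    G = params.genome_length
    max_run = params.max_run
    decay = params.run_length_decay
    probs = decay ** np.arange(max_run)
    probs /= probs.sum()

    runs: list[tuple[str, int]] = []
    total = 0
    prev = ""
    while total < G:
        choices = [b for b in BASES if b != prev]
        base = choices[rng.integers(len(choices))]
        length = int(rng.choice(np.arange(1, max_run + 1), p=probs))
        length = min(length, G - total) or 1
        runs.append((base, length))
        total += length
        prev = base

    if not params.homopolymer_spectrum:
        return "".join(b * l for b, l in runs)[:G]

    # plant, materialize, and verify realized counts (trimming to the genome
    # length can cut tail runs, so replant any deficit and re-check)
    spectrum = dict(params.homopolymer_spectrum)
    want = dict(spectrum)
    for _ in range(20):
        runs = _plant_spectrum(runs, want, rng)
        seq = "".join(b * l for b, l in runs)[:G]
        realized = Counter(_runs_of(seq))
        deficit = {k: w - realized[k] for k, w in spectrum.items() if realized[k] < w}
        if not deficit:
            return seq
        want = {
            k: sum(1 for r in runs if r == k) + deficit.get(k, 0) for k in spectrum
        }
    raise ValueError("unsatisfiable homopolymer spectrum after replanting")


def _plant_spectrum(
    runs: list[tuple[str, int]], spectrum: dict, rng: np.random.Generator
) -> list[tuple[str, int]]:
    runs = list(runs)
    planted: set[int] = set()
    for (base, length), want in spectrum.items():
        have = sum(1 for i, r in enumerate(runs) if r == (base, length))
        attempts = 0
        while have < want:
            attempts += 1
            if attempts > 1000 * want:
                raise ValueError(
                    f"unsatisfiable homopolymer spectrum: cannot place {want} runs of "
                    f"({base},{length})"
                )
            i = int(rng.integers(1, len(runs) - 1))  # keep ends free for trimming
            if i in planted:
                continue
            if runs[i - 1][0] == base or runs[i + 1][0] == base:
                continue
            if runs[i] in spectrum:  # don't consume another target's run
                continue
            runs[i] = (base, length)
            planted.add(i)
            have += 1
    return runs


# ---------------------------------------------------------------------------
# read simulation


def _sample_gap_length(
    model: Union[GeometricParams, ZipfParams], rng: np.random.Generator, cap: int | None = None
) -> int:
    """One draw from the gap-length law, resampled until it fits under cap."""
    if isinstance(model, GeometricParams):
        if model.beta >= 1.0:
            raise ValueError("geometric gap model needs beta < 1")
        draw = lambda: int(rng.geometric(1.0 - model.beta))
    else:
        from scipy import stats

        k = np.arange(1, model.L + 1)
        cdf = np.cumsum(stats.zipfian.pmf(k, model.sigma, model.L))
        cdf[-1] = 1.0
        draw = lambda: int(np.searchsorted(cdf, rng.random()) + 1)
    for _ in range(10_000):
        g = draw()
        if cap is None or g <= cap:
            return g
    raise RuntimeError("gap-length resampling failed to satisfy the cap")


def simulate_reads(
    reference: str, params: SimulationParams, rng: np.random.Generator
) -> tuple[list[SimulatedRead], GroundTruth]:
    """Draw reads from uniform windows and inject errors per homopolymer.

    For every *interior* homopolymer of a read window (the first and last,
    possibly truncated, runs are left untouched), with probability
    ``indel_context_rate(l)`` a single gap is injected: an insertion with
    probability ``insertion_fraction`` (context length l + gap), else a
    deletion of at most l bases (context length l).  Substitutions hit each
    base of every gap-free homopolymer independently.  The true pairwise
    alignment of each read is recorded alongside the event ledger.
    """
    G = len(reference)
    if G == 0:
        raise ValueError("empty reference")
    n_reads = max(1, int(round(params.coverage * G / params.read_length_mean)))
    truth = GroundTruth()
    reads: list[SimulatedRead] = []

    for idx in range(n_reads):
        length = int(round(rng.normal(params.read_length_mean, params.read_length_sd)))
        length = max(min(50, G), min(length, G))
        start = int(rng.integers(0, G - length + 1))
        window = reference[start : start + length]
        read_id = f"read{idx:06d}"

        runs = _runs_of(window)
        template_parts: list[str] = []
        read_parts: list[str] = []
        pos = start  # 0-based reference coordinate of the current run start
        for r, (base, run_len) in enumerate(runs):
            interior = 0 < r < len(runs) - 1
            event = None
            if interior and rng.random() < params.indel_context_rate(run_len):
                if rng.random() < params.insertion_fraction:
                    g = _sample_gap_length(params.gap_model, rng)
                    event = ("insertion", g)
                else:
                    g = _sample_gap_length(params.gap_model, rng, cap=run_len)
                    event = ("deletion", g)

            if event is None:
                # independent substitutions on a gap-free homopolymer
                chars = []
                for k in range(run_len):
                    if rng.random() < params.substitution_rate:
                        others = [b for b in BASES if b != base]
                        chars.append(others[rng.integers(3)])
                    else:
                        chars.append(base)
                for k, c in enumerate(chars):
                    if c != base:
                        truth.substitutions.append(
                            InjectedSubstitution(read_id, pos + k + 1, base, c)
                        )
                template_parts.append(base * run_len)
                read_parts.append("".join(chars))
            elif event[0] == "insertion":
                g = event[1]
                template_parts.append(GAP * g + base * run_len)
                read_parts.append(base * (g + run_len))
                truth.gaps.append(
                    InjectedGap(read_id, "insertion", base, g, run_len + g, pos + 1)
                )
            else:
                g = event[1]
                template_parts.append(base * run_len)
                read_parts.append(GAP * g + base * (run_len - g))
                truth.gaps.append(
                    InjectedGap(read_id, "deletion", base, g, run_len, pos + 1)
                )
            pos += run_len

        reads.append(
            SimulatedRead(
                read_id=read_id,
                start=start,
                template_row="".join(template_parts),
                read_row="".join(read_parts),
            )
        )
    return reads, truth


# ---------------------------------------------------------------------------
# assembly layout


def build_assembly(
    reference: str,
    reads: list[SimulatedRead],
    truth: GroundTruth | None = None,
    contig_id: str = "contig1",
) -> Assembly:
    """Lay simulated reads out against a padded consensus.

    The consensus is the reference padded with ``-`` at the union of all
    insertion slots (one slot per reference position, wide enough for the
    longest insertion any read carries there, inserted bases packed left).
    Reads that do not insert at a slot carry ``-`` across it, producing the
    gap-only columns that pairwise normalization removes.
    """
    # slot widths: insertions recorded per read at the reference position of
    # the homopolymer's first base (0-based), read off the true alignments
    slot: dict[int, int] = {}
    per_read_ins: list[dict[int, int]] = []
    for read in reads:
        ins: dict[int, int] = {}
        pos = read.start
        i = 0
        t = read.template_row
        while i < len(t):
            if t[i] == GAP:
                j = i
                while j < len(t) and t[j] == GAP:
                    j += 1
                ins[pos] = j - i
                slot[pos] = max(slot.get(pos, 0), j - i)
                i = j
            else:
                pos += 1
                i += 1
        per_read_ins.append(ins)

    # padded consensus and the padded column (1-based) of each reference base
    G = len(reference)
    col_of_base = np.zeros(G, dtype=np.int64)
    first_pad_col = {}
    parts = []
    col = 0
    for p in range(G):
        w = slot.get(p, 0)
        if w:
            first_pad_col[p] = col + 1
            parts.append(GAP * w)
            col += w
        parts.append(reference[p])
        col += 1
        col_of_base[p] = col
    consensus = "".join(parts)

    padded_reads = []
    for read, ins in zip(reads, per_read_ins):
        chars: list[str] = []
        start_col: int | None = None
        pos = read.start
        i = 0
        t, r = read.template_row, read.read_row
        while i < len(t):
            if t[i] == GAP:  # this read's insertion occupies the slot's left
                g = ins[pos]
                w = slot[pos]
                if start_col is None:
                    start_col = first_pad_col[pos]
                chars.append(r[i : i + g])
                chars.append(GAP * (w - g))
                i += g
            else:
                w = slot.get(pos, 0)
                if w and pos not in ins and start_col is not None:
                    chars.append(GAP * w)  # slot padded by other reads
                if start_col is None:
                    start_col = int(col_of_base[pos])
                chars.append(r[i])
                pos += 1
                i += 1
        row = "".join(chars).rstrip(GAP)
        # strip leading pads (a slot at the window start the read doesn't use)
        lead = len(row) - len(row.lstrip(GAP))
        row = row[lead:]
        padded_reads.append(
            PaddedRead(
                read_id=read.read_id,
                padded_seq=row,
                contig_offset=int(start_col) + lead,
                orientation="forward",
            )
        )
    contig = PaddedContig(contig_id, consensus, tuple(padded_reads))
    return Assembly((contig,), source="synthetic")


# ---------------------------------------------------------------------------
# mock BLAST hits and FASTA


def emit_blast_hits(
    assembly: Assembly,
    reference: str,
    path=None,
    subject_id: str = "reference",
    evalue: float = 1e-30,
) -> list[BlastHit]:
    """One mock BLAST hit per contig piece, identity measured against the
    reference (edit distance via edlib), written as outfmt-6 if ``path``.

    This exercises the homology filter offline: an error-free consensus piece
    scores pident 100 and passes the default cutoffs.
    """
    import edlib

    hits: list[BlastHit] = []
    seen: set[str] = set()
    for aln in _ace.extract_pairwise(assembly, honor_clip=False):
        aln = _ace.normalize(aln)
        qid = query_id(aln)
        if qid in seen:
            continue
        seen.add(qid)
        piece = aln.template.replace(GAP, "")
        if not piece:
            continue
        start = aln.contig_start
        ref_piece = reference[start - 1 : start - 1 + len(piece)]
        dist = edlib.align(piece, ref_piece)["editDistance"]
        span = max(len(piece), len(ref_piece))
        pident = 100.0 * (span - dist) / span
        hits.append(
            BlastHit(
                query_id=qid,
                subject_id=subject_id,
                pident=round(pident, 2),
                aln_len=span,
                mismatch=dist,
                gapopen=0,
                qstart=1,
                qend=len(piece),
                sstart=start,
                send=start + len(ref_piece) - 1,
                evalue=evalue,
                bitscore=2.0 * span,
            )
        )
    if path is not None:
        write_blast_tab(hits, path)
    return hits


def write_fasta(name: str, sequence: str, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def simulate_assembly(
    params: SimulationParams | None = None, seed: int | None = None
) -> tuple[str, Assembly, GroundTruth]:
    """Convenience wrapper: reference -> reads -> assembly, fully seeded."""
    params = params or SimulationParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    reference = generate_reference(params, rng)
    reads, truth = simulate_reads(reference, params, rng)
    assembly = build_assembly(reference, reads, truth)
    return reference, assembly, truth
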