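"""Summary statistics, table emission and the end-to-end pipeline.

Ties the stages together: ACE parsing -> pairwise extraction ->
normalization -> homology filtering -> error extraction -> gap-model fits ->
context rank tests, and derives every headline number (match coverage,
substitution share, per-cell substitution percentages) from the resulting
counts.  A report's percentages are always recomputed from its own counts —
an internal audit asserts this on every emission.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ace as ace_io
from . import gapfit
from . import ranktests
from .errors import BASES, ErrorSummary, SubstitutionCounts, summarize, context_gap_ratio
from .homology import FilterParams, read_blast_tab, select_bona_fide

__all__ = [
    "RunReport",
    "error_share",
    "match_coverage",
    "substitution_percentages",
    "substitution_pair_sums",
    "gap_samples_by_context",
    "build_report",
    "run_pipeline",
    "write_report",
]


def error_share(substitutions: int, insertion_gaps: int, deletion_gaps: int) -> float:
    """Substitutions as a percentage of all errors (subs + indel gaps)."""
    total = substitutions + insertion_gaps + deletion_gaps
    if total <= 0:
        raise ValueError("no errors to take a share of")
    return 100.0 * substitutions / total


def match_coverage(match_positions: int, aligned_positions: int) -> float:
    """Percentage of aligned positions that are exact matches."""
    if aligned_positions <= 0:
        raise ValueError("aligned_positions must be positive")
    return 100.0 * match_positions / aligned_positions


def substitution_percentages(matrix: SubstitutionCounts) -> pd.DataFrame:
    """Each cell as a percentage of the total substitution count."""
    total = matrix.total
    if total == 0:
        return pd.DataFrame(
            np.zeros((4, 4)), index=list(BASES), columns=list(BASES)
        )
    return matrix.to_frame() * 100.0 / total


def substitution_pair_sums(matrix: SubstitutionCounts) -> pd.DataFrame:
    """Directed and symmetric substitution-pair percentages.

    For each unordered base pair {x, y}: the directed shares x->y and y->x
    and their symmetric sum, as percentages of all substitutions.  Emitted
    for the A<->T vs C<->G comparison without taking a position on which
    direction a published aggregate refers to.
    """
    total = matrix.total
    rows = []
    for i, x in enumerate(BASES):
        for y in BASES[i + 1 :]:
            fwd = matrix[(x, y)]
            rev = matrix[(y, x)]
            rows.append(
                {
                    "pair": f"{x}/{y}",
                    "forward": fwd,
                    "reverse": rev,
                    "forward_pct": 100.0 * fwd / total if total else 0.0,
                    "reverse_pct": 100.0 * rev / total if total else 0.0,
                    "symmetric_pct": 100.0 * (fwd + rev) / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows).set_index("pair")


def gap_samples_by_context(summary: ErrorSummary, kind: str | None = None) -> dict:
    """Gap-length samples keyed by (base, context length)."""
    groups = ranktests.group_gaps(summary.gaps, group_by="context", kind=kind)
    return {
        key: gapfit.GapLengthSample(tuple(lengths), context_key=key)
        for key, lengths in sorted(groups.items())
    }


@dataclass
class RunReport:
    """All derived numbers of one pipeline run, recomputable from its counts."""

    n_candidate_alignments: int = 0
    n_bona_fide_alignments: int = 0
    candidate_avg_length: float = 0.0
    bona_fide_avg_length: float = 0.0
    aligned_positions: int = 0
    match_positions: int = 0
    ambiguous_positions: int = 0
    substitution_total: int = 0
    insertion_gap_count: int = 0
    deletion_gap_count: int = 0
    insertion_columns: int = 0
    deletion_columns: int = 0
    match_coverage_pct: float = 0.0
    substitution_rate_pct: float = 0.0
    substitution_share_pct: float | None = None
    substitution_matrix: list = field(default_factory=list)
    substitution_pct: list = field(default_factory=list)
    gap_length_histogram: dict = field(default_factory=dict)  # kind -> {length: count}
    homopolymer_tally: dict = field(default_factory=dict)  # "base:length" -> count

    def audit(self) -> None:
        """Every percentage must equal its definition on the report's counts."""
        assert abs(
            self.match_coverage_pct - match_coverage(self.match_positions, self.aligned_positions)
        ) < 1e-9
        assert abs(
            self.substitution_rate_pct - 100.0 * self.substitution_total / self.aligned_positions
        ) < 1e-9
        n_err = self.substitution_total + self.insertion_gap_count + self.deletion_gap_count
        if n_err:
            assert self.substitution_share_pct is not None
            assert abs(
                self.substitution_share_pct
                - error_share(
                    self.substitution_total, self.insertion_gap_count, self.deletion_gap_count
                )
            ) < 1e-9
        total = sum(sum(row) for row in self.substitution_matrix)
        assert total == self.substitution_total
        if total:
            for row_c, row_p in zip(self.substitution_matrix, self.substitution_pct):
                for c, p in zip(row_c, row_p):
                    assert abs(p - 100.0 * c / total) < 1e-9

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RunReport":
        payload = json.loads(Path(path).read_text())
        report = cls(**payload)
        report.gap_length_histogram = {
            kind: {int(k): v for k, v in hist.items()}
            for kind, hist in report.gap_length_histogram.items()
        }
        return report


def build_report(
    summary: ErrorSummary,
    n_candidate: int | None = None,
    candidate_positions: int | None = None,
) -> RunReport:
    """Derive every headline number from an :class:`ErrorSummary`."""
    ins = [g for g in summary.gaps if g.kind == "insertion"]
    dels = [g for g in summary.gaps if g.kind == "deletion"]
    n_cand = n_candidate if n_candidate is not None else summary.n_alignments
    report = RunReport(
        n_candidate_alignments=n_cand,
        n_bona_fide_alignments=summary.n_alignments,
        candidate_avg_length=(
            candidate_positions / n_cand if (candidate_positions and n_cand) else 0.0
        ),
        bona_fide_avg_length=(
            summary.aligned_positions / summary.n_alignments if summary.n_alignments else 0.0
        ),
        aligned_positions=summary.aligned_positions,
        match_positions=summary.match_positions,
        ambiguous_positions=summary.ambiguous_positions,
        substitution_total=summary.substitutions.total,
        insertion_gap_count=len(ins),
        deletion_gap_count=len(dels),
        insertion_columns=summary.insertion_columns,
        deletion_columns=summary.deletion_columns,
    )
    if summary.aligned_positions:
        report.match_coverage_pct = match_coverage(
            summary.match_positions, summary.aligned_positions
        )
        report.substitution_rate_pct = (
            100.0 * summary.substitutions.total / summary.aligned_positions
        )
    n_err = report.substitution_total + report.insertion_gap_count + report.deletion_gap_count
    if n_err:
        report.substitution_share_pct = error_share(
            report.substitution_total, report.insertion_gap_count, report.deletion_gap_count
        )
    report.substitution_matrix = summary.substitutions.matrix.tolist()
    report.substitution_pct = substitution_percentages(summary.substitutions).values.tolist()
    for kind, records in (("insertion", ins), ("deletion", dels)):
        hist = Counter(g.length for g in records)
        report.gap_length_histogram[kind] = dict(sorted(hist.items()))
    report.homopolymer_tally = {
        f"{base}:{length}": count for (base, length), count in sorted(summary.tally.items())
    }
    report.audit()
    return report


@dataclass
class PipelineResult:
    report: RunReport
    summary: ErrorSummary
    fits: pd.DataFrame | None
    test_matrices: dict
    ratios: dict


def run_pipeline(
    ace_path,
    blast_path=None,
    params: FilterParams = FilterParams(),
    honor_clip: bool = True,
    pool_small: bool = False,
    group_by: str = "context_length",
    alpha: float = 0.01,
) -> PipelineResult:
    """ACE file (+ optional BLAST hits) -> full error characterization.

    Without a BLAST table the homology filter is skipped and every candidate
    alignment is analysed.
    """
    assembly = ace_io.read_ace(ace_path)
    candidates = [ace_io.normalize(a) for a in ace_io.extract_pairwise(assembly, honor_clip)]
    candidate_positions = sum(len(a) for a in candidates)
    if blast_path is not None:
        hits = read_blast_tab(blast_path)
        by_query: dict = {}
        for h in hits:
            by_query.setdefault(h.query_id, []).append(h)
        bona_fide = select_bona_fide(candidates, by_query, params)
    else:
        bona_fide = candidates

    summary = summarize(bona_fide)
    report = build_report(
        summary, n_candidate=len(candidates), candidate_positions=candidate_positions
    )

    fits = None
    samples = {
        key: s for key, s in gap_samples_by_context(summary).items() if s.n > 0
    }
    if samples:
        fits = gapfit.compare_models(samples, pool_small=pool_small)

    matrices = {}
    for kind in ("insertion", "deletion"):
        if any(g.kind == kind for g in summary.gaps):
            matrices[kind] = ranktests.pairwise_tests(
                summary.gaps, group_by=group_by, alpha=alpha, kind=kind
            )
    return PipelineResult(
        report=report,
        summary=summary,
        fits=fits,
        test_matrices=matrices,
        ratios=context_gap_ratio(summary),
    )


def write_report(result: PipelineResult, out_dir) -> None:
    """Emit report.json plus the TSV tables of one run."""
    out = Path(out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    result.report.to_json(out / "report.json")

    tally = result.summary.tally
    if tally:
        lengths = sorted({length for _, length in tally})
        frame = pd.DataFrame(
            {length: {b: tally.get((b, length), 0) for b in BASES} for length in lengths}
        )
        frame.index.name = "base"
        frame.to_csv(tables / "homopolymer_matches.tsv", sep="\t")

    subs = result.summary.substitutions.to_frame()
    subs.index.name = "template"
    subs.to_csv(tables / "substitutions.tsv", sep="\t")
    pair = substitution_pair_sums(result.summary.substitutions)
    pair.to_csv(tables / "substitution_pairs.tsv", sep="\t")

    gaps = pd.DataFrame(
        [
            {
                "alignment_id": g.alignment_id,
                "kind": g.kind,
                "base": g.base,
                "length": g.length,
                "context_length": g.context_length,
                "template_pos": g.template_pos,
            }
            for g in result.summary.gaps
        ]
    )
    gaps.to_csv(tables / "gaps.tsv", sep="\t", index=False)

    if result.ratios:
        ratio_frame = pd.DataFrame(
            [
                {"base": b, "context_length": length, "ratio": r}
                for (b, length), r in sorted(result.ratios.items())
            ]
        )
        ratio_frame.to_csv(tables / "context_gap_ratios.tsv", sep="\t", index=False)

    if result.fits is not None:
        result.fits.to_csv(tables / "gap_model_fits.tsv", sep="\t")

    for kind, matrix in result.test_matrices.items():
        matrix.to_frame().to_csv(tables / f"mann_whitney_{kind}.tsv", sep="\t")
        matrix.to_records().to_csv(
            tables / f"mann_whitney_{kind}_detail.tsv", sep="\t", index=False
        )
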