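# Methods

## The error-extraction model

The package treats an assembly as an implicit collection of pairwise
read–template alignments. From a padded ACE file, each read's placement
gives an equal-length pair (template piece, read piece) over
{A,C,G,T,N,−}. Two cleaning steps precede any counting:

* **Normalization.** Multi-read padding projects onto a pairwise alignment
  as columns gapped in both rows. Exactly those columns are removed;
  nothing else is touched. The operation is idempotent and conserves every
  non-gap symbol (property-tested).
* **Homology filtering.** An alignment is *bona fide* only if its contig
  piece has a BLAST hit in a related reference genome with identity
  ≥ `i_min` (default 0.8) and e-value ≤ `e_max` (default 0.01). A single
  qualifying hit suffices; hits are never combined. The query unit is the
  unpadded contig substring under each alignment, deduplicated by span. An
  optional minimum query coverage (`min_qcov`, default 0 — i.e. off) is
  exposed for stricter use. BLAST itself is consumed as `-outfmt 6` input;
  the package never shells out to it.

Columns are then classified: x==y bases → match; x≠y bases →
substitution; base over `-` → deletion; `-` over base → insertion; any `N`
→ ambiguous. Ambiguous columns are counted separately and excluded from
every tally (the choice for ambiguity codes was open; exclusion keeps all
other counts interpretable).

**Gap contexts.** A maximal run of deletion (insertion) columns is split
into per-base sub-gaps by template (read) base — a deleted run `AAT`
yields an A-gap of length 2 and a T-gap of length 1. Each sub-gap's
context is its gapped bases plus the maximal flanking runs of *matched*
columns of the same base on both sides; a substitution breaks a flank even
when the template base matches the gap base (literal reading of "maximal
run of matches"). Deletion contexts live on the template, insertion
contexts on the read; both are keyed by (base, context length). Gap
positions are recorded at the first gap column in unpadded template
coordinates, with gaps placed canonical-left inside a homopolymer so that
coordinates are reproducible.

**Exact-match tally.** A maximal template homopolymer counts as an exact
match of (base, length) iff every column it spans is a match and no column
lies inside any gap's context span. Because context flanks are matches of
the gap's own base, only same-base homopolymers can ever be excluded this
way. The ratio (occurrences as gap context) / (exact-match occurrences)
per (base, length) is the per-homopolymer error odds; it is reported as
NaN when the denominator is zero.

## Gap-length models

* Geometric: P(X=k) = β^(k−1)(1−β), k ≥ 1. MLE in closed form,
  β̂ = (x̄−1)/x̄; an all-ones sample sits on the boundary β̂ = 0.
* Truncated Zipf: P(X=k) = k^(−σ)/Σ_{j≤L} j^(−σ), 1 ≤ k ≤ L, with L the
  maximum observed gap length. The log-likelihood depends on the data only
  through Σ log x_i, so σ̂ is found by bounded scalar minimization on
  (10⁻⁶, σ_max] with tolerance 10⁻⁸. σ_max = 20: beyond that the pmf is
  numerically a point mass at 1, and an all-ones sample (whose likelihood
  increases in σ without bound) is reported at σ_max with the convergence
  flag lowered. Evaluation is in the log domain throughout (pmfs via
  `scipy.stats.geom` / `scipy.stats.zipfian`).

**Chi-square comparison.** χ² = Σ_{k=1..L} (O_k − E_k)²/E_k with
E_k = N·pmf(k). The truncated geometric expectations are deliberately not
renormalized over 1..L, so Σ E_k < N slightly; the statistic is read as a
raw sum of squared residuals (smaller = closer), which is how the model
comparison uses it. Degrees of freedom are bins − 2 (one estimated
parameter; p is NaN when df < 1). Bin pooling to E ≥ 5 (classical validity
rule) is available but off by default, since the comparison of raw
residual sums needs no pooling; it is recommended when p-values themselves
are of interest. Bins with E_k = 0 are skipped.

## Rank tests across contexts

Gap lengths are grouped by context length (pooling bases; grouping by
(base, length) is also available) and every unordered pair of groups is
compared with a two-sided Mann-Whitney test at α = 0.01, insertions and
deletions separately. The exact null is used when both groups have ≤ 8
observations and no value occurs in both samples (cross-sample ties are
what distort the exact null; within-group duplicates leave U unchanged);
otherwise the normal approximation with midranks, tie correction and
continuity correction. Pairs with an empty group are reported
`not_performed` (blank cells); asymptotic results on groups smaller than 8
carry an `unreliable` flag. No multiple-testing correction is applied by
default; a Bonferroni option exists. When both groups are a single
repeated value the test is degenerate and reported as accept with p = 1.

Under the null (two groups resampled from one pooled sample) the
rejection rate at α = 0.01 is calibrated to [0.002, 0.03] over 1,000
seeded replicates — conservative rather than anti-conservative, as
expected for heavily tied discrete data under a continuity-corrected
normal approximation.

## The synthetic-assembly generator

The generator emulates the data situation the pipeline assumes, not the
flowgram physics:

* **Reference** (default 100 kb): a chain of homopolymer runs, base ≠
  previous base, run length from a truncated geometric law
  (P(ℓ) ∝ 0.3^(ℓ−1), ℓ ≤ 8), close to the run-length spectrum of random
  DNA while keeping long homopolymers present. A minimum-count spectrum of
  (base, length) runs can be planted for targeted tests; planting is
  verified on the materialized sequence and re-attempted if end-trimming
  cut a planted run, with an explicit error when unsatisfiable.
* **Reads** (default 20× coverage, length 250 ± 30 nt, forward strand):
  uniformly placed windows. Per interior window homopolymer of length ℓ,
  with probability r(ℓ) = min(0.9, 0.007·2^(ℓ−1)) one gap is injected:
  an insertion with probability 0.57, else a deletion capped at ℓ
  (over-draws resampled); gap lengths follow the configured law (default
  Zipf σ = 1.6, L = 10). Substitutions hit each base of gap-free
  homopolymers independently (default 0.008). Defaults were chosen once
  from the published pooled Newbler counts: a 0.8% per-position
  substitution rate, insertions:deletions ≈ 57:43, about 1.2 gaps per
  hundred homopolymer occurrences (hence a substitution share of errors
  near 50%), and a strongly length-1-dominated gap histogram.
* **Exactness constraints.** At most one gap per homopolymer per read;
  no substitutions inside a gapped homopolymer; gaps canonical-left; the
  first and last (possibly truncated) runs of a window receive no gaps so
  that read-edge trimming can never silently drop an event. Under these
  rules the multiset of (kind, base, length, context length) extracted by
  the pipeline equals the injected ledger *exactly*, which the end-to-end
  tests assert.
* **Assembly layout.** The consensus is the reference padded at the union
  of insertion slots (slot width = longest insertion there); reads without
  an insertion at a slot carry `-` across it, reproducing the gap-only
  columns normalization must remove. Mock BLAST hits are emitted per
  contig piece with identity measured by edit distance against the
  reference, so the homology filter is exercised offline.

What the generator does **not** emulate: flowgram noise and flow-value
ambiguity, read-position-dependent error rates, quality scores, PCR
artefacts, strand effects (reads are forward-only by default; strand
handling is exercised by the ACE I/O tests), structural mis-assembly, and
genuine biological divergence between sample and reference. Passing the
recovery tests therefore demonstrates that the *extraction machinery* is
lossless and the *statistical machinery* well calibrated under the assumed
error structure — not that real GS FLX data follows these rates.

## Numerical and design choices

* ACE `*` pads are mapped to `-` internally; coordinates are 1-based
  inclusive (ACE convention); reverse-orientation reads are stored already
  complemented, so all counting is in contig orientation.
* Quality clips (QA records) are honored by default when extracting
  pairwise alignments (`honor_clip`), since assemblers align clipped
  reads; the recovery oracle runs with clipping off, and synthetic reads
  carry no clip. BS and BQ records are parsed and ignored.
* Problem sizes in the analysis scripts and acceptance run — 100 kb at
  20×, N = 10,000 for parameter recovery, 100 replicates for model
  ranking, 1,000 for rank-test calibration — are the package's default
  study conditions; they give sub-minute runs while leaving Monte-Carlo
  error well inside the asserted tolerances.
* Display rounding is 2 decimals for percentages; JSON output keeps full
  precision. Every emitted report re-derives its percentages from its own
  counts and asserts the identity (self-audit).

## Known limitations

* The homology filter trusts the provided BLAST table; it does not verify
  that query ids correspond to the alignment spans beyond the id
  convention `contig:start-end`.
* χ² p-values on unpooled bins with tiny expectations are anti-conservative;
  use `pool_small` when interpreting them (the model *comparison* is
  unaffected).
* The exact Mann-Whitney path is limited to small untied samples; gap-length
  data is heavily tied, so the asymptotic path dominates in practice.
* Consensus recomputation, multiple-alignment construction and SAM/BAM
  input are out of scope.
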