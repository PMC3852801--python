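# pyroerr

Empirical characterization of pyrosequencing (454/GS FLX-style) sequencing
errors from genome assemblies.

Pyrosequencing reads one homopolymer per nucleotide flow, and its dominant
errors are insertions and deletions whose probability grows with the length
of the homopolymer they occur in. This package implements a sequence-level
procedure for extracting those errors from an assembly and asking two
questions a read-mapper author cares about:

1. **What law do indel gap lengths follow?** The affine gap penalty used by
   most aligners corresponds to a *geometric* law
   P(X=k) = β^(k−1)(1−β); a convex (logarithmic) penalty corresponds to a
   *truncated Zipf* law P(X=k) = k^(−σ) / Σ_{j=1..L} j^(−σ). Both are fitted
   by maximum likelihood (β̂ = (x̄−1)/x̄ in closed form; σ̂ by bounded scalar
   search) and compared through Pearson's χ² = Σ_k (O_k − E_k)²/E_k with
   E_k = N·pmf(k).
2. **Do gap lengths depend on their homopolymer context?** Gaps are
   annotated with their *context* — the gapped bases plus the maximal
   flanking runs of matched identical bases — and gap lengths are compared
   across contexts with pairwise two-sided Mann-Whitney tests at α = 0.01.

The extraction pipeline: parse a padded ACE assembly; project each read
onto its contig as a pairwise alignment; *normalize* (drop columns gapped in
both rows — artefacts of multi-read padding); keep only *bona fide*
alignments whose contig piece hits a related reference genome with BLASTN
identity ≥ I_min = 0.8 and e-value ≤ E_max = 0.01; classify every column as
match / substitution / insertion / deletion / ambiguous; decompose indel
runs into per-base gaps with homopolymer contexts; tally exact homopolymer
matches (the denominator for per-context error ratios) and the 4×4
substitution matrix.

Because the original multi-million-read assemblies are not shipped, a
first-class synthetic generator (`pyroerr.simulate`) produces seeded
assemblies with a known reference, configurable error model, and a
ground-truth ledger of every injected event — the pipeline's recovery of
that ledger is exact and tested.

## Worked example

```
$ python analysis/01_simulate_assembly.py --seed 1
reference: 100000 bases (max homopolymer 8)
reads: 8000 at ~20.0x coverage
injected: 15665 substitutions, 16618 gaps (9392 insertions, 7226 deletions)

$ python analysis/02_extract_errors.py
alignments: 8000 candidate -> 8000 bona fide
aligned positions: 2021492; exact-match coverage 97.67%
substitutions: 15665 (0.775% of positions, 48.5% of all errors)
gaps: 9392 insertions, 7226 deletions
ledger check: extracted gap multiset EQUALS the injected ledger

$ python analysis/03_fit_gap_models.py
insertion: n=9392 pooled gaps; beta_hat=0.578, sigma_hat=1.607;
  chi2 geometric=1447.8 vs Zipf=9.8 -> Zipf fits closer

$ python analysis/04_context_rank_tests.py
insertion: 101/120 off-diagonal pairs reject at alpha=0.01 (16 blank)
deletion: 21/28 off-diagonal pairs reject at alpha=0.01 (0 blank)
```

Reading the numbers: 97.67% of aligned positions are exact matches (errors
are rare); substitutions and indel gaps are comparably abundant (~48.5%
share); the extracted gap multiset equals the injected ledger exactly, so
the extraction machinery is lossless; the fitted Zipf shape σ̂ = 1.607 on
insertion gaps recovers the generating σ = 1.6, and its χ² is two orders of
magnitude below the geometric fit — the power-law models gap lengths far
better. The mostly-red Mann-Whitney matrices show gap lengths shifting with
homopolymer context length.

The same operations are available as a library (see `pyroerr.run_pipeline`)
and through a thin CLI (`pyroerr run|simulate|fit|test`).

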