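"""Simulate the study's input data: a pyrosequencing-style genome assembly.

Generates a 100 kb reference, 20x coverage of 250 +/- 30 nt reads carrying
substitutions and homopolymer-context indels (truncated-Zipf gap lengths),
lays them out as a padded ACE assembly, and emits mock BLAST hits against
the reference plus the ground-truth error ledger.  Data files go under
scratch/sim/ (they are inputs for the later steps, not results).
"""

import argparse
from pathlib import Path

from pyroerr import ace as ace_io
from pyroerr.simulate import (
    SimulationParams,
    emit_blast_hits,
    simulate_assembly,
    write_fasta,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("scratch/sim"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    params = SimulationParams(seed=args.seed)
    reference, assembly, truth = simulate_assembly(params)
    write_fasta("reference", reference, args.out / "reference.fasta")
    ace_io.write_ace(assembly, args.out / "assembly.ace")
    hits = emit_blast_hits(assembly, reference, args.out / "hits.tsv")
    truth.to_json(args.out / "ground_truth.json")

    n_ins = sum(1 for g in truth.gaps if g.kind == "insertion")
    print(f"reference: {len(reference)} bases (max homopolymer {params.max_run})")
    print(f"reads: {assembly.n_reads} at ~{params.coverage}x coverage")
    print(
        f"injected: {len(truth.substitutions)} substitutions, {len(truth.gaps)} gaps "
        f"({n_ins} insertions, {len(truth.gaps) - n_ins} deletions)"
    )
    print(f"mock BLAST hits: {len(hits)} contig pieces")
    print(f"wrote assembly.ace, reference.fasta, hits.tsv, ground_truth.json -> {args.out}")


if __name__ == "__main__":
    main()
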