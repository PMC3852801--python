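"""Mann-Whitney tests of gap lengths across homopolymer context lengths.

For insertions and deletions separately, every pair of context lengths is
compared with a two-sided Mann-Whitney test at alpha = 0.01.  A rejection
(red cell) means gaps from the two context lengths follow different length
distributions — the signature of context-dependent indel behaviour.
"""

import argparse
from pathlib import Path

import pandas as pd

from pyroerr.errors import GapRecord
from pyroerr.ranktests import pairwise_tests


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--gaps", type=Path, default=Path("results/errors/tables/gaps.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/ranktests"))
    parser.add_argument("--alpha", type=float, default=0.01)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    frame = pd.read_csv(args.gaps, sep="\t")
    gaps = [
        GapRecord(
            kind=row.kind,
            base=row.base,
            length=int(row.length),
            context_length=int(row.context_length),
        )
        for row in frame.itertuples()
    ]
    for kind in ("insertion", "deletion"):
        matrix = pairwise_tests(gaps, group_by="context_length", alpha=args.alpha, kind=kind)
        matrix.to_frame().to_csv(args.out / f"matrix_{kind}.tsv", sep="\t")
        matrix.to_records().to_csv(
            args.out / f"matrix_{kind}_detail.tsv", sep="\t", index=False
        )
        performed = [
            o
            for (a, b), o in matrix.outcomes.items()
            if a != b and o.decision != "not_performed"
        ]
        n_reject = sum(1 for o in performed if o.decision == "reject")
        blank = sum(
            1
            for (a, b), o in matrix.outcomes.items()
            if a != b and o.decision == "not_performed"
        )
        print(f"{kind}: {n_reject}/{len(performed)} off-diagonal pairs reject at "
              f"alpha={args.alpha} ({blank} blank); context lengths 1..{max(matrix.labels)}")
    print(f"matrices -> {args.out}")


if __name__ == "__main__":
    main()
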