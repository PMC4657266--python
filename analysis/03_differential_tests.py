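#!/usr/bin/env python
"""The five pairwise differential-expression tests.

Runs the NB exact test on each retained design comparison (ctrl vs hh,
ctrl vs esrrb, ctrl vs esrrb_hh, hh vs esrrb_hh, esrrb vs esrrb_hh —
hh vs esrrb carries no biological contrast and is skipped), adjusts
p-values per comparison with Benjamini-Hochberg, and stores the per-gene
decision artifacts (log2FC, p, q, Y/N flag at q < 0.05 and |log2FC| >= 1).
"""

import argparse
from pathlib import Path

from hhsort import detest, quantify


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/detest"))
    args = ap.parse_args()

    counts = quantify.read_expression_tsv(args.data / "counts.tsv")
    args.out.mkdir(parents=True, exist_ok=True)
    for cid, res in detest.run_comparisons(counts).items():
        cond1, cond2 = detest.COMPARISONS[cid]
        detest.write_comparison_tsv(res, args.out / f"comparison_{cid}.tsv")
        n_sig = int(res["significant"].sum())
        n_up = int((res["significant"] & (res["log2fc"] > 0)).sum())
        print(f"{cid} ({cond1} vs {cond2}): {n_sig} significant "
              f"({n_up} up, {n_sig - n_up} down)")


if __name__ == "__main__":
    main()
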