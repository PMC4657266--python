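#!/usr/bin/env python
"""Literature gene-set overlap enrichment on the synthetic experiment.

Builds a synthetic "previously published" Hedgehog target-gene compendium:
a fold-change table that covers part of the truly Hh-responsive genes plus
unrelated genes (this stands in for a literature compilation, which cannot
ship with the package).  Both the compendium and our Hh-responsive list
are twofold-filtered and direction-labelled, then scored with the
hypergeometric upper tail over the expressed-gene universe.
"""

import argparse
from pathlib import Path

import numpy as np

from hhsort import detest, enrich, quantify, simdata


def synthetic_literature_set(truth, rng, coverage=0.5, n_unrelated=150):
    """Fold-change table emulating a published target compendium."""
    fold_changes = {}
    responsive = [t for t in truth if abs(t.beta_h) >= 1]
    rng.shuffle(responsive)
    for t in responsive[: int(coverage * len(responsive))]:
        # reported ratio near the true one, on a noisy linear scale
        ratio = 2.0 ** (t.beta_h + rng.normal(0, 0.3))
        fold_changes[t.gene_id] = ratio
    null_ids = [t.gene_id for t in truth if t.class_label == "null"]
    for gid in rng.choice(null_ids, size=n_unrelated, replace=False):
        # unrelated genes the other studies saw move; ours do not
        fold_changes[gid] = 2.0 ** rng.normal(0, 2.0)
    return enrich.GeneSet.from_symbols(
        "literature_hh_targets", list(fold_changes), fold_changes
    )


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--tests", type=Path, default=Path("results/detest"))
    ap.add_argument("--out", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    c1 = detest.read_comparison_tsv(args.tests / "comparison_C1.tsv")
    hits = c1[c1["significant"]]
    query = enrich.GeneSet.from_symbols(
        "hh_responsive",
        hits.index,
        {g: float(2.0 ** fc) for g, fc in hits["log2fc"].items()},
    )
    query = enrich.twofold_filter(query)

    truth = simdata.read_truth_tsv(args.data / "truth.tsv")
    rng = np.random.default_rng(args.seed)
    reference = enrich.twofold_filter(synthetic_literature_set(truth, rng))

    counts = quantify.read_expression_tsv(args.data / "counts.tsv")
    rpkm = quantify.compute_rpkm(counts)
    universe = int((rpkm.values.max(axis=1) > 0).sum())

    result = enrich.overlap_enrichment(query, reference, universe)
    args.out.mkdir(parents=True, exist_ok=True)
    enrich.result_to_frame(result).to_csv(
        args.out / "enrichment.tsv", sep="\t", index=False
    )
    enrich.write_gmt([query, reference], args.out / "gene_sets.gmt")

    print(f"query (our Hh-responsive, >2-fold): {len(query)} genes")
    print(f"reference (synthetic literature, >2-fold): {len(reference)} genes")
    print(f"expressed-gene universe: {universe}")
    print(f"overlap: {result.overlap_size} genes "
          f"({result.up_overlap_size} up, {result.down_overlap_size} down)")
    print(f"enrichment p = {result.p_value:.3g}")


if __name__ == "__main__":
    main()
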