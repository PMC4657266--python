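"""End-to-end orchestration: counts -> tests -> sorting -> validations.

The stages mirror the experimental flow: quantify expression, run the five
pairwise tests, sort genes into the 32 logical groups and classify
differential responders, then compute the sample-correlation QC.  Every run
writes a JSON manifest recording the configuration actually used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import pandas as pd

from . import correlate, detest, quantify, sorter
from .detest import TestConfig
from .sorter import FilterConfig


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _config_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def run_all(
    counts: quantify.ExpressionMatrix,
    out_dir,
    test_config: TestConfig = TestConfig(),
    filter_config: FilterConfig = FilterConfig(),
    retained_ids=None,
    seed=None,
) -> dict:
    """Run every analysis stage on a counts matrix, writing all artifacts.

    Returns a dict with the in-memory stage outputs: ``rpkm``,
    ``condition_means``, ``comparisons``, ``classification``,
    ``correlation``, ``manifest``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.perf_counter()
    rpkm = quantify.compute_rpkm(counts)
    means = quantify.condition_means(rpkm)
    means.to_csv(out_dir / "condition_means.tsv", sep="\t",
                 index_label="gene_id", float_format="%.8g")
    timings["quantify"] = time.perf_counter() - t0
    _log(f"[quantify] {len(rpkm.gene_ids)} genes, "
         f"{len(rpkm.sample_labels)} samples")

    t0 = time.perf_counter()
    comparisons = detest.run_comparisons(counts, test_config)
    for cid, res in comparisons.items():
        detest.write_comparison_tsv(res, out_dir / f"comparison_{cid}.tsv")
        _log(f"[detest] {cid}: {int(res['significant'].sum())} significant")
    timings["detest"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    classification = sorter.classify_all(
        comparisons, means, filter_config, retained_ids
    )
    sorter.write_classification_tsv(
        classification, out_dir / "classification.tsv"
    )
    n_diff = int(classification["is_differential"].sum())
    _log(f"[sorter] {n_diff} differential-response genes")
    timings["sorter"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    corr = correlate.spearman_matrix(rpkm.values)
    corr.to_frame().to_csv(out_dir / "spearman_matrix.tsv", sep="\t",
                           float_format="%.6g")
    leaves, linkage = correlate.hierarchical_cluster(corr)
    (out_dir / "sample_tree.nwk").write_text(
        correlate.linkage_to_newick(linkage, corr.labels) + "\n"
    )
    timings["correlate"] = time.perf_counter() - t0
    _log(f"[correlate] leaf order: {' '.join(leaves)}")

    config_blob = json.dumps(
        {
            "test": _config_dict(test_config),
            "filter": _config_dict(filter_config),
            "retained_ids": sorted(retained_ids)
            if retained_ids is not None
            else sorted(sorter.default_retained_groups()),
        },
        sort_keys=True,
    )
    manifest = {
        "config": json.loads(config_blob),
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest()[:16],
        "seed": seed,
        "n_genes": int(len(counts.gene_ids)),
        "n_differential": n_diff,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "rpkm": rpkm,
        "condition_means": means,
        "comparisons": comparisons,
        "classification": classification,
        "correlation": corr,
        "manifest": manifest,
    }
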