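"""Simulation benchmarks: statistical calibration and planted-class recovery.

These are the package's standing evaluation experiments.  They are ordinary
library functions so the test suite and the reproduction script run exactly
the same computation.

Problem sizes are fixed design choices: calibration uses 1000 all-null genes
per seed at a 1e6-read library; recovery uses the 2000-gene planted design
(100 enhanced, 100 lost, 100 gated, 1700 null, dispersion 0.02) at a
2e6-read library, which puts per-condition means in the few-hundred to
few-thousand count range.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import detest, pipeline, quantify, simdata


def null_calibration_config(seed: int) -> simdata.SimulationConfig:
    """All-null experiment used for type-I-error calibration."""
    return simdata.SimulationConfig(
        n_genes=1000,
        seed=seed,
        dispersion=0.05,
        class_proportions={"null": 1.0},
        library_size=1e6,
        baseline_log2_mean_range=(5.0, 9.0),
    )


def recovery_config(seed: int) -> simdata.SimulationConfig:
    """Planted-class experiment used for end-to-end recovery."""
    return simdata.SimulationConfig(
        n_genes=2000,
        seed=seed,
        dispersion=0.02,
        class_proportions={
            "null": 0.85,
            "enhanced": 0.05,
            "lost": 0.05,
            "gated": 0.05,
        },
        library_size=2e6,
        baseline_log2_mean_range=(8.0, 11.0),
    )


def null_calibration(seeds) -> dict:
    """False-flag rate and p-value uniformity on all-null data.

    Runs the ctrl-vs-hh test per seed; reports the mean fraction of genes
    flagged significant (q < 0.05 and |log2FC| >= 1), the binomial standard
    error of the nominal 0.05 level at this gene count, and the mean
    Kolmogorov-Smirnov distance of the p-values from U(0, 1).
    """
    rates, ks = [], []
    n_genes = None
    for seed in seeds:
        config = null_calibration_config(seed)
        n_genes = config.n_genes
        counts, _ = simdata.generate_experiment(config)
        res = detest.pairwise_test(
            counts.condition_counts("ctrl"),
            counts.condition_counts("hh"),
            counts.gene_lengths_bp,
            counts.library_sizes,
        )
        res["q"] = detest.bh_adjust(res["p"].to_numpy())
        rates.append(float(detest.flag_significant(res).mean()))
        ks.append(float(stats.kstest(res["p"], "uniform").statistic))
    return {
        "flag_rate": float(np.mean(rates)),
        "nominal_se": float(np.sqrt(0.05 * 0.95 / n_genes)),
        "ks_distance": float(np.mean(ks)),
        "n_genes": n_genes,
        "n_seeds": len(list(seeds)),
    }


def recovery_benchmark(seeds, out_dir=None) -> dict:
    """Planted differential-response recovery through the whole pipeline.

    Per seed: simulate, run every stage, then compare calls against the
    noiseless expected verdicts.  Sensitivity is the fraction of planted
    differential genes called differential; the false-call rate is the
    fraction of differential calls that land on genes planted as
    non-differential; category accuracy is scored on the recovered genes.
    """
    sens, fdr, cat_acc = [], [], []
    n_planted = 0
    for i, seed in enumerate(seeds):
        config = recovery_config(seed)
        counts, truth = simdata.generate_experiment(config)
        expected = simdata.truth_to_expected_calls(truth)
        target = out_dir if out_dir is None else f"{out_dir}/seed_{seed}"
        if target is None:
            import tempfile

            with tempfile.TemporaryDirectory() as tmp:
                result = pipeline.run_all(counts, tmp, seed=seed)
        else:
            result = pipeline.run_all(counts, target, seed=seed)
        cls = result["classification"]
        planted = {g for g, c in expected.items() if c.is_differential}
        n_planted = len(planted)
        called = set(cls.index[cls["is_differential"]])
        true_calls = called & planted
        sens.append(len(true_calls) / len(planted))
        fdr.append(
            (len(called) - len(true_calls)) / len(called) if called else 0.0
        )
        if true_calls:
            cat_acc.append(
                np.mean(
                    [
                        cls.loc[g, "category"] == expected[g].category
                        for g in true_calls
                    ]
                )
            )
    return {
        "sensitivity": float(np.mean(sens)),
        "false_call_rate": float(np.mean(fdr)),
        "category_accuracy": float(np.mean(cat_acc)),
        "n_planted_per_seed": n_planted,
        "n_seeds": len(list(seeds)),
    }
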