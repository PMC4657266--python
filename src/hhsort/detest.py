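"""Pairwise differential-expression testing on replicate counts.

Each of the five design comparisons (ctrl vs hh, ctrl vs esrrb, ctrl vs
esrrb_hh, hh vs esrrb_hh, esrrb vs esrrb_hh) yields, per gene, a log2 fold
change on mean RPKM, an exact-test p-value on counts, a Benjamini-Hochberg
q-value, and a Y/N significance flag (q < 0.05 and |log2FC| >= 1 under the
defaults).

The count test is a negative-binomial conditional exact test in the style of
edgeR's ``exactTest``: replicate counts are normalised to a common library
size, summed within each group, and the two group sums are compared
conditionally on their total, under a common dispersion estimated across all
genes by method of moments (floored at zero; zero dispersion degenerates to
Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CONDITIONS, ExpressionMatrix, compute_rpkm

#: the five retained pairwise comparisons, as (condition_1, condition_2);
#: log2FC is condition_2 over condition_1.  hh-vs-esrrb is deliberately absent.
COMPARISONS: dict[str, tuple[str, str]] = {
    "C1": ("ctrl", "hh"),
    "C2": ("ctrl", "esrrb"),
    "C3": ("ctrl", "esrrb_hh"),
    "C4": ("hh", "esrrb_hh"),
    "C5": ("esrrb", "esrrb_hh"),
}


@dataclass(frozen=True)
class TestConfig:
    """Significance thresholds for the pairwise decision artifacts."""

    q_threshold: float = 0.05
    log2fc_threshold: float = 1.0
    pseudocount: float = 0.001

    def __post_init__(self):
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.log2fc_threshold < 0 or self.pseudocount <= 0:
            raise ValueError("thresholds must be positive")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def estimate_common_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion across genes, floored at 0.

    Uses within-group sums of squares on library-size-normalised counts:
    E[SS_g] = (n-1) * (mu + phi * mu^2), summed over genes and both groups.
    """
    num = 0.0
    den = 0.0
    for grp in (norm_a, norm_b):
        n = grp.shape[1]
        if n < 2:
            continue
        m = grp.mean(axis=1)
        ss = ((grp - m[:, None]) ** 2).sum(axis=1)
        num += float((ss / (n - 1) - m).sum())
        den += float((m**2).sum())
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _median_ratio_factors(norm: np.ndarray, min_genes: int = 10) -> np.ndarray:
    """Median-of-ratios residual size factors (DESeq-style), per sample.

    Library-size scaling alone leaves composition bias: when strongly
    induced genes absorb sequencing depth in one condition, every other
    gene's relative count drops although its expression did not.  The
    median ratio of each sample to the per-gene geometric-mean reference is
    robust to such minorities of changed genes.  Factors are rescaled to
    geometric mean 1; with fewer than ``min_genes`` all-positive genes the
    correction is skipped.
    """
    positive = (norm > 0).all(axis=1)
    if positive.sum() < min_genes:
        return np.ones(norm.shape[1])
    logs = np.log(norm[positive])
    log_ref = logs.mean(axis=1)
    log_factors = np.median(logs - log_ref[:, None], axis=0)
    log_factors -= log_factors.mean()
    return np.exp(log_factors)


def _group_sum_logpmf(x: np.ndarray, mean: float, phi: float, n_rep: int):
    """log PMF of the sum of n_rep iid NB(mean, phi) variates at integers x."""
    total_mean = n_rep * mean
    if phi <= 1e-12:
        return stats.poisson.logpmf(x, total_mean)
    size = n_rep / phi  # NB size parameter adds over iid replicates
    p = size / (size + total_mean)
    return stats.nbinom.logpmf(x, size, p)


def _exact_p(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p for group sums under a common mean.

    Conditions on total = sum_a + sum_b and accumulates the probability of
    all splits no more likely than the observed one.  Enumeration is
    truncated to a +-12 sd window around each group's expectation (tail mass
    < 1e-15), always extended to include the observed split.
    """
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)  # common per-replicate mean under the null
    mean_a, mean_b = n_a * mu, n_b * mu
    sd_a = np.sqrt(mean_a + phi * mean_a**2 / n_a)
    lo = int(max(0, min(mean_a - 12 * sd_a, sum_a)))
    hi = int(min(total, max(mean_a + 12 * sd_a, sum_a)))
    s = np.arange(lo, hi + 1)
    log_joint = _group_sum_logpmf(s, mu, phi, n_a) + _group_sum_logpmf(
        total - s, mu, phi, n_b
    )
    log_joint -= log_joint.max()
    joint = np.exp(log_joint)
    observed = joint[sum_a - lo]
    # 1+1e-12 guard keeps ties (incl. the observed split) in the rejection set
    p = joint[joint <= observed * (1 + 1e-12)].sum() / joint.sum()
    return float(min(1.0, p))


def pairwise_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
    config: TestConfig = TestConfig(),
) -> pd.DataFrame:
    """Per-gene log2FC and exact-test p for one pairwise comparison.

    ``counts_a``/``counts_b`` are genes x replicates raw counts for the two
    conditions; ``library_sizes`` covers every replicate column.  Returns a
    DataFrame with columns ``log2fc`` and ``p``.  With fewer than two
    replicates on either side p is NaN (fold change is still reported).
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("gene sets differ between the two sides")
    lib_a = library_sizes[counts_a.columns].to_numpy(float)
    lib_b = library_sizes[counts_b.columns].to_numpy(float)

    # fold change on mean RPKM with the package-wide pseudocount
    kb = lengths.reindex(counts_a.index).to_numpy(float) / 1e3
    rpkm_a = (counts_a.to_numpy(float) / (lib_a / 1e6)).mean(axis=1) / kb
    rpkm_b = (counts_b.to_numpy(float) / (lib_b / 1e6)).mean(axis=1) / kb
    log2fc = np.log2((rpkm_b + config.pseudocount) / (rpkm_a + config.pseudocount))

    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if n_a < 2 or n_b < 2:
        p = np.full(len(counts_a), np.nan)
        return pd.DataFrame({"log2fc": log2fc, "p": p}, index=counts_a.index)

    # normalise to the geometric mean library size, then round to integers
    ref = float(np.exp(np.mean(np.log(np.concatenate([lib_a, lib_b])))))
    norm_a = counts_a.to_numpy(float) * (ref / lib_a)
    norm_b = counts_b.to_numpy(float) * (ref / lib_b)
    factors = _median_ratio_factors(np.hstack([norm_a, norm_b]))
    norm_a = norm_a / factors[: n_a]
    norm_b = norm_b / factors[n_a:]
    phi = estimate_common_dispersion(norm_a, norm_b)
    sums_a = np.rint(norm_a.sum(axis=1)).astype(np.int64)
    sums_b = np.rint(norm_b.sum(axis=1)).astype(np.int64)

    p = np.array(
        [_exact_p(a, b, n_a, n_b, phi) for a, b in zip(sums_a, sums_b)]
    )
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=counts_a.index)


def flag_significant(result: pd.DataFrame, config: TestConfig = TestConfig()):
    """Y/N decision: q strictly below threshold AND |log2FC| >= threshold."""
    return (result["q"] < config.q_threshold) & (
        result["log2fc"].abs() >= config.log2fc_threshold
    )


def run_comparisons(
    counts: ExpressionMatrix, config: TestConfig = TestConfig()
) -> dict[str, pd.DataFrame]:
    """All five design comparisons on a counts matrix.

    Returns ``{comparison_id: DataFrame(log2fc, p, q, significant)}`` with BH
    adjustment applied per comparison across all genes.
    """
    if counts.units != "counts":
        raise ValueError("run_comparisons expects raw counts")
    out = {}
    for cid, (cond1, cond2) in COMPARISONS.items():
        res = pairwise_test(
            counts.condition_counts(cond1),
            counts.condition_counts(cond2),
            counts.gene_lengths_bp,
            counts.library_sizes,
            config,
        )
        res["q"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = flag_significant(res, config)
        out[cid] = res
    return out


def write_comparison_tsv(result: pd.DataFrame, path) -> None:
    out = result.copy()
    out["flag"] = np.where(out.pop("significant"), "Y", "N")
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.8g")


def read_comparison_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    df["significant"] = df.pop("flag") == "Y"
    return df
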