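"""Validation statistics: sample-correlation structure and qPCR agreement.

Two independent checks of an expression experiment:

* a Spearman rank-correlation matrix over all samples (replicates within a
  condition should correlate more tightly than samples across conditions),
  hierarchically clustered with average linkage on 1 - rho;
* per-gene Pearson correlation between RNA-seq and qPCR after both are
  normalised the same way — qPCR relative levels against a housekeeping
  reference gene and then against the control condition, RNA-seq RPKM
  against the control condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


@dataclass
class CorrelationMatrix:
    labels: list
    values: np.ndarray  # symmetric, unit diagonal; NaN marks undefined pairs
    method: str  # "spearman" or "pearson"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def spearman_matrix(values: pd.DataFrame, method: str = "spearman") -> CorrelationMatrix:
    """Pairwise Spearman rho between all sample columns, over genes.

    Ties receive average ranks.  A constant column has no rank variance;
    its correlations are recorded as NaN (undefined), never coerced to 0.
    """
    if values.shape[0] < 3 or values.shape[1] < 2:
        raise ValueError("need at least 3 genes and 2 samples")
    x = values.to_numpy(float)
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    constant = ranks.std(axis=0) == 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2  # enforce exact symmetry
    return CorrelationMatrix(list(values.columns), corr, "spearman")


def hierarchical_cluster(corr: CorrelationMatrix):
    """Average-linkage agglomeration on distance 1 - rho.

    Returns ``(leaf_labels, linkage_matrix)``; the scipy linkage matrix is
    the merge tree.  Merges at equal height happen in label order (scipy
    resolves ties by cluster index, which follows input order here).
    Undefined correlations are an error naming the offending pairs.
    """
    vals = corr.values
    bad = [
        (corr.labels[i], corr.labels[j])
        for i in range(len(corr.labels))
        for j in range(i + 1, len(corr.labels))
        if np.isnan(vals[i, j])
    ]
    if bad:
        raise ValueError(f"undefined correlations for pairs: {bad}")
    dist = 1.0 - vals
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = hierarchy.linkage(np.clip(condensed, 0, None), method="average")
    order = hierarchy.leaves_list(linkage)
    return [corr.labels[i] for i in order], linkage


def linkage_to_newick(linkage: np.ndarray, labels: list) -> str:
    """Serialise a scipy merge tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def normalize_qpcr(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    efficiency: float = 2.0,
    input_kind: str = "ct",
) -> pd.DataFrame:
    """qPCR normalisation: against the reference gene, then the control.

    ``table`` is genes x conditions.  For Ct input the relative level is
    efficiency ** -(Ct_target - Ct_reference) per condition; already-relative
    input skips that step.  Every gene is then divided by its own level in
    the control condition, which therefore comes out exactly 1.
    """
    if reference_gene not in table.index:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    if control_condition not in table.columns:
        raise ValueError(f"control condition {control_condition!r} not in table")
    if input_kind == "ct":
        delta = table.drop(index=reference_gene) - table.loc[reference_gene]
        relative = pd.DataFrame(
            np.power(float(efficiency), -delta.to_numpy(float)),
            index=delta.index,
            columns=delta.columns,
        )
    elif input_kind == "relative":
        relative = table.astype(float)
    else:
        raise ValueError("input_kind must be 'ct' or 'relative'")
    control = relative[control_condition]
    if (control == 0).any():
        zeros = list(relative.index[control == 0])
        raise ValueError(f"zero control value for genes: {zeros}")
    return relative.div(control, axis=0)


def normalize_rnaseq_to_control(
    condition_rpkm: pd.DataFrame, control_condition: str = "ctrl"
) -> pd.DataFrame:
    """Per-gene RPKM divided by the control condition's value."""
    control = condition_rpkm[control_condition]
    if (control == 0).any():
        zeros = list(condition_rpkm.index[control == 0])
        raise ValueError(f"zero control RPKM for genes: {zeros}")
    return condition_rpkm.div(control, axis=0)


def pearson_validation(
    qpcr: pd.DataFrame, rnaseq: pd.DataFrame
) -> pd.Series:
    """Per-gene Pearson r between matched qPCR and RNA-seq profiles.

    Both tables are genes x conditions with identical labels; needs at
    least three conditions.  Zero variance in either profile is an error.
    The minimum over genes is the experiment-level acceptance statistic.
    """
    genes = qpcr.index.intersection(rnaseq.index)
    if len(genes) == 0:
        raise ValueError("no genes in common")
    cols = list(qpcr.columns)
    if set(cols) != set(rnaseq.columns) or len(cols) < 3:
        raise ValueError("need >= 3 matching condition labels")
    out = {}
    for g in genes:
        x = qpcr.loc[g, cols].to_numpy(float)
        y = rnaseq.loc[g, cols].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"zero variance for gene {g!r}")
        out[g] = float(stats.pearsonr(x, y).statistic)
    return pd.Series(out, name="pearson_r")
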