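"""Logical gene sorting over the five pairwise-comparison flags.

Every gene carries an ordered 5-tuple of Y/N flags (C1..C5) from the five
design comparisons; the 2^5 flag patterns partition the genes into 32 groups.
Candidate groups are the Hh-responsive (C1 = Y) patterns whose flags are
jointly satisfiable under a transitive reading of "not significantly
different"; candidate genes then pass through two branches of RPKM
effect-size filters, and survivors are classified by how Esrrb reshapes the
Hedgehog response: enhanced, depressed, lost, or proportional-additive.
Genes with no Hh response alone that gain one under Esrrb (the group-25
pattern) are called gated.

Flag order and semantics::

    C1  ctrl  vs hh          C4  hh    vs esrrb_hh
    C2  ctrl  vs esrrb       C5  esrrb vs esrrb_hh
    C3  ctrl  vs esrrb_hh
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

FLAG_IDS = ("C1", "C2", "C3", "C4", "C5")

#: comparison id -> (condition_1, condition_2) it contrasts; used by the
#: consistency predicate.  Mirrors detest.COMPARISONS.
_FLAG_PAIRS = {
    "C1": ("ctrl", "hh"),
    "C2": ("ctrl", "esrrb"),
    "C3": ("ctrl", "esrrb_hh"),
    "C4": ("hh", "esrrb_hh"),
    "C5": ("esrrb", "esrrb_hh"),
}

CATEGORIES = (
    "enhanced",
    "depressed",
    "lost",
    "proportional_additive",
    "gated",
    "none",
)


@dataclass(frozen=True)
class FilterConfig:
    """Constants of the two-branch RPKM effect-size filters.

    rel_change_floor
        minimum |relative change| a real response must show (0.5 = 50%).
    abs_change_floor_rpkm
        minimum |RPKM difference| between esrrb_hh and hh in branch A.
    nonsig_drift_ceiling
        maximum |relative drift| of esrrb_hh vs hh tolerated in branch B
        (whose genes by definition did not move in that comparison).
    denominator_pseudocount
        added to ratio denominators, matching the RPKM + 0.001 convention.
    combination
        "any": a gene is removed if any removal inequality holds (default);
        "all": removed only if all hold.
    tau_log2
        margin separating enhanced/depressed from proportional responses,
        in log2 units (default 0.585 ~ 1.5-fold).
    """

    rel_change_floor: float = 0.5
    abs_change_floor_rpkm: float = 5.0
    nonsig_drift_ceiling: float = 0.1
    denominator_pseudocount: float = 0.001
    combination: str = "any"
    tau_log2: float = 0.585

    def __post_init__(self):
        for name in (
            "rel_change_floor",
            "abs_change_floor_rpkm",
            "nonsig_drift_ceiling",
            "denominator_pseudocount",
            "tau_log2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.combination not in ("any", "all"):
            raise ValueError("combination must be 'any' or 'all'")


@dataclass
class ResponseCall:
    gene_id: str
    is_differential: bool
    branch: str  # "A", "B" or "none"
    category: str  # one of CATEGORIES

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.is_differential and self.branch not in ("A", "B"):
            raise ValueError("differential calls must carry a branch")


def assign_group(flags) -> int:
    """Flag 5-tuple -> group id in 1..32.

    Encoding: index = 16*C1 + 8*C2 + 4*C3 + 2*C4 + C5 with Y = 1, group =
    32 - index.  All-Y is group 1, all-N group 32; the 16 Hh-responsive
    (C1 = Y) patterns occupy groups 1-16, and the pattern (N,N,Y,Y,Y) -- a
    gene that responds to Hedgehog only when Esrrb is present -- is group 25.
    """
    flags = tuple(bool(f) for f in flags)
    if len(flags) != 5:
        raise ValueError("exactly five flags required")
    index = sum(w * f for w, f in zip((16, 8, 4, 2, 1), flags))
    return 32 - index


def group_flags(group_id: int) -> tuple[bool, ...]:
    """Inverse of :func:`assign_group`."""
    if not 1 <= group_id <= 32:
        raise ValueError("group_id must lie in 1..32")
    index = 32 - group_id
    return tuple(bool(index & w) for w in (16, 8, 4, 2, 1))


def flags_consistent(flags) -> bool:
    """Can the five Y/N flags hold simultaneously for any condition means?

    Treats a non-significant comparison (N) as "the two conditions sit at
    the same expression level" and a significant one (Y) as "at clearly
    different levels", i.e. a large gap dominating any tolerance, so
    equality propagates transitively.  A pattern is consistent iff no chain
    of N-comparisons forces two Y-flagged conditions together.
    """
    flags = dict(zip(FLAG_IDS, (bool(f) for f in flags)))
    parent = {c: c for c in ("ctrl", "hh", "esrrb", "esrrb_hh")}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for cid, (a, b) in _FLAG_PAIRS.items():
        if not flags[cid]:
            parent[find(a)] = find(b)
    return all(
        find(a) != find(b) for cid, (a, b) in _FLAG_PAIRS.items() if flags[cid]
    )


def default_retained_groups() -> frozenset[int]:
    """Shipped candidate groups: C1 = Y patterns with self-consistent flags.

    Enumerates the 16 Hh-responsive flag patterns through
    :func:`flags_consistent`; exactly 8 survive.
    """
    kept = []
    for rest in itertools.product([True, False], repeat=4):
        flags = (True, *rest)
        if flags_consistent(flags):
            kept.append(assign_group(flags))
    return frozenset(kept)


def sort_genes(comparisons: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-gene flags and group ids from the five comparison results.

    Returns a DataFrame with boolean columns C1..C5 and an integer
    ``group_id`` column.
    """
    missing = [c for c in FLAG_IDS if c not in comparisons]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    index = comparisons["C1"].index
    flags = pd.DataFrame(
        {cid: comparisons[cid]["significant"].reindex(index) for cid in FLAG_IDS}
    )
    if flags.isna().any().any():
        raise ValueError("comparisons cover different gene sets")
    weights = np.array([16, 8, 4, 2, 1])
    flags["group_id"] = 32 - flags[list(FLAG_IDS)].to_numpy(bool) @ weights
    return flags


def retain_candidate_groups(
    assignments: pd.DataFrame, retained_ids=None
) -> pd.DataFrame:
    """Keep exactly the genes whose group_id is in the retained set."""
    if retained_ids is None:
        retained_ids = default_retained_groups()
    retained_ids = set(retained_ids)
    if not retained_ids <= set(range(1, 33)):
        raise ValueError("retained ids must lie in 1..32")
    return assignments[assignments["group_id"].isin(retained_ids)]


def apply_branch_filters(
    means: pd.Series | dict,
    c4_significant: bool,
    config: FilterConfig = FilterConfig(),
) -> tuple[bool, str]:
    """Two-branch RPKM effect-size filter for one candidate (C1 = Y) gene.

    ``means`` maps the four condition names to mean RPKM.  Branch A (C4
    significant) removes a gene if any of::

        |(EH - H) / H| < 0.5     |(H - C) / C| < 0.5     |EH - H| < 5

    branch B (C4 not significant) removes it if any of::

        |(H - C) / C| < 0.5      |(EH - H) / H| > 0.1    |(E - C) / C| < 0.5

    (defaults shown; denominators get the pseudocount).  Returns
    ``(survives, branch)``.
    """
    c = float(means["ctrl"])
    h = float(means["hh"])
    e = float(means["esrrb"])
    eh = float(means["esrrb_hh"])
    for v in (c, h, e, eh):
        if np.isnan(v):
            raise ValueError("missing condition mean")
    eps = config.denominator_pseudocount
    rel_eh_h = (eh - h) / (h + eps)
    rel_h_c = (h - c) / (c + eps)
    rel_e_c = (e - c) / (c + eps)
    if c4_significant:
        branch = "A"
        removals = [
            abs(rel_eh_h) < config.rel_change_floor,
            abs(rel_h_c) < config.rel_change_floor,
            abs(eh - h) < config.abs_change_floor_rpkm,
        ]
    else:
        branch = "B"
        removals = [
            abs(rel_h_c) < config.rel_change_floor,
            abs(rel_eh_h) > config.nonsig_drift_ceiling,
            abs(rel_e_c) < config.rel_change_floor,
        ]
    removed = any(removals) if config.combination == "any" else all(removals)
    return (not removed, branch)


def classify_response(
    gene_id: str,
    flags,
    log2fc: dict,
    survived_filters: bool,
    config: FilterConfig = FilterConfig(),
) -> ResponseCall:
    """Differential-response verdict for one gene.

    ``flags`` is the C1..C5 Y/N 5-tuple and ``log2fc`` maps comparison ids
    to fold changes.  Candidates (C1 = Y) must have survived the branch
    filters; the gated pattern (C1 = N, C5 = Y with a >= 2-fold C5 change)
    bypasses them.  For surviving candidates the Hh response without Esrrb
    (r1 = log2FC of C1) is compared against the response with Esrrb
    (r5 = log2FC of C5): lost if C5 is not significant, otherwise enhanced /
    depressed when |r5| and |r1| differ by more than tau, and
    proportional-additive when they agree and Esrrb shifts the baseline
    (C2 = Y).  Opposite-sign responses are left uncalled.
    """
    c1, c2, c3, c4, c5 = (bool(f) for f in flags)
    r1 = float(log2fc["C1"])
    r5 = float(log2fc["C5"])
    none = ResponseCall(gene_id, False, "none", "none")
    if not c1:
        if c5 and abs(r5) >= 1.0:
            return ResponseCall(gene_id, True, "B", "gated")
        return none
    if not survived_filters:
        return none
    branch = "A" if c4 else "B"
    if not c5:
        return ResponseCall(gene_id, True, branch, "lost")
    if np.sign(r1) != np.sign(r5):
        return none  # opposite-direction responses: no coherent category
    tau = config.tau_log2
    if abs(r5) - abs(r1) > tau:
        return ResponseCall(gene_id, True, branch, "enhanced")
    if abs(r1) - abs(r5) > tau:
        return ResponseCall(gene_id, True, branch, "depressed")
    if c2:
        return ResponseCall(gene_id, True, branch, "proportional_additive")
    return none


def classify_all(
    comparisons: dict[str, pd.DataFrame],
    condition_means: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    retained_ids=None,
) -> pd.DataFrame:
    """Full sorting stage: flags, groups, retention, filters, categories.

    Returns one row per input gene with columns C1..C5, group_id, retained,
    branch, survives_filters, is_differential, category.
    """
    flags = sort_genes(comparisons)
    retained = retain_candidate_groups(flags, retained_ids)
    out = flags.copy()
    out["retained"] = out.index.isin(retained.index)
    log2fc = {cid: comparisons[cid]["log2fc"] for cid in FLAG_IDS}
    branches, survives, categories, differential = [], [], [], []
    for gene in out.index:
        row = out.loc[gene]
        gene_flags = tuple(bool(row[c]) for c in FLAG_IDS)
        if row["retained"]:
            ok, branch = apply_branch_filters(
                condition_means.loc[gene], gene_flags[3], config
            )
        else:
            ok, branch = False, "none"
        call = classify_response(
            gene,
            gene_flags,
            {cid: log2fc[cid].loc[gene] for cid in FLAG_IDS},
            ok and bool(row["retained"]),
            config,
        )
        branches.append(call.branch if call.is_differential else branch)
        survives.append(ok)
        categories.append(call.category)
        differential.append(call.is_differential)
    out["branch"] = branches
    out["survives_filters"] = survives
    out["is_differential"] = differential
    out["category"] = categories
    return out


def write_classification_tsv(classification: pd.DataFrame, path) -> None:
    out = classification.copy()
    for cid in FLAG_IDS:
        out[cid] = np.where(out[cid], "Y", "N")
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_classification_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    for cid in FLAG_IDS:
        df[cid] = df[cid] == "Y"
    return df
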