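"""Literature gene-set comparison: twofold pre-filter and overlap enrichment.

Published target-gene sets come with linear fold changes; only genes altered
more than twofold (ratio > 2 or < 0.5, strict) enter the comparison, split
into up- and down-regulated subsets.  The overlap between a query set and a
reference set is scored with the one-sided hypergeometric upper tail
(Fisher's exact enrichment) over a configurable gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats


def _canon(symbol: str) -> str:
    return symbol.strip().lower()


@dataclass
class GeneSet:
    """A named set of gene symbols, optionally with fold changes/directions.

    Symbols are matched case-insensitively after whitespace stripping
    (mouse-symbol capitalisation is not stable across sources); the
    original spelling of each member is preserved for output.
    """

    name: str
    members: dict = field(default_factory=dict)  # canonical -> original
    fold_changes: dict = field(default_factory=dict)  # canonical -> ratio
    directions: dict = field(default_factory=dict)  # canonical -> up|down

    @classmethod
    def from_symbols(cls, name, symbols, fold_changes=None):
        gs = cls(name=name)
        for s in symbols:
            gs.members[_canon(s)] = s.strip()
        if fold_changes is not None:
            for s, r in fold_changes.items():
                key = _canon(s)
                if key in gs.members:
                    gs.fold_changes[key] = float(r)
        extra = set(gs.directions) - set(gs.members)
        if extra:
            raise ValueError("direction labels on non-members")
        return gs

    def __len__(self):
        return len(self.members)

    def __contains__(self, symbol):
        return _canon(symbol) in self.members


@dataclass
class EnrichmentResult:
    overlap_members: list
    overlap_size: int
    up_overlap_size: int | None
    down_overlap_size: int | None
    universe_size: int
    p_value: float


def twofold_filter(gene_set: GeneSet) -> GeneSet:
    """Keep members altered more than twofold; label direction.

    Strict thresholds: ratio > 2 kept as "up", ratio < 0.5 kept as "down";
    exactly twofold is excluded.  Ratios must be positive.
    """
    out = GeneSet(name=gene_set.name)
    for key, ratio in gene_set.fold_changes.items():
        if ratio <= 0:
            raise ValueError(f"nonpositive fold-change ratio for {key!r}")
        if ratio > 2:
            direction = "up"
        elif ratio < 0.5:
            direction = "down"
        else:
            continue
        out.members[key] = gene_set.members[key]
        out.fold_changes[key] = ratio
        out.directions[key] = direction
    return out


def overlap_enrichment(
    query: GeneSet, reference: GeneSet, universe_size: int
) -> EnrichmentResult:
    """Hypergeometric upper-tail p for the query/reference overlap.

    P(X >= k) for k = |overlap| when |query| genes are drawn without
    replacement from a universe containing |reference| successes; symmetric
    in the two sets.
    """
    n_q, n_r = len(query), len(reference)
    overlap_keys = sorted(set(query.members) & set(reference.members))
    k = len(overlap_keys)
    if universe_size < n_q + n_r - k:
        raise ValueError("universe smaller than the union of the two sets")
    p = float(stats.hypergeom.sf(k - 1, universe_size, n_r, n_q))
    up = down = None
    if query.directions and reference.directions:
        agree = [
            key
            for key in overlap_keys
            if query.directions.get(key) == reference.directions.get(key)
        ]
        up = sum(1 for key in agree if query.directions[key] == "up")
        down = sum(1 for key in agree if query.directions[key] == "down")
    elif reference.directions or query.directions:
        labels = reference.directions or query.directions
        up = sum(1 for key in overlap_keys if labels.get(key) == "up")
        down = sum(1 for key in overlap_keys if labels.get(key) == "down")
    return EnrichmentResult(
        overlap_members=[reference.members.get(key, query.members[key])
                         for key in overlap_keys],
        overlap_size=k,
        up_overlap_size=up,
        down_overlap_size=down,
        universe_size=universe_size,
        p_value=min(1.0, p),
    )


# -- IO ----------------------------------------------------------------------


def read_gmt(path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then member symbols."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets.append(GeneSet.from_symbols(fields[0], fields[2:]))
    return sets


def write_gmt(sets: list[GeneSet], path, description="") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *gs.members.values()]))
            fh.write("\n")


def read_fold_change_tsv(path, name=None) -> GeneSet:
    """Two-column TSV (symbol, linear fold-change ratio) -> GeneSet."""
    df = pd.read_csv(path, sep="\t", comment="#")
    sym_col, fc_col = df.columns[:2]
    return GeneSet.from_symbols(
        name or str(path),
        df[sym_col].astype(str),
        dict(zip(df[sym_col].astype(str), df[fc_col].astype(float))),
    )


def result_to_frame(result: EnrichmentResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "overlap_size": [result.overlap_size],
            "up_overlap_size": [result.up_overlap_size],
            "down_overlap_size": [result.down_overlap_size],
            "universe_size": [result.universe_size],
            "p_value": [result.p_value],
            "overlap_members": [",".join(result.overlap_members)],
        }
    )
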