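"""Expression containers, RPKM normalisation and the log2(x + 0.001) transform.

The four-condition design is fixed throughout the package: ``ctrl`` (vehicle
control), ``hh`` (Hedgehog-ligand conditioned medium), ``esrrb`` (Esrrb
transfection), and ``esrrb_hh`` (both).  Samples are named
``<condition>_<replicate>``, e.g. ``hh_1``.

Expression is carried either as raw counts or as RPKM (reads per kilobase of
transcript per million mapped reads); the :class:`ExpressionMatrix` carries a
``units`` tag so downstream code can refuse the wrong one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("ctrl", "hh", "esrrb", "esrrb_hh")

#: offset added before log2, matching the RPKM + 0.001 convention
LOG_OFFSET = 0.001


def split_sample_label(label: str) -> tuple[str, str]:
    """Split ``<condition>_<rep>`` into its condition and replicate parts."""
    cond, _, rep = label.rpartition("_")
    if cond not in CONDITIONS:
        raise ValueError(
            f"sample label {label!r} does not start with one of {CONDITIONS}"
        )
    return cond, rep


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-gene and per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample
        (``<condition>_<rep>``); non-negative.
    gene_lengths_bp
        Series of transcript lengths in bp, indexed like ``values``.
    library_sizes
        Series of total mapped reads per sample, indexed by sample label.
    units
        ``"counts"`` or ``"rpkm"``.
    """

    values: pd.DataFrame
    gene_lengths_bp: pd.Series
    library_sizes: pd.Series
    units: str = "counts"
    _conditions: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        if self.units not in ("counts", "rpkm"):
            raise ValueError(f"unknown units tag {self.units!r}")
        if (np.asarray(self.values) < 0).any():
            raise ValueError("negative expression values")
        if not self.values.index.is_unique:
            raise ValueError("gene ids are not unique")
        self.gene_lengths_bp = self.gene_lengths_bp.reindex(self.values.index)
        if self.gene_lengths_bp.isna().any() or (self.gene_lengths_bp < 1).any():
            raise ValueError("every gene needs a length >= 1 bp")
        self.library_sizes = self.library_sizes.reindex(self.values.columns)
        if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
            raise ValueError("every sample needs a positive library size")
        self._conditions = {}
        for s in self.values.columns:
            cond, _ = split_sample_label(s)
            self._conditions.setdefault(cond, []).append(s)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_labels(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        """Sample labels belonging to one condition, in column order."""
        if condition not in self._conditions:
            raise KeyError(f"no samples for condition {condition!r}")
        return list(self._conditions[condition])

    def condition_counts(self, condition: str) -> pd.DataFrame:
        return self.values[self.samples_for(condition)]


def compute_rpkm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Counts -> RPKM: count / (length_kb * mapped_reads_in_millions).

    Library sizes are the supplied total mapped reads, not column sums.
    """
    if expr.units != "counts":
        raise ValueError("compute_rpkm expects a counts matrix")
    length_kb = expr.gene_lengths_bp.astype(float) / 1e3
    per_million = expr.library_sizes.astype(float) / 1e6
    rpkm = expr.values.div(length_kb, axis=0).div(per_million, axis=1)
    return replace(expr, values=rpkm, units="rpkm")


def log2_with_offset(values, offset: float = LOG_OFFSET):
    """Elementwise log2(value + offset); values must be non-negative."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values passed to log2_with_offset")
    out = np.log2(arr + offset)
    if isinstance(values, (pd.DataFrame, pd.Series)):
        return type(values)(out, index=values.index)
    return out


def condition_means(rpkm: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean RPKM over replicates, per gene per condition.

    Returns a genes x 4 DataFrame with the canonical condition order.
    """
    if rpkm.units != "rpkm":
        raise ValueError("condition_means expects an RPKM matrix")
    cols = {}
    for cond in CONDITIONS:
        samples = rpkm.samples_for(cond)  # raises if a condition is absent
        cols[cond] = rpkm.values[samples].mean(axis=1)
    return pd.DataFrame(cols)


# -- TSV interface -----------------------------------------------------------
#
# One flat table: gene_id, length_bp, then one column per sample.  Library
# sizes ride along in a '# library_sizes:' comment so a single file round-trips
# the whole object.


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: {expr.units}\n")
        sizes = " ".join(
            f"{s}={expr.library_sizes[s]:.10g}" for s in expr.sample_labels
        )
        fh.write(f"# library_sizes: {sizes}\n")
        out = expr.values.copy()
        out.insert(0, "length_bp", expr.gene_lengths_bp)
        out.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.10g")


def read_expression_tsv(path) -> ExpressionMatrix:
    units = "counts"
    sizes: dict[str, float] = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                text = line[1:].strip()
                if text.startswith("units:"):
                    units = text.split(":", 1)[1].strip()
                elif text.startswith("library_sizes:"):
                    for item in text.split(":", 1)[1].split():
                        k, v = item.split("=")
                        sizes[k] = float(v)
            else:
                body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t", index_col="gene_id")
    lengths = df.pop("length_bp")
    if not sizes:
        sizes = {s: float(df[s].sum()) for s in df.columns}
    return ExpressionMatrix(
        values=df,
        gene_lengths_bp=lengths,
        library_sizes=pd.Series(sizes),
        units=units,
    )
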