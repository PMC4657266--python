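"""Synthetic 2x2 factorial RNA-seq counts with planted gene classes.

The generator emulates the study design downstream code expects: four
conditions (ctrl, hh, esrrb, esrrb_hh) x a small number of biological
replicates, gene-level negative-binomial counts, and a known per-gene truth.
Expression follows a log2-linear factorial model: for Hedgehog status H and
Esrrb status E in {0, 1},

    log2 mu(H, E) = baseline + beta_H * H + beta_E * E + beta_I * H * E

so beta_I is the interaction — the quantity the downstream sorter hunts for.
Counts are NB with variance mu + phi * mu^2 (phi = 0 gives Poisson), after
scaling every sample's expected total to the library size.

Planted classes and their (beta_H, beta_E, beta_I) archetypes:

    null         (0, 0, 0)      hh_only     (2, 0, 0)
    esrrb_only   (0, 2, 0)      additive    (2, 2, 0)
    enhanced     (2, 0, 1.5)    depressed   (2, 0, -1)
    lost         (2, 0, -2)     gated       (0, 0, 2)

"lost" genes respond to Hedgehog only without Esrrb (beta_H + beta_I = 0);
"gated" genes respond only with it (beta_H = 0, beta_I != 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detest import TestConfig
from .quantify import CONDITIONS, ExpressionMatrix
from .sorter import FilterConfig, ResponseCall

#: (beta_H, beta_E, beta_I) per planted class, log2 units
CLASS_EFFECTS: dict[str, tuple[float, float, float]] = {
    "null": (0.0, 0.0, 0.0),
    "hh_only": (2.0, 0.0, 0.0),
    "esrrb_only": (0.0, 2.0, 0.0),
    "additive": (2.0, 2.0, 0.0),
    "enhanced": (2.0, 0.0, 1.5),
    "depressed": (2.0, 0.0, -1.0),
    "lost": (2.0, 0.0, -2.0),
    "gated": (0.0, 0.0, 2.0),
}

#: (H, E) indicator per condition, in canonical condition order
_DESIGN = {"ctrl": (0, 0), "hh": (1, 0), "esrrb": (0, 1), "esrrb_hh": (1, 1)}


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    replicates_per_condition: int = 2
    class_proportions: dict = field(
        default_factory=lambda: {
            "null": 0.85,
            "enhanced": 0.05,
            "lost": 0.05,
            "gated": 0.05,
        }
    )
    effect_sizes: dict = field(default_factory=lambda: dict(CLASS_EFFECTS))
    baseline_log2_mean_range: tuple = (8.0, 11.0)
    dispersion: float = 0.02
    gene_length_range: tuple = (500, 5000)
    library_size: float = 5e6
    scale_to_library: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.replicates_per_condition < 1:
            raise ValueError("n_genes and replicates must be positive")
        fracs = np.array(list(self.class_proportions.values()), float)
        if (fracs < 0).any():
            raise ValueError("class proportions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        unknown = set(self.class_proportions) - set(self.effect_sizes)
        if unknown:
            raise ValueError(f"no effect sizes for classes: {sorted(unknown)}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.gene_length_range[0] < 1:
            raise ValueError("gene lengths must be >= 1 bp")


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    class_label: str
    baseline_log2: float
    beta_h: float
    beta_e: float
    beta_i: float
    length_bp: int


def allocate_classes(config: SimulationConfig) -> list[str]:
    """Per-gene class labels by the largest-remainder method.

    Quotas are floor(p * n); leftover genes go to classes in decreasing
    order of fractional remainder, ties broken by insertion order of the
    proportions mapping.  Labels are laid out block-wise, so the allocation
    is exactly reproducible.
    """
    n = config.n_genes
    labels = list(config.class_proportions)
    exact = np.array([config.class_proportions[c] * n for c in labels])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    out = []
    for label, k in zip(labels, counts):
        out.extend([label] * k)
    return out


def generate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[GeneTruth]]:
    """Draw one synthetic experiment: counts matrix plus per-gene truth.

    One root seed sequence per experiment; each gene gets its own child
    stream (baseline and length first, then its counts in sample order), so
    draws for a gene never depend on how many genes follow it.
    """
    root = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(config.n_genes)]
    labels = allocate_classes(config)
    width = len(str(config.n_genes))

    lo, hi = config.baseline_log2_mean_range
    len_lo, len_hi = config.gene_length_range
    truth: list[GeneTruth] = []
    mu = np.empty((config.n_genes, 4))
    for g, (rng, label) in enumerate(zip(streams, labels)):
        baseline = rng.uniform(lo, hi)
        length = int(rng.integers(len_lo, len_hi + 1))
        bh, be, bi = config.effect_sizes[label]
        truth.append(
            GeneTruth(f"g{g:0{width}d}", label, baseline, bh, be, bi, length)
        )
        for j, cond in enumerate(CONDITIONS):
            h, e = _DESIGN[cond]
            mu[g, j] = 2.0 ** (baseline + bh * h + be * e + bi * h * e)

    if config.scale_to_library:
        mu = mu * (config.library_size / mu.sum(axis=0))

    reps = config.replicates_per_condition
    phi = config.dispersion
    sample_labels = [f"{c}_{r + 1}" for c in CONDITIONS for r in range(reps)]
    counts = np.empty((config.n_genes, len(sample_labels)), dtype=np.int64)
    for g, rng in enumerate(streams):
        k = 0
        for j in range(4):
            m = mu[g, j]
            for _ in range(reps):
                if phi <= 0:
                    counts[g, k] = rng.poisson(m)
                else:
                    size = 1.0 / phi
                    counts[g, k] = rng.negative_binomial(size, size / (size + m))
                k += 1

    values = pd.DataFrame(
        counts, index=[t.gene_id for t in truth], columns=sample_labels
    )
    expr = ExpressionMatrix(
        values=values,
        gene_lengths_bp=pd.Series(
            [t.length_bp for t in truth], index=values.index
        ),
        library_sizes=pd.Series(
            float(config.library_size), index=sample_labels
        ),
        units="counts",
    )
    return expr, truth


def truth_to_expected_calls(
    truth: list[GeneTruth],
    thresholds: TestConfig = TestConfig(),
    filters: FilterConfig = FilterConfig(),
) -> dict[str, ResponseCall]:
    """Expected downstream verdict per gene under noiseless data.

    Derived from the planted effects alone: the Hh response without Esrrb is
    r1 = beta_H, with Esrrb r5 = beta_H + beta_I; the fold-change threshold
    stands in for significance.
    """
    if not truth:
        raise ValueError("truth list is empty")
    fc = thresholds.log2fc_threshold
    tau = filters.tau_log2
    out: dict[str, ResponseCall] = {}
    for t in truth:
        if t.class_label not in CLASS_EFFECTS:
            raise ValueError(f"unknown class label {t.class_label!r}")
        r1 = t.beta_h
        r5 = t.beta_h + t.beta_i
        gid = t.gene_id
        if abs(r1) < fc:
            if abs(r5) >= fc:
                call = ResponseCall(gid, True, "B", "gated")
            else:
                call = ResponseCall(gid, False, "none", "none")
        elif abs(r5) < fc:
            call = ResponseCall(gid, True, "A", "lost")
        elif np.sign(r1) != np.sign(r5):
            call = ResponseCall(gid, False, "none", "none")
        elif abs(r5) - abs(r1) > tau:
            call = ResponseCall(gid, True, "A", "enhanced")
        elif abs(r1) - abs(r5) > tau:
            call = ResponseCall(gid, True, "A", "depressed")
        elif abs(t.beta_e) >= fc:
            call = ResponseCall(gid, True, "A" if t.beta_e + t.beta_i else "B",
                                "proportional_additive")
        else:
            call = ResponseCall(gid, False, "none", "none")
        out[gid] = call
    return out


# -- truth TSV ---------------------------------------------------------------

_TRUTH_COLUMNS = (
    "gene_id",
    "class_label",
    "baseline_log2",
    "beta_h",
    "beta_e",
    "beta_i",
    "length_bp",
)


def write_truth_tsv(truth: list[GeneTruth], path) -> None:
    df = pd.DataFrame([t.__dict__ for t in truth], columns=_TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth_tsv(path) -> list[GeneTruth]:
    # keep_default_na: the class label "null" must survive as a string
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    return [
        GeneTruth(
            gene_id=str(r.gene_id),
            class_label=str(r.class_label),
            baseline_log2=float(r.baseline_log2),
            beta_h=float(r.beta_h),
            beta_e=float(r.beta_e),
            beta_i=float(r.beta_i),
            length_bp=int(r.length_bp),
        )
        for r in df.itertuples()
    ]
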