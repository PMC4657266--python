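# Methods

## Model and procedure

The pipeline classifies interaction effects in a 2×2 factorial RNA-seq
design (Hedgehog stimulation H × Esrrb expression E, four conditions,
replicated). It deliberately mirrors a decision-artifact workflow rather
than fitting a factorial GLM: each of the five biologically meaningful
pairwise contrasts is tested on its own, reduced to a Y/N flag, and the
flag pattern — not a model coefficient — drives the classification. The
trade-off is transparency and auditability of every intermediate table at
the cost of statistical efficiency relative to a single interaction test;
the planted-truth benchmark (below) quantifies what the workflow actually
recovers.

Stages:

1. **Quantification.** Counts → RPKM = count / (length_kb ·
   mapped_reads_millions), with the supplied total mapped reads, never
   column sums. Displays and scatter comparisons use log₂(RPKM + 0.001);
   the same 0.001 appears as the fold-change pseudocount and the
   ratio-filter denominator offset, so one convention covers all
   zero-handling. Per-condition expression is the arithmetic mean of
   replicate RPKM.
2. **Pairwise tests.** A negative-binomial conditional exact test on the
   two within-contrast group sums (edgeR-style `exactTest`): counts are
   scaled to the geometric-mean library size, residual composition bias is
   removed with DESeq-style median-of-ratios size factors, group sums are
   compared conditionally on their total under a common dispersion
   estimated by pooled method of moments (floored at 0; φ = 0 degenerates
   to Poisson). The two-sided p accumulates all splits no more likely than
   the observed one; enumeration is truncated at ±12 sd (tail mass
   < 1e-15). Benjamini–Hochberg adjustment is applied per contrast;
   significance = q < 0.05 (strict) and |log₂FC| ≥ 1, with log₂FC taken
   from mean RPKM.

   The median-of-ratios step matters: when planted (or real) induction is
   one-directional, fixing sequencing depth makes every unchanged gene's
   relative count drop in the induced condition. Without the correction,
   null genes inherit a ~0.7-log₂ artifactual shift in the
   esrrb-vs-esrrb_hh contrast and flood the gated category. Fold changes,
   being defined on RPKM, still carry that compositional drift — it is a
   real property of depth-normalised expression — but significance does
   not.
3. **Sorting.** Flags (C1..C5) → group id via
   `32 − (16·C1 + 8·C2 + 4·C3 + 2·C4 + C5)`. The encoding is a design
   choice (see below). Candidate groups are the C1 = Y patterns that pass
   a satisfiability predicate: treat each N flag as "same expression
   level", each Y as "clearly different", union-find the N-pairs and
   reject patterns where a Y-pair collapses into one block. Exactly 8 of
   the 16 C1 = Y patterns survive: groups {1, 2, 3, 4, 5, 9, 11, 14}.
4. **Effect-size filters and categories.** As stated in the README; the
   branch filters remove a gene if **any** removal inequality holds
   (configurable to `all`), and the category logic compares r₁ = log₂FC(C1)
   against r₅ = log₂FC(C5) with margin τ.
5. **Enrichment.** Literature sets are twofold-filtered (strict >2 or
   <0.5 on linear ratios), direction-labelled, and overlap significance is
   the one-sided hypergeometric upper tail P(X ≥ k) — symmetric in the two
   sets. The universe defaults to genes with nonzero RPKM in at least one
   condition and is exposed because enrichment p-values are only
   interpretable relative to a stated universe.
6. **Validation statistics.** Spearman rank correlation across all samples
   (average ranks for ties; constant columns yield an explicit undefined
   marker, never 0), hierarchically clustered with average linkage on
   1 − ρ; and per-gene Pearson r between qPCR (normalised to the reference
   gene at amplification efficiency 2.0, then to the control condition)
   and RNA-seq (RPKM normalised to control).

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| q_threshold | 0.05 | — | published decision rule; q = 0.05 exactly is non-significant (strict <) |
| log2fc_threshold | 1 | log₂ | published decision rule |
| pseudocount | 0.001 | RPKM | the package-wide zero-handling convention |
| rel_change_floor | 0.5 | relative | minimum 50% change for a "real" response |
| abs_change_floor_rpkm | 5 | RPKM | suppresses large ratios on tiny expressors (only binding for low-expressed genes) |
| nonsig_drift_ceiling | 0.1 | relative | branch-B coherence: a "no change" call may drift at most 10% |
| τ (tau_log2) | 0.585 | log₂ | ≈1.5-fold margin separating enhanced/depressed from proportional responses; not externally fixed, exposed in config |
| combination | any | — | a gene is removed if any inequality holds; `all` exposed because the conjunction is a defensible alternative reading |
| NB dispersion φ | 0.02 | — | typical biological-replicate overdispersion for cell-line RNA-seq |
| efficiency | 2.0 | — | perfect primer doubling per qPCR cycle |

## Synthetic data: what it emulates and what it does not

`simdata` draws gene-level NB counts (variance μ + φμ²) from a log₂-linear
factorial model with per-class effect archetypes (see module docstring),
uniform baselines on a log₂ range so both high and low expressors exercise
the absolute-RPKM filter, uniform gene lengths, and per-sample expected
totals scaled to the library size. Class quotas use largest-remainder
rounding; every gene has its own counter-derived RNG substream, so
enlarging an experiment never perturbs earlier genes' draws. Default
library size is 5e6 reads.

Emulated: replicate overdispersion, interaction archetypes, depth
normalisation, composition bias (via the column-sum constraint — this is
why the analysis needs median-of-ratios factors, exactly as real data
does). Not emulated: read-level artifacts (mapping, GC bias),
batch effects, correlated genes, transcript-level ambiguity, heavy-tailed
dispersion across genes (a single φ is shared). Passing the recovery
benchmark therefore shows the logic and calibration of the pipeline are
sound under its stated noise model; it does not certify performance on
data with structured technical variation.

## Benchmarks and problem sizes

Two standing experiments live in `hhsort.benchmarks`:

* **Null calibration** — 1000 all-null genes, φ = 0.05, 2 replicates,
  library 1e6, baselines 2⁵–2⁹, 20 seeds: the flagged fraction must stay
  within 3 binomial SE of the nominal 0.05 (empirically ≈0 because the
  fold-change gate compounds the q gate), and null p-values must be
  near-uniform (mean KS distance ≈ 0.03).
* **Planted recovery** — 2000 genes, 100 each enhanced (β_H 2, β_I 1.5),
  lost (2, −2), gated (0, 2), 1700 null, φ = 0.02, library 2e6, baselines
  2⁸–2¹¹ (per-condition means of a few hundred to a few thousand counts),
  10 seeds: sensitivity ≥ 80% with ≤ 10% false calls. Measured ≈ 86% and
  ≈ 4%. The dominant miss mode is instructive: enhanced genes whose
  hh-vs-esrrb_hh RPKM fold change lands under the |log₂FC| ≥ 1 gate once
  compositional drift is subtracted, sending them to branch B where the
  drift ceiling removes them.

These sizes are the package's chosen benchmark conditions; they make the
full suite and the reproduction script run in minutes on a single CPU.

## Design choices where the design was open

* **Group numbering.** Any bijection between flag patterns and 1..32
  works; the shipped encoding puts the Hh-responsive patterns at 1–16 and
  decodes group 25 as "responds to Hh only when Esrrb is present", which
  keeps the ids semantically aligned with how the groups are discussed.
  The map is swappable via `retained_ids`/a label table.
* **Candidate-group predicate.** "Self-contradictory" flag patterns are
  defined by transitive satisfiability (above) — a data-free rule that can
  be enumerated and audited over all 32 patterns, rather than a hard-coded
  id list. The retained set is nevertheless configurable by explicit ids.
* **Removal-inequality combination.** `any` (each inequality is an
  independent effect-size floor); under the `all` reading branch B would
  retain genes whose esrrb_hh-vs-hh drift exceeds 10%, contradicting the
  premise that those genes showed no significant C4 change.
* **Replicate aggregation** for filter inequalities: arithmetic mean RPKM.
* **BH per contrast**, not pooled across the five contrasts, matching how
  per-comparison q-values are reported by standard DE tools.
* **Linkage**: average, on 1 − ρ, with ties resolved by input (label)
  order; exposed in `hierarchical_cluster`.

## Numerical notes and degenerate inputs

Exact-test ties are kept in the rejection region with a 1 + 1e-12
relative guard; totals of zero give p = 1; single-replicate sides yield
fold changes with p marked unavailable (NaN) rather than a fabricated
p-value. Ratio filters add 0.001 to denominators, so zero-RPKM conditions
are well-defined. Constant samples make Spearman ρ undefined and
clustering refuses them by name. `bh_adjust` rejects p outside [0, 1];
`overlap_enrichment` rejects universes smaller than the set union.
Opposite-sign r₁/r₅ pairs are left uncategorised ("none") rather than
forced into enhanced/depressed.

## Known limitations

The five-test + sorting workflow inherits the multiple-decision character
of the original design: its error rates are controlled empirically (the
benchmarks), not analytically. A single common dispersion understates
gene-specific variability on real data. Fold changes carry compositional
drift by construction (see above). The literature-compendium driver uses a
synthetic stand-in set; real enrichment runs should supply curated GMT/TSV
sets and an explicit universe.
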