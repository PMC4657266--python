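# hhsort

Factorial interaction analysis for bulk RNA-seq: which genes change their
response to Hedgehog-pathway stimulation when the orphan nuclear receptor
Esrrb (estrogen-related receptor β) is expressed?

## The problem

A 2×2 factorial experiment crosses two perturbations of a
Hedgehog-responsive fibroblast line: Hedgehog-ligand conditioned medium
(Hh-CM) and Esrrb transfection, giving four conditions — control, `hh`,
`esrrb`, `esrrb_hh` — with replicated gene-level RNA-seq. The question is
not which genes respond to either factor, but which genes respond to
Hedgehog *differently* depending on Esrrb: an interaction, read out as a
change in the Hh response between the Esrrb-absent contrast
(`ctrl vs hh`) and the Esrrb-present contrast (`esrrb vs esrrb_hh`).

The analysis works on decision artifacts rather than a single GLM
interaction coefficient. Five pairwise comparisons are tested
(`C1: ctrl–hh`, `C2: ctrl–esrrb`, `C3: ctrl–esrrb_hh`, `C4: hh–esrrb_hh`,
`C5: esrrb–esrrb_hh`; `hh–esrrb` has no biological contrast). Each gene
gets five Y/N flags (significant at BH q < 0.05 with |log₂FC| ≥ 1), hence
one of 2⁵ = 32 logical groups:

    group = 32 − (16·C1 + 8·C2 + 4·C3 + 2·C4 + C5)      (Y = 1)

Hh-responsive genes (C1 = Y) fill groups 1–16; the 8 of those 16 whose
flag patterns are jointly satisfiable (no chain of "not different"
comparisons forcing two "different" conditions together) are the candidate
groups. Candidates then pass two branches of RPKM effect-size filters —
branch A (C4 = Y) drops genes with |Δ(EH,H)/H| < 0.5, |Δ(H,C)/C| < 0.5, or
|RPKM(EH) − RPKM(H)| < 5; branch B (C4 = N) drops genes with
|Δ(H,C)/C| < 0.5, |Δ(EH,H)/H| > 0.1, or |Δ(E,C)/C| < 0.5 — and survivors
are categorised by comparing r₁ = log₂FC(C1) with r₅ = log₂FC(C5):

| category | meaning |
|---|---|
| enhanced | \|r₅\| − \|r₁\| > τ (default τ = 0.585 ≈ 1.5-fold) |
| depressed | \|r₁\| − \|r₅\| > τ |
| lost | C5 not significant: the Hh response disappears with Esrrb |
| proportional_additive | r₁ ≈ r₅ with an Esrrb baseline shift (C2 = Y) |
| gated | C1 = N but C5 = Y with \|r₅\| ≥ 1: responds to Hh only with Esrrb (the group-25 pattern) |

Because the original raw reads are not re-processed here, all statistical
machinery is validated on synthetic data: the `simdata` module plants these
archetypes in negative-binomial counts (variance μ + φμ², log₂-linear
factorial means) so every downstream call can be scored against truth.

## Worked example

```
python analysis/01_simulate.py            # 2000 genes, 100 per archetype
python analysis/03_differential_tests.py
python analysis/04_sort_and_classify.py
```

prints (seed 1):

```
C1 (ctrl vs hh): 203 significant (200 up, 3 down)
...
retained candidate groups: [1, 2, 3, 4, 5, 9, 11, 14]
differential-response genes: 268
category
gated       100
lost         99
enhanced     69

against planted truth (300 differential genes):
  sensitivity 85.7%, false calls 4.1%
```

203 genes pass the ctrl-vs-hh test — the 200 planted enhanced and lost
genes (both respond to Hh alone at 4-fold) plus a few noise calls; gated
genes correctly stay out of C1. The sorter then recovers 268
differential-response genes of the 300 planted, with 4.1% of calls landing
on null genes.
`analysis/02_sample_correlation.py` reproduces the expected sample-QC
pattern (replicates cluster; control vs `esrrb_hh` is the least-correlated
pair), `05_enrichment.py` scores a twofold-filtered overlap against a
synthetic literature compendium with the hypergeometric upper tail, and
`06_qpcr_validation.py` emulates the qPCR cross-check (minimum per-gene
Pearson r = 0.996 between control-normalised qPCR and RNA-seq profiles).

The same stages are available as subcommands of the `hhsort` console
script (`simulate`, `quantify`, `test`, `sort`, `enrich`, `correlate`,
`run-all`, `report`).

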