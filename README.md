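# g2dscreen

**GWAS-informed in-silico drug repurposing screen** — from risk-gene
pathway annotations and a perturbagen rank-profile corpus, through
Kolmogorov–Smirnov pathway enrichment and a cross-gene co-occurrence
merge, to drug-set pathway back-mapping (E-scores) and pooled
viability-screen validation statistics.

The package is for computational pharmacologists who want to turn a GWAS
trait's annotated risk genes into a ranked, validated list of approved
drugs, the way it was done for glioblastoma against Temozolomide (TMZ) as
the reference treatment — but with every stage reproducible, seeded, and
testable against synthetic corpora with planted ground truth.

## The method in brief

For a gene set occupying sorted positions `p_1 < … < p_t` of a ranking of
`n` genes, the enrichment score is the unweighted two-sided running-sum
statistic

    a = max_j (j/t − p_j/n),   b = max_j (p_j/n − (j−1)/t),
    es = a if a > b else −b          (es ∈ (−1, 1])

with empirical two-sided permutation p-values
`p = (1 + #{|es_rand| ≥ |es|}) / (n_perm + 1)`. The same statistic is
applied at three levels:

1. **PEP**: pathway members' positions in a drug's gene ranking → a
   Pathway Expression Profile per drug (replicates merged by mean
   pathway rank).
2. **Gene→drug**: a risk gene's pathway set's positions in each drug's
   *pathway* ranking → one candidate drug list per risk gene
   (keep p < 1e−2); lists are merged by co-occurrence (drug kept if it
   appears in ≥ 4 per-gene lists), then filtered to FDA-approved,
   CNS-active drugs.
3. **DSEA**: the candidate set's positions in each pathway's *drug*
   ranking → E-scores in [−1, +1] for the pathways the candidates
   collectively up-/down-regulate.

Validation uses pooled-screen sensitivity (`−log2` barcode ratio, higher
= more killing): replicate-concordance exclusion, mean-sensitivity
ranking with 95% t-intervals, Mann–Whitney tests versus the reference
drug, mutation association, Welch differential expression between
sensitive and non-sensitive cell lines, and a panel-wide "direct screen".
See `docs/methods.md` for the full model and all defaults.

## Worked example

The numbered scripts under `analysis/` run the whole study on a seeded
synthetic corpus (100 drugs × 3 replicate profiles over 1,000 genes and
150 pathways; 15 risk genes of which 9 are pathway-annotated; a
140-series viability screen on 42 cell lines with 10 planted active
drugs):

```sh
python analysis/01_simulate_study.py --seed 7
python analysis/02_build_peps.py
python analysis/03_gene2drug_merge.py --seed 7
python analysis/04_dsea_pathways.py --seed 7
python analysis/05_validate_viability.py
python analysis/06_direct_screen.py
```

Stage 03 prints (abridged):

```
g0985: 6 pathways -> 9 significant drugs
...
co-occurrence histogram (lists -> drugs): {9: 8, 5: 1, 4: 1}
kept at cutoff 4: ['drug017', 'drug019', 'drug031', 'drug033', 'drug038',
                   'drug051', 'drug067', 'drug078', 'drug087', 'drug007']
FDA-approved + CNS-active candidates: [same 10 drugs]
```

All ten planted active drugs co-occur in at least four of the nine
per-gene lists and survive the filters — the histogram reads "8 drugs in
9 lists, 1 in 5, 1 in 4". Stage 05 then validates them on the screen:

```
discordant replicate treatments excluded: ['drug002']
mean-sensitivity ranking (10 candidates + TMZ):
  drug007    mean +1.29 CI [+0.96, +1.61] p=2.01e-07
  drug017    mean +1.15 CI [+0.78, +1.52] p=7.02e-06
  ...
  TMZ        mean -0.08 CI [-0.39, +0.24] (reference)
mutation association drug007 ~ TP53: p = 0.009
DE genes for drug007 (sensitive vs non-sensitive, p < 1e-3):
  ['EXPR000', 'EXPR001', 'EXPR002', 'EXPR003', 'EXPR004']
```

Every candidate's mean sensitivity beats the reference, the planted
TP53-linked sensitivity shift is detected, and the five planted
expression markers are recovered exactly. Stage 06 reports the direct
screen: `higher mean sensitivity than TMZ: 83/155 (53.55%)`,
`significantly higher at p < 0.001: 13 (8.39%)` — the 13 hits are the 10
planted potent drugs plus their replicate datasets.

The same flow is exposed as a CLI (`g2dscreen simulate | pep | gene2drug
| merge | dsea | validate | screen`) and as one library call,
`g2dscreen.run_screen(ScreenConfig(...))`, which persists every stage and
writes a checksum manifest so reruns are byte-identical.

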