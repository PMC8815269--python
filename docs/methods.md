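# Methods

`g2dscreen` implements a GWAS-informed drug repurposing screen as a tested
pipeline. This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic corpora do and do not emulate,
and the numerical choices made where the design was genuinely open.

## The screening model

The screen starts from a list of disease risk genes (GWAS-annotated) and a
perturbagen corpus: for each drug treatment instance, a total ranking of a
gene universe by differential expression (rank 1 = most up-regulated,
CMap-style). Pathways are flat gene sets (GO/KEGG-style, GMT files); no
ontology structure is used.

### KS running-sum enrichment

The core statistic throughout is the unweighted two-sided
connectivity-score running sum. For a set occupying sorted positions
`p_1 < ... < p_t` of a ranking of length `n`:

    a  = max_j ( j/t − p_j/n )
    b  = max_j ( p_j/n − (j−1)/t )
    es = a  if a > b,  else −b

`es` lies in (−1, 1]: positive when the set crowds the top of the ranking,
negative toward the bottom. Two properties worth knowing: the extremal
magnitude at set size `t` is `1 − (t−1)/n`, and reversing the ranking
flips the sign only up to a `1/n` shift (the two excesses swap roles with
an off-by-one in the step function), so near-null scores may keep their
sign under reversal. Significance is always empirical: two-sided with the
small-sample correction,

    p = (1 + #{ |es_rand| ≥ |es| }) / (n_perm + 1)

over `n_perm` random same-size sets from a seeded generator, so `p` is in
(0, 1] and valid at any finite `n_perm`. A practical corollary: the
minimum attainable p is `1/(n_perm+1)`, so a significance threshold of
1e−2 needs `n_perm ≥ 100` (the pipeline warns otherwise). The default is
`n_perm = 999`.

### Pathway Expression Profiles (PEPs)

Applying the statistic to every pathway's member positions turns one
ranked profile into a pathway-level profile: es, empirical p, and a
pathway rank (1 = most up-regulated pathway; ties broken by pathway id so
results are reproducible). Replicate treatment instances of one drug are
merged by mean pathway rank (Borda-style) — scale-free across replicates —
with the es averaged and replicate p-values dropped (they do not combine
meaningfully). Whether the source engine merged replicates before or
after pathway ranking is not documented; merging after is this package's
choice.

### Gene-to-drug lists and the co-occurrence merge

For each risk gene, its pathway annotations form a query set; the same KS
statistic applied to the query's positions within each drug's pathway
ranking (universe size = number of pathways) scores every drug, and
random same-size pathway sets give the null (one shared null sample
serves all drugs: positions of a uniform set are uniform in any
permutation). Entries with p < 1e−2 survive.

Per-gene lists are merged by co-occurrence: a drug's evidence is the
number of distinct lists containing it, and drugs in at least 4 lists are
kept. The `≥` (rather than `>`) semantics follow the screen's reported
survivors, which include compounds at exactly the cutoff. Kept drugs are
ordered by count, then best p across lists, then id — the source ordering
is not reproducible, so a deterministic rule is imposed. A final filter
keeps FDA-approved, CNS-active drugs (annotation absent = not approved).

### Drug-set enrichment (DSEA)

The merged candidate set is mapped back to pathways: per pathway, all D
corpus drugs are ranked by that pathway's es (descending, ties by id) and
the E-score is the KS statistic of the candidate set's positions —
directly in [−1, +1], positive = up-regulated by the set. The null
permutes the drug set (random equal-size sets), not the pathway, keeping
pathway identities fixed; p-values are two-sided (sidedness was an open
choice).

## Viability validation

Sensitivity follows the pooled-barcode convention
`−log2((treatment + pc)/(control + pc))` with pseudocount 0.5, so higher =
more killing; files storing viability log-fold-change are negated at
ingest. Statistics are pairwise-complete over available cell lines
(pooled screens are incomplete by design) and deliberately uncorrected
for multiple testing — the protocol thresholds raw p-values (1e−2, 1e−3);
a Benjamini–Hochberg helper exists but is off by default.

* **Ranking**: per treatment series, mean, sd, and the two-sided 95%
  t-interval `mean ± t(0.975, n−1)·sd/√n`.
* **Tests vs the reference** (the standard-of-care drug): unpaired
  Mann–Whitney U, exact enumeration when both n ≤ 8 with no ties, else
  the normal approximation with tie and continuity corrections. The
  screen uses `alternative = greater`; mutation association (mutated vs
  wild-type lines) is two-sided.
* **Replicate concordance**: treatments screened in ≥ 2 datasets are
  excluded when any pair of series has Pearson r < 0.3 over shared lines
  (< 3 shared lines = undefined → flagged for review, never
  auto-excluded). The exclusion criterion for "disparate responses" is
  not documented anywhere; r_min = 0.3 is this package's stand-in.
* **Direct screen**: every series (replicate datasets as separate
  treatments) vs the reference; "significant" means higher mean *and*
  p < 1e−3; fractions are over the non-reference series.
* **Differential expression**: per-gene Welch tests between sensitive and
  non-sensitive lines (per-drug median split of observed sensitivity —
  the grouping was undefined upstream and is exposed as a parameter);
  genes with both groups at zero variance get p = 1. The heatmap matrix
  orders columns by descending sensitivity and rows by average-linkage
  hierarchical clustering on correlation distance.

## Synthetic study conditions

The generators stand in for the external corpora (perturbagen database,
pathway database, pooled screen, mutation/expression annotations) at a
scale where the full pipeline runs in seconds on one CPU.

**Corpus** (`gen_corpus`): 1,000 genes, 150 pathways of 10–50 members
drawn without replacement from the non-risk genes, 100 drugs × 3
replicate instances. Fifteen risk genes mirror the 15-gene / 9-annotated
structure of a GWAS trait list: 9 carry pathway annotations, 6 none. The
9 annotated genes form two clusters (5 + 4) whose members share one
pathway set of 2–6 pathways — planted convergence of risk genes on shared
processes, which is what makes a drug perturbing the pathway sets of 1–3
risk genes discoverable in ≥ 4 per-gene lists. Ten drugs are active: each
shifts the standard-normal scores of every member gene of its perturbed
pathways by `direction · δ` (δ = 2.0) before ranking, so rank statistics
compete against a realistic background.

**Screen** (`gen_viability`): sensitivity of drug d on line c in dataset
s is `μ_d + γ_c + η_dc + m(d,c) + ε_dcs` with line effect γ ~ N(0, 0.5²),
drug-by-line interaction η ~ N(0, 0.5²) shared between replicate
datasets, per-dataset noise ε ~ N(0, 0.5²), `μ_d = 1.0` for potent drugs
(10%) and 0 otherwise, and a neutral reference treatment. Defaults give
140 series on 42 lines: 124 drugs with 16 replicate datasets, one of
which is planted discordant (inverted line effect) to exercise the
concordance filter. Mutation-linked shifts (+0.8 on mutated lines, genes
TP53/PTEN) and expression markers (five genes per top potent drug,
shifted +3 in the lines above the observed primary-dataset median) give
the association and DE stages known answers. `gen_study` ties the two
together: the corpus's active drugs are the screen's potent drugs.

What the generators do not emulate — and hence what green tests do not
establish about real corpora: transcriptome covariance (genes are
independent Gaussians), dose–response structure, batch effects, the
vocabulary and overlap structure of real pathway databases, and the
heavy-tailed sensitivity distributions of real pooled screens. Tests on
these corpora establish correctness of the statistics and the plumbing,
plus power/calibration under the planted model, not real-data effect
sizes.

## Numerical and reproducibility choices

* Score-to-rank conversion: stable sort on descending score = average-tie
  rank followed by a deterministic tie-break in universe (gene) order, so
  every profile is a strict permutation.
* All tie-breaks (pathway rank, drug ranking, output orderings) fall back
  to lexical ids; every ordering in the pipeline is total.
* Every random draw flows from an explicit seed; pipeline stages derive
  child seeds by hashing `seed:stage-tag`, so results are independent of
  stage iteration order and reruns are byte-identical (the output
  manifest records checksums to prove it).
* Degenerate inputs fail loudly: empty position sets, non-permutation
  rank columns, queries covering the whole collection, drug sets equal to
  the whole corpus, empty Mann–Whitney groups. Warn-and-continue is
  reserved for expected data imperfections (out-of-universe GMT members,
  non-finite viability values, pathways with no in-universe members).
* Problem sizes in the shipped tests and drivers (100-drug corpora,
  999 permutations, 20-seed recovery sweeps) were chosen so the whole
  suite completes in about a minute while keeping permutation p-values
  meaningful at the 1e−2 list threshold.

## Known limitations

* The empirical permutation p-values are not numerically comparable to
  whatever analytic or tool-specific p-values an external implementation
  produces; only thresholds and orderings should be compared.
* The concordance rule (r_min) and the sensitive/non-sensitive median
  split are documented stand-ins for undocumented upstream choices and
  are exposed as parameters.
* DSEA reports the raw KS es as the E-score (already in [−1, 1]); no
  additional normalisation is applied.
* Checks against the original study's printed numbers require its
  supplementary tables and the frozen PRISM 19Q4 release at
  `data/external/` (schemas documented in `tests/test_acceptance.py`);
  without them those two checks report failure rather than silently
  passing.
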