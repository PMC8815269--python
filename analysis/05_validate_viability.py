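#!/usr/bin/env python
"""Validate the candidates on the pooled viability screen.

Excludes replicate-discordant treatments, ranks candidates by mean
sensitivity with 95% t-intervals, tests each against the reference
treatment (one-sided Mann-Whitney), probes mutation associations, and
extracts differentially expressed genes between sensitive and
non-sensitive lines for the top candidate.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from g2dscreen.geneset_io import read_viability_table
from g2dscreen.viability import (
    de_genes,
    mannwhitney_vs_reference,
    mean_sensitivity_ranking,
    mutation_association,
    replicate_concordance_filter,
)

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--candidates", type=Path,
                    default=Path("results/candidates.json"))
parser.add_argument("--reference", default="TMZ")
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

vm = read_viability_table(
    args.study / "viability.csv",
    mutations=args.study / "mutations.csv",
    expression=args.study / "expression.csv",
)
candidates = json.loads(args.candidates.read_text())
screened = {t for t, _ in vm.series_keys()}

concordance = replicate_concordance_filter(vm)
print(f"discordant replicate treatments excluded: {concordance.excluded}")
usable = [d for d in candidates
          if d in screened and d not in set(concordance.excluded)]

ranking = mean_sensitivity_ranking(vm, usable + [args.reference])
print(f"mean-sensitivity ranking ({len(usable)} candidates + {args.reference}):")
rows = []
for s in ranking:
    p = None
    if s.treatment_id != args.reference:
        _, p = mannwhitney_vs_reference(vm, s.treatment_id, args.reference, "greater")
    tag = f"p={p:.2e}" if p is not None else "(reference)"
    print(f"  {s.treatment_id:10s} mean {s.mean:+.2f} "
          f"CI [{s.ci95[0]:+.2f}, {s.ci95[1]:+.2f}] {tag}")
    rows.append({"treatment_id": s.treatment_id, "mean": s.mean, "sd": s.sd,
                 "ci95_lo": s.ci95[0], "ci95_hi": s.ci95[1], "p_vs_ref": p})
pd.DataFrame(rows).to_csv(args.out / "candidate_ranking.tsv", sep="\t",
                          index=False, float_format="%.10g")

top = next(s.treatment_id for s in ranking if s.treatment_id != args.reference)
for gene in vm.mutations.columns:
    p = mutation_association(vm, top, gene)
    print(f"mutation association {top} ~ {gene}: p = {p:.3f}")

sens = vm.series(top)
groups = (sens > sens.median()).reindex(vm.expression.columns).fillna(False)
selected, matrix = de_genes(vm.expression, groups, alpha=1e-3, ordering=sens)
print(f"DE genes for {top} (sensitive vs non-sensitive, p < 1e-3): {selected}")
matrix.to_csv(args.out / "de_heatmap_matrix.tsv", sep="\t", float_format="%.10g")
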