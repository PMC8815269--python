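#!/usr/bin/env python
"""Gene-to-drug stage and candidate merge.

For every annotated risk gene: rank all drugs by enrichment of the gene's
pathway set in their PEPs, keep candidates at p < 1e-2, then merge the
per-gene lists by co-occurrence (a drug must appear in at least 4 lists)
and restrict to FDA-approved, CNS-active treatments.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from g2dscreen.geneset_io import pathways_of_gene, read_gmt, read_rank_matrix, \
    read_viability_table
from g2dscreen.gep2pep import rank_drugs_for_pathway_set
from g2dscreen.pipeline import build_drug_peps
from g2dscreen.screening import cooccurrence_merge, filter_fda_cns, \
    filter_significant, venn_text

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--n-perm", type=int, default=999)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

collection = read_gmt(args.study / "pathways.gmt")
profiles = read_rank_matrix(args.study / "profiles.tsv", mode="ranks")
bound = collection.bind(profiles[0].universe)
peps = build_drug_peps(profiles, bound)
risk_genes = (args.study / "risk_genes.txt").read_text().split()
vm = read_viability_table(args.study / "viability.csv")

lists = []
for gene in sorted(risk_genes):
    query = pathways_of_gene(bound, gene)
    if not query:
        print(f"{gene}: no pathway annotation, skipped")
        continue
    dl = rank_drugs_for_pathway_set(peps, query, args.n_perm, args.seed, gene_id=gene)
    sig = filter_significant(dl, alpha=1e-2)
    print(f"{gene}: {len(query)} pathways -> {len(sig)} significant drugs")
    lists.append(sig)

merged = cooccurrence_merge(lists, cutoff=4)
candidates = filter_fda_cns(merged, vm.treatment_meta)

print(f"co-occurrence histogram (lists -> drugs): {merged.histogram()}")
print(f"kept at cutoff 4: {merged.kept}")
print(f"FDA-approved + CNS-active candidates: {candidates}")

args.out.mkdir(parents=True, exist_ok=True)
rows = []
for dl in lists:
    sub = dl.table.copy()
    sub.insert(0, "gene_id", dl.gene_id)
    rows.append(sub)
pd.concat(rows, ignore_index=True).to_csv(
    args.out / "gene_drug_lists.tsv", sep="\t", index=False, float_format="%.10g")
merged.to_frame().to_csv(args.out / "merged_candidates.tsv", sep="\t",
                         index=False, float_format="%.10g")
(args.out / "venn_summary.txt").write_text(venn_text(lists) + "\n")
(args.out / "candidates.json").write_text(json.dumps(candidates) + "\n")
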