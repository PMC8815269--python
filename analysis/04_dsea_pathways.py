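#!/usr/bin/env python
"""Drug-set enrichment: which pathways do the candidate drugs share?

Maps the merged candidate set back onto the pathway collection: per
pathway, the E-score in [-1, +1] of the candidate drugs' positions in the
pathway's corpus-wide drug ranking (positive = up-regulated by the set),
with a drug-set permutation p-value.
"""

import argparse
import json
from pathlib import Path

from g2dscreen.dsea import dsea_table
from g2dscreen.geneset_io import read_gmt, read_rank_matrix
from g2dscreen.pipeline import build_drug_peps

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--candidates", type=Path,
                    default=Path("results/candidates.json"))
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--n-perm", type=int, default=999)
parser.add_argument("--out", type=Path, default=Path("results/dsea.tsv"))
args = parser.parse_args()

collection = read_gmt(args.study / "pathways.gmt")
profiles = read_rank_matrix(args.study / "profiles.tsv", mode="ranks")
peps = build_drug_peps(profiles, collection.bind(profiles[0].universe))
candidates = [d for d in json.loads(args.candidates.read_text()) if d in peps]

table = dsea_table(peps, candidates, n_perm=args.n_perm, seed=args.seed)
table.to_csv(args.out, sep="\t", index=False, float_format="%.10g")

print(f"{len(candidates)} candidate drugs against {len(table)} pathways")
print("strongest shared pathways (E-score, p):")
for _, row in table.head(8).iterrows():
    print(f"  {row['pathway_id']}  {row['e_score']:+.2f}  {row['p_value']:.2e}")
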