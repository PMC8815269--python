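#!/usr/bin/env python
"""Convert the ranked profiles into per-drug Pathway Expression Profiles.

Each treatment instance's gene ranking becomes a pathway-level enrichment
vector (KS running sum); replicate instances are merged by mean pathway
rank.  The result is a PEP store under results/pep_store/.
"""

import argparse
from pathlib import Path

from g2dscreen.geneset_io import read_gmt, read_rank_matrix
from g2dscreen.gep2pep import write_pep_store
from g2dscreen.pipeline import build_drug_peps

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--out", type=Path, default=Path("results/pep_store"))
args = parser.parse_args()

collection = read_gmt(args.study / "pathways.gmt")
profiles = read_rank_matrix(args.study / "profiles.tsv", mode="ranks")
bound = collection.bind(profiles[0].universe)
peps = build_drug_peps(profiles, bound)
write_pep_store(peps, args.out)

example = next(iter(peps.values()))
print(f"built {len(peps)} drug-level PEPs over {example.n_pathways} pathways "
      f"-> {args.out}")
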