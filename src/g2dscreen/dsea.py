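"""Drug-set enrichment analysis (DSEA): map a candidate drug set back to
the pathways it collectively perturbs.

For each pathway, all D drugs in the corpus are ranked by that pathway's
enrichment score (descending, ties by drug id); the E-score is the KS
running-sum statistic of the candidate set's positions in that ranking,
so it lies in [-1, +1] with positive values meaning the pathway is
up-regulated by the drug set and negative values down-regulated.
Significance comes from a seeded drug-set permutation null (random equal-
size drug sets), two-sided on |E-score|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .gep2pep import (
    PathwayExpressionProfile,
    empirical_pvalues,
    ks_statistic,
    ks_statistic_batch,
    sample_position_sets,
)

__all__ = ["DseaResult", "dsea_escore", "dsea_table"]


@dataclass(frozen=True)
class DseaResult:
    pathway_id: str
    e_score: float
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.e_score <= 1.0:
            raise ValueError(f"E-score {self.e_score} outside [-1, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _validate(peps: Mapping[str, PathwayExpressionProfile], drug_set: set[str]) -> list[str]:
    if not drug_set:
        raise ValueError("drug set is empty")
    drugs = sorted(peps)
    if not drug_set < set(drugs):
        missing = drug_set - set(drugs)
        if missing:
            raise ValueError(f"drug set members missing from PEPs: {sorted(missing)}")
        raise ValueError("drug set must be a strict subset of the corpus drugs")
    return drugs


def _set_positions(
    peps: Mapping[str, PathwayExpressionProfile],
    drugs: list[str],
    drug_set: set[str],
    pathway_id: str,
) -> np.ndarray:
    """Positions of drug_set within the pathway's drug ranking (by es desc)."""
    es = np.array([peps[d].table.loc[pathway_id, "es"] for d in drugs])
    order = np.lexsort((np.array(drugs, dtype=object), -es))
    in_set = np.array([drugs[i] in drug_set for i in order])
    return np.flatnonzero(in_set) + 1


def dsea_escore(
    peps: Mapping[str, PathwayExpressionProfile],
    drug_set: Iterable[str],
    pathway_id: str,
    n_perm: int = 999,
    seed: int = 0,
) -> DseaResult:
    """E-score and drug-set-permutation p for one pathway."""
    drug_set = set(drug_set)
    drugs = _validate(peps, drug_set)
    for d in drugs:
        if pathway_id not in peps[d].table.index:
            raise ValueError(f"pathway {pathway_id!r} absent from PEP of {d!r}")
    n_drugs = len(drugs)
    positions = _set_positions(peps, drugs, drug_set, pathway_id)
    es = ks_statistic(positions, n_drugs)
    rng = np.random.default_rng(seed)
    null_es = ks_statistic_batch(
        sample_position_sets(rng, max(n_perm, 1), len(drug_set), n_drugs), n_drugs
    )
    p = float(empirical_pvalues(np.array([es]), null_es)[0])
    return DseaResult(pathway_id, es, p)


def dsea_table(
    peps: Mapping[str, PathwayExpressionProfile],
    drug_set: Iterable[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """DSEA over every pathway in the corpus.

    Returns a DataFrame with columns pathway_id, e_score, p_value, sorted
    by ascending p, then descending |E-score|, then pathway id.  The
    permutation null (random drug sets of equal size) is shared across
    pathways — positions of a uniform drug set are uniform regardless of
    the pathway's ranking.
    """
    drug_set = set(drug_set)
    drugs = _validate(peps, drug_set)
    n_drugs = len(drugs)
    pathways = list(peps[drugs[0]].table.index)
    for d in drugs:
        if set(peps[d].table.index) != set(pathways):
            raise ValueError("PEPs cover different pathway ids")
    es = np.array(
        [
            ks_statistic(_set_positions(peps, drugs, drug_set, pw), n_drugs)
            for pw in pathways
        ]
    )
    rng = np.random.default_rng(seed)
    null_es = ks_statistic_batch(
        sample_position_sets(rng, max(n_perm, 1), len(drug_set), n_drugs), n_drugs
    )
    pvals = empirical_pvalues(es, null_es)
    out = pd.DataFrame({"pathway_id": pathways, "e_score": es, "p_value": pvals})
    out = out.sort_values(
        by=["p_value", "e_score", "pathway_id"],
        key=lambda col: -col.abs() if col.name == "e_score" else col,
        kind="stable",
    ).reset_index(drop=True)
    return out
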