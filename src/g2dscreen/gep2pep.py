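"""Kolmogorov-Smirnov running-sum enrichment over ranked profiles.

This module converts gene-level rankings (one per treatment instance) into
Pathway Expression Profiles (PEPs): per pathway, a signed enrichment score
measuring how concentrated the pathway's member genes are at either end of
the ranking, plus an empirical permutation p-value and a pathway rank.

The statistic is the unweighted two-sided connectivity-score running sum.
For a set occupying sorted positions ``p_1 < ... < p_t`` of ``1..n``::

    a = max_j ( j/t - p_j/n )        # excess toward the top
    b = max_j ( p_j/n - (j-1)/t )    # excess toward the bottom
    es = a   if a > b
       = -b  otherwise

so ``es`` is positive when the set crowds the top of the ranking
(up-regulation) and negative when it crowds the bottom.  Empirical
p-values are two-sided with the +1 small-sample correction:
``p = (1 + #{ |es_rand| >= |es| }) / (n_perm + 1)``, drawn from seeded
uniform same-size sets, so ``p`` always lies in (0, 1].

A second application of the same statistic — positions of a *pathway set*
within a drug's pathway ranking — turns a query gene's pathway annotations
into a ranked candidate-drug list (the gene-to-drug stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geneset_io import GeneSetCollection, RankedProfile

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentScore",
    "PathwayExpressionProfile",
    "DrugList",
    "ks_statistic",
    "ks_statistic_batch",
    "sample_position_sets",
    "empirical_pvalues",
    "profile_to_pep",
    "aggregate_replicates",
    "rank_drugs_for_pathway_set",
    "write_pep_store",
    "read_pep_store",
]


@dataclass(frozen=True)
class EnrichmentScore:
    """Signed KS enrichment of one set in one ranking."""

    es: float
    p_value: float | None
    set_size: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.es <= 1.0:
            raise ValueError(f"enrichment score {self.es} outside [-1, 1]")
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def ks_statistic(positions: Sequence[int] | np.ndarray, n: int) -> float:
    """Signed running-sum statistic of a position set in a ranking of size n.

    ``positions`` must be non-empty, strictly increasing integers in
    ``1..n``.  Returns ``es`` in ``(-1, 1]`` (positive = top-concentrated).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("positions must be non-empty")
    if pos.size > n:
        raise ValueError(f"set size {pos.size} exceeds universe size {n}")
    if pos[0] < 1 or pos[-1] > n:
        raise ValueError(f"positions must lie in 1..{n}")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    t = pos.size
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - pos / n)
    b = np.max(pos / n - (j - 1) / t)
    return float(a if a > b else -b)


def ks_statistic_batch(position_matrix: np.ndarray, n: int) -> np.ndarray:
    """Vectorised :func:`ks_statistic` over rows of sorted position sets."""
    pos = np.asarray(position_matrix, dtype=float)
    if pos.ndim != 2:
        raise ValueError("position_matrix must be 2-dimensional")
    t = pos.shape[1]
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - pos / n, axis=1)
    b = np.max(pos / n - (j - 1) / t, axis=1)
    return np.where(a > b, a, -b)


def sample_position_sets(
    rng: np.random.Generator, n_perm: int, t: int, n: int
) -> np.ndarray:
    """Draw ``n_perm`` sorted uniform ``t``-subsets of positions ``1..n``."""
    if t > n:
        raise ValueError("subset size exceeds universe size")
    # argpartition of uniform noise = uniform subset without replacement
    noise = rng.random((n_perm, n))
    picks = np.argpartition(noise, t - 1, axis=1)[:, :t] + 1
    return np.sort(picks, axis=1)


def empirical_pvalues(
    observed: np.ndarray, null_es: np.ndarray
) -> np.ndarray:
    """Two-sided empirical p with +1 correction against a shared null sample."""
    obs = np.abs(np.asarray(observed, dtype=float))
    null_abs = np.sort(np.abs(null_es))
    n_perm = null_abs.size
    # count of null |es| >= |obs| via right-side search on the sorted null
    n_ge = n_perm - np.searchsorted(null_abs, obs, side="left")
    return (1.0 + n_ge) / (n_perm + 1.0)


@dataclass
class PathwayExpressionProfile:
    """Per-drug pathway enrichment table.

    ``table`` is indexed by pathway id with columns ``es`` (float), ``p``
    (float, NaN when permutations were skipped), ``rank`` (int, 1 = most
    up-regulated pathway; a permutation of 1..P ordered by descending es
    with ties broken by pathway id).
    """

    drug_id: str
    table: pd.DataFrame
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        required = {"es", "p", "rank"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"PEP table needs columns {sorted(required)}")
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("pathway ranks are not a permutation of 1..P")
        if (self.table["es"].abs() > 1 + 1e-12).any():
            raise ValueError("enrichment scores outside [-1, 1]")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_pathways(self) -> int:
        return len(self.table)

    def score(self, pathway_id: str) -> EnrichmentScore:
        row = self.table.loc[pathway_id]
        p = None if pd.isna(row["p"]) else float(row["p"])
        return EnrichmentScore(float(row["es"]), p, int(row.get("set_size", 0) or 0))

    def positions_of(self, pathway_ids: Iterable[str]) -> np.ndarray:
        """Sorted pathway-rank positions of the given pathways."""
        ranks = self.table.loc[list(pathway_ids), "rank"].to_numpy()
        return np.sort(ranks)


def _rank_by_es(es: pd.Series) -> np.ndarray:
    """Ranks 1..P by descending es, ties broken by index (pathway id)."""
    order = np.lexsort((np.array(es.index, dtype=object), -es.to_numpy()))
    ranks = np.empty(len(es), dtype=np.int64)
    ranks[order] = np.arange(1, len(es) + 1)
    return ranks


def profile_to_pep(
    profile: RankedProfile,
    collection: GeneSetCollection,
    n_perm: int = 999,
    seed: int = 0,
) -> PathwayExpressionProfile:
    """Convert one ranked profile into a Pathway Expression Profile.

    Per pathway: the KS enrichment of its member genes' rank positions;
    an empirical two-sided p at ``n_perm`` seeded permutations (absent as
    NaN when ``n_perm=0``); and a rank by descending es (ties by pathway
    id).  Pathways with no member in the profile's universe are skipped
    with a warning.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    bound = collection
    if bound.universe is None or bound.universe.genes != profile.universe.genes:
        bound = collection.bind(profile.universe)
    n = profile.n
    ids: list[str] = []
    sizes: list[int] = []
    es_vals: list[float] = []
    for set_id in sorted(bound.sets):
        gs = bound.sets[set_id]
        positions = profile.positions_of(gs.members)
        if positions.size == 0:
            log.warning("pathway %s has no in-universe members; skipped", set_id)
            continue
        ids.append(set_id)
        sizes.append(positions.size)
        es_vals.append(ks_statistic(positions, n))
    if not ids:
        raise ValueError("no pathway overlaps the profile's universe")
    es = pd.Series(es_vals, index=ids, dtype=float)
    pvals = pd.Series(np.nan, index=ids, dtype=float)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        size_arr = np.asarray(sizes)
        for t in np.unique(size_arr):  # shared null per set size
            null_es = ks_statistic_batch(
                sample_position_sets(rng, n_perm, int(t), n), n
            )
            mask = size_arr == t
            pvals.iloc[np.flatnonzero(mask)] = empirical_pvalues(
                es.to_numpy()[mask], null_es
            )
    table = pd.DataFrame(
        {"es": es, "p": pvals, "rank": _rank_by_es(es), "set_size": sizes}
    )
    return PathwayExpressionProfile(profile.drug_id, table, profile.replicate_id)


def aggregate_replicates(
    peps: Sequence[PathwayExpressionProfile],
) -> PathwayExpressionProfile:
    """Merge replicate PEPs of one drug by mean pathway rank (Borda-style).

    The drug-level rank re-ranks pathways by mean per-replicate rank
    (lower mean = better rank, ties by pathway id); es becomes the mean
    es.  Replicate p-values do not combine and are dropped.
    """
    if not peps:
        raise ValueError("at least one PEP required")
    drug_ids = {p.drug_id for p in peps}
    if len(drug_ids) != 1:
        raise ValueError(f"mixed drug ids in replicate set: {sorted(drug_ids)}")
    index = peps[0].table.index
    for p in peps[1:]:
        if set(p.table.index) != set(index):
            raise ValueError("replicate PEPs cover different pathway ids")
    if len(peps) == 1:
        return PathwayExpressionProfile(peps[0].drug_id, peps[0].table.copy())
    mean_rank = sum(p.table["rank"].reindex(index) for p in peps) / len(peps)
    mean_es = sum(p.table["es"].reindex(index) for p in peps) / len(peps)
    order = np.lexsort((np.array(index, dtype=object), mean_rank.to_numpy()))
    ranks = np.empty(len(index), dtype=np.int64)
    ranks[order] = np.arange(1, len(index) + 1)
    table = pd.DataFrame(
        {"es": mean_es, "p": np.nan, "rank": ranks}, index=index
    )
    return PathwayExpressionProfile(peps[0].drug_id, table)


@dataclass
class DrugList:
    """Candidate drugs for one query gene's pathway set.

    ``table`` columns: drug_id, es, p — sorted by ascending p, ties by
    descending |es| then drug id.
    """

    gene_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"drug_id", "es", "p"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"drug list needs columns {sorted(required)}")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.table["drug_id"])

    def __len__(self) -> int:
        return len(self.table)


def rank_drugs_for_pathway_set(
    peps: Mapping[str, PathwayExpressionProfile],
    query: Iterable[str],
    n_perm: int = 999,
    seed: int = 0,
    gene_id: str = "",
) -> DrugList:
    """Rank drugs by enrichment of a query pathway set in their PEPs.

    For every drug, the KS statistic of the query pathways' positions
    within that drug's pathway ranking (universe size = P pathways);
    empirical p from seeded random same-size pathway sets (the null is
    identical for every drug since positions of a random set are uniform).
    """
    query_ids = sorted(set(query))
    if not query_ids:
        raise ValueError("query pathway set is empty")
    if not peps:
        raise ValueError("no PEPs supplied")
    first = next(iter(peps.values()))
    n_pathways = first.n_pathways
    for drug, pep in peps.items():
        missing = set(query_ids) - set(pep.table.index)
        if missing:
            raise ValueError(
                f"query pathways {sorted(missing)} absent from PEP of {drug!r}"
            )
        if pep.n_pathways != n_pathways:
            raise ValueError("PEPs cover different numbers of pathways")
    if len(query_ids) >= n_pathways:
        raise ValueError("query covers every pathway; enrichment is degenerate")

    drugs = sorted(peps)
    es = np.array(
        [ks_statistic(peps[d].positions_of(query_ids), n_pathways) for d in drugs]
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null_es = ks_statistic_batch(
            sample_position_sets(rng, n_perm, len(query_ids), n_pathways),
            n_pathways,
        )
        pvals = empirical_pvalues(es, null_es)
    else:
        pvals = np.full(len(drugs), np.nan)
    table = pd.DataFrame({"drug_id": drugs, "es": es, "p": pvals})
    table = table.sort_values(
        by=["p", "es", "drug_id"],
        key=lambda col: -col.abs() if col.name == "es" else col,
        kind="stable",
    ).reset_index(drop=True)
    return DrugList(gene_id, table)


# ---------------------------------------------------------------------------
# PEP store (directory of per-drug TSVs + index)
# ---------------------------------------------------------------------------

def write_pep_store(
    peps: Mapping[str, PathwayExpressionProfile], directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for drug in sorted(peps):
        fname = f"{drug}.pep.tsv"
        out = peps[drug].table.copy()
        out.index.name = "pathway_id"
        out.to_csv(directory / fname, sep="\t", float_format="%.10g")
        index_rows.append({"drug_id": drug, "file": fname})
    pd.DataFrame(index_rows).to_csv(directory / "index.tsv", sep="\t", index=False)


def read_pep_store(directory: str | Path) -> dict[str, PathwayExpressionProfile]:
    directory = Path(directory)
    index = pd.read_csv(directory / "index.tsv", sep="\t")
    peps: dict[str, PathwayExpressionProfile] = {}
    for _, row in index.iterrows():
        table = pd.read_csv(directory / row["file"], sep="\t", index_col="pathway_id")
        peps[row["drug_id"]] = PathwayExpressionProfile(row["drug_id"], table)
    return peps
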