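"""Candidate-selection protocol: significance filter, cross-gene
co-occurrence merge, and FDA/CNS filtering.

Each query risk gene yields one candidate drug list; a compound's evidence
is the number of distinct per-gene lists it appears in.  Compounds present
in at least ``cutoff`` lists are kept (count >= cutoff: the screen's
survivors explicitly include compounds at exactly the cutoff), then
restricted to FDA-approved, CNS-active drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .gep2pep import DrugList

log = logging.getLogger(__name__)

__all__ = [
    "MergedCandidates",
    "filter_significant",
    "cooccurrence_merge",
    "filter_fda_cns",
    "cooccurrence_histogram",
    "venn_text",
]


@dataclass
class MergedCandidates:
    """Per-drug list co-occurrence counts and the surviving drug set.

    ``kept`` is ordered by descending count, then best (minimum) p across
    the contributing lists, then drug id — a deterministic stand-in for a
    ranking the source protocol leaves unspecified.
    """

    counts: dict[str, int]
    min_p: dict[str, float]
    kept: list[str]
    cutoff: int

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("co-occurrence counts must be >= 1")
        if not set(self.kept) <= set(self.counts):
            raise ValueError("kept drugs must appear in counts")

    def histogram(self) -> dict[int, int]:
        """Map count-of-lists -> number of drugs with that count."""
        hist: dict[int, int] = {}
        for c in self.counts.values():
            hist[c] = hist.get(c, 0) + 1
        return dict(sorted(hist.items(), reverse=True))

    def to_frame(self) -> pd.DataFrame:
        drugs = sorted(
            self.counts,
            key=lambda d: (-self.counts[d], self.min_p.get(d, 1.0), d),
        )
        return pd.DataFrame(
            {
                "drug_id": drugs,
                "n_lists": [self.counts[d] for d in drugs],
                "min_p": [self.min_p.get(d, float("nan")) for d in drugs],
                "kept_flag": [d in set(self.kept) for d in drugs],
            }
        )


def filter_significant(drug_list: DrugList, alpha: float = 1e-2) -> DrugList:
    """Retain entries with p strictly below ``alpha`` (order preserved)."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    table = drug_list.table
    if table["p"].isna().any():
        raise ValueError(
            f"drug list {drug_list.gene_id!r} has entries without p-values"
        )
    kept = table[table["p"] < alpha].reset_index(drop=True)
    return DrugList(drug_list.gene_id, kept)


def cooccurrence_merge(
    lists: Sequence[DrugList], cutoff: int = 4
) -> MergedCandidates:
    """Count, per drug, the number of distinct lists containing it.

    Drugs in at least ``cutoff`` lists form ``kept``; all counted drugs
    stay in ``counts`` for reporting.  Duplicates within one list count
    once, and the result is invariant to list order.
    """
    if not lists:
        raise ValueError("at least one drug list required")
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")
    counts: dict[str, int] = {}
    min_p: dict[str, float] = {}
    for dl in lists:
        seen = set(dl.drug_ids)
        for drug in seen:
            counts[drug] = counts.get(drug, 0) + 1
        for _, row in dl.table.iterrows():
            d, p = row["drug_id"], float(row["p"])
            if d not in min_p or p < min_p[d]:
                min_p[d] = p
    kept = sorted(
        (d for d, c in counts.items() if c >= cutoff),
        key=lambda d: (-counts[d], min_p.get(d, 1.0), d),
    )
    return MergedCandidates(counts, min_p, kept, cutoff)


def filter_fda_cns(
    candidates: MergedCandidates,
    meta: Mapping[str, Mapping[str, bool]] | pd.DataFrame,
) -> list[str]:
    """Kept drugs that are both FDA-approved and CNS-active, order preserved.

    ``meta`` maps drug id -> flags (``fda_approved``, ``cns_active``); a
    drug absent from the annotation counts as not approved.
    """
    def flag(drug: str, name: str) -> bool:
        if isinstance(meta, pd.DataFrame):
            if drug not in meta.index or name not in meta.columns:
                return False
            return bool(meta.loc[drug, name])
        entry = meta.get(drug)
        if entry is None:
            return False
        return bool(entry.get(name, False))

    return [
        d for d in candidates.kept
        if flag(d, "fda_approved") and flag(d, "cns_active")
    ]


def cooccurrence_histogram(lists: Sequence[DrugList]) -> dict[int, int]:
    """Count histogram {n_lists: n_drugs} without applying any cutoff."""
    return cooccurrence_merge(lists, cutoff=1).histogram()


def venn_text(lists: Sequence[DrugList]) -> str:
    """Venn-style text summary of drug membership across the lists.

    One line per non-empty list combination, largest combinations first,
    mirroring text-format Venn diagram exports.
    """
    names = [dl.gene_id or f"list{i+1}" for i, dl in enumerate(lists)]
    membership: dict[str, set[str]] = {}
    for name, dl in zip(names, lists):
        for drug in set(dl.drug_ids):
            membership.setdefault(drug, set()).add(name)
    regions: dict[tuple[str, ...], list[str]] = {}
    for drug, in_lists in membership.items():
        key = tuple(sorted(in_lists))
        regions.setdefault(key, []).append(drug)
    out = []
    for key in sorted(regions, key=lambda k: (-len(k), k)):
        drugs = sorted(regions[key])
        out.append(f"[{' & '.join(key)}] n={len(drugs)}: {', '.join(drugs)}")
    return "\n".join(out)
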