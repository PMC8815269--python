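"""Core domain types and readers/writers for gene sets, perturbagen rank
profiles, and pooled viability screens.

The in-memory containers here are shared by every downstream stage:

* :class:`GeneUniverse` — the ordered gene space of a perturbagen corpus
  (CMap-style platform gene list).  Its order is the canonical index used
  by every ranking.
* :class:`GeneSet` / :class:`GeneSetCollection` — flat GO/KEGG-style
  pathways, read from and written to GMT.
* :class:`RankedProfile` — one treatment instance's total ranking of the
  universe (rank 1 = most up-regulated gene).
* :class:`ViabilityMatrix` — a long-format pooled-barcode viability screen
  (PRISM-style) with treatment metadata (FDA approval, CNS activity) and
  cell-line annotations (mutations, expression).

Sign convention, fixed repo-wide: *higher sensitivity = greater viability
reduction* (more cell killing).  PRISM-style log-fold-change files store the
opposite sign; pass ``negate=True`` to :func:`read_viability_table` to
convert at ingest.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GeneUniverse",
    "GeneSet",
    "GeneSetCollection",
    "GeneSetSource",
    "RankedProfile",
    "ViabilityMatrix",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_rank_matrix",
    "write_rank_matrix",
    "pathways_of_gene",
    "read_viability_table",
    "write_viability_table",
    "read_mutation_table",
    "read_expression_matrix",
]


class GmtParseError(ValueError):
    """Raised for a malformed GMT line (names the 1-based line number)."""


class GeneSetSource(str, Enum):
    GO = "GO"
    KEGG = "KEGG"
    OTHER = "other"


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered, unique gene identifiers; the canonical ranking index."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("gene universe must be non-empty")
        index = {g: i for i, g in enumerate(self.genes)}
        if len(index) != len(self.genes):
            raise ValueError("gene universe contains duplicate identifiers")
        object.__setattr__(self, "_index", index)

    @property
    def n(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index  # type: ignore[attr-defined]

    def index_of(self, gene: str) -> int:
        return self._index[gene]  # type: ignore[attr-defined]

    def indices_of(self, genes: Iterable[str]) -> np.ndarray:
        idx = self._index  # type: ignore[attr-defined]
        return np.fromiter((idx[g] for g in genes), dtype=np.intp)


@dataclass(frozen=True)
class GeneSet:
    """A flat named pathway (no ontology structure)."""

    id: str
    name: str
    source: GeneSetSource
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


def _infer_source(set_id: str) -> GeneSetSource:
    upper = set_id.upper()
    if upper.startswith("GO"):
        return GeneSetSource.GO
    if upper.startswith("KEGG") or upper.startswith("HSA"):
        return GeneSetSource.KEGG
    return GeneSetSource.OTHER


@dataclass
class GeneSetCollection:
    """A keyed collection of gene sets, optionally bound to a universe.

    Binding intersects every set with the universe (platform-limited
    corpora miss genes); genes dropped this way are logged, and sets left
    empty are removed with a warning.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)
    universe: GeneUniverse | None = None

    def __post_init__(self) -> None:
        for key, gs in self.sets.items():
            if key != gs.id:
                raise ValueError(f"collection key {key!r} != set id {gs.id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    @property
    def ids(self) -> list[str]:
        return list(self.sets)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.id in self.sets:
            raise ValueError(f"duplicate gene set id {gene_set.id!r}")
        self.sets[gene_set.id] = gene_set

    def bind(self, universe: GeneUniverse) -> "GeneSetCollection":
        bound: dict[str, GeneSet] = {}
        n_dropped_genes = 0
        for set_id, gs in self.sets.items():
            kept = frozenset(g for g in gs.members if g in universe)
            n_dropped_genes += len(gs.members) - len(kept)
            if not kept:
                log.warning(
                    "gene set %s has no members in the universe; dropped", set_id
                )
                continue
            bound[set_id] = GeneSet(gs.id, gs.name, gs.source, kept)
        if n_dropped_genes:
            log.warning(
                "dropped %d out-of-universe gene memberships while binding",
                n_dropped_genes,
            )
        return GeneSetCollection(bound, universe)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated; id, description, members...).

    Duplicate members within a line are de-duplicated with a warning;
    a line with fewer than 3 fields or a repeated set id is an error.
    """
    collection = GeneSetCollection()
    n_lines = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line:
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, name = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    log.warning(
                        "%s: line %d: duplicate member %r in set %s; keeping once",
                        path, lineno, g, set_id,
                    )
                    continue
                seen.add(g)
                members.append(g)
            if set_id in collection:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            collection.add(
                GeneSet(set_id, name, _infer_source(set_id), frozenset(members))
            )
    if n_lines == 0:
        log.warning("%s: empty GMT file, returning empty collection", path)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for set_id in sorted(collection.sets):
            gs = collection.sets[set_id]
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.id}\t{gs.name}\t{members}\n")


def pathways_of_gene(collection: GeneSetCollection, gene: str) -> set[str]:
    """Ids of every set in the collection containing ``gene`` (may be empty)."""
    return {set_id for set_id, gs in collection.sets.items() if gene in gs.members}


@dataclass(frozen=True)
class RankedProfile:
    """One treatment instance's total gene ranking (1 = most up-regulated).

    ``ranks[i]`` is the rank of ``universe.genes[i]``; the vector is a
    permutation of ``1..n`` (validated on construction).
    """

    drug_id: str
    replicate_id: str
    universe: GeneUniverse
    ranks: np.ndarray

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks, dtype=np.int64)
        object.__setattr__(self, "ranks", ranks)
        n = self.universe.n
        if ranks.shape != (n,):
            raise ValueError(
                f"profile {self.instance_id}: rank vector length {ranks.shape} "
                f"does not match universe size {n}"
            )
        counts = np.bincount(ranks, minlength=n + 1)
        if counts[0] != 0 or not np.all(counts[1:] == 1):
            raise ValueError(
                f"profile {self.instance_id}: ranks are not a permutation of 1..{n}"
            )

    @property
    def instance_id(self) -> str:
        return f"{self.drug_id}::{self.replicate_id}"

    @property
    def n(self) -> int:
        return self.universe.n

    def positions_of(self, genes: Iterable[str]) -> np.ndarray:
        """Sorted rank positions of the given genes within this profile."""
        idx = self.universe.indices_of(genes)
        return np.sort(self.ranks[idx])

    @classmethod
    def from_scores(
        cls,
        drug_id: str,
        replicate_id: str,
        universe: GeneUniverse,
        scores: np.ndarray,
    ) -> "RankedProfile":
        """Convert real-valued scores to ranks (highest score -> rank 1).

        Ties take average ranks, then are resolved deterministically by
        universe (gene identifier) order so the result is a permutation.
        """
        scores = np.asarray(scores, dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"profile {drug_id}::{replicate_id}: non-finite score")
        # stable sort on descending score == average-tie then universe order
        order = np.argsort(-scores, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        return cls(drug_id, replicate_id, universe, ranks)


def _split_instance(column: str) -> tuple[str, str]:
    if "::" in column:
        drug, rep = column.split("::", 1)
    else:
        drug, rep = column, "0"
    return drug, rep


def read_rank_matrix(
    path: str | Path, mode: str = "ranks"
) -> list[RankedProfile]:
    """Read a genes x treatment-instances TSV into ranked profiles.

    Rows are genes (first column = gene id), columns are treatment
    instances named ``drugid::replicateid``.  ``mode="ranks"`` validates
    each column as a permutation of ``1..n``; ``mode="scores"`` converts
    scores to ranks (highest score -> rank 1, average-tie then gene-order
    tie-break).
    """
    if mode not in {"ranks", "scores"}:
        raise ValueError(f"mode must be 'ranks' or 'scores', got {mode!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty rank matrix")
    universe = GeneUniverse(tuple(str(g) for g in df.index))
    profiles: list[RankedProfile] = []
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy()
        if np.isnan(values).any():
            raise ValueError(f"{path}: column {col!r} contains non-numeric cells")
        drug, rep = _split_instance(str(col))
        if mode == "ranks":
            ranks = values.astype(np.int64)
            if not np.array_equal(np.sort(ranks), np.arange(1, len(ranks) + 1)):
                raise ValueError(
                    f"{path}: column {col!r} is not a permutation of 1..{len(ranks)}"
                )
            profiles.append(RankedProfile(drug, rep, universe, ranks))
        else:
            profiles.append(RankedProfile.from_scores(drug, rep, universe, values))
    return profiles


def write_rank_matrix(profiles: Sequence[RankedProfile], path: str | Path) -> None:
    if not profiles:
        raise ValueError("no profiles to write")
    universe = profiles[0].universe
    data = {p.instance_id: p.ranks for p in profiles}
    for p in profiles:
        if p.universe.genes != universe.genes:
            raise ValueError("profiles span different universes")
    df = pd.DataFrame(data, index=list(universe.genes))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Viability screens
# ---------------------------------------------------------------------------

_VIABILITY_COLUMNS = ["treatment_id", "name", "cell_line", "value", "screen_dataset_id"]


@dataclass
class ViabilityMatrix:
    """Long-format pooled viability screen with annotations.

    ``entries`` columns: treatment_id, cell_line, sensitivity,
    screen_dataset_id — at most one row per (treatment, cell line, screen
    dataset).  Missing cells are simply absent and excluded pairwise from
    statistics.  Repeated (treatment, cell line) under distinct screen
    datasets are retained as separate series (replicate screens).
    """

    entries: pd.DataFrame
    treatment_meta: pd.DataFrame  # index treatment_id: name, fda_approved, cns_active
    mutations: pd.DataFrame | None = None  # cell_line x gene, boolean
    expression: pd.DataFrame | None = None  # gene x cell_line, float

    def __post_init__(self) -> None:
        required = {"treatment_id", "cell_line", "sensitivity", "screen_dataset_id"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"viability entries missing columns: {sorted(missing)}")
        if self.entries.empty:
            raise ValueError("viability matrix has no entries")
        key = self.entries[["treatment_id", "cell_line", "screen_dataset_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate viability entry for {tuple(dup)}")
        if not np.isfinite(self.entries["sensitivity"]).all():
            raise ValueError("viability sensitivities must be finite")

    @property
    def treatments(self) -> list[str]:
        return sorted(self.entries["treatment_id"].unique())

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.entries["cell_line"].unique())

    def series_keys(self) -> list[tuple[str, str]]:
        """All (treatment_id, screen_dataset_id) series, sorted."""
        key = self.entries[["treatment_id", "screen_dataset_id"]].drop_duplicates()
        return sorted(map(tuple, key.to_numpy()))

    def series(self, treatment_id: str, screen_dataset_id: str | None = None) -> pd.Series:
        """Sensitivity values for one treatment, indexed by cell line.

        With ``screen_dataset_id=None`` all of the treatment's datasets are
        pooled (a warning is logged if there are several).
        """
        sub = self.entries[self.entries["treatment_id"] == treatment_id]
        if sub.empty:
            raise KeyError(f"unknown treatment {treatment_id!r}")
        if screen_dataset_id is not None:
            sub = sub[sub["screen_dataset_id"] == screen_dataset_id]
            if sub.empty:
                raise KeyError(
                    f"treatment {treatment_id!r} has no dataset {screen_dataset_id!r}"
                )
            return sub.set_index("cell_line")["sensitivity"].sort_index()
        n_datasets = sub["screen_dataset_id"].nunique()
        if n_datasets > 1:
            log.warning(
                "treatment %s has %d screen datasets; pooling values",
                treatment_id, n_datasets,
            )
        return sub.set_index(["screen_dataset_id", "cell_line"])[
            "sensitivity"
        ].sort_index().droplevel(0)

    def wide(self) -> pd.DataFrame:
        """(treatment, dataset) x cell-line matrix with NaN for missing cells."""
        return self.entries.pivot_table(
            index=["treatment_id", "screen_dataset_id"],
            columns="cell_line",
            values="sensitivity",
            aggfunc="first",
        )

    def meta_flag(self, treatment_id: str, flag: str) -> bool:
        if treatment_id not in self.treatment_meta.index:
            return False
        return bool(self.treatment_meta.loc[treatment_id, flag])


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    return series.astype(str).str.strip().str.lower().map(mapping).fillna(False)


def read_viability_table(
    path: str | Path,
    negate: bool = False,
    mutations: str | Path | None = None,
    expression: str | Path | None = None,
) -> ViabilityMatrix:
    """Read a long-format viability CSV (PRISM-style).

    Mandatory columns: treatment_id, name, cell_line, value,
    screen_dataset_id; optional: fda_approved, cns_active.  Non-finite
    values are dropped with a warning; a duplicate (treatment, cell line,
    screen dataset) triple or an empty table is an error.  ``negate=True``
    flips the sign at ingest (viability log-fold-change -> sensitivity).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty viability table")
    missing = set(_VIABILITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = ~np.isfinite(values)
    if bad.any():
        log.warning("%s: dropping %d rows with non-finite values", path, int(bad.sum()))
        df = df[~bad].copy()
        values = values[~bad]
    if df.empty:
        raise ValueError(f"{path}: no finite viability values")
    entries = pd.DataFrame(
        {
            "treatment_id": df["treatment_id"].astype(str),
            "cell_line": df["cell_line"].astype(str),
            "sensitivity": (-values if negate else values).astype(float).to_numpy(),
            "screen_dataset_id": df["screen_dataset_id"].astype(str),
        }
    ).reset_index(drop=True)

    meta_cols = {"name": df["name"].astype(str).to_numpy()}
    for flag in ("fda_approved", "cns_active"):
        meta_cols[flag] = (
            _coerce_bool(df[flag]).to_numpy() if flag in df.columns else False
        )
    meta = pd.DataFrame(meta_cols, index=df["treatment_id"].astype(str))
    meta = meta[~meta.index.duplicated(keep="first")]
    meta.index.name = "treatment_id"

    mut_df = read_mutation_table(mutations) if mutations is not None else None
    expr_df = read_expression_matrix(expression) if expression is not None else None
    return ViabilityMatrix(entries, meta, mut_df, expr_df)


def write_viability_table(vm: ViabilityMatrix, path: str | Path) -> None:
    df = vm.entries.copy()
    meta = vm.treatment_meta
    df["name"] = df["treatment_id"].map(meta["name"]).fillna(df["treatment_id"])
    df["fda_approved"] = df["treatment_id"].map(meta["fda_approved"]).fillna(False)
    df["cns_active"] = df["treatment_id"].map(meta["cns_active"]).fillna(False)
    df = df.rename(columns={"sensitivity": "value"})
    df[_VIABILITY_COLUMNS + ["fda_approved", "cns_active"]].to_csv(path, index=False)


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a (cell_line, gene, is_mutated) CSV into a cell-line x gene table."""
    df = pd.read_csv(path)
    required = {"cell_line", "gene", "is_mutated"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: mutation table needs columns {sorted(required)}")
    df["is_mutated"] = _coerce_bool(df["is_mutated"])
    wide = df.pivot_table(
        index="cell_line", columns="gene", values="is_mutated", aggfunc="first"
    ).fillna(False).astype(bool)
    return wide


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x cell-line expression CSV (first column = gene)."""
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    return df.astype(float)
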