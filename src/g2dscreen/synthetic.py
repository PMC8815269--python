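"""Seeded synthetic corpora with planted ground truth.

Two generators emulate the external resources the screen consumes, at a
scale where every pipeline stage runs in seconds:

* :func:`gen_corpus` — a CMap-like perturbagen corpus (gene-level rank
  profiles with replicate instances) plus a GO/KEGG-style pathway
  collection and a GWAS-style risk-gene list.  Risk genes fall into two
  annotation clusters whose members share their pathway sets, reflecting
  the convergence of trait-associated genes on a small number of shared
  processes; "active" drugs shift the scores of the genes in the pathway
  sets of 1-3 risk genes before ranking, so rank statistics see realistic
  competition against the Gaussian background.
* :func:`gen_viability` — a PRISM-like pooled viability screen over
  glioma-sized panels (default 140 treatment series on 42 cell lines),
  with planted potent drugs, a neutral reference treatment, replicate
  screen datasets (one deliberately discordant), mutation-linked
  sensitivity shifts, and expression markers separating sensitive from
  non-sensitive lines.

All draws come from one ``numpy`` generator per call, so identical seeds
give bit-identical outputs.  What the generators deliberately do not
model: transcriptome covariance, dose structure, batch effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geneset_io import (
    GeneSet,
    GeneSetCollection,
    GeneSetSource,
    GeneUniverse,
    RankedProfile,
    ViabilityMatrix,
    write_gmt,
    write_rank_matrix,
    write_viability_table,
)

__all__ = [
    "ActiveDrug",
    "CorpusTruth",
    "ScreenTruth",
    "gen_corpus",
    "gen_viability",
    "gen_study",
    "write_corpus",
    "write_screen",
]


@dataclass(frozen=True)
class ActiveDrug:
    """Planted perturbation: which pathways a drug shifts, and how."""

    pathways: tuple[str, ...]
    direction: int  # +1 up-regulates members, -1 down-regulates
    delta: float
    risk_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.delta < 0:
            raise ValueError("effect size delta must be >= 0")


@dataclass
class CorpusTruth:
    """Ground truth of a generated perturbagen corpus."""

    active_drugs: dict[str, ActiveDrug]
    risk_genes: dict[str, tuple[str, ...]]  # gene -> annotated pathway ids

    @property
    def annotated_risk_genes(self) -> list[str]:
        return sorted(g for g, pws in self.risk_genes.items() if pws)

    def to_json(self) -> str:
        payload = {
            "active_drugs": {d: asdict(a) for d, a in sorted(self.active_drugs.items())},
            "risk_genes": {g: list(p) for g, p in sorted(self.risk_genes.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class ScreenTruth:
    """Ground truth of a generated viability screen."""

    reference: str
    potent_drugs: dict[str, float]  # drug -> planted mean sensitivity shift
    mutation_effects: dict[tuple[str, str], float]  # (drug, gene) -> shift
    de_truth: dict[str, tuple[str, ...]]  # drug -> planted DE genes
    discordant: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "reference": self.reference,
            "potent_drugs": dict(sorted(self.potent_drugs.items())),
            "mutation_effects": {
                f"{d}|{g}": s for (d, g), s in sorted(self.mutation_effects.items())
            },
            "de_truth": {d: list(g) for d, g in sorted(self.de_truth.items())},
            "discordant": sorted(self.discordant),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _pathway_id(i: int) -> str:
    return f"GO:{7000000 + i:07d}"


def gen_corpus(
    n_genes: int = 1000,
    n_pathways: int = 150,
    set_size: tuple[int, int] = (10, 50),
    n_drugs: int = 100,
    replicates: int = 3,
    n_risk_genes: int = 9,
    n_unannotated_risk_genes: int = 6,
    n_active_drugs: int = 10,
    delta: float = 2.0,
    seed: int = 0,
) -> tuple[GeneSetCollection, list[RankedProfile], CorpusTruth]:
    """Generate a pathway collection, ranked profiles, and planted truth.

    Pathway members are drawn without replacement from the non-risk genes;
    each annotated risk gene carries 2-6 pathways, shared within its
    annotation cluster (clusters sized ceil/floor of the 9 genes into two
    groups).  Each active drug perturbs the pathway sets of 1-3 risk genes
    by adding ``direction * delta`` to the standard-normal scores of every
    member gene before ranking.  The remaining
    ``n_unannotated_risk_genes`` risk genes belong to no pathway,
    emulating trait genes without usable process annotations.
    """
    lo, hi = set_size
    if not (0 < lo <= hi <= n_genes):
        raise ValueError(f"infeasible set sizes {set_size} for {n_genes} genes")
    if n_risk_genes < 2:
        raise ValueError("need at least 2 annotated risk genes")
    if n_active_drugs > n_drugs:
        raise ValueError("more active drugs than drugs")
    total_risk = n_risk_genes + n_unannotated_risk_genes
    if total_risk >= n_genes:
        raise ValueError("risk genes exceed the gene universe")
    rng = np.random.default_rng(seed)

    genes = tuple(f"g{i:04d}" for i in range(n_genes))
    universe = GeneUniverse(genes)
    background = np.arange(n_genes - total_risk)  # indices drawable as members
    risk_gene_ids = list(genes[n_genes - total_risk:])
    annotated = risk_gene_ids[:n_risk_genes]
    unannotated = risk_gene_ids[n_risk_genes:]

    pathway_ids = [_pathway_id(i) for i in range(n_pathways)]
    members: dict[str, set[str]] = {}
    for pw in pathway_ids:
        size = int(rng.integers(lo, hi + 1))
        picked = rng.choice(background, size=size, replace=False)
        members[pw] = {genes[i] for i in picked}

    # Two annotation clusters: genes in a cluster share one pathway set of
    # size 2..6, drawn from disjoint halves of the collection.
    n_a = (n_risk_genes + 1) // 2
    clusters = [annotated[:n_a], annotated[n_a:]]
    half = n_pathways // 2
    pools = [np.arange(half), np.arange(half, n_pathways)]
    risk_annotations: dict[str, tuple[str, ...]] = {g: () for g in unannotated}
    for cluster, pool in zip(clusters, pools):
        q = int(rng.integers(2, 7))
        chosen = sorted(_pathway_id(i) for i in rng.choice(pool, size=q, replace=False))
        for gene in cluster:
            risk_annotations[gene] = tuple(chosen)
            for pw in chosen:
                members[pw].add(gene)

    collection = GeneSetCollection()
    for pw in pathway_ids:
        collection.add(
            GeneSet(pw, f"synthetic process {pw}", GeneSetSource.GO,
                    frozenset(members[pw]))
        )
    collection = collection.bind(universe)

    drug_ids = [f"drug{i:03d}" for i in range(n_drugs)]
    active = sorted(rng.choice(n_drugs, size=n_active_drugs, replace=False))
    active_drugs: dict[str, ActiveDrug] = {}
    for i in active:
        k = int(rng.integers(1, 4))
        picked_genes = sorted(
            annotated[j] for j in rng.choice(n_risk_genes, size=k, replace=False)
        )
        perturbed = sorted({pw for g in picked_genes for pw in risk_annotations[g]})
        direction = int(rng.choice([-1, 1]))
        active_drugs[drug_ids[i]] = ActiveDrug(
            tuple(perturbed), direction, delta, tuple(picked_genes)
        )

    gene_index = {g: i for i, g in enumerate(genes)}
    profiles: list[RankedProfile] = []
    for drug in drug_ids:
        shift = np.zeros(n_genes)
        if drug in active_drugs:
            truth = active_drugs[drug]
            hit = sorted({gene_index[g] for pw in truth.pathways
                          for g in collection[pw].members})
            shift[hit] = truth.direction * truth.delta
        for rep in range(1, replicates + 1):
            scores = rng.normal(0.0, 1.0, size=n_genes) + shift
            profiles.append(
                RankedProfile.from_scores(drug, f"r{rep}", universe, scores)
            )

    truth = CorpusTruth(active_drugs, risk_annotations)
    return collection, profiles, truth


def gen_viability(
    n_treatments: int = 140,
    n_lines: int = 42,
    potent_fraction: float = 0.1,
    mu: float = 1.0,
    sigma: float = 0.5,
    mutation_genes: Sequence[str] = ("TP53", "PTEN"),
    seed: int = 0,
    treatment_ids: Sequence[str] | None = None,
    potent_ids: Sequence[str] | None = None,
    reference_id: str = "TMZ",
    n_extra_datasets: int = 16,
    n_discordant: int = 1,
    line_sd: float = 0.5,
    interaction_sd: float = 0.5,
    mutation_shift: float = 0.8,
    n_expression_genes: int = 60,
    n_de_genes: int = 5,
    de_shift: float = 3.0,
) -> tuple[ViabilityMatrix, ScreenTruth]:
    """Generate a pooled viability screen with planted potency.

    The sensitivity of drug *d* on line *c* in screen dataset *s* is::

        mu_d + gamma_c + eta_{d,c} + m(d, c) + eps_{d,c,s}

    with ``gamma_c ~ N(0, line_sd^2)`` a cell-line effect, ``eta`` a
    drug-by-line interaction shared between replicate datasets,
    ``m`` the planted mutation shift on mutated lines, and
    ``eps ~ N(0, sigma^2)`` per-dataset noise.  ``mu_d = mu`` for potent
    drugs and 0 otherwise; the reference treatment is always neutral.
    ``n_treatments`` counts series (reference included): replicate
    datasets of one drug are extra series, and one replicated background
    drug is planted discordant (its second dataset inverts the line
    effect) to exercise the concordance filter.
    """
    if not 0 <= potent_fraction <= 1:
        raise ValueError("potent fraction must lie in [0, 1]")
    if sigma <= 0 or mu < 0:
        raise ValueError("sigma must be > 0 and mu >= 0")
    rng = np.random.default_rng(seed)

    if treatment_ids is not None:
        drugs = [str(t) for t in treatment_ids if str(t) != reference_id]
    else:
        n_base = n_treatments - 1 - n_extra_datasets
        if n_base < 1:
            raise ValueError("n_treatments too small for the extra datasets")
        drugs = [f"trt{i:03d}" for i in range(n_base)]
    all_drugs = [reference_id] + drugs

    if potent_ids is not None:
        potent = [d for d in potent_ids if d in set(drugs)]
    else:
        n_potent = int(round(potent_fraction * len(drugs)))
        potent = sorted(
            np.array(drugs, dtype=object)[
                rng.choice(len(drugs), size=n_potent, replace=False)
            ].tolist()
        )
    mu_d = {d: (mu if d in set(potent) else 0.0) for d in all_drugs}
    mu_d[reference_id] = 0.0

    lines = [f"CL{i:03d}" for i in range(n_lines)]
    gamma = rng.normal(0.0, line_sd, size=n_lines)

    mutations = pd.DataFrame(
        {g: rng.random(n_lines) < p
         for g, p in zip(mutation_genes, np.linspace(0.45, 0.3, len(mutation_genes)))},
        index=lines,
    )
    mutation_effects: dict[tuple[str, str], float] = {}
    for drug, gene in zip(potent, mutation_genes):
        mutation_effects[(drug, gene)] = mutation_shift

    # replicate screen datasets for a few drugs; the first replicated
    # background drug is planted discordant
    n_extra = min(n_extra_datasets, len(drugs))
    replicated = sorted(
        np.array(drugs, dtype=object)[
            rng.choice(len(drugs), size=n_extra, replace=False)
        ].tolist()
    )
    background_replicated = [d for d in replicated if d not in set(potent)]
    discordant = background_replicated[:n_discordant]

    rows = []
    de_truth: dict[str, tuple[str, ...]] = {}
    sens_by_drug: dict[str, np.ndarray] = {}
    for drug in all_drugs:
        eta = rng.normal(0.0, interaction_sd, size=n_lines)
        m = np.zeros(n_lines)
        for (d, gene), shift in mutation_effects.items():
            if d == drug:
                m += shift * mutations[gene].to_numpy()
        base = mu_d[drug] + gamma + eta + m
        datasets = ["S1"] + (["S2"] if drug in set(replicated) else [])
        for ds in datasets:
            eps = rng.normal(0.0, sigma, size=n_lines)
            if ds == "S2" and drug in set(discordant):
                values = mu_d[drug] - (gamma + eta) + m + eps
            else:
                values = base + eps
            if ds == "S1":
                sens_by_drug[drug] = values  # observed primary-screen series
            for line, v in zip(lines, values):
                rows.append((drug, line, float(v), ds))

    entries = pd.DataFrame(
        rows, columns=["treatment_id", "cell_line", "sensitivity", "screen_dataset_id"]
    )

    fda = {d: bool(rng.random() < 0.7) for d in drugs}
    cns = {d: bool(rng.random() < 0.5) for d in drugs}
    for d in potent:
        fda[d] = True
        cns[d] = True
    fda[reference_id] = True
    cns[reference_id] = True
    meta = pd.DataFrame(
        {
            "name": [d.capitalize() for d in all_drugs],
            "fda_approved": [fda[d] for d in all_drugs],
            "cns_active": [cns[d] for d in all_drugs],
        },
        index=pd.Index(all_drugs, name="treatment_id"),
    )

    expr_genes = [f"EXPR{i:03d}" for i in range(n_expression_genes)] + ["EGFR"]
    expression = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(expr_genes), n_lines)),
        index=expr_genes,
        columns=lines,
    )
    # plant DE markers for up to two potent drugs: shifted in the lines
    # whose observed primary-screen sensitivity is above the panel median,
    # i.e. the split an analyst recovers from the screen itself
    for i, drug in enumerate(potent[:2]):
        gene_block = expr_genes[i * n_de_genes:(i + 1) * n_de_genes]
        sens = sens_by_drug[drug]
        sensitive = sens > np.median(sens)
        expression.loc[gene_block, np.array(lines)[sensitive]] += de_shift
        de_truth[drug] = tuple(gene_block)

    vm = ViabilityMatrix(entries, meta, mutations, expression)
    truth = ScreenTruth(
        reference=reference_id,
        potent_drugs={d: mu for d in potent},
        mutation_effects=mutation_effects,
        de_truth=de_truth,
        discordant=list(discordant),
    )
    return vm, truth


def gen_study(
    seed: int = 0, **corpus_kwargs
) -> tuple[GeneSetCollection, list[RankedProfile], CorpusTruth,
           ViabilityMatrix, ScreenTruth]:
    """One coherent study: a perturbagen corpus plus a viability screen
    over the same drugs (padded with extra screen-only treatments), where
    the corpus's planted active drugs are also the screen's potent drugs.
    """
    collection, profiles, corpus_truth = gen_corpus(seed=seed, **corpus_kwargs)
    corpus_drugs = sorted({p.drug_id for p in profiles})
    extra = [f"xtrt{i:03d}" for i in range(39)]
    vm, screen_truth = gen_viability(
        seed=seed + 1,
        treatment_ids=corpus_drugs + extra,
        potent_ids=sorted(corpus_truth.active_drugs),
    )
    return collection, profiles, corpus_truth, vm, screen_truth


def write_corpus(
    collection: GeneSetCollection,
    profiles: Sequence[RankedProfile],
    truth: CorpusTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write GMT + rank TSV + risk-gene list + truth JSON; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "collection": directory / "pathways.gmt",
        "profiles": directory / "profiles.tsv",
        "risk_genes": directory / "risk_genes.txt",
        "truth": directory / "corpus_truth.json",
    }
    write_gmt(collection, paths["collection"])
    write_rank_matrix(list(profiles), paths["profiles"])
    paths["risk_genes"].write_text(
        "".join(f"{g}\n" for g in sorted(truth.risk_genes))
    )
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths


def write_screen(
    vm: ViabilityMatrix, truth: ScreenTruth, directory: str | Path
) -> dict[str, Path]:
    """Write viability CSV + mutation CSV + expression CSV + truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "viability": directory / "viability.csv",
        "mutations": directory / "mutations.csv",
        "expression": directory / "expression.csv",
        "truth": directory / "screen_truth.json",
    }
    write_viability_table(vm, paths["viability"])
    if vm.mutations is not None:
        long = vm.mutations.stack().rename("is_mutated").reset_index()
        long.columns = ["cell_line", "gene", "is_mutated"]
        long.to_csv(paths["mutations"], index=False)
    if vm.expression is not None:
        out = vm.expression.copy()
        out.index.name = "gene"
        out.to_csv(paths["expression"], float_format="%.10g")
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
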