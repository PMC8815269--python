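"""End-to-end orchestration of the in-silico repurposing screen.

The flow: per risk gene, collect its pathway annotations; rank every
corpus drug by enrichment of that pathway set in its Pathway Expression
Profile; keep significant candidates (p < alpha_list); merge lists by
cross-gene co-occurrence (count >= cutoff); restrict to FDA-approved,
CNS-active drugs; back-map the surviving drug set to pathways (DSEA); and
validate against the pooled viability screen (concordance filter, mean-
sensitivity ranking, Mann-Whitney vs the reference treatment, full direct
screen).  Every stage's output is persisted and a manifest records the
configuration, seed, and output checksums so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dsea as dsea_mod
from . import screening, viability
from .geneset_io import (
    GeneSetCollection,
    RankedProfile,
    ViabilityMatrix,
    pathways_of_gene,
    read_gmt,
    read_rank_matrix,
    read_viability_table,
)
from .gep2pep import (
    DrugList,
    PathwayExpressionProfile,
    aggregate_replicates,
    profile_to_pep,
    rank_drugs_for_pathway_set,
)

log = logging.getLogger(__name__)

__all__ = ["ScreenConfig", "ScreenReport", "run_screen", "run_screen_objects",
           "build_drug_peps"]

_FLOAT_FMT = "%.10g"


@dataclass
class ScreenConfig:
    """File paths and parameters of a full screen run."""

    collection: str
    profiles: str
    risk_genes: str
    viability: str
    mutations: str | None = None
    expression: str | None = None
    out_dir: str = "screen_out"
    reference: str = "TMZ"
    alpha_list: float = 1e-2
    cutoff: int = 4
    alpha_screen: float = 1e-3
    n_perm: int = 999
    seed: int = 0
    r_min: float = 0.3

    def __post_init__(self) -> None:
        for name in ("alpha_list", "alpha_screen"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.cutoff < 1:
            raise ValueError("cutoff must be >= 1")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ScreenConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ScreenReport:
    """Everything the pipeline computed, stage by stage."""

    per_gene_lists: dict[str, DrugList]
    skipped_genes: list[str]
    merged: screening.MergedCandidates
    candidates: list[str]                       # after the FDA/CNS filter
    dsea_table: pd.DataFrame | None
    concordance: viability.ConcordanceReport
    ranking: list[viability.TreatmentSummary]
    candidate_tests: pd.DataFrame
    screen: viability.DirectScreenReport


def _gene_seed(seed: int, tag: str) -> int:
    """Stable per-stage child seed (independent of iteration order)."""
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_drug_peps(
    profiles: Sequence[RankedProfile],
    collection: GeneSetCollection,
    n_perm: int = 0,
    seed: int = 0,
) -> dict[str, PathwayExpressionProfile]:
    """Per-instance PEPs aggregated to one profile per drug (mean rank)."""
    by_drug: dict[str, list[PathwayExpressionProfile]] = {}
    for prof in profiles:
        pep = profile_to_pep(
            prof, collection, n_perm=n_perm,
            seed=_gene_seed(seed, f"pep:{prof.instance_id}"),
        )
        by_drug.setdefault(prof.drug_id, []).append(pep)
    return {drug: aggregate_replicates(reps) for drug, reps in sorted(by_drug.items())}


def run_screen_objects(
    collection: GeneSetCollection,
    profiles: Sequence[RankedProfile],
    vm: ViabilityMatrix,
    risk_genes: Sequence[str],
    reference: str = "TMZ",
    alpha_list: float = 1e-2,
    cutoff: int = 4,
    alpha_screen: float = 1e-3,
    n_perm: int = 999,
    seed: int = 0,
    r_min: float = 0.3,
) -> ScreenReport:
    """Run the full screen on in-memory objects (see module docstring)."""
    if not profiles:
        raise ValueError("no perturbagen profiles supplied")
    universe = profiles[0].universe
    bound = collection if (
        collection.universe is not None
        and collection.universe.genes == universe.genes
    ) else collection.bind(universe)

    if n_perm > 0 and 1.0 / (n_perm + 1) >= alpha_list:
        log.warning(
            "n_perm=%d cannot produce p-values below alpha_list=%g "
            "(minimum attainable is %g); no candidate will survive",
            n_perm, alpha_list, 1.0 / (n_perm + 1),
        )

    peps = build_drug_peps(profiles, bound, n_perm=0, seed=seed)

    per_gene: dict[str, DrugList] = {}
    skipped: list[str] = []
    for gene in sorted(set(risk_genes)):
        query = pathways_of_gene(bound, gene)
        if not query:
            skipped.append(gene)
            log.info("risk gene %s has no pathway annotation; skipped", gene)
            continue
        dl = rank_drugs_for_pathway_set(
            peps, query, n_perm=n_perm,
            seed=_gene_seed(seed, f"g2d:{gene}"), gene_id=gene,
        )
        per_gene[gene] = screening.filter_significant(dl, alpha_list)

    if not per_gene:
        raise ValueError("no risk gene carries a pathway annotation")
    merged = screening.cooccurrence_merge(list(per_gene.values()), cutoff)
    candidates = screening.filter_fda_cns(merged, vm.treatment_meta)

    dsea_out = None
    dsea_set = [d for d in candidates if d in peps]
    if dsea_set and len(dsea_set) < len(peps):
        dsea_out = dsea_mod.dsea_table(
            peps, dsea_set, n_perm=n_perm, seed=_gene_seed(seed, "dsea")
        )

    concordance = viability.replicate_concordance_filter(vm, r_min=r_min)
    screened_treatments = {t for t, _ in vm.series_keys()}
    usable = [
        d for d in candidates
        if d in screened_treatments and d not in set(concordance.excluded)
    ]
    ranking = viability.mean_sensitivity_ranking(vm, usable + [reference])
    test_rows = []
    for drug in usable:
        u, p = viability.mannwhitney_vs_reference(vm, drug, reference, "greater")
        test_rows.append({"treatment_id": drug, "u_stat": u, "p_vs_ref": p})
    candidate_tests = pd.DataFrame(
        test_rows, columns=["treatment_id", "u_stat", "p_vs_ref"]
    ).sort_values("p_vs_ref").reset_index(drop=True) if test_rows else pd.DataFrame(
        columns=["treatment_id", "u_stat", "p_vs_ref"]
    )

    screen = viability.direct_screen(vm, reference, alpha=alpha_screen)

    return ScreenReport(
        per_gene_lists=per_gene,
        skipped_genes=skipped,
        merged=merged,
        candidates=candidates,
        dsea_table=dsea_out,
        concordance=concordance,
        ranking=ranking,
        candidate_tests=candidate_tests,
        screen=screen,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _ranking_frame(ranking: list[viability.TreatmentSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "treatment_id": s.treatment_id,
                "screen_dataset_id": s.screen_dataset_id,
                "n_lines": s.n_lines,
                "mean": s.mean,
                "sd": s.sd,
                "ci95_lo": s.ci95[0],
                "ci95_hi": s.ci95[1],
            }
            for s in ranking
        ]
    )


def persist_report(report: ScreenReport, config: ScreenConfig) -> Path:
    """Write every stage output plus a checksum manifest; returns out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    gene_rows = []
    for gene, dl in sorted(report.per_gene_lists.items()):
        sub = dl.table.copy()
        sub.insert(0, "gene_id", gene)
        gene_rows.append(sub)
    per_gene = (
        pd.concat(gene_rows, ignore_index=True)
        if gene_rows
        else pd.DataFrame(columns=["gene_id", "drug_id", "es", "p"])
    )
    path = out / "gene_drug_lists.tsv"
    per_gene.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written.append(path)

    path = out / "merged_candidates.tsv"
    merged_frame = report.merged.to_frame()
    merged_frame["approved_cns_flag"] = merged_frame["drug_id"].isin(
        set(report.candidates)
    )
    merged_frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written.append(path)

    path = out / "venn_summary.txt"
    path.write_text(
        screening.venn_text(list(report.per_gene_lists.values())) + "\n"
    )
    written.append(path)

    path = out / "candidates.txt"
    path.write_text("".join(f"{d}\n" for d in report.candidates))
    written.append(path)

    if report.dsea_table is not None:
        path = out / "dsea.tsv"
        report.dsea_table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(path)

    path = out / "concordance.tsv"
    report.concordance.details.to_csv(path, sep="\t", index=False,
                                      float_format=_FLOAT_FMT)
    written.append(path)

    path = out / "candidate_ranking.tsv"
    _ranking_frame(report.ranking).to_csv(path, sep="\t", index=False,
                                          float_format=_FLOAT_FMT)
    written.append(path)

    path = out / "candidate_tests.tsv"
    report.candidate_tests.to_csv(path, sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
    written.append(path)

    path = out / "direct_screen.tsv"
    report.screen.to_frame().to_csv(path, sep="\t", index=False,
                                    float_format=_FLOAT_FMT)
    written.append(path)

    summary = {
        "n_gene_lists": len(report.per_gene_lists),
        "skipped_genes": report.skipped_genes,
        "cooccurrence_histogram": report.merged.histogram(),
        "n_kept": len(report.merged.kept),
        "n_candidates": len(report.candidates),
        "candidates": report.candidates,
        "excluded_discordant": report.concordance.excluded,
        "direct_screen": {
            "n_treatments": report.screen.n_treatments,
            "n_higher_mean": report.screen.n_higher_mean,
            "frac_higher": report.screen.frac_higher,
            "n_significant": report.screen.n_significant,
            "frac_significant": report.screen.frac_significant,
            "alpha": report.screen.alpha,
        },
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    written.append(path)

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return out


def run_screen(config: ScreenConfig) -> ScreenReport:
    """File-based entry point: pre-flight check, run, persist, manifest."""
    required = {
        "collection": config.collection,
        "profiles": config.profiles,
        "risk_genes": config.risk_genes,
        "viability": config.viability,
    }
    optional = {"mutations": config.mutations, "expression": config.expression}
    missing = [name for name, p in required.items() if not p or not Path(p).exists()]
    missing += [
        name for name, p in optional.items() if p is not None and not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"missing input file(s) before any stage ran: {sorted(missing)}"
        )

    collection = read_gmt(config.collection)
    profiles = read_rank_matrix(config.profiles, mode="ranks")
    risk_genes = [
        line.strip()
        for line in Path(config.risk_genes).read_text().splitlines()
        if line.strip()
    ]
    vm = read_viability_table(
        config.viability, mutations=config.mutations, expression=config.expression
    )
    report = run_screen_objects(
        collection, profiles, vm, risk_genes,
        reference=config.reference,
        alpha_list=config.alpha_list,
        cutoff=config.cutoff,
        alpha_screen=config.alpha_screen,
        n_perm=config.n_perm,
        seed=config.seed,
        r_min=config.r_min,
    )
    persist_report(report, config)
    return report
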