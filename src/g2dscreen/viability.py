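"""Pooled viability-screen validation statistics.

Covers the validation arm of the screen: barcode-abundance sensitivity,
mean-sensitivity ranking against a reference treatment (e.g. the standard-
of-care chemotherapy), Mann-Whitney comparisons, replicate-concordance
exclusion, the direct screening protocol over a whole treatment panel,
mutation association, and sensitive-vs-non-sensitive differential
expression with heatmap ordering.

Sensitivity is stored so that *higher = more cell killing*; statistics are
pairwise-complete over available cell lines (pooled screens are incomplete
by design).  No multiple-testing correction is applied by default — raw
thresholds govern candidate selection — but a Benjamini-Hochberg adjust
helper is provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .geneset_io import ViabilityMatrix

log = logging.getLogger(__name__)

__all__ = [
    "TreatmentSummary",
    "DirectScreenReport",
    "ConcordanceReport",
    "sensitivity_from_counts",
    "mean_sensitivity_ranking",
    "mann_whitney",
    "mannwhitney_vs_reference",
    "replicate_concordance_filter",
    "direct_screen",
    "mutation_association",
    "de_genes",
    "drug_correlation_matrices",
    "adjust_bh",
]


@dataclass(frozen=True)
class TreatmentSummary:
    """Per-treatment sensitivity summary (optionally vs a reference)."""

    treatment_id: str
    screen_dataset_id: str
    n_lines: int
    mean: float
    sd: float
    ci95: tuple[float, float]
    u_stat: float | None = None
    p_vs_ref: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.mean <= hi):
            raise ValueError("confidence interval does not contain the mean")
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")


@dataclass
class DirectScreenReport:
    """Panel-wide comparison of every treatment against the reference."""

    reference: str
    n_treatments: int          # series in the panel, reference included
    n_higher_mean: int
    frac_higher: float
    n_significant: int         # higher mean AND p < alpha vs reference
    frac_significant: float
    alpha: float
    summaries: list[TreatmentSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.n_significant <= self.n_higher_mean <= self.n_treatments:
            raise ValueError("inconsistent direct-screen counts")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            rows.append(
                {
                    "treatment_id": s.treatment_id,
                    "screen_dataset_id": s.screen_dataset_id,
                    "n_lines": s.n_lines,
                    "mean": s.mean,
                    "sd": s.sd,
                    "ci95_lo": s.ci95[0],
                    "ci95_hi": s.ci95[1],
                    "u_stat": s.u_stat,
                    "p_vs_ref": s.p_vs_ref,
                }
            )
        return pd.DataFrame(rows)


def sensitivity_from_counts(
    treatment_abundance: float,
    control_abundance: float,
    pseudocount: float = 0.5,
) -> float:
    """Barcode-abundance sensitivity: ``-log2((t + pc) / (c + pc))``.

    Depleted barcodes under treatment (killing) give positive values.
    """
    if treatment_abundance < 0 or control_abundance < 0:
        raise ValueError("abundances must be non-negative")
    if pseudocount <= 0 and (treatment_abundance == 0 or control_abundance == 0):
        raise ValueError("zero abundance requires a positive pseudocount")
    return float(
        -math.log2(
            (treatment_abundance + pseudocount) / (control_abundance + pseudocount)
        )
    )


def _summary(
    treatment_id: str, dataset: str, values: np.ndarray,
    u: float | None = None, p: float | None = None,
) -> TreatmentSummary:
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    else:
        half = 0.0
    return TreatmentSummary(
        treatment_id, dataset, n, mean, sd, (mean - half, mean + half), u, p
    )


def mean_sensitivity_ranking(
    vm: ViabilityMatrix, treatments: Iterable[str] | None = None
) -> list[TreatmentSummary]:
    """Per-series summaries sorted by descending mean sensitivity.

    95% CI is the two-sided t-interval ``mean +/- t(0.975, n-1) sd/sqrt(n)``.
    Series with fewer than 2 values are excluded with a warning.
    """
    wanted = None if treatments is None else set(treatments)
    out: list[TreatmentSummary] = []
    for treatment_id, dataset in vm.series_keys():
        if wanted is not None and treatment_id not in wanted:
            continue
        values = vm.series(treatment_id, dataset).to_numpy()
        if values.size < 2:
            log.warning(
                "treatment %s (%s) has %d value(s); excluded from ranking",
                treatment_id, dataset, values.size,
            )
            continue
        out.append(_summary(treatment_id, dataset, values))
    out.sort(key=lambda s: (-s.mean, s.treatment_id, s.screen_dataset_id))
    return out


def mann_whitney(
    x: np.ndarray, y: np.ndarray, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Mann-Whitney U of x vs y.

    Exact null enumeration when both samples have n <= 8 and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both series must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and x.size <= 8 and y.size <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_vs_reference(
    vm: ViabilityMatrix,
    treatment: str,
    reference: str,
    alternative: str = "greater",
    screen_dataset_id: str | None = None,
) -> tuple[float, float]:
    """Unpaired Mann-Whitney of a treatment's sensitivities vs the reference."""
    x = vm.series(treatment, screen_dataset_id).to_numpy()
    y = vm.series(reference).to_numpy()
    return mann_whitney(x, y, alternative)


@dataclass
class ConcordanceReport:
    excluded: list[str]
    needs_review: list[str]
    details: pd.DataFrame  # treatment_id, dataset_a, dataset_b, n_shared, r


def replicate_concordance_filter(
    vm: ViabilityMatrix, r_min: float = 0.3
) -> ConcordanceReport:
    """Exclude treatments whose replicate screen datasets disagree.

    Treatments with >= 2 screen datasets are excluded when any pair of
    their series has Pearson r < ``r_min`` over shared cell lines.  Pairs
    with < 3 shared lines have an undefined correlation; such treatments
    are flagged for manual review, never auto-excluded.  Single-dataset
    treatments are never excluded.
    """
    excluded: list[str] = []
    review: list[str] = []
    rows = []
    by_treatment: dict[str, list[str]] = {}
    for treatment_id, dataset in vm.series_keys():
        by_treatment.setdefault(treatment_id, []).append(dataset)
    for treatment_id, datasets in sorted(by_treatment.items()):
        if len(datasets) < 2:
            continue
        discordant = False
        undefined = False
        for i, a in enumerate(datasets):
            for b in datasets[i + 1:]:
                sa = vm.series(treatment_id, a)
                sb = vm.series(treatment_id, b)
                shared = sa.index.intersection(sb.index)
                if len(shared) < 3:
                    undefined = True
                    rows.append((treatment_id, a, b, len(shared), np.nan))
                    continue
                r = float(np.corrcoef(sa[shared], sb[shared])[0, 1])
                rows.append((treatment_id, a, b, len(shared), r))
                if np.isnan(r) or r < r_min:
                    discordant = True
        if discordant:
            excluded.append(treatment_id)
        elif undefined:
            review.append(treatment_id)
    details = pd.DataFrame(
        rows, columns=["treatment_id", "dataset_a", "dataset_b", "n_shared", "r"]
    )
    return ConcordanceReport(excluded, review, details)


def direct_screen(
    vm: ViabilityMatrix,
    reference: str,
    alpha: float = 1e-3,
    alternative: str = "greater",
) -> DirectScreenReport:
    """Rank every treatment series in the panel against the reference.

    Replicate screen datasets of one drug are treated as separate
    treatments.  For each non-reference series: mean comparison and a
    Mann-Whitney test vs the reference; a series counts as significant
    when its mean is higher *and* p < alpha.  Fractions are over the
    ``n_treatments - 1`` non-reference series.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    keys = vm.series_keys()
    if reference not in {t for t, _ in keys}:
        raise KeyError(f"reference treatment {reference!r} absent from the screen")
    non_ref = [(t, d) for t, d in keys if t != reference]
    if not non_ref:
        raise ValueError("screen contains only the reference treatment")
    ref_values = vm.series(reference).to_numpy()
    ref_mean = float(np.mean(ref_values))
    summaries: list[TreatmentSummary] = []
    n_higher = 0
    n_sig = 0
    for treatment_id, dataset in non_ref:
        values = vm.series(treatment_id, dataset).to_numpy()
        u, p = mann_whitney(values, ref_values, alternative)
        summaries.append(_summary(treatment_id, dataset, values, u, p))
        higher = float(np.mean(values)) > ref_mean
        if higher:
            n_higher += 1
            if p < alpha:
                n_sig += 1
    summaries.sort(key=lambda s: (-s.mean, s.treatment_id, s.screen_dataset_id))
    denom = len(non_ref)
    return DirectScreenReport(
        reference=reference,
        n_treatments=len(non_ref) + 1,
        n_higher_mean=n_higher,
        frac_higher=n_higher / denom,
        n_significant=n_sig,
        frac_significant=n_sig / denom,
        alpha=alpha,
        summaries=summaries,
    )


def mutation_association(
    vm: ViabilityMatrix, treatment: str, gene: str
) -> float:
    """Two-sided Mann-Whitney p: sensitivity in mutated vs wild-type lines."""
    if vm.mutations is None:
        raise ValueError("viability matrix carries no mutation annotations")
    if gene not in vm.mutations.columns:
        raise KeyError(f"gene {gene!r} absent from mutation annotations")
    values = vm.series(treatment)
    values = values[~values.index.duplicated(keep="first")]
    status = vm.mutations[gene].reindex(values.index)
    known = values[status.notna().to_numpy()]
    status = status.dropna().astype(bool)
    mutated = known[status.to_numpy()]
    wildtype = known[~status.to_numpy()]
    if mutated.empty:
        raise ValueError(f"no mutated lines for {gene!r} among screened lines")
    if wildtype.empty:
        raise ValueError(f"no wild-type lines for {gene!r} among screened lines")
    _, p = mann_whitney(mutated.to_numpy(), wildtype.to_numpy(), "two_sided")
    return p


def de_genes(
    expression: pd.DataFrame,
    groups: Mapping[str, bool] | pd.Series,
    alpha: float = 1e-3,
    ordering: pd.Series | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Welch differential expression between sensitive / non-sensitive lines.

    ``expression`` is gene x cell-line; ``groups`` maps cell line -> True
    for the sensitive group.  Genes with Welch p < alpha are returned
    together with a heatmap-ready matrix: columns ordered by descending
    ``ordering`` (typically the sensitivity vector), rows by hierarchical
    clustering with correlation distance and average linkage.  A gene with
    zero variance in both groups gets p = 1 (skipped, not an error).
    """
    groups = pd.Series(groups)
    lines = [c for c in expression.columns if c in groups.index]
    if len(lines) < len(expression.columns):
        log.warning(
            "%d expression columns lack a group label; ignored",
            len(expression.columns) - len(lines),
        )
    labels = groups.reindex(lines).astype(bool)
    sens = expression[labels.index[labels]].to_numpy(dtype=float)
    non = expression[labels.index[~labels]].to_numpy(dtype=float)
    if sens.shape[1] < 2 or non.shape[1] < 2:
        raise ValueError("both groups need at least 2 cell lines")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(sens, non, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    flat = (np.var(sens, axis=1) == 0) & (np.var(non, axis=1) == 0)
    pvals[flat | np.isnan(pvals)] = 1.0
    selected = [g for g, p in zip(expression.index, pvals) if p < alpha]

    if ordering is not None:
        col_order = (
            ordering.reindex(lines).sort_values(ascending=False).index.tolist()
        )
    else:
        col_order = lines
    matrix = expression.loc[selected, col_order]
    if len(selected) > 2:
        dist = pdist(matrix.to_numpy(), metric="correlation")
        dist = np.nan_to_num(dist, nan=1.0)
        link = hierarchy.linkage(dist, method="average")
        row_order = hierarchy.leaves_list(link)
        matrix = matrix.iloc[row_order]
    return selected, matrix


def drug_correlation_matrices(
    membership: pd.DataFrame, vm: ViabilityMatrix
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Pathway-annotation vs sensitivity drug-drug correlation structure.

    ``membership`` is a drug x pathway binary matrix.  Returns the drug-
    drug Pearson correlation of annotation rows, the pairwise-complete
    Pearson correlation of sensitivity profiles over cell lines, and a
    per-drug discrepancy: the mean absolute difference between the drug's
    two correlation vectors (self excluded).  Drugs with a constant
    profile have undefined correlations, reported as NaN.
    """
    sens_wide = vm.wide().groupby(level="treatment_id").mean().T  # lines x drugs
    shared = sorted(set(membership.index) & set(sens_wide.columns))
    if not shared:
        raise ValueError("no drugs shared between membership matrix and screen")
    corr_go = membership.loc[shared].T.astype(float).corr()
    corr_sens = sens_wide[shared].corr(min_periods=3)
    diff = (corr_go - corr_sens).abs()
    np.fill_diagonal(diff.values, np.nan)
    discrepancy = diff.mean(axis=1, skipna=True)
    discrepancy[diff.isna().all(axis=1)] = np.nan
    return corr_go, corr_sens, discrepancy


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float))
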