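import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from g2dscreen.geneset_io import ViabilityMatrix
from g2dscreen.viability import (
    de_genes,
    direct_screen,
    drug_correlation_matrices,
    mann_whitney,
    mannwhitney_vs_reference,
    mean_sensitivity_ranking,
    mutation_association,
    replicate_concordance_filter,
    sensitivity_from_counts,
)
from oracles import mann_whitney_enumeration


def build_vm(series: dict, mutations=None, expression=None) -> ViabilityMatrix:
    """series: {(treatment, dataset): {line: value}}."""
    rows = []
    for (t, ds), values in series.items():
        for line, v in values.items():
            rows.append((t, line, float(v), ds))
    entries = pd.DataFrame(
        rows, columns=["treatment_id", "cell_line", "sensitivity", "screen_dataset_id"]
    )
    treatments = sorted({t for t, _ in series})
    meta = pd.DataFrame(
        {"name": treatments, "fda_approved": True, "cns_active": True},
        index=pd.Index(treatments, name="treatment_id"),
    )
    return ViabilityMatrix(entries, meta, mutations, expression)


class TestSensitivityFromCounts:
    def test_equal_abundance_is_zero(self):
        assert sensitivity_from_counts(100, 100, pseudocount=0) == 0.0

    def test_fourfold_depletion(self):
        assert sensitivity_from_counts(50, 200, pseudocount=0) == pytest.approx(2.0)

    def test_pseudocount_guards_zero_abundance(self):
        value = sensitivity_from_counts(0, 100, pseudocount=0.5)
        assert np.isfinite(value) and value > 0

    def test_negative_abundance_is_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            sensitivity_from_counts(-1, 10)

    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
    def test_antisymmetric_under_swap(self, a, b):
        assert sensitivity_from_counts(a, b, 0) == pytest.approx(
            -sensitivity_from_counts(b, a, 0), rel=1e-9
        )


class TestMeanSensitivityRanking:
    def test_constant_values_have_zero_width_ci(self):
        vm = build_vm({("t1", "S1"): {"c1": 2.0, "c2": 2.0, "c3": 2.0}})
        (summary,) = mean_sensitivity_ranking(vm)
        assert summary.sd == 0.0
        assert summary.ci95 == (2.0, 2.0)

    def test_t_interval_on_three_values(self):
        vm = build_vm({("t1", "S1"): {"c1": 1.0, "c2": 2.0, "c3": 3.0}})
        (summary,) = mean_sensitivity_ranking(vm)
        assert summary.mean == pytest.approx(2.0)
        assert summary.sd == pytest.approx(1.0)
        # t(0.975, 2) = 4.3027 -> half-width 4.3027 / sqrt(3) = 2.4841
        assert summary.ci95[0] == pytest.approx(-0.4841, abs=1e-3)
        assert summary.ci95[1] == pytest.approx(4.4841, abs=1e-3)

    def test_sorted_by_descending_mean_and_small_series_excluded(self):
        vm = build_vm(
            {
                ("low", "S1"): {"c1": 0.0, "c2": 0.2},
                ("high", "S1"): {"c1": 3.0, "c2": 3.5},
                ("tiny", "S1"): {"c1": 9.0},
            }
        )
        summaries = mean_sensitivity_ranking(vm)
        assert [s.treatment_id for s in summaries] == ["high", "low"]


class TestMannWhitney:
    def test_complete_separation_exact(self):
        u, p = mann_whitney([3, 4, 5], [1, 2], alternative="greater")
        assert u == 6.0
        assert p == pytest.approx(0.1)  # 1 / C(5, 2)

    def test_identical_series_two_sided_near_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3], alternative="two_sided")
        assert p > 0.9

    def test_empty_series_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("alternative", ["greater", "two_sided"])
    def test_exact_matches_enumeration(self, alternative):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            _, p = mann_whitney(x, y, alternative)
            assert p == pytest.approx(
                mann_whitney_enumeration(x, y, alternative), abs=1e-12
            )

    def test_vs_reference_wrapper(self):
        vm = build_vm(
            {
                ("drug", "S1"): {"c1": 3, "c2": 4, "c3": 5},
                ("ref", "S1"): {"c1": 1, "c2": 2},
            }
        )
        _, p = mannwhitney_vs_reference(vm, "drug", "ref", "greater")
        assert p == pytest.approx(0.1)


class TestReplicateConcordance:
    def test_identical_replicates_kept(self):
        values = {f"c{i}": float(v) for i, v in enumerate([1, 3, 2, 5, 4])}
        vm = build_vm({("t", "S1"): values, ("t", "S2"): values})
        report = replicate_concordance_filter(vm, r_min=0.3)
        assert report.excluded == []

    def test_anticorrelated_replicates_excluded(self):
        a = {f"c{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5])}
        b = {f"c{i}": float(v) for i, v in enumerate([5, 4, 3, 2, 1])}
        vm = build_vm({("t", "S1"): a, ("t", "S2"): b})
        report = replicate_concordance_filter(vm, r_min=0.3)
        assert report.excluded == ["t"]
        assert report.details["r"].iloc[0] == pytest.approx(-1.0)

    def test_single_dataset_never_excluded(self):
        vm = build_vm({("t", "S1"): {"c1": 1.0, "c2": 2.0}})
        report = replicate_concordance_filter(vm, r_min=0.99)
        assert report.excluded == []

    def test_too_few_shared_lines_flags_review(self):
        vm = build_vm(
            {
                ("t", "S1"): {"c1": 1.0, "c2": 2.0, "c3": 3.0},
                ("t", "S2"): {"c3": 9.0, "c4": 1.0, "c5": 2.0},
            }
        )
        report = replicate_concordance_filter(vm, r_min=0.3)
        assert report.excluded == []
        assert report.needs_review == ["t"]


class TestDirectScreen:
    def test_single_treatment_equal_to_reference(self):
        values = {f"c{i}": float(v) for i, v in enumerate([1, 2, 3, 4])}
        vm = build_vm({("t", "S1"): dict(values), ("ref", "S1"): dict(values)})
        report = direct_screen(vm, "ref", alpha=1e-3)
        assert report.n_treatments == 2
        assert report.n_higher_mean == 0
        assert report.n_significant == 0

    def test_reference_only_input_is_error(self):
        vm = build_vm({("ref", "S1"): {"c1": 1.0, "c2": 2.0}})
        with pytest.raises(ValueError, match="only the reference"):
            direct_screen(vm, "ref")

    def test_replicate_datasets_counted_as_separate_treatments(self):
        base = {f"c{i}": float(i) for i in range(5)}
        vm = build_vm(
            {("t", "S1"): base, ("t", "S2"): base, ("ref", "S1"): base}
        )
        report = direct_screen(vm, "ref")
        assert report.n_treatments == 3  # t/S1, t/S2, ref

    def test_planted_potent_drugs_detected(self):
        from g2dscreen.synthetic import gen_viability

        vm, truth = gen_viability(
            n_treatments=40, n_lines=30, potent_fraction=0.2,
            n_extra_datasets=0, n_discordant=0, seed=21,
        )
        report = direct_screen(vm, truth.reference, alpha=1e-3)
        significant = {
            s.treatment_id for s in report.summaries
            if s.p_vs_ref is not None and s.p_vs_ref < 1e-3
        }
        assert set(truth.potent_drugs) <= significant
        assert report.n_significant <= report.n_higher_mean <= report.n_treatments


class TestMutationAssociation:
    def _vm(self, mutations):
        series = {("t", "S1"): {f"c{i}": float(v) for i, v in enumerate([3, 4, 5, 1, 2])}}
        mut = pd.DataFrame({"TP53": mutations}, index=[f"c{i}" for i in range(5)])
        return build_vm(series, mutations=mut)

    def test_exact_two_sided_p(self):
        # mutated lines hold {3,4,5}, wild-type {1,2}: two-sided p = 0.2
        vm = self._vm([True, True, True, False, False])
        assert mutation_association(vm, "t", "TP53") == pytest.approx(0.2)

    def test_all_lines_mutated_is_error(self):
        vm = self._vm([True] * 5)
        with pytest.raises(ValueError, match="wild-type"):
            mutation_association(vm, "t", "TP53")

    def test_unknown_gene_is_error(self):
        vm = self._vm([True, False, True, False, True])
        with pytest.raises(KeyError, match="PTEN"):
            mutation_association(vm, "t", "PTEN")


class TestDeGenes:
    def _planted(self, seed=5, n_genes=100, n_planted=5, shift=3.0):
        rng = np.random.default_rng(seed)
        lines = [f"c{i:02d}" for i in range(20)]
        genes = [f"G{i:03d}" for i in range(n_genes)]
        expr = pd.DataFrame(rng.normal(size=(n_genes, 20)), index=genes, columns=lines)
        groups = pd.Series([True] * 10 + [False] * 10, index=lines)
        expr.iloc[:n_planted, :10] += shift
        return expr, groups, genes[:n_planted]

    def test_planted_genes_recovered_at_strict_alpha(self):
        expr, groups, planted = self._planted()
        selected, matrix = de_genes(expr, groups, alpha=1e-3)
        assert set(selected) == set(planted)
        assert set(matrix.index) == set(planted)

    def test_columns_ordered_by_descending_sensitivity(self):
        expr, groups, _ = self._planted()
        sensitivity = pd.Series(
            np.linspace(0, 1, len(expr.columns)), index=expr.columns
        )
        _, matrix = de_genes(expr, groups, alpha=1e-3, ordering=sensitivity)
        assert list(matrix.columns) == list(sensitivity.sort_values(ascending=False).index)

    def test_null_labels_yield_about_alpha_fraction(self):
        rng = np.random.default_rng(8)
        n_genes = 400
        lines = [f"c{i:02d}" for i in range(30)]
        expr = pd.DataFrame(
            rng.normal(size=(n_genes, 30)),
            index=[f"G{i:03d}" for i in range(n_genes)],
            columns=lines,
        )
        groups = pd.Series(rng.permutation([True] * 15 + [False] * 15), index=lines)
        selected, _ = de_genes(expr, groups, alpha=0.05)
        assert len(selected) <= 40  # mean 20, sd ~4.4 under the null

    def test_zero_variance_gene_skipped_not_error(self):
        expr, groups, planted = self._planted()
        expr.loc["G099"] = 1.0
        selected, _ = de_genes(expr, groups, alpha=1e-3)
        assert "G099" not in selected

    def test_too_small_group_is_error(self):
        expr, groups, _ = self._planted()
        groups[:] = True
        groups.iloc[0] = False
        with pytest.raises(ValueError, match="at least 2"):
            de_genes(expr, groups)


class TestDrugCorrelationMatrices:
    def _vm(self):
        rng = np.random.default_rng(2)
        series = {}
        for d in ["d1", "d2", "d3"]:
            series[(d, "S1")] = {f"c{i}": float(v)
                                 for i, v in enumerate(rng.normal(size=8))}
        return build_vm(series)

    def test_identical_membership_rows_correlate_perfectly(self):
        membership = pd.DataFrame(
            [[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]],
            index=["d1", "d2", "d3"],
            columns=["P1", "P2", "P3", "P4"],
        )
        corr_go, corr_sens, disc = drug_correlation_matrices(membership, self._vm())
        assert corr_go.loc["d1", "d2"] == pytest.approx(1.0)
        assert corr_go.loc["d1", "d3"] == pytest.approx(-1.0)
        assert disc.notna().all()

    def test_hand_computed_pearson(self):
        membership = pd.DataFrame(
            [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 1, 1]],
            index=["d1", "d2", "d3"],
            columns=["P1", "P2", "P3", "P4"],
        )
        corr_go, _, _ = drug_correlation_matrices(membership, self._vm())
        expected = np.corrcoef(membership.loc["d1"], membership.loc["d2"])[0, 1]
        assert corr_go.loc["d1", "d2"] == pytest.approx(expected)

    def test_constant_membership_row_gives_nan(self):
        membership = pd.DataFrame(
            [[1, 1, 1, 1], [1, 0, 1, 0], [0, 0, 1, 1]],
            index=["d1", "d2", "d3"],
            columns=["P1", "P2", "P3", "P4"],
        )
        corr_go, _, _ = drug_correlation_matrices(membership, self._vm())
        assert np.isnan(corr_go.loc["d1", "d2"])
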