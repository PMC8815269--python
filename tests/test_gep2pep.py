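import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from g2dscreen.geneset_io import (
    GeneSet,
    GeneSetCollection,
    GeneSetSource,
    GeneUniverse,
    RankedProfile,
)
from g2dscreen.gep2pep import (
    aggregate_replicates,
    ks_statistic,
    ks_statistic_batch,
    profile_to_pep,
    rank_drugs_for_pathway_set,
    read_pep_store,
    write_pep_store,
)
from conftest import make_pep, make_profile
from oracles import ks_running_sum_oracle


@st.composite
def position_sets(draw, max_n=50):
    n = draw(st.integers(2, max_n))
    t = draw(st.integers(1, n))
    positions = draw(
        st.lists(st.integers(1, n), min_size=t, max_size=t, unique=True)
    )
    return sorted(positions), n


class TestKsStatistic:
    def test_whole_universe_gives_minus_one_over_n(self):
        assert ks_statistic(list(range(1, 11)), 10) == pytest.approx(-0.1)

    def test_top_concentration(self):
        assert ks_statistic([1, 2], 10) == pytest.approx(0.8)

    def test_bottom_concentration(self):
        assert ks_statistic([9, 10], 10) == pytest.approx(-0.9)

    @pytest.mark.parametrize(
        "positions,n,message",
        [
            ([], 10, "non-empty"),
            ([0, 3], 10, "1..10"),
            ([3, 11], 10, "1..10"),
            ([3, 3], 10, "strictly increasing"),
        ],
    )
    def test_invalid_inputs(self, positions, n, message):
        with pytest.raises(ValueError, match=message):
            ks_statistic(positions, n)

    @given(position_sets())
    def test_agrees_with_running_sum_oracle(self, case):
        positions, n = case
        assert ks_statistic(positions, n) == pytest.approx(
            ks_running_sum_oracle(positions, n), abs=1e-12
        )

    @given(position_sets())
    def test_extremal_bound_never_exceeded(self, case):
        positions, n = case
        t = len(positions)
        es = ks_statistic(positions, n)
        assert abs(es) <= 1 - (t - 1) / n + 1e-12

    @given(position_sets())
    def test_sign_flips_under_ranking_reversal(self, case):
        # reversal swaps the roles of the top and bottom excesses (up to a
        # 1/n shift), so the sign flips whenever the two are not nearly tied
        positions, n = case
        t = len(positions)
        p = np.asarray(positions, dtype=float)
        j = np.arange(1, t + 1)
        a = np.max(j / t - p / n)
        b = np.max(p / n - (j - 1) / t)
        if abs(a - b) <= 2.0 / n + 1e-9:
            return
        es = ks_statistic(positions, n)
        es_rev = ks_statistic(sorted(n + 1 - q for q in positions), n)
        assert np.sign(es_rev) == -np.sign(es)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(0)
        n = 40
        mats = np.sort(
            np.array([rng.choice(n, size=5, replace=False) + 1 for _ in range(50)]),
            axis=1,
        )
        batch = ks_statistic_batch(mats, n)
        for row, es in zip(mats, batch):
            assert es == pytest.approx(ks_statistic(row, n), abs=1e-12)


class TestProfileToPep:
    def _setup(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        universe = GeneUniverse(tuple(f"g{i:03d}" for i in range(n)))
        coll = GeneSetCollection()
        # planted pathway = genes at the top of the ranking
        coll.add(GeneSet("TOP", "planted", GeneSetSource.GO,
                         frozenset(f"g{i:03d}" for i in range(5))))
        for k in range(6):
            members = rng.choice(n, size=8, replace=False)
            coll.add(GeneSet(f"R{k}", "random", GeneSetSource.GO,
                             frozenset(f"g{i:03d}" for i in members)))
        coll = coll.bind(universe)
        ranks = np.arange(1, n + 1)  # g000 is rank 1: TOP occupies 1..5
        profile = RankedProfile("d1", "r1", universe, ranks)
        return profile, coll

    def test_no_permutations_leaves_p_absent_but_ranks_defined(self):
        profile, coll = self._setup()
        pep = profile_to_pep(profile, coll, n_perm=0)
        assert pep.table["p"].isna().all()
        assert sorted(pep.table["rank"]) == list(range(1, len(coll) + 1))

    def test_planted_top_pathway_gets_rank_one_and_minimal_p(self):
        profile, coll = self._setup()
        n_perm = 199
        pep = profile_to_pep(profile, coll, n_perm=n_perm, seed=42)
        assert pep.table.loc["TOP", "rank"] == 1
        assert pep.table.loc["TOP", "p"] == pytest.approx(1 / (n_perm + 1))

    def test_identical_member_positions_tie_break_by_pathway_id(self, universe10):
        coll = GeneSetCollection()
        coll.add(GeneSet("B", "b", GeneSetSource.GO, frozenset({"g0", "g1"})))
        coll.add(GeneSet("A", "a", GeneSetSource.GO, frozenset({"g0", "g1"})))
        coll = coll.bind(universe10)
        profile = make_profile(universe10, np.arange(1, 11))
        pep = profile_to_pep(profile, coll, n_perm=0)
        assert pep.table.loc["A", "es"] == pep.table.loc["B", "es"]
        assert pep.table.loc["A", "rank"] == 1
        assert pep.table.loc["B", "rank"] == 2

    def test_deterministic_under_fixed_seed(self):
        profile, coll = self._setup()
        a = profile_to_pep(profile, coll, n_perm=99, seed=5)
        b = profile_to_pep(profile, coll, n_perm=99, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_empirical_p_valid_under_uniform_null(self):
        # random profiles: P(p <= alpha) should not exceed alpha by much
        rng = np.random.default_rng(9)
        universe = GeneUniverse(tuple(f"g{i:03d}" for i in range(200)))
        coll = GeneSetCollection()
        for k in range(40):
            members = rng.choice(200, size=10, replace=False)
            coll.add(GeneSet(f"R{k:02d}", "rnd", GeneSetSource.GO,
                             frozenset(f"g{i:03d}" for i in members)))
        coll = coll.bind(universe)
        pvals = []
        for i in range(25):
            profile = RankedProfile("d", f"r{i}", universe, rng.permutation(200) + 1)
            pep = profile_to_pep(profile, coll, n_perm=99, seed=1000 + i)
            pvals.append(pep.table["p"].to_numpy())
        pvals = np.concatenate(pvals)
        assert (pvals > 0).all() and (pvals <= 1).all()
        assert np.mean(pvals <= 0.05) <= 0.05 + 0.03


class TestAggregateReplicates:
    def test_single_replicate_is_identity(self, universe10, toy_collection):
        pep = profile_to_pep(
            make_profile(universe10, np.arange(1, 11)), toy_collection, n_perm=0
        )
        merged = aggregate_replicates([pep])
        pd.testing.assert_frame_equal(merged.table, pep.table)

    def test_mean_rank_merge_breaks_ties_by_pathway_id(self):
        # X and Y swap ranks 1 and 3 across replicates, Z is rank 2 twice:
        # all means tie at 2 and pathway-id order decides.
        rep1 = make_pep("d", {"X": 0.9, "Z": 0.5, "Y": 0.1})
        rep2 = make_pep("d", {"Y": 0.9, "Z": 0.5, "X": 0.1})
        merged = aggregate_replicates([rep1, rep2])
        assert merged.table.loc["X", "rank"] == 1
        assert merged.table.loc["Y", "rank"] == 2
        assert merged.table.loc["Z", "rank"] == 3
        assert merged.table.loc["X", "es"] == pytest.approx(0.5)

    def test_mismatched_pathways_error(self):
        a = make_pep("d", {"X": 0.5, "Y": 0.1})
        b = make_pep("d", {"X": 0.5, "Z": 0.1})
        with pytest.raises(ValueError, match="different pathway ids"):
            aggregate_replicates([a, b])

    def test_mixed_drugs_error(self):
        a = make_pep("d1", {"X": 0.5, "Y": 0.1})
        b = make_pep("d2", {"X": 0.5, "Y": 0.1})
        with pytest.raises(ValueError, match="mixed drug ids"):
            aggregate_replicates([a, b])


class TestRankDrugsForPathwaySet:
    def _peps(self):
        # drugHIT ranks the query pathways Q1, Q2 at the very top
        pathways = {f"N{i}": 0.0 for i in range(8)}
        rng = np.random.default_rng(3)
        peps = {}
        for d in ["drugA", "drugB", "drugC"]:
            es = {k: float(v) for k, v in
                  zip(pathways, rng.normal(0, 0.2, len(pathways)))}
            es.update({"Q1": float(rng.normal(0, 0.2)),
                       "Q2": float(rng.normal(0, 0.2))})
            peps[d] = make_pep(d, es)
        hit = {k: 0.0 for k in pathways}
        hit.update({"Q1": 0.99, "Q2": 0.98})
        peps["drugHIT"] = make_pep("drugHIT", hit)
        return peps

    def test_planted_drug_has_maximal_es_and_minimal_p(self):
        peps = self._peps()
        result = rank_drugs_for_pathway_set(peps, {"Q1", "Q2"}, n_perm=199, seed=0)
        top = result.table.iloc[0]
        assert top["drug_id"] == "drugHIT"
        assert top["es"] == max(result.table["es"])
        assert top["p"] == min(result.table["p"])

    def test_query_not_in_collection_is_error(self):
        peps = self._peps()
        with pytest.raises(ValueError, match="absent"):
            rank_drugs_for_pathway_set(peps, {"NOPE"}, n_perm=9, seed=0)

    def test_query_covering_all_pathways_is_error(self):
        peps = self._peps()
        every = set(peps["drugA"].table.index)
        with pytest.raises(ValueError, match="degenerate"):
            rank_drugs_for_pathway_set(peps, every, n_perm=9, seed=0)

    def test_empty_inputs_are_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rank_drugs_for_pathway_set(self._peps(), set(), n_perm=9, seed=0)
        with pytest.raises(ValueError, match="no PEPs"):
            rank_drugs_for_pathway_set({}, {"Q1"}, n_perm=9, seed=0)

    def test_deterministic_under_fixed_seed(self):
        peps = self._peps()
        a = rank_drugs_for_pathway_set(peps, {"Q1", "Q2"}, n_perm=99, seed=7)
        b = rank_drugs_for_pathway_set(peps, {"Q1", "Q2"}, n_perm=99, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)


def test_pep_store_round_trip(tmp_path):
    peps = {
        "d1": make_pep("d1", {"X": 0.4, "Y": -0.2, "Z": 0.1}),
        "d2": make_pep("d2", {"X": -0.9, "Y": 0.3, "Z": 0.0}),
    }
    write_pep_store(peps, tmp_path / "store")
    back = read_pep_store(tmp_path / "store")
    assert set(back) == {"d1", "d2"}
    for d in peps:
        pd.testing.assert_series_equal(
            back[d].table["es"], peps[d].table["es"],
            check_exact=False, check_names=False,
        )
        assert back[d].table["rank"].tolist() == peps[d].table["rank"].tolist()
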