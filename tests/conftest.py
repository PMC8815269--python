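import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from g2dscreen.geneset_io import (
    GeneSet,
    GeneSetCollection,
    GeneSetSource,
    GeneUniverse,
    RankedProfile,
)
from g2dscreen.gep2pep import PathwayExpressionProfile

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("g2dscreen").setLevel(logging.ERROR)


@pytest.fixture
def universe10() -> GeneUniverse:
    return GeneUniverse(tuple(f"g{i}" for i in range(10)))


@pytest.fixture
def toy_collection(universe10) -> GeneSetCollection:
    coll = GeneSetCollection()
    coll.add(GeneSet("P1", "pathway one", GeneSetSource.GO, frozenset({"g0", "g1"})))
    coll.add(GeneSet("P2", "pathway two", GeneSetSource.GO, frozenset({"g1"})))
    coll.add(
        GeneSet("P3", "pathway three", GeneSetSource.KEGG, frozenset({"g5", "g8", "g9"}))
    )
    return coll.bind(universe10)


def make_profile(universe: GeneUniverse, ranks, drug="d1", rep="r1") -> RankedProfile:
    return RankedProfile(drug, rep, universe, np.asarray(ranks))


def make_pep(drug_id: str, es_by_pathway: dict[str, float]) -> PathwayExpressionProfile:
    """Build a PEP directly from pathway -> es (ranks derived by the
    descending-es, id-tie-break rule)."""
    ids = list(es_by_pathway)
    es = pd.Series([es_by_pathway[i] for i in ids], index=ids, dtype=float)
    order = np.lexsort((np.array(ids, dtype=object), -es.to_numpy()))
    ranks = np.empty(len(ids), dtype=np.int64)
    ranks[order] = np.arange(1, len(ids) + 1)
    table = pd.DataFrame({"es": es, "p": np.nan, "rank": ranks})
    return PathwayExpressionProfile(drug_id, table)


@pytest.fixture
def make_pep_fixture():
    return make_pep


@pytest.fixture(scope="session")
def small_study():
    """One seeded corpus + matching viability screen, shared across tests."""
    from g2dscreen.synthetic import gen_study

    return gen_study(seed=7)
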