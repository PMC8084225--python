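import numpy as np
import pytest

from eaa.io import PhyloDistances, PlotCensus, StemRecord, infer_statuses


def make_record(tree_id, species, x, y, dbh):
    """dbh: list of per-census tuples or None."""
    return StemRecord(tree_id=tree_id, species=species, x=x, y=y,
                      dbh_by_census=list(dbh), status_by_census=infer_statuses(list(dbh)))


@pytest.fixture
def toy_plot():
    """Three trees, two censuses: one survivor, one recruit, one death."""
    recs = [
        make_record("t1", "AA", 10.0, 10.0, [(5.0,), (6.0,)]),
        make_record("t2", "AA", 12.0, 11.0, [None, (1.5,)]),
        make_record("t3", "BB", 40.0, 40.0, [(8.0,), None]),
    ]
    return PlotCensus(width=50.0, height=50.0, n_censuses=2, interval_years=5.0,
                      records=recs, species_list=["AA", "BB"])


@pytest.fixture
def toy_distances():
    return PhyloDistances(["AA", "BB"], np.array([[0.0, 120.0], [120.0, 0.0]]))


@pytest.fixture(scope="session")
def small_null_sim():
    """A small neutral plot reused across tests (session-scoped for speed)."""
    from eaa.scenarios import neutral_community
    from eaa.synthetic import simulate_plot

    return simulate_plot(neutral_community(seed=42, n_trees=900, width=70, height=70,
                                           n_species=10, n_censuses=2))
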