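import numpy as np
import pytest

from abforge import fixtures
from abforge.datasets import CanonicalEntry, filter_repertoire
from abforge.regions import RegionTable, assign_regions


@pytest.fixture(scope="session")
def table():
    return RegionTable.default()


@pytest.fixture(scope="session")
def expanded_table():
    return RegionTable.default("expanded")


@pytest.fixture(scope="session")
def fv(table):
    return fixtures.make_fv(seed=11, table=table)


@pytest.fixture(scope="session")
def fv_regions(fv, table):
    return {
        "H": assign_regions(fv.heavy, table),
        "L": assign_regions(fv.light, table),
    }


@pytest.fixture(scope="session")
def repertoire():
    return fixtures.make_repertoire(fixtures.RepertoireSpec(seed=7))


@pytest.fixture(scope="session")
def naive_records(repertoire):
    return filter_repertoire(repertoire[0], "naive")


@pytest.fixture(scope="session")
def memory_records(repertoire):
    return filter_repertoire(repertoire[0], "memory")


@pytest.fixture(scope="session")
def registry(fv, table):
    df = fixtures.make_registry(None, n_clusters=53, seed=13, fv=fv, table=table)
    return [
        CanonicalEntry(r.cluster_id, r.cdr_type, int(r.length), r.sequence, r.de_loop)
        for r in df.itertuples()
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
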