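import numpy as np
import pytest

import opucall as oc


@pytest.fixture(scope="session")
def sim_params():
    return oc.SimParams(seed=3)


@pytest.fixture(scope="session")
def refdb(sim_params):
    db, _ = oc.simulate_reference_db(sim_params)
    return db


@pytest.fixture(scope="session")
def ref_tree(sim_params):
    _, tree = oc.simulate_reference_db(sim_params)
    return tree


@pytest.fixture(scope="session")
def community(refdb, sim_params):
    return oc.simulate_community(refdb, sim_params)


@pytest.fixture(scope="session")
def reads_truth(community, sim_params):
    return oc.simulate_reads(community, sim_params)


@pytest.fixture(scope="session")
def pipeline_result(reads_truth, refdb):
    """Full pipeline over the default simulated cohort (shared: expensive)."""
    reads, _ = reads_truth
    return oc.run_pipeline(reads, refdb)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
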