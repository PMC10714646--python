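import numpy as np
import pandas as pd
import pytest

from ashmtwin.cohort import build_cohort
from ashmtwin.simulate import SimParams, simulate_cohort, write_fixture_bundle


@pytest.fixture(scope="session")
def default_cohort():
    return build_cohort(6, 4, 4)


@pytest.fixture(scope="session")
def small_sim():
    """A small default-parameter simulated cohort shared across tests."""
    params = SimParams(n_sites=60, seed=11)
    cohort, counts, truth = simulate_cohort(params)
    return params, cohort, counts, truth


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, small_sim):
    _, cohort, counts, truth = small_sim
    directory = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(cohort, counts, truth, directory)
    return cohort, counts, truth, paths


def make_counts(rows):
    """Helper: count table from (site_id, individual_id, ref, alt) tuples."""
    return pd.DataFrame(
        [
            {
                "site_id": sid, "chrom": "chr1", "pos": 100 + 10 * i,
                "ref": "A", "alt": "G", "individual_id": ind,
                "ref_reads": r, "alt_reads": a,
            }
            for i, (sid, ind, r, a) in enumerate(rows)
        ]
    )
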