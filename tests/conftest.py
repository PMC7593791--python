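import logging

import numpy as np
import pytest

from clubnet.connectome import BinaryNetwork
from clubnet.io import RegionAtlas
from clubnet.synthetic import CohortSpec, generate_cohort_full, write_cohort

logging.getLogger("clubnet").setLevel(logging.ERROR)


def net_from_edges(n_nodes: int, edges, sparsity: float = 0.15) -> BinaryNetwork:
    adj = np.zeros((n_nodes, n_nodes), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adj, sparsity)


@pytest.fixture(scope="session")
def atlas90() -> RegionAtlas:
    return RegionAtlas.aal90()


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A fast 30-region cohort spec for statistical unit tests."""
    return CohortSpec(
        seed=11,
        n_regions=30,
        n_communities=3,
        n_timepoints=60,
        n_per_group={"HC": 4, "SCD": 3, "aMCI": 3},
    )


@pytest.fixture(scope="session")
def demo_cohort(tmp_path_factory):
    """A seeded full-atlas cohort written to disk (8 subjects)."""
    spec = CohortSpec(
        seed=42,
        n_timepoints=100,
        n_per_group={"HC": 4, "SCD": 2, "aMCI": 2},
    )
    cohort = generate_cohort_full(spec)
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(cohort, out)
    return spec, cohort, out
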