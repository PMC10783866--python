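import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import mutstrat as ms

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def small_spec() -> ms.SyntheticSpec:
    """Small but fully structured cohort: 4 communities, 3 informative."""
    return ms.SyntheticSpec(
        n_genes=120,
        community_size=30,
        n_samples=80,
        n_pathways=12,
        pathway_size_range=(5, 12),
        n_informative_pathways=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    network = ms.generate_network(small_spec)
    pathways = ms.generate_pathways(network, small_spec)
    mutations, clinical, labels = ms.generate_cohort(network, pathways, small_spec)
    return {
        "spec": small_spec,
        "network": network,
        "pathways": pathways,
        "mutations": mutations,
        "clinical": clinical,
        "labels": labels,
    }


@pytest.fixture()
def two_node_transition():
    import scipy.sparse as sp

    from mutstrat.network import TransitionMatrix

    return TransitionMatrix(
        W=sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])), genes=("A", "B")
    )


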