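import numpy as np
import pytest

from cpmnet import Cohort, ConnectivityMatrix


def cohort_from_edges(W: np.ndarray, scores: np.ndarray, n_nodes: int,
                      labels=None, covariates=None) -> Cohort:
    """Build a Cohort from an (n_subjects x n_edges) upper-triangle weight matrix."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    assert W.shape[1] == iu.size
    subjects = []
    for s in range(W.shape[0]):
        z = np.zeros((n_nodes, n_nodes))
        z[iu, ju] = W[s]
        z += z.T
        subjects.append(ConnectivityMatrix(subject_id=f"s{s:03d}", z=z))
    return Cohort(subjects=subjects, scores=scores, labels=labels, covariates=covariates)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort(rng):
    """20 subjects, 10 nodes, unstructured noise edges."""
    n, n_nodes = 20, 10
    W = rng.normal(0.3, 0.15, size=(n, n_nodes * (n_nodes - 1) // 2))
    scores = rng.uniform(3, 95, size=n)
    return cohort_from_edges(W, scores, n_nodes)
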