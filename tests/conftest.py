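import numpy as np
import pytest
from scipy import sparse

from metacellkit import preprocess
from metacellkit.types import CellMatrix, Embedding


@pytest.fixture(scope="session")
def blob_embedding():
    """Three well-separated Gaussian blobs in 5-D, 240 cells."""
    rng = np.random.default_rng(7)
    centers = rng.normal(size=(3, 5)) * 12.0
    coords = np.vstack([c + rng.normal(scale=0.8, size=(80, 5)) for c in centers])
    labels = np.repeat([0, 1, 2], 80)
    emb = Embedding(
        coords=coords, component_variances=np.sort(coords.var(axis=0))[::-1]
    )
    return emb, labels


@pytest.fixture(scope="session")
def blob_kernel(blob_embedding):
    emb, labels = blob_embedding
    graph = preprocess.build_knn_graph(emb, k=20)
    kernel = preprocess.compute_adaptive_kernel(graph, emb, l=7)
    return kernel, labels


@pytest.fixture(scope="session")
def blob_dcs(blob_kernel):
    import warnings

    kernel, _ = blob_kernel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return preprocess.diffusion_map(kernel, n_dcs=6)


@pytest.fixture
def small_counts():
    """Tiny RNA count matrix with deterministic entries."""
    rng = np.random.default_rng(3)
    X = rng.poisson(2.0, size=(30, 12)) + (np.arange(12) == 0)  # no zero-total cells
    return CellMatrix(
        values=sparse.csr_matrix(X),
        cell_ids=np.array([f"c{i}" for i in range(30)]),
        feature_ids=np.array([f"g{j}" for j in range(12)]),
        modality="rna",
    )


def random_small_kernel(rng, n=12):
    """Random symmetric positive sparse kernel for optimizer tests."""
    from metacellkit.types import KernelMatrix

    D = rng.random((n, n))
    D = (D + D.T) / 2
    mask = rng.random((n, n)) < 0.6
    mask = mask | mask.T
    np.fill_diagonal(mask, True)
    M = sparse.csr_matrix(np.where(mask, D, 0.0))
    return KernelMatrix(affinities=M, bandwidths=np.ones(n), l=1)
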