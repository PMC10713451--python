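"""Phenotypic-manifold construction.

Normalization, low-dimensional embedding (PCA for RNA, TF-IDF + SVD for
ATAC), exact k-nearest-neighbor graph, the adaptive Gaussian kernel, and
the diffusion-map embedding derived from it.

The adaptive kernel is the object every downstream module consumes::

    M(x_i, x_j) = 1 / sqrt(2 pi (sigma_i + sigma_j))
                  * exp(-1/2 * ||x_i - x_j||^2 / (sigma_i + sigma_j))

where sigma_i is the Euclidean distance from cell i to its l-th nearest
neighbor. Support follows the symmetrized k-nearest-neighbor graph (union
by default; a mutual-only variant is available).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph, linalg as sparse_linalg
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .types import CellMatrix, DiffusionEmbedding, Embedding, KernelMatrix, NeighborGraph

PSEUDOCOUNT = 0.1
DEFAULT_N_HVG = 2500
DEFAULT_N_COMPONENTS = {"rna": 50, "atac": 30}
DEFAULT_K = 50
DEFAULT_L = 15
DEFAULT_N_DCS = 10
ATAC_DROP_CORRELATION = 0.9
_SIGMA_FLOOR = 1e-12


def normalize_expression(counts: CellMatrix, n_hvg: int = DEFAULT_N_HVG):
    """Library-size normalize, log-transform and select highly variable genes.

    Each entry becomes ``log(count / cell_total + 0.1)``. At most ``n_hvg``
    genes are retained, ranked by normalized dispersion (dispersion z-scored
    within mean-expression bins).

    Returns
    -------
    (normalized, gene_ids) : dense ``cells x n_hvg`` float array and the ids
    of the retained genes, in their original order.
    """
    if counts.modality != "rna":
        raise ValueError("normalize_expression expects an RNA CellMatrix")
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    X = counts.values
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = counts.cell_ids[int(np.argmin(totals))]
        raise ValueError(f"cell {bad!r} has zero total count")

    rel = X.multiply(1.0 / totals[:, None]).tocsc()
    keep = _select_hvg(rel, n_hvg)
    dense = np.asarray(rel[:, keep].todense())
    return np.log(dense + PSEUDOCOUNT), counts.feature_ids[keep]


def _select_hvg(rel: sparse.csc_matrix, n_hvg: int, n_bins: int = 20) -> np.ndarray:
    n_genes = rel.shape[1]
    if n_hvg >= n_genes:
        return np.arange(n_genes)
    mean = np.asarray(rel.mean(axis=0)).ravel()
    sq = np.asarray(rel.multiply(rel).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # z-score dispersion within equal-frequency mean bins
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    norm_disp = np.zeros(n_genes)
    for b in bins:
        if len(b) == 0:
            continue
        mu, sd = disp[b].mean(), disp[b].std()
        norm_disp[b] = (disp[b] - mu) / sd if sd > 0 else 0.0
    top = np.argsort(-norm_disp, kind="stable")[:n_hvg]
    return np.sort(top)


def tfidf_transform(counts: sparse.spmatrix) -> sparse.csr_matrix:
    """TF-IDF for ATAC counts.

    Term frequency = count / cell total; inverse document frequency =
    ``log(1 + n_cells / (1 + n_cells_with_feature))``.
    """
    X = sparse.csr_matrix(counts, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    tf = X.multiply(1.0 / totals[:, None]).tocsr()
    n_cells = X.shape[0]
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + n_cells / (1.0 + df))
    return tf.multiply(idf[None, :]).tocsr()


def compute_embedding(
    data,
    modality: str = "rna",
    n_components: int | None = None,
    drop_correlated_first: float = ATAC_DROP_CORRELATION,
    seed: int = 0,
) -> Embedding:
    """Low-dimensional embedding of cells.

    RNA: principal components of the (already normalized) dense HVG matrix.
    ATAC: TF-IDF normalization of the raw count ``CellMatrix`` followed by a
    truncated SVD; the first component is dropped when its absolute Pearson
    correlation with log total counts exceeds ``drop_correlated_first``
    (depth, not biology, dominates it in that case).
    """
    if n_components is None:
        n_components = DEFAULT_N_COMPONENTS[modality]
    if modality == "rna":
        X = np.asarray(data, dtype=float)
        n, f = X.shape
        if n_components >= min(n, f):
            raise ValueError(
                f"n_components={n_components} must be < min(cells, features)={min(n, f)}"
            )
        pca = PCA(n_components=n_components, random_state=seed)
        coords = pca.fit_transform(X)
        variances = pca.explained_variance_
        return Embedding(coords=coords, component_variances=variances, modality="rna")
    if modality == "atac":
        if isinstance(data, CellMatrix):
            raw = data.values
        else:
            raw = sparse.csr_matrix(data)
        n, f = raw.shape
        if n_components >= min(n, f):
            raise ValueError(
                f"n_components={n_components} must be < min(cells, features)={min(n, f)}"
            )
        norm = tfidf_transform(raw)
        svd = TruncatedSVD(n_components=min(n_components + 1, min(n, f) - 1), random_state=seed)
        coords = svd.fit_transform(norm)
        variances = svd.singular_values_**2 / (n - 1)  # non-increasing by construction
        log_depth = np.log1p(np.asarray(raw.sum(axis=1)).ravel())
        first = coords[:, 0]
        if first.std() > 0 and log_depth.std() > 0:
            r = float(np.corrcoef(first, log_depth)[0, 1])
        else:
            r = 0.0
        dropped = abs(r) > drop_correlated_first
        if dropped:
            coords, variances = coords[:, 1:], variances[1:]
        coords, variances = coords[:, :n_components], variances[:n_components]
        return Embedding(
            coords=coords,
            component_variances=variances,
            modality="atac",
            dropped_first_component=bool(dropped),
            first_component_correlation=r,
        )
    raise ValueError("modality must be 'rna' or 'atac'")


def build_knn_graph(embedding: Embedding, k: int = DEFAULT_K) -> NeighborGraph:
    """Exact Euclidean k-nearest-neighbor graph (self excluded)."""
    coords = embedding.coords
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} too large for {n} cells; use k <= n-1")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute", metric="euclidean")
    nn.fit(coords)
    dist, idx = nn.kneighbors(coords)
    # remove self (distance 0 at its own index; with duplicates, self may not
    # be first — drop the column matching the row index instead)
    rows = np.arange(n)
    keep = idx != rows[:, None]
    # ensure exactly k kept per row (duplicates can make self appear never/twice)
    dist_k = np.empty((n, k))
    idx_k = np.empty((n, k), dtype=int)
    for i in range(n):
        d_i, j_i = dist[i][keep[i]], idx[i][keep[i]]
        dist_k[i], idx_k[i] = d_i[:k], j_i[:k]
    indptr = np.arange(0, n * k + 1, k)
    D = sparse.csr_matrix((dist_k.ravel(), idx_k.ravel(), indptr), shape=(n, n))
    return NeighborGraph(distances=D, k=k)


def compute_adaptive_kernel(
    graph: NeighborGraph,
    embedding: Embedding,
    l: int = DEFAULT_L,
    kernel_support: str = "union",
) -> KernelMatrix:
    """Adaptive Gaussian kernel on the kNN graph.

    sigma_i is the distance from cell i to its l-th nearest neighbor; the
    affinity of a supported pair is
    ``1/sqrt(2 pi (sigma_i + sigma_j)) * exp(-||x_i-x_j||^2 / (2 (sigma_i + sigma_j)))``.
    Support is the union-symmetrized kNN graph by default; ``kernel_support="mutual"``
    restricts support to mutual k-nearest neighbors instead. The diagonal
    carries the kernel value at zero distance, ``1/sqrt(4 pi sigma_i)``.
    """
    if kernel_support not in ("mutual", "union"):
        raise ValueError("kernel_support must be 'mutual' or 'union'")
    D = graph.distances
    k = graph.k
    if l >= k:
        raise ValueError(f"l={l} must be < k={k}")
    if l < 1:
        raise ValueError("l must be >= 1")
    n = D.shape[0]
    # sigma_i = distance to the l-th nearest neighbor (rows of D hold the k
    # nearest neighbors; sort each row's stored distances)
    sigmas = np.empty(n)
    for i in range(n):
        row = np.sort(D.data[D.indptr[i] : D.indptr[i + 1]])
        sigmas[i] = row[l - 1] if row.size >= l else (row[-1] if row.size else 0.0)
    degenerate = sigmas < _SIGMA_FLOOR
    if degenerate.any():
        positive = sigmas[~degenerate]
        if positive.size == 0:
            raise ValueError("all bandwidths are degenerate (all points identical?)")
        sigmas[degenerate] = positive.min()

    pattern = D.copy()
    pattern.data = np.ones_like(pattern.data)  # keep duplicate (zero-distance) edges
    if kernel_support == "mutual":
        support = pattern.minimum(pattern.T)
    else:
        support = pattern.maximum(pattern.T)
    support = sparse.coo_matrix(support)
    i, j = support.row, support.col
    coords = embedding.coords
    d2 = np.sum((coords[i] - coords[j]) ** 2, axis=1)
    ss = sigmas[i] + sigmas[j]
    vals = np.exp(-0.5 * d2 / ss) / np.sqrt(2.0 * np.pi * ss)
    M = sparse.csr_matrix((vals, (i, j)), shape=(n, n))
    M.setdiag(1.0 / np.sqrt(4.0 * np.pi * sigmas))
    M = (M + M.T) * 0.5  # exact symmetry against floating-point asymmetry
    return KernelMatrix(affinities=M.tocsr(), bandwidths=sigmas, l=l)


def diffusion_map(kernel: KernelMatrix, n_dcs: int = DEFAULT_N_DCS) -> DiffusionEmbedding:
    """Diffusion components of the row-normalized kernel.

    The kernel is row-normalized into a transition operator; its leading
    right eigenvectors are returned with the trivial constant component
    removed, ordered by eigenvalue magnitude. Disconnected kernels are
    handled globally (a warning is emitted): the eigenvalue-1 eigenspace is
    rotated so the constant direction can be removed while the components'
    indicator structure is retained.
    """
    M = kernel.affinities.tocsr()
    n = M.shape[0]
    if n_dcs >= n:
        raise ValueError(f"n_dcs={n_dcs} must be < number of cells ({n})")
    n_comp, _ = csgraph.connected_components(M, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"kernel graph has {n_comp} connected components; diffusion map "
            "computed on the full (block) operator"
        )
    deg = np.asarray(M.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    inv_sqrt = 1.0 / np.sqrt(deg)
    S = M.multiply(inv_sqrt[:, None]).multiply(inv_sqrt[None, :]).tocsr()
    S = (S + S.T) * 0.5
    k_eig = min(n_dcs + n_comp, n - 1)
    if n <= max(3 * (k_eig + 1), 50):
        w, v = np.linalg.eigh(S.toarray())
    else:
        # deterministic start vector: eigsh would otherwise seed from the
        # global RNG, making results depend on unrelated prior computations
        v0 = np.full(n, 1.0 / np.sqrt(n))
        w, v = sparse_linalg.eigsh(S, k=k_eig, which="LA", v0=v0)
    order = np.argsort(-np.abs(w))
    w, v = w[order], v[:, order]
    # rotate the (possibly multiple) eigenvalue-1 eigenspace so that the
    # trivial stationary direction is an explicit basis vector, then drop it
    triv = inv_sqrt * np.sqrt(deg)  # constant vector in right-eigenvector coords
    v0 = np.sqrt(deg) / np.linalg.norm(np.sqrt(deg))  # symmetric-coords trivial vector
    near_one = np.abs(w - 1.0) < 1e-10
    if near_one.any():
        block = v[:, near_one]
        proj = block - np.outer(v0, v0 @ block)
        q, r = np.linalg.qr(proj)
        keep_cols = np.abs(np.diag(r)) > 1e-8
        rotated = q[:, keep_cols]
        v = np.column_stack([rotated, v[:, ~near_one]])
        w = np.concatenate([np.ones(rotated.shape[1]), w[~near_one]])
    else:
        # connected, well-behaved: first vector is the trivial one
        v = v[:, 1:]
        w = w[1:]
    dcs = v * inv_sqrt[:, None]  # back to right eigenvectors of the transition operator
    # normalize each component for scale stability
    norms = np.linalg.norm(dcs, axis=0)
    norms[norms == 0] = 1.0
    dcs = dcs / norms
    dcs, w = dcs[:, :n_dcs], w[:n_dcs]
    return DiffusionEmbedding(dcs=dcs, eigenvalues=w, n_dcs=dcs.shape[1])
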