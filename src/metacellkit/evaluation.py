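"""Metacell quality metrics and robustness statistics.

Compactness (diffusion-space dispersion; lower is better), separation
(distance to the nearest other metacell; higher is better), cell-type
purity, NMI between labelings, density stratification of cells and
metacells, and neighborhood mixing entropy.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score
from sklearn.neighbors import NearestNeighbors

from .types import DiffusionEmbedding, MetacellAssignment

DEFAULT_DENSITY_RANK = 150
DEFAULT_DENSITY_CAP = 0.3
DEFAULT_ENTROPY_K = 10


def evaluate_metacells(
    assignment: MetacellAssignment,
    dcs: DiffusionEmbedding,
    celltypes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-metacell compactness, separation and (optionally) purity.

    compactness(m): mean over diffusion components of the population
    standard deviation of member-cell coordinates. separation(m): Euclidean
    distance from the metacell centroid to its nearest other metacell
    centroid in diffusion space. purity(m): frequency of the modal cell type.
    """
    labels = assignment.labels
    X = dcs.dcs
    mids = np.unique(labels)
    centroids = np.vstack([X[labels == m].mean(axis=0) for m in mids])
    compactness = np.array(
        [X[labels == m].std(axis=0, ddof=0).mean() for m in mids]
    )
    if len(mids) > 1:
        d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        separation = d.min(axis=1)
    else:
        separation = np.zeros(1)
    out = pd.DataFrame(
        {"metacell": mids, "compactness": compactness, "separation": separation}
    )
    if celltypes is not None:
        celltypes = np.asarray(celltypes)
        purity = np.empty(len(mids))
        modal = np.empty(len(mids), dtype=object)
        for i, m in enumerate(mids):
            mem = celltypes[labels == m]
            types, cnts = np.unique(mem, return_counts=True)
            best = cnts.max()
            modal[i] = sorted(types[cnts == best])[0]
            purity[i] = best / mem.size
        out["celltype"] = modal
        out["purity"] = purity
    return out


def compute_nmi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual information with arithmetic-mean normalization."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must cover the same cells")
    if len(np.unique(labels_a)) == 1 and len(np.unique(labels_b)) == 1:
        warnings.warn("both labelings are single-cluster; NMI defined as 1")
        return 1.0
    return float(
        normalized_mutual_info_score(labels_a, labels_b, average_method="arithmetic")
    )


def classify_density(
    dcs: DiffusionEmbedding,
    assignment: MetacellAssignment,
    rank: int = DEFAULT_DENSITY_RANK,
    cap: float = DEFAULT_DENSITY_CAP,
) -> dict:
    """Stratify cells and metacells by local density in diffusion space.

    The distance to the ``rank``-th nearest neighbor approximates inverse
    density; cells in the upper quartile of that distance are low-density
    cells, lower quartile high-density. A metacell inherits a stratum when
    it contains such cells, with each stratum capped at ``cap`` (30%) of all
    metacells, prioritized by how many stratum cells a metacell holds.
    """
    X = dcs.dcs
    n = X.shape[0]
    if n <= rank:
        raise ValueError(f"need more than rank={rank} cells; have {n}. Use a smaller rank.")
    nn = NearestNeighbors(n_neighbors=rank + 1, algorithm="brute")
    nn.fit(X)
    dist, _ = nn.kneighbors(X)
    d_rank = dist[:, rank]  # self occupies column 0
    n_quart = n // 4
    order = np.argsort(d_rank, kind="stable")
    cell_stratum = np.full(n, "mid", dtype=object)
    cell_stratum[order[:n_quart]] = "high"  # smallest distances = densest
    cell_stratum[order[n - n_quart :]] = "low"

    labels = assignment.labels
    mids = np.unique(labels)
    cap_n = math.ceil(cap * len(mids))
    mc_stratum = np.full(len(mids), "mid", dtype=object)
    for stratum in ("low", "high"):
        counts = np.array(
            [np.sum(cell_stratum[labels == m] == stratum) for m in mids]
        )
        candidates = np.flatnonzero(counts > 0)
        chosen = candidates[np.argsort(-counts[candidates], kind="stable")][:cap_n]
        for c in chosen:
            if mc_stratum[c] == "mid":
                mc_stratum[c] = stratum
    return {
        "cell_rank_distance": d_rank,
        "cell_stratum": cell_stratum,
        "metacell_ids": mids,
        "metacell_stratum": mc_stratum,
    }


def neighborhood_entropy(
    metacell_embedding: np.ndarray,
    metacell_types: np.ndarray,
    k: int = DEFAULT_ENTROPY_K,
) -> np.ndarray:
    """Shannon entropy (natural log) of cell-type composition over each
    metacell's k nearest metacell neighbors. Higher entropy means more mixed
    neighborhoods."""
    X = np.asarray(metacell_embedding, dtype=float)
    types = np.asarray(metacell_types)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} metacells; have {n}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute")
    nn.fit(X)
    _, idx = nn.kneighbors(X)
    ent = np.empty(n)
    for i in range(n):
        neigh = idx[i][idx[i] != i][:k]
        _, cnts = np.unique(types[neigh], return_counts=True)
        p = cnts / cnts.sum()
        ent[i] = float(-(p * np.log(p)).sum())
    return ent
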