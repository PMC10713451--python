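"""Core in-memory containers shared across the toolkit.

All containers are thin dataclasses around numpy / scipy.sparse / pandas
objects; they carry the identifiers needed to keep cells, features, peaks
and metacells aligned between modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse


def _as_array(ids, name: str) -> np.ndarray:
    arr = np.asarray(ids)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if len(np.unique(arr)) != arr.shape[0]:
        raise ValueError(f"duplicate entries in {name}")
    return arr


@dataclass
class CellMatrix:
    """Raw cells x features count matrix for one modality (rna or atac)."""

    values: sparse.csr_matrix
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    modality: str

    def __post_init__(self):
        self.values = sparse.csr_matrix(self.values)
        self.cell_ids = _as_array(self.cell_ids, "cell_ids")
        self.feature_ids = _as_array(self.feature_ids, "feature_ids")
        if self.modality not in ("rna", "atac"):
            raise ValueError("modality must be 'rna' or 'atac'")
        n, f = self.values.shape
        if n != len(self.cell_ids) or f != len(self.feature_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        if n < 2:
            raise ValueError("need at least 2 cells")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.values.nnz and np.any(self.values.data != np.floor(self.values.data)):
            raise ValueError("counts must be integral")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """Low-dimensional cell embedding (PCA for RNA, LSI/SVD for ATAC)."""

    coords: np.ndarray
    component_variances: np.ndarray
    modality: str = "rna"
    dropped_first_component: bool = False
    first_component_correlation: Optional[float] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.component_variances = np.asarray(self.component_variances, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite values")
        if np.any(np.diff(self.component_variances) > 1e-8):
            raise ValueError("component variances must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class NeighborGraph:
    """k-nearest-neighbor graph; distances[i, j] > 0 iff j is a kNN of i."""

    distances: sparse.csr_matrix
    k: int
    metric: str = "euclidean"


@dataclass
class KernelMatrix:
    """Sparse symmetric adaptive-Gaussian affinity matrix with bandwidths."""

    affinities: sparse.csr_matrix
    bandwidths: np.ndarray
    l: int

    def __post_init__(self):
        if np.any(self.bandwidths <= 0):
            raise ValueError("all bandwidths must be positive")

    @property
    def n_cells(self) -> int:
        return self.affinities.shape[0]


@dataclass
class DiffusionEmbedding:
    """Leading non-trivial diffusion components of the kernel transition operator."""

    dcs: np.ndarray
    eigenvalues: np.ndarray
    n_dcs: int


@dataclass
class Decomposition:
    """Kernel archetypal decomposition M ~= M B A with column-stochastic A, B."""

    A: sparse.csr_matrix
    B: sparse.csr_matrix
    s: int
    sre_trace: np.ndarray
    converged: bool
    init_cells: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def sre(self) -> float:
        return float(self.sre_trace[-1])


@dataclass
class MetacellAssignment:
    """Binarized metacell assignment with regularized soft weights."""

    labels: np.ndarray
    soft_weights: sparse.csr_matrix  # s x n, columns sum to 1
    max_weight: np.ndarray
    n_nontrivial: np.ndarray

    @property
    def n_metacells(self) -> int:
        return self.soft_weights.shape[0]

    @property
    def n_cells(self) -> int:
        return self.labels.shape[0]


@dataclass
class MetacellCounts:
    """Per-metacell summed raw counts."""

    values: sparse.csr_matrix  # s x features
    sizes: np.ndarray
    feature_ids: np.ndarray
    metacell_ids: np.ndarray
    celltype: Optional[np.ndarray] = None
    purity: Optional[np.ndarray] = None

    @property
    def n_metacells(self) -> int:
        return self.values.shape[0]


@dataclass
class FragmentSet:
    """ATAC fragment records, 0-based half-open coordinates."""

    records: pd.DataFrame  # chrom, start, end, barcode, count
    n_unmapped: int = 0

    def __post_init__(self):
        req = ["chrom", "start", "end", "barcode", "count"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"fragment records missing columns: {missing}")
        bad = np.flatnonzero(
            (self.records["end"].to_numpy() <= self.records["start"].to_numpy())
        )
        if bad.size:
            raise ValueError(f"fragment end <= start at record {bad[0]}")
        if len(self.records) and (self.records["count"] < 1).any():
            raise ValueError("fragment counts must be >= 1")

    @property
    def lengths(self) -> np.ndarray:
        return (self.records["end"] - self.records["start"]).to_numpy()

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PeakSet:
    """Fixed-width peak atlas with per-peak GC content."""

    intervals: pd.DataFrame  # chrom, start, end, peak_id
    gc_content: Optional[np.ndarray] = None

    def __post_init__(self):
        req = ["chrom", "start", "end", "peak_id"]
        missing = [c for c in req if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"peak intervals missing columns: {missing}")
        if self.gc_content is not None:
            self.gc_content = np.asarray(self.gc_content, dtype=float)
            if len(self.gc_content) != len(self.intervals):
                raise ValueError("gc_content length does not match peaks")
            if np.any((self.gc_content < 0) | (self.gc_content > 1)):
                raise ValueError("gc_content must lie in [0, 1]")

    @property
    def widths(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()

    @property
    def peak_ids(self) -> np.ndarray:
        return self.intervals["peak_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class OpenPeakMatrix:
    """Per-(metacell, peak) Poisson open/closed calls."""

    is_open: np.ndarray  # s x peaks bool
    pvalues: np.ndarray  # s x peaks
    lam: np.ndarray  # per-metacell Poisson rate
    peak_ids: np.ndarray


@dataclass
class TFTargetMatrix:
    """Gene x TF matrix of correlation-weighted motif scores."""

    G: pd.DataFrame  # genes x TFs
    qualifying_peaks: dict  # gene -> list of peak ids (S_g)
    p_threshold: float = 0.1
    r_threshold: float = 0.1


@dataclass
class TFActivityResult:
    """Per-metacell lasso fits and signed leave-one-out TF activities."""

    activities: pd.DataFrame  # TFs x metacells
    coefficients: pd.DataFrame  # TFs x metacells
    alphas: np.ndarray  # chosen lasso penalty per metacell
    ranking: pd.Series  # TFs ordered by total activity


@dataclass
class Meta2Assignment:
    """Metacell -> meta2cell grouping with condition composition."""

    labels: np.ndarray  # per-metacell meta2cell index
    conditions: np.ndarray  # per-metacell condition label
    samples: np.ndarray  # per-metacell sample id
    proportions: np.ndarray  # per-meta2cell focal-condition proportion
    annotations: np.ndarray  # per-meta2cell cell type or "Mixed"
    focal_condition: str = ""
    pvalues: Optional[np.ndarray] = None
    significant: Optional[np.ndarray] = None

    @property
    def n_meta2(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0
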