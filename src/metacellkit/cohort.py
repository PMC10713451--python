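"""Multi-sample cohort analysis.

Per-sample metacells are mapped across samples (mutual top-2 nearest
neighbors in diffusion space), pooled into second-level metacells
("meta2cells") by re-running the kernel archetypal pipeline on metacell
rows, and tested for differential abundance of a condition with a
label-permutation test that preserves meta2cell sizes.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse

from . import preprocess
from .pipeline import compute_metacells
from .types import Embedding, Meta2Assignment

DEFAULT_META2_RATIO = 10
DEFAULT_N_PERMUTATIONS = 5_000
DEFAULT_DA_ALPHA = 0.1
META2_PURITY_RULE = 0.8
MAP_TOP = 2


def _metacell_dcs(coords: np.ndarray, n_dcs: int = 10) -> np.ndarray:
    """Diffusion components of a metacell-level embedding (the standard
    kernel construction at metacell scale)."""
    n = coords.shape[0]
    emb = Embedding(
        coords=coords, component_variances=np.sort(coords.var(axis=0))[::-1]
    )
    k = min(30, n - 1)
    l = max(1, min(10, k - 1))
    graph = preprocess.build_knn_graph(emb, k=k)
    kernel = preprocess.compute_adaptive_kernel(graph, emb, l=l)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm = preprocess.diffusion_map(kernel, n_dcs=min(n_dcs, n - 1))
    return dm.dcs


def map_metacells_between_samples(
    embedding: np.ndarray,
    sample_ids: np.ndarray,
    celltypes: np.ndarray | None = None,
    n_dcs: int = 10,
) -> dict:
    """Mutual-top-2 metacell equivalence across sample pairs.

    ``embedding`` holds one row per metacell (batch-corrected PCs or
    similar); the top ``n_dcs`` diffusion components are computed from it.
    Two metacells from different samples are equivalent when each lies in
    the other's top two nearest cross-sample neighbors. When cell types are
    supplied, the fraction of equivalent pairs with matching type is
    reported.
    """
    sample_ids = np.asarray(sample_ids)
    uniq = pd.unique(sample_ids)
    if len(uniq) < 2:
        raise ValueError("need metacells from at least 2 samples")
    small = [s for s in uniq if np.sum(sample_ids == s) < 3]
    if small:
        warnings.warn(f"samples with < 3 metacells excluded: {small}")
        keepmask = ~np.isin(sample_ids, small)
    else:
        keepmask = np.ones(len(sample_ids), dtype=bool)
    idx_all = np.flatnonzero(keepmask)
    dcs = _metacell_dcs(np.asarray(embedding, dtype=float)[keepmask], n_dcs=n_dcs)
    sids = sample_ids[keepmask]

    pairs = []
    for sa, sb in combinations(pd.unique(sids), 2):
        ia = np.flatnonzero(sids == sa)
        ib = np.flatnonzero(sids == sb)
        d = np.linalg.norm(dcs[ia][:, None, :] - dcs[ib][None, :, :], axis=2)
        top_ab = np.argsort(d, axis=1, kind="stable")[:, :MAP_TOP]  # a -> b
        top_ba = np.argsort(d.T, axis=1, kind="stable")[:, :MAP_TOP]  # b -> a
        for ai in range(len(ia)):
            for bj in top_ab[ai]:
                if ai in top_ba[bj]:
                    pairs.append((idx_all[ia[ai]], idx_all[ib[bj]], sa, sb))
    out = pd.DataFrame(pairs, columns=["metacell_a", "metacell_b", "sample_a", "sample_b"])
    result = {"pairs": out}
    if celltypes is not None and len(out):
        ct = np.asarray(celltypes)
        match = ct[out["metacell_a"]] == ct[out["metacell_b"]]
        result["matched_type_fraction"] = float(match.mean())
    return result


def build_meta2cells(
    embedding: np.ndarray,
    samples: np.ndarray,
    conditions: np.ndarray,
    celltypes: np.ndarray | None = None,
    ratio: int = DEFAULT_META2_RATIO,
    focal_condition: str | None = None,
    seed: int = 0,
) -> Meta2Assignment:
    """Group pooled metacells into meta2cells.

    Re-runs the kernel archetypal pipeline on the metacell rows of a
    (batch-corrected) embedding with one meta2cell per ``ratio`` metacells.
    Each meta2cell is annotated with the modal cell type when purity
    exceeds 80%, otherwise "Mixed", and carries the proportion of its
    metacells drawn from the focal condition (default: the last condition
    in sorted order, conventionally the disease arm).
    """
    embedding = np.asarray(embedding, dtype=float)
    samples = np.asarray(samples)
    conditions = np.asarray(conditions)
    n = embedding.shape[0]
    uniq_cond = sorted(pd.unique(conditions))
    if focal_condition is None:
        focal_condition = uniq_cond[-1]
    s2 = max(1, math.ceil(n / ratio))
    emb = Embedding(
        coords=embedding, component_variances=np.sort(embedding.var(axis=0))[::-1]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = compute_metacells(
            embedding=emb,
            n_metacells=s2,
            k=min(30, n - 1),
            l=max(1, min(10, min(30, n - 1) - 1)),
            seed=seed,
            aggregate=False,
        )
    labels = res.assignment.labels
    # re-index to the occupied meta2cells
    occupied, labels = np.unique(labels, return_inverse=True)
    m2 = labels.max() + 1
    z = (conditions == focal_condition).astype(float)
    props = np.array([z[labels == m].mean() for m in range(m2)])
    annotations = np.full(m2, "Mixed", dtype=object)
    if celltypes is not None:
        ct = np.asarray(celltypes)
        for m in range(m2):
            mem = ct[labels == m]
            types, cnts = np.unique(mem, return_counts=True)
            best = cnts.max()
            if best / mem.size > META2_PURITY_RULE:
                annotations[m] = sorted(types[cnts == best])[0]
    if len(uniq_cond) < 2:
        warnings.warn("single condition: proportions computed, abundance test disabled")
    return Meta2Assignment(
        labels=labels,
        conditions=conditions,
        samples=samples,
        proportions=props,
        annotations=annotations,
        focal_condition=str(focal_condition),
    )


def test_differential_abundance(
    meta2: Meta2Assignment,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    alpha: float = DEFAULT_DA_ALPHA,
    seed: int = 0,
    alternative: str = "two-sided",
) -> Meta2Assignment:
    """Permutation test for condition enrichment per meta2cell.

    The metacell-to-meta2cell assignment is permuted (meta2cell sizes are
    preserved exactly); the null distribution of each meta2cell's
    focal-condition proportion yields an add-one empirical p-value
    (two-sided by default: ``min(1, 2 * min(p_high, p_low))``). Significance
    at ``p < alpha`` (default 0.1).
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    if len(pd.unique(meta2.conditions)) < 2:
        # degenerate null: every permutation reproduces the observation
        warnings.warn("single condition: permutation null equals the observation; p = 1")
        meta2.pvalues = np.ones(meta2.n_meta2)
        meta2.significant = np.zeros(meta2.n_meta2, dtype=bool)
        return meta2
    rng = np.random.default_rng(seed)
    labels = meta2.labels
    n = labels.shape[0]
    m2 = meta2.n_meta2
    z = (meta2.conditions == meta2.focal_condition).astype(float)
    sizes = np.bincount(labels, minlength=m2).astype(float)
    ind = sparse.csr_matrix(
        (np.ones(n) , (labels, np.arange(n))), shape=(m2, n)
    ).multiply(1.0 / sizes[:, None]).tocsr()
    obs = ind @ z

    ge = np.zeros(m2, dtype=np.int64)
    le = np.zeros(m2, dtype=np.int64)
    batch = 250
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        Z = np.empty((n, b))
        for c in range(b):
            Z[:, c] = z[rng.permutation(n)]
        P = ind @ Z  # m2 x b null proportions
        ge += (P >= obs[:, None] - 1e-12).sum(axis=1)
        le += (P <= obs[:, None] + 1e-12).sum(axis=1)
        done += b
    p_hi = (1.0 + ge) / (1.0 + n_permutations)
    p_lo = (1.0 + le) / (1.0 + n_permutations)
    if alternative == "greater":
        pvals = p_hi
    else:
        pvals = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    meta2.pvalues = pvals
    meta2.significant = pvals < alpha
    return meta2
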