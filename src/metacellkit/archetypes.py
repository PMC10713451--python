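"""Kernel archetypal analysis.

Decomposes the cell-cell affinity kernel M (n x n) as M ~= M B A where
B (n x s) expresses each archetype as a convex combination of cells and
A (s x n) expresses each cell as a convex combination of archetypes; both
are column-stochastic. The squared reconstruction error

    SRE = || M - M B A ||_F^2

is minimized by alternating Frank-Wolfe passes over the simplex-constrained
columns of A and B, with exact line search on the quadratic objective.
Initialization combines per-diffusion-component maximum-minimum waypoint
sampling with greedy column-subset selection on the kernel.

All heavy products exploit that M is sparse and that Frank-Wolfe iterates
of A and B stay sparse (each pass adds at most one vertex per column):
products with M run sparse x sparse, everything else is dense BLAS.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import sparse

from .types import (
    CellMatrix,
    Decomposition,
    DiffusionEmbedding,
    KernelMatrix,
    MetacellAssignment,
    MetacellCounts,
)

DEFAULT_CELLS_PER_METACELL = 75
DEFAULT_TRIVIAL_THRESHOLD = 0.05
DEFAULT_MAX_ITER = 150
DEFAULT_TOL = 1e-5
CONFIDENCE_BIN_EDGES = (0.0, 0.5, 0.8, 0.9, 1.0 + 1e-12)
_B_BATCH = 32  # Gauss-Seidel batch width for archetype (B) updates


def suggest_n_metacells(
    n_cells: int, cells_per_metacell: int = DEFAULT_CELLS_PER_METACELL
) -> int:
    """Heuristic number of metacells: one per ``cells_per_metacell`` cells."""
    if n_cells < cells_per_metacell:
        raise ValueError(
            f"n_cells={n_cells} is below cells_per_metacell={cells_per_metacell}"
        )
    return math.ceil(n_cells / cells_per_metacell)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _maxmin_1d(values: np.ndarray, n_pick: int, first: int) -> list[int]:
    """Max-min sampling on a single 1-D component, seeded at ``first``."""
    n = values.shape[0]
    n_pick = min(n_pick, n)
    picked = [first]
    mind = np.abs(values - values[first])
    while len(picked) < n_pick:
        nxt = int(np.argmax(mind))  # ties -> lowest index
        picked.append(nxt)
        np.minimum(mind, np.abs(values - values[nxt]), out=mind)
    return picked


def _greedy_css(M: sparse.csr_matrix, n_pick: int, exclude: set[int]) -> list[int]:
    """Greedy column-subset selection on the kernel.

    Column-pivoted Gram-Schmidt: at each step the candidate column with the
    largest residual norm (after projecting out the selected columns) is
    added, greedily growing a basis that best captures the kernel's column
    space. Deterministic; ties break to the lowest index.
    """
    n = M.shape[0]
    res2 = np.asarray(M.multiply(M).sum(axis=0)).ravel()  # ||M_c||^2
    Mc = M.tocsc()
    basis: list[np.ndarray] = []
    picked: list[int] = []
    res2[list(exclude)] = -np.inf
    for _ in range(n_pick):
        c = int(np.argmax(res2))
        if not np.isfinite(res2[c]) or res2[c] <= 1e-12:
            # kernel column space exhausted; fall back to unused indices
            for j in range(n):
                if j not in exclude and j not in picked:
                    picked.append(j)
                    if len(picked) == n_pick:
                        break
            break
        col = np.asarray(Mc[:, c].todense()).ravel()
        for q in basis:
            col -= (q @ col) * q
        nrm = np.linalg.norm(col)
        if nrm > 1e-12:
            q = col / nrm
            basis.append(q)
            proj = M @ q  # M symmetric: row of q^T M
            res2 -= proj**2
        picked.append(c)
        res2[c] = -np.inf
    return picked[:n_pick]


def sample_waypoints(
    dcs: DiffusionEmbedding,
    kernel: KernelMatrix,
    n_waypoints: int,
    maxmin_proportion: float = 1.0,
    seed: int | None = 0,
    start: str = "random",
) -> np.ndarray:
    """Select ``n_waypoints`` initialization cells.

    ``ceil(maxmin_proportion * n_waypoints)`` cells come from per-component
    max-min sampling of the diffusion components (pooled round-robin and
    de-duplicated); greedy column-subset selection on the kernel fills the
    remainder. The first waypoint of each component is drawn from the seeded
    RNG (``start="extremal"`` uses the component's extremal cell instead,
    making the initialization fully deterministic).
    """
    n = kernel.n_cells
    if not 1 <= n_waypoints <= n:
        raise ValueError(f"n_waypoints={n_waypoints} must be in [1, {n}]")
    if not 0.0 <= maxmin_proportion <= 1.0:
        raise ValueError("maxmin_proportion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    target = math.ceil(maxmin_proportion * n_waypoints)
    comps = dcs.dcs
    n_comp = comps.shape[1]
    picked: list[int] = []
    if target > 0 and n_comp > 0:
        per_comp = math.ceil(target / n_comp)
        per_component_lists = []
        for c in range(n_comp):
            vals = comps[:, c]
            if start == "extremal":
                first = int(np.argmax(np.abs(vals)))
            else:
                first = int(rng.integers(n))
            per_component_lists.append(_maxmin_1d(vals, per_comp, first))
        # round-robin pooling preserves the max-min ordering within components
        seen: set[int] = set()
        for rank in range(per_comp):
            for lst in per_component_lists:
                if rank < len(lst) and lst[rank] not in seen:
                    seen.add(lst[rank])
                    picked.append(lst[rank])
        picked = picked[:target]
    if len(picked) < n_waypoints:
        fill = _greedy_css(kernel.affinities, n_waypoints - len(picked), set(picked))
        picked.extend(fill)
    return np.asarray(picked[:n_waypoints], dtype=int)


# ---------------------------------------------------------------------------
# Frank-Wolfe optimization
# ---------------------------------------------------------------------------


def _init_A(T: np.ndarray, init: np.ndarray, n: int, s: int) -> np.ndarray:
    """Indicator initialization of A: each cell joins its highest-affinity
    waypoint archetype; waypoint cells join their own archetype."""
    labels = np.argmax(T, axis=1)
    no_signal = T[np.arange(n), labels] <= 0
    labels[no_signal] = np.arange(n)[no_signal] % s
    labels[init] = np.arange(s)
    A = np.zeros((s, n))
    A[labels, np.arange(n)] = 1.0
    return A


def _fw_pass_A(
    A: np.ndarray,
    H: np.ndarray,
    V: np.ndarray,
    HA: np.ndarray,
    cols: np.ndarray,
) -> np.ndarray:
    """One Frank-Wolfe pass over the given columns of A (in place).

    The A subproblem separates over columns, so each column takes its own
    exact line-search step toward the most-negative-gradient vertex. ``HA``
    is maintained incrementally (it is linear in A): the column update
    ``A_j <- (1-g) A_j + g e_i`` maps to ``HA_j <- (1-g) HA_j + g H_i``.
    Returns each column's objective improvement, letting the caller shrink
    the active set to columns that still make progress.
    """
    full = cols.size == A.shape[1]
    Asub = A if full else A[:, cols]
    HAsub = HA if full else HA[:, cols]
    Vsub = V if full else V[:, cols]
    W = HAsub - Vsub  # gradient / 2
    istar = np.argmin(W, axis=0)
    rng_ = np.arange(cols.size)
    e_aha = np.einsum("tj,tj->j", Asub, HAsub)
    e_av = np.einsum("tj,tj->j", Asub, Vsub)
    num = W[istar, rng_] - (e_aha - e_av)
    den = H[istar, istar] - 2.0 * HAsub[istar, rng_] + e_aha
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where((num < 0) & (den > 0), -num / den, 0.0)
    gamma = np.clip(gamma, 0.0, 1.0)
    if full:
        A *= 1.0 - gamma
        A[istar, rng_] += gamma
        HA *= 1.0 - gamma
        HA += H[:, istar] * gamma
    else:
        A[:, cols] = Asub * (1.0 - gamma)
        A[istar, cols] += gamma
        HA[:, cols] = HAsub * (1.0 - gamma) + H[:, istar] * gamma
    # per-column objective improvement num^2 / (2 den) = -num * gamma / 2
    return -num * gamma


def _sre_from_parts(m2: float, V: np.ndarray, A: np.ndarray, HA: np.ndarray) -> float:
    """SRE via the trace identity using the maintained products
    V = (M^2 B)^T and HA = (T^T T) A."""
    return (
        m2
        - 2.0 * float(np.einsum("tj,tj->", V, A))
        + float(np.einsum("tj,tj->", HA, A))
    )


def fit_kernel_archetypes(
    kernel: KernelMatrix,
    s: int,
    init: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    min_iter: int = 10,
    conv_window: int = 3,
    inner_iter: int = 4,
    inner_iter_b: int = 1,
) -> Decomposition:
    """Alternating Frank-Wolfe minimization of ``||M - M B A||^2``.

    ``init`` supplies ``s`` unique cell indices; B starts as indicator
    columns on those cells. Each outer iteration runs ``inner_iter``
    Frank-Wolfe passes on the (convex) A subproblem — per-column
    most-negative-gradient vertex with exact line search clipped to [0, 1] —
    then ``inner_iter_b`` joint-direction passes on the B subproblem, each
    with one exact global step (B's columns couple through A, so the joint
    line search keeps every pass monotone; each B pass costs two dense
    n x s x s products, hence the lower default). Stops when the relative SRE decrease
    stays below ``tol`` for ``conv_window`` consecutive outer iterations
    (after ``min_iter``) or at ``max_iter``; a final A polish then runs the
    membership subproblem to convergence for the fitted archetypes.
    """
    M = kernel.affinities.tocsr()
    n = M.shape[0]
    if s > n:
        raise ValueError(f"s={s} cannot exceed the number of cells ({n})")
    init = np.asarray(init, dtype=int)
    if init.shape[0] != s or len(np.unique(init)) != s:
        raise ValueError("init must hold s unique cell indices")
    asym = abs(M - M.T)
    if asym.nnz and asym.max() > 1e-10:
        raise ValueError("kernel matrix must be symmetric")

    m2 = float(M.multiply(M).sum())  # ||M||_F^2
    Mcsc = M.tocsc()
    arcs = np.arange(s)

    B = np.zeros((n, s))
    B[init, arcs] = 1.0
    T = (M @ sparse.csc_matrix(B)).toarray()
    U = (M @ sparse.csc_matrix(T)).toarray()  # M^2 B
    A = _init_A(T, init, n, s)

    sre_trace: list[float] = []
    below = 0
    converged = False
    H = T.T @ T
    V = U.T
    HA = H @ A
    sre_trace.append(_sre_from_parts(m2, V, A, HA))  # objective at init
    for _ in range(max_iter):
        # ---- A block: inner FW passes on the convex membership problem;
        # after the first full pass only columns still making measurable
        # progress are revisited ----
        active = np.arange(n)
        for _ in range(inner_iter):
            improvement = _fw_pass_A(A, H, V, HA, active)
            if improvement.size == 0 or improvement.max() <= 0:
                break
            active = active[improvement > 1e-3 * improvement.max()]
            if active.size == 0:
                break

        # ---- B block: batched Gauss-Seidel Frank-Wolfe sweeps. Each batch
        # of columns takes a joint most-negative-gradient direction with one
        # exact line search (monotone by construction); small batches give
        # near per-column granularity while staying vectorized. ----
        # negligible membership weights (decayed FW vertices) are pruned
        # before the sparse product; the gradient perturbation is ~1e-8 of
        # scale, far below the line-search tolerances
        As = sparse.csr_matrix(np.where(A >= 1e-8, A, 0.0))
        P = A @ A.T  # s x s
        MQ = (M @ (M @ As.T)).toarray()  # M^2 A^T
        for _ in range(inner_iter_b):
            moved = False
            for start in range(0, s, _B_BATCH):
                bt = arcs[start : start + _B_BATCH]
                Wb = U @ P[:, bt] - MQ[:, bt]  # gradient / 2 on the batch
                istar = np.argmin(Wb, axis=0)
                rng_b = np.arange(bt.size)
                percol = Wb[istar, rng_b] - np.einsum("ib,ib->b", B[:, bt], Wb)
                sel = percol < 0  # batch columns with a descent vertex
                if not sel.any():
                    continue
                act = bt[sel]
                numB = float(percol[sel].sum())
                ist = istar[sel]
                MV_sp = Mcsc[:, ist]
                MV = MV_sp.toarray()
                MD = MV - T[:, act]  # M (vertex - B) on the active columns
                G = MD.T @ MD
                denB = float(np.einsum("ts,ts->", G, P[np.ix_(act, act)]))
                if denB <= 0:
                    continue
                gammaB = min(max(-numB / denB, 0.0), 1.0)
                if gammaB <= 1e-12:
                    continue
                B[:, act] *= 1.0 - gammaB
                B[ist, act] += gammaB
                # incremental updates keep T = M B and U = M^2 B exact
                T[:, act] *= 1.0 - gammaB
                T[:, act] += gammaB * MV
                U[:, act] *= 1.0 - gammaB
                U[:, act] += gammaB * (M @ MV_sp).toarray()
                moved = True
            if not moved:
                break

        # refresh products that depend on B, record the objective
        H = T.T @ T
        V = U.T
        HA = H @ A
        sre = _sre_from_parts(m2, V, A, HA)
        prev = sre_trace[-1]
        rel = (prev - sre) / max(abs(prev), 1e-300)
        below = below + 1 if rel < tol else 0
        sre_trace.append(sre)
        if len(sre_trace) - 1 >= min_iter and below >= conv_window:
            converged = True
            break

    # final A polish: solve the membership problem for the fitted archetypes
    prev = sre_trace[-1]
    active = np.arange(n)
    for _ in range(50):
        improvement = _fw_pass_A(A, H, V, HA, active)
        if improvement.size == 0 or improvement.max() <= 0:
            break
        active = active[improvement > 1e-4 * improvement.max()]
        if active.size == 0:
            break
        cur = _sre_from_parts(m2, V, A, HA)
        if prev - cur < tol * max(abs(cur), 1e-300):
            prev = min(prev, cur)
            break
        prev = cur

    final = _sre_from_parts(m2, V, A, HA)
    if final <= sre_trace[-1] + 1e-9:
        sre_trace.append(final)
    return Decomposition(
        A=sparse.csr_matrix(A),
        B=sparse.csr_matrix(B),
        s=s,
        sre_trace=np.asarray(sre_trace),
        converged=converged,
        init_cells=init,
    )


def reconstruction_error(kernel: KernelMatrix, A, B) -> float:
    """``||M - M B A||_F^2`` via the trace identity, without densifying M."""
    M = kernel.affinities.tocsr()
    n = M.shape[0]
    A = np.asarray(A.todense() if sparse.issparse(A) else A, dtype=float)
    B = np.asarray(B.todense() if sparse.issparse(B) else B, dtype=float)
    if B.shape[0] != n or A.shape[1] != n or A.shape[0] != B.shape[1]:
        raise ValueError(
            f"shape mismatch: M {M.shape}, B {B.shape}, A {A.shape}"
        )
    T = (M @ sparse.csc_matrix(B)).toarray()
    V = (M @ sparse.csc_matrix(T)).toarray().T
    H = T.T @ T
    sre = (
        float(M.multiply(M).sum())
        - 2.0 * float(np.einsum("tj,tj->", V, A))
        + float(np.einsum("ts,ts->", H, A @ A.T))
    )
    return max(sre, 0.0)


# ---------------------------------------------------------------------------
# hard assignment and aggregation
# ---------------------------------------------------------------------------


def hard_assignments(
    decomposition: Decomposition,
    trivial_threshold: float = DEFAULT_TRIVIAL_THRESHOLD,
) -> MetacellAssignment:
    """Binarize the membership matrix A into metacell labels.

    Per cell, weights below ``trivial_threshold`` are zeroed as
    regularization, the remainder renormalized to sum 1, and the label is
    the argmax (ties break to the lowest metacell index).
    """
    A = np.asarray(decomposition.A.todense())
    s, n = A.shape
    kept = np.where(A >= trivial_threshold, A, 0.0)
    colsum = kept.sum(axis=0)
    dead = colsum <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} cells had all assignment weights below "
            f"{trivial_threshold}; assigned by pre-threshold argmax"
        )
        top = np.argmax(A[:, dead], axis=0)
        kept[:, dead] = 0.0
        kept[top, np.flatnonzero(dead)] = 1.0
        colsum = kept.sum(axis=0)
    weights = kept / colsum
    labels = np.argmax(weights, axis=0)
    max_weight = weights[labels, np.arange(n)]
    n_nontrivial = (weights > 0).sum(axis=0)
    return MetacellAssignment(
        labels=labels,
        soft_weights=sparse.csr_matrix(weights),
        max_weight=max_weight,
        n_nontrivial=n_nontrivial,
    )


def aggregate_metacell_counts(
    counts: CellMatrix,
    assignment: MetacellAssignment,
    celltypes: np.ndarray | None = None,
) -> MetacellCounts:
    """Sum raw counts over the cells of each metacell.

    Empty metacells (possible when the requested number of archetypes
    exceeds the data's structure) are dropped with a warning and the
    remaining metacells re-indexed.
    """
    labels = assignment.labels
    n = counts.n_cells
    if labels.shape[0] != n:
        raise ValueError("assignment does not cover all cells")
    s = assignment.n_metacells
    if labels.min() < 0 or labels.max() >= s:
        raise ValueError("metacell label out of range")
    sizes = np.bincount(labels, minlength=s)
    keep = np.flatnonzero(sizes > 0)
    if keep.size < s:
        warnings.warn(f"dropping {s - keep.size} empty metacells and re-indexing")
    remap = -np.ones(s, dtype=int)
    remap[keep] = np.arange(keep.size)
    new_labels = remap[labels]
    ind = sparse.csr_matrix(
        (np.ones(n), (new_labels, np.arange(n))), shape=(keep.size, n)
    )
    values = (ind @ counts.values).tocsr()
    sizes = sizes[keep]
    celltype = purity = None
    if celltypes is not None:
        celltypes = np.asarray(celltypes)
        celltype = np.empty(keep.size, dtype=object)
        purity = np.empty(keep.size)
        for m in range(keep.size):
            members = celltypes[new_labels == m]
            types, cnts = np.unique(members, return_counts=True)
            best = cnts.max()
            celltype[m] = sorted(types[cnts == best])[0]  # ties lexicographic
            purity[m] = best / members.size
    return MetacellCounts(
        values=values,
        sizes=sizes,
        feature_ids=counts.feature_ids,
        metacell_ids=np.array([f"MC-{m}" for m in range(keep.size)]),
        celltype=celltype,
        purity=purity,
    )


def normalize_metacell_counts(mc: MetacellCounts) -> np.ndarray:
    """Depth-normalize metacell counts to the median total, then log with
    pseudocount 0.1: ``log(count / total * median_total + 0.1)``."""
    totals = np.asarray(mc.values.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = mc.metacell_ids[int(np.argmin(totals))]
        raise ValueError(f"metacell {bad!r} has zero total count")
    med = np.median(totals)
    scaled = np.asarray(mc.values.multiply(med / totals[:, None]).todense())
    return np.log(scaled + 0.1)


def summarize_assignment_confidence(assignment: MetacellAssignment) -> dict:
    """Histogram the per-cell maximal assignment weight over the bins
    [0, 0.5), [0.5, 0.8), [0.8, 0.9), [0.9, 1], plus the distribution of the
    number of non-trivially assigned metacells per cell."""
    edges = np.asarray(CONFIDENCE_BIN_EDGES)
    counts, _ = np.histogram(assignment.max_weight, bins=edges)
    nnt = np.bincount(assignment.n_nontrivial)
    return {
        "bin_edges": (0.0, 0.5, 0.8, 0.9, 1.0),
        "bin_counts": counts,
        "n_nontrivial_counts": nnt,
        "n_cells": assignment.n_cells,
    }
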