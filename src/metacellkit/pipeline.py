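"""End-to-end metacell inference: embedding -> kNN -> adaptive kernel ->
diffusion components -> waypoint initialization -> kernel archetypal fit ->
hard assignment -> aggregation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import archetypes, preprocess
from .types import (
    CellMatrix,
    Decomposition,
    DiffusionEmbedding,
    Embedding,
    KernelMatrix,
    MetacellAssignment,
    MetacellCounts,
)


@dataclass
class MetacellResult:
    embedding: Embedding
    kernel: KernelMatrix
    dcs: DiffusionEmbedding
    decomposition: Decomposition
    assignment: MetacellAssignment
    counts: Optional[MetacellCounts]
    seed: int
    params: dict


def compute_metacells(
    counts: CellMatrix | None = None,
    embedding: Embedding | None = None,
    n_metacells: int | None = None,
    cells_per_metacell: int = archetypes.DEFAULT_CELLS_PER_METACELL,
    n_hvg: int = preprocess.DEFAULT_N_HVG,
    n_components: int | None = None,
    k: int = preprocess.DEFAULT_K,
    l: int = preprocess.DEFAULT_L,
    n_dcs: int = preprocess.DEFAULT_N_DCS,
    kernel_support: str = "union",
    maxmin_proportion: float = 1.0,
    trivial_threshold: float = archetypes.DEFAULT_TRIVIAL_THRESHOLD,
    max_iter: int = archetypes.DEFAULT_MAX_ITER,
    tol: float = archetypes.DEFAULT_TOL,
    celltypes: np.ndarray | None = None,
    aggregate: bool = True,
    seed: int = 0,
) -> MetacellResult:
    """Run the full metacell pipeline on a count matrix or a precomputed
    embedding.

    When ``counts`` is given and ``embedding`` is not, the modality's
    standard embedding is computed (PCA on log-normalized HVGs for RNA,
    TF-IDF + SVD for ATAC). ``n_metacells`` defaults to the one-per-75-cells
    heuristic. All randomness derives from ``seed``.
    """
    if counts is None and embedding is None:
        raise ValueError("provide counts and/or a precomputed embedding")
    if embedding is None:
        if counts.modality == "rna":
            normalized, _ = preprocess.normalize_expression(counts, n_hvg=n_hvg)
            embedding = preprocess.compute_embedding(
                normalized, modality="rna", n_components=n_components, seed=seed
            )
        else:
            embedding = preprocess.compute_embedding(
                counts, modality="atac", n_components=n_components, seed=seed
            )
    n = embedding.coords.shape[0]
    if n_metacells is None:
        n_metacells = archetypes.suggest_n_metacells(n, cells_per_metacell)
    k_eff = min(k, n - 1)
    l_eff = min(l, k_eff - 1) if k_eff > 1 else 1
    graph = preprocess.build_knn_graph(embedding, k=k_eff)
    kernel = preprocess.compute_adaptive_kernel(
        graph, embedding, l=l_eff, kernel_support=kernel_support
    )
    dcs = preprocess.diffusion_map(kernel, n_dcs=min(n_dcs, n - 1))
    waypoints = archetypes.sample_waypoints(
        dcs, kernel, n_metacells, maxmin_proportion=maxmin_proportion, seed=seed
    )
    decomposition = archetypes.fit_kernel_archetypes(
        kernel, n_metacells, waypoints, max_iter=max_iter, tol=tol
    )
    assignment = archetypes.hard_assignments(decomposition, trivial_threshold)
    mc = None
    if aggregate and counts is not None:
        mc = archetypes.aggregate_metacell_counts(counts, assignment, celltypes=celltypes)
    return MetacellResult(
        embedding=embedding,
        kernel=kernel,
        dcs=dcs,
        decomposition=decomposition,
        assignment=assignment,
        counts=mc,
        seed=seed,
        params={
            "n_metacells": n_metacells,
            "cells_per_metacell": cells_per_metacell,
            "k": k_eff,
            "l": l_eff,
            "n_dcs": n_dcs,
            "kernel_support": kernel_support,
            "trivial_threshold": trivial_threshold,
            "max_iter": max_iter,
            "tol": tol,
        },
    )
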