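"""Synthetic multiome and cohort generators with known ground truth.

The generators emulate the data regimes the metacell machinery is meant to
handle: discrete cell states (including rare populations), a continuous
trajectory mode, coupled RNA/ATAC programs with planted peak-gene links, an
ATAC fragment-length mixture with a nucleosome-free mode, and a multi-sample
cohort with condition-enriched states. Counts are negative binomial
(gamma-Poisson) around state means with log-normal per-cell library sizes.

Every stochastic choice flows from the single ``seed`` argument; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .types import CellMatrix, FragmentSet, PeakSet

# study-condition defaults
DEFAULT_N_CELLS = 10_000
DEFAULT_N_GENES = 1_000
DEFAULT_N_PEAKS = 2_000
DEFAULT_N_STATES = 20
DEFAULT_COUPLING = 0.8
DEFAULT_NB_DISPERSION = 0.5
DEFAULT_RNA_DEPTH = 2_000
DEFAULT_ATAC_DEPTH = 2_000
DEFAULT_NFR_WEIGHT = 0.6
PROGRAM_GENES_PER_STATE = 40
PROGRAM_PEAKS_PER_STATE = 80
PROGRAM_EFFECT = 6.0
PEAK_WIDTH = 500
PEAK_SPACING = 2_000
PEAKS_PER_CHROM = 500


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic multiome draw."""

    state: np.ndarray  # per-cell state label
    state_frequencies: np.ndarray
    expression_profiles: np.ndarray  # states x genes relative expression
    accessibility_profiles: Optional[np.ndarray] = None  # states x peaks
    planted_links: Optional[pd.DataFrame] = None  # gene, peak, coupling
    nfr_weight: float = DEFAULT_NFR_WEIGHT
    fragment_modes: tuple = ((70.0, 20.0), (220.0, 30.0))
    pseudotime: Optional[np.ndarray] = None
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class SimulatedMultiome:
    rna: Optional[CellMatrix]
    atac: Optional[CellMatrix]
    fragments: Optional[FragmentSet]
    peaks: Optional[PeakSet]
    genes: Optional[pd.DataFrame]  # gene, chrom, start, end
    truth: SyntheticTruth


@dataclass
class SimulatedCohort:
    samples: dict  # sample_id -> CellMatrix
    manifest: pd.DataFrame  # sample_id, condition
    celltypes: dict  # sample_id -> per-cell state names
    truth: SyntheticTruth


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _state_frequencies(n_states: int, rare_fractions: Sequence[float] | None) -> np.ndarray:
    rare = np.asarray(rare_fractions if rare_fractions is not None else [], dtype=float)
    if rare.size >= n_states:
        raise ValueError("rare_fractions must leave at least one common state")
    if rare.sum() >= 1.0:
        raise ValueError("rare fractions must sum to < 1")
    freqs = np.empty(n_states)
    freqs[: rare.size] = rare
    freqs[rare.size :] = (1.0 - rare.sum()) / (n_states - rare.size)
    return freqs


def _program_profiles(
    rng: np.random.Generator,
    n_states: int,
    n_features: int,
    per_state: int,
    effect: float,
) -> np.ndarray:
    """Relative feature profile per state: a log-normal baseline boosted on a
    state-specific random program; rows sum to 1."""
    base = rng.lognormal(mean=0.0, sigma=0.5, size=n_features)
    profiles = np.tile(base, (n_states, 1))
    for s in range(n_states):
        program = rng.choice(n_features, size=min(per_state, n_features), replace=False)
        profiles[s, program] *= effect
    return profiles / profiles.sum(axis=1, keepdims=True)


def _toy_peak_atlas(n_peaks: int, rng: np.random.Generator) -> PeakSet:
    chroms = [f"chr{i + 1}" for i in range(int(np.ceil(n_peaks / PEAKS_PER_CHROM)))]
    rows = []
    for p in range(n_peaks):
        c = p // PEAKS_PER_CHROM
        offset = (p % PEAKS_PER_CHROM) * PEAK_SPACING + 1_000
        rows.append((chroms[c], offset, offset + PEAK_WIDTH, f"peak_{p}"))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])
    gc = rng.uniform(0.3, 0.7, size=n_peaks)
    return PeakSet(intervals=intervals, gc_content=gc)


def _toy_gene_annotations(
    n_genes: int, peaks: PeakSet, planted: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Place gene bodies on the toy contigs; planted-link genes are placed
    adjacent to their partner peak so the link falls inside the +/-100 kb
    candidate window."""
    iv = peaks.intervals
    pos = {}
    planted_gene_to_peak = dict(zip(planted["gene"], planted["peak"])) if planted is not None else {}
    peak_lookup = iv.set_index("peak_id")
    for g in range(n_genes):
        name = f"gene_{g}"
        if name in planted_gene_to_peak:
            prow = peak_lookup.loc[planted_gene_to_peak[name]]
            start = int(prow["end"]) + int(rng.integers(1_000, 20_000))
            pos[name] = (prow["chrom"], start, start + 1_000)
        else:
            prow = iv.iloc[int(rng.integers(len(iv)))]
            start = int(prow["start"]) + int(rng.integers(-50_000, 50_000))
            pos[name] = (prow["chrom"], max(start, 0), max(start, 0) + 1_000)
    return pd.DataFrame(
        [(g, c, s, e) for g, (c, s, e) in pos.items()],
        columns=["gene", "chrom", "start", "end"],
    )


def simulate_multiome(
    n_cells: int = DEFAULT_N_CELLS,
    n_genes: int = DEFAULT_N_GENES,
    n_peaks: int = DEFAULT_N_PEAKS,
    n_states: int = DEFAULT_N_STATES,
    rare_fractions: Sequence[float] | None = None,
    coupling: float = DEFAULT_COUPLING,
    n_planted_links: int = 50,
    dispersion: float = DEFAULT_NB_DISPERSION,
    rna_depth: float = DEFAULT_RNA_DEPTH,
    atac_depth: float = DEFAULT_ATAC_DEPTH,
    nfr_weight: float = DEFAULT_NFR_WEIGHT,
    mode: str = "discrete",
    modalities: Sequence[str] = ("rna", "atac"),
    with_fragments: bool = True,
    seed: int = 0,
) -> SimulatedMultiome:
    """Draw a synthetic multiome dataset with known state structure.

    ``rare_fractions`` plants rare populations (e.g. ``[0.002]`` for a 0.2%
    state) occupying the first state labels. ``coupling`` in [0, 1] sets how
    strongly each planted peak's accessibility profile follows its partner
    gene's expression profile across states. ``mode="trajectory"`` replaces
    discrete states with a latent 1-D pseudotime and smoothly interpolated
    programs.
    """
    rng = np.random.default_rng(seed)
    if rare_fractions is not None:
        for f in rare_fractions:
            if f * n_cells < 1:
                raise ValueError(f"rare fraction {f} yields < 1 cell at n_cells={n_cells}")

    if mode == "trajectory":
        return _simulate_trajectory(
            rng, n_cells, n_genes, n_states, dispersion, rna_depth, seed
        )
    if mode != "discrete":
        raise ValueError("mode must be 'discrete' or 'trajectory'")

    freqs = _state_frequencies(n_states, rare_fractions)
    state = rng.choice(n_states, size=n_cells, p=freqs)
    expr = _program_profiles(rng, n_states, n_genes, PROGRAM_GENES_PER_STATE, PROGRAM_EFFECT)

    rna = atac = fragments = peaks = genes = None
    acc = None
    planted = None
    cell_ids = np.array([f"cell_{i}" for i in range(n_cells)])

    if "rna" in modalities:
        lib = rng.lognormal(np.log(rna_depth), 0.35, size=n_cells)
        mu = lib[:, None] * expr[state]
        counts = _nb_counts(rng, mu, dispersion)
        rna = CellMatrix(
            values=sparse.csr_matrix(counts),
            cell_ids=cell_ids,
            feature_ids=np.array([f"gene_{g}" for g in range(n_genes)]),
            modality="rna",
        )

    if "atac" in modalities:
        acc = _program_profiles(rng, n_states, n_peaks, PROGRAM_PEAKS_PER_STATE, PROGRAM_EFFECT)
        # plant peak-gene couplings: the peak's cross-state accessibility
        # profile tracks the partner gene's expression profile. Links are
        # planted on well-expressed genes and well-covered peaks (as real
        # regulatory links are): a link on a count-starved gene could never
        # show correlation at any coupling strength
        n_links = min(n_planted_links, n_genes // 2, n_peaks // 2)
        # cross-state standard deviation favors genes that are both expressed
        # and state-variable; a flat gene has no correlation to detect
        expressed = np.argsort(-expr.std(axis=0))[: n_genes // 2]
        covered = np.argsort(-acc.mean(axis=0))[: n_peaks // 2]
        link_genes = rng.choice(expressed, size=n_links, replace=False)
        link_peaks = rng.choice(covered, size=n_links, replace=False)
        for g, p in zip(link_genes, link_peaks):
            gene_prof = expr[:, g] / expr[:, g].sum()
            peak_prof = acc[:, p] / acc[:, p].sum()
            mixed = coupling * gene_prof + (1 - coupling) * peak_prof
            acc[:, p] = mixed * acc[:, p].sum()
        acc = acc / acc.sum(axis=1, keepdims=True)
        planted = pd.DataFrame(
            {
                "gene": [f"gene_{g}" for g in link_genes],
                "peak": [f"peak_{p}" for p in link_peaks],
                "coupling": coupling,
            }
        )
        lib_a = rng.lognormal(np.log(atac_depth), 0.4, size=n_cells)
        mu_a = lib_a[:, None] * acc[state]
        counts_a = _nb_counts(rng, mu_a, dispersion)
        peaks = _toy_peak_atlas(n_peaks, rng)
        genes = _toy_gene_annotations(n_genes, peaks, planted, rng)
        atac = CellMatrix(
            values=sparse.csr_matrix(counts_a),
            cell_ids=cell_ids,
            feature_ids=peaks.peak_ids.copy(),
            modality="atac",
        )
        if with_fragments:
            fragments = _draw_fragments(rng, counts_a, peaks, cell_ids, nfr_weight)

    truth = SyntheticTruth(
        state=state,
        state_frequencies=freqs,
        expression_profiles=expr,
        accessibility_profiles=acc,
        planted_links=planted,
        nfr_weight=nfr_weight,
        seed=seed,
        params={
            "n_cells": n_cells,
            "n_genes": n_genes,
            "n_peaks": n_peaks,
            "n_states": n_states,
            "coupling": coupling,
            "dispersion": dispersion,
            "rna_depth": rna_depth,
            "atac_depth": atac_depth,
        },
    )
    return SimulatedMultiome(
        rna=rna, atac=atac, fragments=fragments, peaks=peaks, genes=genes, truth=truth
    )


def _simulate_trajectory(rng, n_cells, n_genes, n_states, dispersion, rna_depth, seed):
    """Latent 1-D pseudotime with smoothly varying gene programs."""
    tau = np.sort(rng.uniform(0.0, 1.0, size=n_cells))
    base = rng.lognormal(0.0, 0.5, size=n_genes)
    kind = rng.choice(3, size=n_genes, p=[0.35, 0.35, 0.3])  # up, down, bump
    center = rng.uniform(0.2, 0.8, size=n_genes)
    scale = rng.uniform(0.05, 0.2, size=n_genes)
    amp = rng.uniform(1.0, 4.0, size=n_genes)
    t = tau[:, None]
    up = 1.0 / (1.0 + np.exp(-(t - center) / scale))
    shape = np.where(kind == 0, up, np.where(kind == 1, 1.0 - up, np.exp(-0.5 * ((t - center) / scale) ** 2)))
    mu_rel = base * (1.0 + amp * shape)
    mu_rel /= mu_rel.sum(axis=1, keepdims=True)
    lib = rng.lognormal(np.log(rna_depth), 0.35, size=n_cells)
    counts = _nb_counts(rng, lib[:, None] * mu_rel, dispersion)
    rna = CellMatrix(
        values=sparse.csr_matrix(counts),
        cell_ids=np.array([f"cell_{i}" for i in range(n_cells)]),
        feature_ids=np.array([f"gene_{g}" for g in range(n_genes)]),
        modality="rna",
    )
    state = np.minimum((tau * n_states).astype(int), n_states - 1)
    truth = SyntheticTruth(
        state=state,
        state_frequencies=np.bincount(state, minlength=n_states) / n_cells,
        expression_profiles=np.empty((0, n_genes)),
        pseudotime=tau,
        seed=seed,
        params={"mode": "trajectory", "n_cells": n_cells, "n_genes": n_genes},
    )
    return SimulatedMultiome(rna=rna, atac=None, fragments=None, peaks=None, genes=None, truth=truth)


def _draw_fragments(rng, counts, peaks: PeakSet, cell_ids, nfr_weight) -> FragmentSet:
    """Per (cell, peak) fragment records with a two-component length mixture
    (nucleosome-free mode < 147 bases, mono-nucleosomal mode above)."""
    coo = sparse.coo_matrix(counts)
    reps = coo.data.astype(int)
    cell_idx = np.repeat(coo.row, reps)
    peak_idx = np.repeat(coo.col, reps)
    n_frag = cell_idx.size
    iv = peaks.intervals
    p_start = iv["start"].to_numpy()[peak_idx]
    starts = p_start + rng.integers(0, PEAK_WIDTH - 50, size=n_frag)
    is_nfr = rng.random(n_frag) < nfr_weight
    lengths = np.where(
        is_nfr,
        np.clip(np.round(rng.normal(70.0, 20.0, n_frag)), 20, 146),
        np.clip(np.round(rng.normal(220.0, 30.0, n_frag)), 147, 400),
    ).astype(int)
    records = pd.DataFrame(
        {
            "chrom": iv["chrom"].to_numpy()[peak_idx],
            "start": starts,
            "end": starts + lengths,
            "barcode": cell_ids[cell_idx],
            "count": 1,
        }
    )
    order = np.lexsort((records["start"].to_numpy(), records["chrom"].to_numpy()))
    return FragmentSet(records=records.iloc[order].reset_index(drop=True))


def simulate_cohort(
    n_samples_per_condition: int = 8,
    n_cells_per_sample: int = 1_200,
    n_genes: int = 600,
    n_states: int = 6,
    enriched_states: Sequence[int] = (0,),
    effect_size: float = 3.0,
    conditions: Sequence[str] = ("healthy", "disease"),
    dispersion: float = DEFAULT_NB_DISPERSION,
    rna_depth: float = DEFAULT_RNA_DEPTH,
    batch_sigma: float = 0.15,
    seed: int = 0,
) -> SimulatedCohort:
    """Multi-sample cohort sharing one state space.

    ``enriched_states`` are over-represented by ``effect_size`` in the second
    condition (the "disease" arm); ``effect_size=1`` gives an exchangeable
    null. Per-sample batch structure is injected as gene-wise log-normal
    factors and library-size shifts.
    """
    if n_samples_per_condition < 1:
        raise ValueError("need at least one sample per condition")
    rng = np.random.default_rng(seed)
    expr = _program_profiles(rng, n_states, n_genes, PROGRAM_GENES_PER_STATE, PROGRAM_EFFECT)
    base_freq = np.full(n_states, 1.0 / n_states)
    enr_freq = base_freq.copy()
    for s in enriched_states:
        enr_freq[s] *= effect_size
    enr_freq /= enr_freq.sum()

    samples, celltypes, rows = {}, {}, []
    gene_ids = np.array([f"gene_{g}" for g in range(n_genes)])
    state_all = []
    for ci, cond in enumerate(conditions):
        freqs = enr_freq if ci == 1 else base_freq
        for si in range(n_samples_per_condition):
            sample_id = f"{cond}_{si}"
            batch = rng.lognormal(0.0, batch_sigma, size=n_genes)
            depth = rna_depth * rng.lognormal(0.0, 0.2)
            state = rng.choice(n_states, size=n_cells_per_sample, p=freqs)
            lib = rng.lognormal(np.log(depth), 0.35, size=n_cells_per_sample)
            prof = expr[state] * batch
            prof /= prof.sum(axis=1, keepdims=True)
            counts = _nb_counts(rng, lib[:, None] * prof, dispersion)
            samples[sample_id] = CellMatrix(
                values=sparse.csr_matrix(counts),
                cell_ids=np.array([f"{sample_id}:cell_{i}" for i in range(n_cells_per_sample)]),
                feature_ids=gene_ids,
                modality="rna",
            )
            celltypes[sample_id] = np.array([f"state_{s}" for s in state])
            state_all.append(state)
            rows.append((sample_id, cond))
    manifest = pd.DataFrame(rows, columns=["sample_id", "condition"])
    truth = SyntheticTruth(
        state=np.concatenate(state_all),
        state_frequencies=base_freq,
        expression_profiles=expr,
        seed=seed,
        params={
            "n_samples_per_condition": n_samples_per_condition,
            "n_cells_per_sample": n_cells_per_sample,
            "enriched_states": tuple(enriched_states),
            "effect_size": effect_size,
            "conditions": tuple(conditions),
        },
    )
    return SimulatedCohort(samples=samples, manifest=manifest, celltypes=celltypes, truth=truth)
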