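"""Metacell-level scATAC toolkit.

Nucleosome-free-region (NFR) fragment filtering, per-metacell peak fragment
counting with Tn5-insertion-site semantics, a Poisson open-peak test with a
MACS2-style local rate, peak-gene correlation against GC/accessibility-
matched empirical backgrounds, gene scores and gene accessibility scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .types import (
    FragmentSet,
    MetacellAssignment,
    OpenPeakMatrix,
    PeakSet,
)

DEFAULT_NFR_BOUND = 147
DEFAULT_PEAK_WIDTH = 500
DEFAULT_EFF_LENGTH_MULTIPLIER = 5_000
DEFAULT_OPEN_P_THRESHOLD = 0.01
DEFAULT_WINDOW_KB = 100
DEFAULT_N_BACKGROUND = 100
DEFAULT_N_BINS = 100
DEFAULT_LINK_P_THRESHOLD = 0.1


def filter_nfr_fragments(
    fragments: FragmentSet, max_length_exclusive: int = DEFAULT_NFR_BOUND
) -> tuple[FragmentSet, float]:
    """Retain nucleosome-free fragments: length strictly below the bound
    (147 bases, one nucleosome wrap). Returns the filtered set and the
    retained fraction."""
    lengths = fragments.lengths
    keep = lengths < max_length_exclusive
    retained = float(keep.mean()) if len(fragments) else 0.0
    out = FragmentSet(
        records=fragments.records.loc[keep].reset_index(drop=True),
        n_unmapped=fragments.n_unmapped,
    )
    return out, retained


def count_peak_fragments(
    fragments: FragmentSet,
    peaks: PeakSet,
    assignment: MetacellAssignment,
    barcodes: np.ndarray,
    dcs_metacell: np.ndarray | None = None,
    augment: bool = False,
):
    """Count fragments per (metacell, peak) by Tn5 insertion sites.

    A fragment is counted in a peak when either of its two insertion sites
    (start, or end - 1) lies within the peak interval; a fragment counts at
    most once per peak. ``barcodes`` maps assignment rows to fragment
    barcodes; fragments with unknown barcodes are dropped (their number is
    reported). With ``augment``, each metacell's per-peak counts and total
    are pooled with its two nearest metacells (centroid distance in
    ``dcs_metacell``, one row per metacell).

    Returns ``(counts, totals, n_dropped)`` where ``counts`` is a dense
    s x peaks integer array and ``totals`` holds all counted fragments per
    metacell (peak hits and misses alike contribute to totals).
    """
    s = assignment.n_metacells
    n_peaks = len(peaks)
    bc_to_mc = dict(zip(barcodes, assignment.labels))
    rec = fragments.records
    mc = rec["barcode"].map(bc_to_mc)
    known = mc.notna().to_numpy()
    n_dropped = int((~known).sum())
    rec = rec.loc[known]
    mc = mc.loc[known].to_numpy().astype(int)
    weights = rec["count"].to_numpy()

    counts = np.zeros((s, n_peaks), dtype=np.int64)
    totals = np.zeros(s, dtype=np.int64)
    np.add.at(totals, mc, weights)

    iv = peaks.intervals.reset_index(drop=True)
    frag_chroms = rec["chrom"].to_numpy()
    missing = set(pd.unique(frag_chroms)) - set(iv["chrom"].unique())
    if missing:
        warnings.warn(f"fragments on chromosomes without peaks skipped: {sorted(missing)}")
    all_starts = iv["start"].to_numpy()
    all_ends = iv["end"].to_numpy()
    all_chrom = iv["chrom"].to_numpy()
    for chrom in pd.unique(all_chrom):
        psel = all_chrom == chrom
        order = np.argsort(all_starts[psel], kind="stable")
        starts = all_starts[psel][order]
        ends = all_ends[psel][order]
        pidx = np.flatnonzero(psel)[order]
        sel = frag_chroms == chrom
        if not sel.any():
            continue
        f_start = rec.loc[sel, "start"].to_numpy()
        f_end1 = rec.loc[sel, "end"].to_numpy() - 1  # right insertion site
        f_mc = mc[sel]
        f_w = weights[sel]

        def site_hits(site):
            j = np.searchsorted(starts, site, side="right") - 1
            ok = (j >= 0) & (site < ends[np.maximum(j, 0)]) & (site >= starts[np.maximum(j, 0)])
            return j, ok

        j1, ok1 = site_hits(f_start)
        j2, ok2 = site_hits(f_end1)
        # each insertion site can hit a peak; a fragment counts at most once
        # per peak, so suppress the second site when it lands in the same peak
        dup = ok1 & ok2 & (j1 == j2)
        ok2 = ok2 & ~dup
        if ok1.any():
            np.add.at(counts, (f_mc[ok1], pidx[j1[ok1]]), f_w[ok1])
        if ok2.any():
            np.add.at(counts, (f_mc[ok2], pidx[j2[ok2]]), f_w[ok2])
    if augment:
        if dcs_metacell is None:
            raise ValueError("augment=True requires per-metacell diffusion coordinates")
        counts, totals = _augment_two_nearest(counts, totals, np.asarray(dcs_metacell))
    return counts, totals, n_dropped


def _augment_two_nearest(counts, totals, centroids):
    """Pool each metacell's counts with its two nearest metacells in
    diffusion space (low-fragment-count smoothing, applied to all metacells
    to avoid bias)."""
    s = counts.shape[0]
    if s < 3:
        return counts.copy(), totals.copy()
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nearest2 = np.argsort(d, axis=1, kind="stable")[:, :2]
    out = counts + counts[nearest2[:, 0]] + counts[nearest2[:, 1]]
    out_tot = totals + totals[nearest2[:, 0]] + totals[nearest2[:, 1]]
    return out, out_tot


def call_open_peaks(
    counts: np.ndarray,
    totals: np.ndarray | None = None,
    peak_width: int = DEFAULT_PEAK_WIDTH,
    eff_length_multiplier: int = DEFAULT_EFF_LENGTH_MULTIPLIER,
    p_threshold: float = DEFAULT_OPEN_P_THRESHOLD,
    peak_ids: np.ndarray | None = None,
) -> OpenPeakMatrix:
    """Poisson open-peak test per metacell.

    The per-metacell rate is the MACS2-style local estimate
    ``lambda = peak_width * total_fragments / (n_peaks * eff_length_multiplier)``
    and a peak with n fragments is called open when
    ``P(Poisson(lambda) > n) < p_threshold``.
    """
    counts = np.asarray(counts)
    if counts.min() < 0 or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be non-negative integers")
    s, n_peaks = counts.shape
    if totals is None:
        totals = counts.sum(axis=1)
    totals = np.asarray(totals, dtype=float)
    lam = peak_width * totals / (n_peaks * eff_length_multiplier)
    zero = lam <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} metacells have zero total fragments; all peaks closed"
        )
    # P(X > n) = sf(n); metacells with lambda = 0 get p = 1 (nothing open)
    pvals = np.ones_like(counts, dtype=float)
    ok = ~zero
    if ok.any():
        pvals[ok] = stats.poisson.sf(counts[ok], lam[ok, None])
    is_open = pvals < p_threshold
    if peak_ids is None:
        peak_ids = np.array([f"peak_{i}" for i in range(n_peaks)])
    return OpenPeakMatrix(is_open=is_open, pvalues=pvals, lam=lam, peak_ids=peak_ids)


# ---------------------------------------------------------------------------
# peak-gene associations
# ---------------------------------------------------------------------------


def _pearson_matrix(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pearson r of vector y against each column of X."""
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((yc**2).sum()) * np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ Xc) / denom
    return r


def _spearman_matrix(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    ry = stats.rankdata(y)
    rX = np.apply_along_axis(stats.rankdata, 0, X)
    return _pearson_matrix(ry, rX)


@dataclass
class _BackgroundSampler:
    """Draws background peaks from the joint (GC bin x accessibility bin)
    of a query peak; equal-frequency bin edges, sampling with replacement
    when a joint bin is small."""

    joint_bin: np.ndarray
    bin_members: dict

    @classmethod
    def build(cls, gc: np.ndarray, accessibility: np.ndarray, n_bins: int):
        def bin_ids(v):
            # equal-frequency bins via rank quantiles
            ranks = stats.rankdata(v, method="average") / (len(v) + 1)
            return np.minimum((ranks * n_bins).astype(int), n_bins - 1)

        gc_bin = bin_ids(gc)
        acc_bin = bin_ids(accessibility)
        joint = gc_bin * n_bins + acc_bin
        members = {}
        for b in np.unique(joint):
            members[b] = np.flatnonzero(joint == b)
        return cls(joint_bin=joint, bin_members=members)

    def sample(self, peak_index: int, n: int, rng: np.random.Generator) -> np.ndarray:
        pool = self.bin_members[self.joint_bin[peak_index]]
        pool = pool[pool != peak_index]  # the peak is not its own background
        if pool.size == 0:
            n_peaks = self.joint_bin.shape[0]
            pool = np.delete(np.arange(n_peaks), peak_index)
        replace = len(pool) < n
        return rng.choice(pool, size=n, replace=replace)


def correlate_peaks_genes(
    mc_expr: np.ndarray,
    gene_ids: np.ndarray,
    mc_acc: np.ndarray,
    peaks: PeakSet,
    gene_annotations: pd.DataFrame,
    window_kb: int = DEFAULT_WINDOW_KB,
    n_background: int = DEFAULT_N_BACKGROUND,
    n_bins: int = DEFAULT_N_BINS,
    p_threshold: float = DEFAULT_LINK_P_THRESHOLD,
    method: str = "pearson",
    seed: int = 0,
) -> pd.DataFrame:
    """Peak-gene association with a matched empirical null.

    For each gene, candidate peaks lie within ``window_kb`` of the gene body
    (0-based half-open intervals in ``gene_annotations``: gene, chrom, start,
    end). The observed correlation of normalized metacell accessibility with
    normalized metacell expression is compared to ``n_background`` peaks
    drawn from the candidate peak's joint (GC content x total accessibility)
    bin; the one-sided add-one empirical p is
    ``(1 + #{background r >= observed r}) / (1 + n_background)`` and a link
    is significant at ``p < p_threshold`` (default 0.1).

    Peaks or genes with zero variance across metacells are excluded with
    reason "zero variance".
    """
    if peaks.gc_content is None:
        raise ValueError("peak GC content is required for the matched background")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = _pearson_matrix if method == "pearson" else _spearman_matrix
    rng = np.random.default_rng(seed)
    mc_expr = np.asarray(mc_expr, dtype=float)
    mc_acc = np.asarray(mc_acc, dtype=float)
    if mc_expr.shape[0] != mc_acc.shape[0]:
        raise ValueError("expression and accessibility must share the metacell set")
    total_acc = mc_acc.sum(axis=0)
    sampler = _BackgroundSampler.build(peaks.gc_content, total_acc, n_bins)
    gene_pos = {
        r["gene"]: (r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in gene_annotations.iterrows()
    }
    iv = peaks.intervals
    peak_chrom = iv["chrom"].to_numpy()
    peak_start = iv["start"].to_numpy()
    peak_end = iv["end"].to_numpy()
    pid = peaks.peak_ids
    window = window_kb * 1_000
    acc_sd = mc_acc.std(axis=0)

    rows = []
    excluded = []
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for gene, (chrom, gstart, gend) in gene_pos.items():
        gi = gene_index.get(gene)
        if gi is None:
            continue
        y = mc_expr[:, gi]
        cand = np.flatnonzero(
            (peak_chrom == chrom)
            & (peak_end > gstart - window)
            & (peak_start < gend + window)
        )
        if cand.size == 0:
            continue
        if y.std() == 0:
            excluded.extend((gene, pid[c], "zero variance") for c in cand)
            continue
        r_obs = corr(y, mc_acc[:, cand])
        for ci, c in enumerate(cand):
            if acc_sd[c] == 0 or not np.isfinite(r_obs[ci]):
                excluded.append((gene, pid[c], "zero variance"))
                continue
            bg = sampler.sample(c, n_background, rng)
            r_bg = corr(y, mc_acc[:, bg])
            r_bg = r_bg[np.isfinite(r_bg)]
            p = (1.0 + np.sum(r_bg >= r_obs[ci])) / (1.0 + n_background)
            rows.append((gene, pid[c], float(r_obs[ci]), float(p), p < p_threshold))
    links = pd.DataFrame(rows, columns=["gene", "peak", "r", "p", "significant"])
    links.attrs["excluded"] = pd.DataFrame(
        excluded, columns=["gene", "peak", "reason"]
    )
    return links


def compute_gene_scores(
    links: pd.DataFrame, mc_acc: np.ndarray, peak_ids: np.ndarray
) -> pd.DataFrame:
    """Gene score = summed normalized accessibility over the gene's
    significantly linked peaks, per metacell. Genes without significant
    links score 0 and are flagged."""
    s = mc_acc.shape[0]
    pidx = {p: i for i, p in enumerate(peak_ids)}
    genes = sorted(links["gene"].unique())
    scores = np.zeros((s, len(genes)))
    flagged = []
    for gi, gene in enumerate(genes):
        sig = links[(links["gene"] == gene) & links["significant"]]
        if len(sig) == 0:
            flagged.append(gene)
            continue
        cols = [pidx[p] for p in sig["peak"]]
        scores[:, gi] = mc_acc[:, cols].sum(axis=1)
    out = pd.DataFrame(scores, columns=genes)
    out.attrs["no_significant_links"] = flagged
    return out


def compute_gene_accessibility(
    open_peaks: OpenPeakMatrix, links: pd.DataFrame
) -> pd.DataFrame:
    """Gene accessibility = fraction of the gene's significantly linked
    peaks called open in each metacell (0 = all closed, 1 = all open).
    Genes with no significant links are excluded."""
    pidx = {p: i for i, p in enumerate(open_peaks.peak_ids)}
    cols = {}
    for gene, sub in links[links["significant"]].groupby("gene"):
        idx = [pidx[p] for p in sub["peak"]]
        cols[gene] = open_peaks.is_open[:, idx].mean(axis=1)
    return pd.DataFrame(cols)
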