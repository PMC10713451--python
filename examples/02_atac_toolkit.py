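"""Metacell-level ATAC analysis on synthetic multiome data.

Filters nucleosome-free fragments, counts fragments per (metacell, peak) by
Tn5 insertion sites, calls open peaks with the Poisson test, links peaks to
genes against a GC/accessibility-matched empirical background, and derives
gene scores and gene accessibility.
"""

import numpy as np

from metacellkit import atac
from metacellkit.archetypes import normalize_metacell_counts
from metacellkit.pipeline import compute_metacells
from metacellkit.synthetic import simulate_multiome

sim = simulate_multiome(
    n_cells=1_500, n_genes=300, n_peaks=400, n_states=6,
    n_planted_links=25, seed=0,
)

# NFR filter: the simulator mixes a <147 bp nucleosome-free mode with a
# mono-nucleosomal mode, so roughly the mixture weight should survive
nfr, retained = atac.filter_nfr_fragments(sim.fragments)
print(f"fragments: {len(sim.fragments)}; NFR (<147 bp) retained: {retained:.1%}")

# metacells from the ATAC modality, as used for peak-gene association
res = compute_metacells(counts=sim.atac, seed=0)
print(f"ATAC metacells: {res.assignment.n_metacells}")

counts, totals, dropped = atac.count_peak_fragments(
    nfr, sim.peaks, res.assignment, sim.atac.cell_ids,
)
open_peaks = atac.call_open_peaks(counts, totals, peak_ids=sim.peaks.peak_ids)
print(f"Poisson rate lambda per metacell: median {np.median(open_peaks.lam):.2f}; "
      f"open-peak fraction {open_peaks.is_open.mean():.2f}")

# peak-gene links on normalized metacell matrices (RNA metacells aggregated
# with the same cell grouping, as with paired multiome barcodes)
from metacellkit.archetypes import aggregate_metacell_counts

rna_mc = aggregate_metacell_counts(sim.rna, res.assignment)
expr = normalize_metacell_counts(rna_mc)
acc = normalize_metacell_counts(res.counts)
links = atac.correlate_peaks_genes(
    expr, rna_mc.feature_ids, acc, sim.peaks, sim.genes, seed=0
)
sig = links[links["significant"]]
print(f"candidate peak-gene pairs within +/-100 kb: {len(links)}; "
      f"significant at empirical p<0.1: {len(sig)}")

planted = set(zip(sim.truth.planted_links["gene"], sim.truth.planted_links["peak"]))
hit = sum((g, p) in planted for g, p in zip(sig["gene"], sig["peak"]))
print(f"planted links recovered: {hit}/{len(planted)}")

scores = atac.compute_gene_scores(links, acc, sim.peaks.peak_ids)
ga = atac.compute_gene_accessibility(open_peaks, links)
print(f"gene scores computed for {scores.shape[1]} genes; "
      f"gene accessibility (fraction of linked peaks open) for {ga.shape[1]} genes, "
      f"range [{ga.min().min():.2f}, {ga.max().max():.2f}]")
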