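# Methods

## The model

`metacellkit` groups single cells into *metacells*: small, homogeneous
groups of cells whose within-group variation is treated as technical
noise. The grouping is obtained by archetypal analysis of a cell-cell
affinity kernel rather than by clustering, which lets group boundaries
follow the geometry of continuous differentiation trajectories as well as
discrete cell types.

### Affinity kernel

Cells are embedded in a low-dimensional space (PCA of log-normalized
highly variable genes for RNA; TF-IDF + truncated SVD for ATAC, with the
first component dropped when it tracks sequencing depth, |r| > 0.9 with
log total counts). On the exact Euclidean k-nearest-neighbor graph
(k = 50) an adaptive Gaussian kernel is computed:

    M(x_i, x_j) = 1/sqrt(2 pi (s_i + s_j)) * exp(-||x_i - x_j||^2 / (2 (s_i + s_j)))

where the bandwidth `s_i` is the distance from cell `i` to its l-th
nearest neighbor (default l = 15; l is a tuning knob, not a published
constant). The adaptive bandwidth equalizes effective resolution between
dense and sparse regions of the phenotypic manifold, which is what makes
rare populations recoverable. The kernel diagonal carries the
zero-distance value `1/sqrt(4 pi s_i)`.

**Kernel support.** The kNN graph is directed; the kernel needs a
symmetric support. Two symmetrizations are offered:
`kernel_support="union"` (default: an edge survives when either direction
exists) and `"mutual"` (both directions required). The mutual rule reads
more restrictive but interacts badly with hubness in 50-dimensional
embeddings: anti-hub cells retain few or no mutual edges, their kernel
rows become tiny, and — because the membership weights are
simplex-constrained — a fully optimized decomposition then recruits one
near-zero archetype as a scale sink that absorbs a seed-dependent block of
fringe cells. Under union support this degeneracy does not arise and
metacell partitions are reproducible across random initializations
(median pairwise NMI ~0.92 on the 10,000-cell 20-state simulation, versus
~0.67 under mutual support). Union is therefore the default; the mutual
variant is kept for sensitivity analyses.

### Kernel archetypal analysis

The kernel M (n x n, sparse) is decomposed as `M ~= M B A` with
column-stochastic `B` (n x s; archetypes as convex mixtures of cells) and
`A` (s x n; cells as convex mixtures of archetypes), minimizing the
squared reconstruction error `SRE = ||M - M B A||_F^2`. The number of
archetypes s defaults to one metacell per 75 cells (`ceil(n/75)`).

Optimization is alternating block minimization with Frank-Wolfe updates:

- **A block** (B fixed; the problem separates over columns): each column
  steps toward the most-negative-gradient vertex of the simplex with an
  exact line search on the quadratic objective, clipped to [0, 1]. Up to
  4 passes per outer iteration; after the first pass only columns still
  contributing a non-negligible share of the improvement are revisited.
- **B block** (A fixed; columns couple through A): one batched
  Gauss-Seidel sweep per outer iteration. Batches of 32 columns take a
  joint most-negative-gradient direction restricted to columns with
  descent, with one exact line search per batch. The exact joint step
  keeps every batch update monotone (simultaneous independent per-column
  steps would not be, because B's columns interact through A), while the
  small batches give near per-column granularity.

Both blocks decrease SRE by construction, so the per-iteration SRE trace
is non-increasing. Convergence is declared when the relative SRE decrease
stays below 1e-5 for 3 consecutive outer iterations (after a minimum of
10); the cap is 150 iterations. A final A polish re-solves the membership
problem for the fitted archetypes. All products exploit sparsity of M and
of the Frank-Wolfe iterates; negligible membership weights (< 1e-8) are
pruned before sparse products, a perturbation far below the line-search
tolerances.

**Initialization.** B starts as indicator columns on waypoint cells:
max-min sampling on each of the top 10 diffusion components of the kernel
transition operator (the first waypoint per component is drawn from the
run seed; the paper's robustness-to-initialization experiment requires a
random start, and a deterministic `start="extremal"` variant is
available), pooled round-robin and de-duplicated; greedy column-subset
selection on the kernel (column-pivoted Gram-Schmidt, largest residual
norm first) fills any shortfall. A starts as the indicator of each cell's
highest-affinity waypoint.

### Metacell construction

Hard assignments binarize A: per cell, weights below 0.05 are zeroed as
regularization, the rest renormalized, and the argmax taken (ties to the
lowest index; cells with all weights below threshold fall back to the
pre-threshold argmax with a warning). Metacell counts are plain sums of
raw counts; normalization divides by metacell totals, multiplies by the
median total and applies log with pseudocount 0.1. Assignment confidence
is summarized over the max-weight bins [0, 0.5), [0.5, 0.8), [0.8, 0.9),
[0.9, 1].

## ATAC toolkit

- **NFR filter**: fragments shorter than 147 bases (sub-nucleosomal) are
  retained for peak-level analyses.
- **Fragment counting**: a fragment is counted in a peak when either Tn5
  insertion site (start, or end-1; 0-based half-open) falls inside the
  peak, at most once per peak per fragment. Optionally each metacell's
  counts are pooled with its two nearest metacells (centroid distance in
  diffusion space) to stabilize low-depth metacells; applied to all
  metacells to avoid selection bias.
- **Open-peak test**: per metacell, fragments-in-peaks are modeled as
  Poisson with the MACS2-style local rate
  `lambda = 500 * total_fragments / (n_peaks * 5000)`; a peak with n
  fragments is open when `P(X > n) < 0.01`.
- **Peak-gene links**: for each gene, candidate peaks within +/-100 kb of
  the gene body are correlated (Pearson; Spearman available) with
  normalized metacell expression across metacells. Significance uses an
  empirical null of 100 background peaks drawn from the candidate peak's
  joint (GC content x total accessibility) equal-frequency bin (100 bins
  per margin; sampling with replacement when a bin is small; the query
  peak is excluded from its own background). The one-sided add-one
  estimator `p = (1 + #{r_bg >= r_obs}) / 101` never returns zero;
  links are significant at p < 0.1.
- **Gene scores**: summed normalized accessibility over a gene's
  significant peaks. **Gene accessibility**: the fraction of a gene's
  significant peaks called open in a metacell (0..1).

## TF activity

Gene expression trends along a supplied pseudotime are fit per gene with
a penalized cubic B-spline additive model (6 basis functions on uniform
interior knots; exact integrated-squared-second-derivative penalty, so
linear trends are never penalized; dimensionless smoothing parameter
0.01, mainly for conditioning) and z-scored across metacells. The
TF-target matrix weights motif scores by peak-gene correlation over
qualifying peaks (p < 0.1, r > 0.1):
`G_gt = sum_k c_kg F_kt / sum_k c_kg`. Per metacell, the z-scored trend
column is regressed on the standardized columns of G by lasso with the
penalty chosen by 10-fold cross-validation (seeded fold shuffle). TF
activity is the increase in squared prediction error when the TF's term
is dropped from the fitted predictor (no refit), signed by the
coefficient; TFs are ranked by total signed activity (absolute-value
ranking available).

## Cohort analysis

Metacells are computed per sample; equivalence across samples uses mutual
top-2 nearest neighbors in the top-10 diffusion components of a pooled
(batch-corrected) metacell embedding. Meta2cells re-run the kernel
archetypal pipeline on metacell rows with one meta2cell per 10 metacells;
annotations use the modal constituent type when purity exceeds 80%, else
"Mixed". Differential abundance permutes the metacell-to-meta2cell
assignment (sizes preserved exactly), computes the null distribution of
each meta2cell's focal-condition proportion over 5,000 permutations, and
reports two-sided add-one p-values (`min(1, 2 min(p_hi, p_lo))`);
significance at p < 0.1. A one-sided variant (`alternative="greater"`)
is available for directional hypotheses such as a planted enrichment.

## Synthetic data

The generator emulates the data regimes above without reproducing real
genomes:

- Discrete states with log-normal baseline expression and state-specific
  programs (40 genes / 80 peaks per state, 6x boost); counts are
  gamma-Poisson (negative binomial, dispersion 0.5) around
  state-profile x library-size means; library sizes are log-normal
  (mean depth 2,000, sigma 0.35-0.4).
- Rare populations at requested frequencies occupy the first state
  labels.
- Planted peak-gene links: the peak's cross-state accessibility profile
  is mixed toward the partner gene's expression profile with coupling 0.8;
  partner genes are placed within the +/-100 kb window on toy contigs
  (500-base peaks every 2 kb).
- Fragments per (cell, peak) draw lengths from a two-component mixture:
  nucleosome-free N(70, 20) clipped to [20, 146] with weight 0.6, and
  mono-nucleosomal N(220, 30) clipped to [147, 400].
- The cohort generator shares one state space across samples, enriches
  designated states by a factor (default 3) in the second condition, and
  injects per-sample batch structure (gene-wise log-normal factors,
  sigma 0.15, and library shifts). Defaults (8 samples per condition,
  1,800 cells per sample) were sized by a power calculation so that a 3x
  enrichment yields ~10 enriched meta2cells, enough for reliable
  detection by the directional permutation test.
- A trajectory mode replaces discrete states with a latent 1-D
  pseudotime and smoothly varying (sigmoid / bump) programs for
  trend-fitting tests.

What the generator does *not* emulate: doublets, ambient contamination,
batch-specific peak sets, realistic genome coordinates, sequencing error,
or cell-cycle structure. Passing tests therefore demonstrate correctness
of the algorithms under the stated generative assumptions, not
performance on any particular real dataset.

## Problem sizes used in the test suite and acceptance script

Simulation-backed checks run at sizes chosen to keep a full run on one
CPU within a desktop time budget; each size is stated where it is used:
robustness across initializations at 4,000 cells / 12 states in the test
suite and 6,000 cells / 20 states in the acceptance script; rare-state
recovery at 10,000 cells (0.5%) in the suite and the full
{0.7, 0.5, 0.2}% grid at 8,000 cells in the acceptance script (run from
the rarest frequency upward; the reported value — the smallest recovered
frequency — is unchanged by skipping coarser grid points once a rarer one
has recovered); cohort power at 6 replicates of the default cohort
design; TF recovery at 50 replicates.

## Numerical choices and degenerate inputs

- Duplicate points give zero bandwidths; bandwidths below 1e-12 are
  replaced by the smallest positive bandwidth in the dataset.
- Disconnected kernels are handled globally in the diffusion map: the
  eigenvalue-1 eigenspace is rotated so the constant direction can be
  removed while component-indicator structure is retained (with a
  warning).
- Argmax ties break to the lowest index everywhere; modal-type ties break
  lexicographically.
- Empty metacells after binarization are dropped and re-indexed with a
  warning (expected when s is over-specified).
- Empirical p-values use add-one estimators and can never be zero.
- Constant (zero-variance) expression or accessibility vectors are
  excluded from correlation analyses with an explicit reason; constant
  genes produce all-zero trends.
- All randomness flows from a single seed per entry point; identical
  seeds give byte-identical outputs.

## Known limitations

- Exact brute-force kNN only; practical to a few 10^5 cells on one core.
- The mutual-support kernel variant remains susceptible to the
  scale-sink degeneracy described above when fully optimized.
- The lasso activity model assumes the trend matrix and TF-target matrix
  share a gene universe; genes absent from either are silently dropped
  from the fit (reported via the shared-gene count).
- Fragment-level simulation stores one record per fragment and is
  memory-bound beyond ~10^7 fragments; large simulations should disable
  fragment generation.
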