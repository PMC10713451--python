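"""ATAC toolkit: NFR filtering, insertion-site counting, the Poisson
open-peak test, matched-background peak-gene links, gene scores and gene
accessibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from metacellkit import atac
from metacellkit.types import FragmentSet, MetacellAssignment, OpenPeakMatrix, PeakSet


def _fragments(rows):
    return FragmentSet(
        records=pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
    )


def _peaks(intervals, gc=None):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    df["peak_id"] = [f"peak_{i}" for i in range(len(df))]
    return PeakSet(intervals=df, gc_content=gc)


def _assignment(labels, s):
    labels = np.asarray(labels)
    n = len(labels)
    w = sparse.csr_matrix((np.ones(n), (labels, np.arange(n))), shape=(s, n))
    return MetacellAssignment(
        labels=labels, soft_weights=w, max_weight=np.ones(n),
        n_nontrivial=np.ones(n, dtype=int),
    )


class TestNfrFilter:
    def test_strict_length_bound(self):
        frags = _fragments(
            [("chr1", 100, 246, "BC1", 1),  # length 146: kept
             ("chr1", 100, 247, "BC1", 1)]  # length 147: removed
        )
        kept, retained = atac.filter_nfr_fragments(frags)
        assert len(kept) == 1
        assert kept.records.iloc[0]["end"] == 246
        assert retained == pytest.approx(0.5)

    def test_empty_input(self):
        kept, retained = atac.filter_nfr_fragments(_fragments([]))
        assert len(kept) == 0 and retained == 0.0

    def test_partition_of_input(self):
        rng = np.random.default_rng(0)
        rows = [("chr1", int(s), int(s + l), "BC", 1)
                for s, l in zip(rng.integers(0, 1000, 50), rng.integers(30, 300, 50))]
        frags = _fragments(rows)
        kept, retained = atac.filter_nfr_fragments(frags)
        assert np.all(kept.lengths < 147)
        assert len(kept) + np.sum(frags.lengths >= 147) == len(frags)

    def test_malformed_record_rejected(self):
        with pytest.raises(ValueError, match="record 0"):
            _fragments([("chr1", 100, 100, "BC1", 1)])

    def test_default_bound(self):
        assert atac.DEFAULT_NFR_BOUND == 147


class TestCountPeakFragments:
    def test_insertion_site_semantics(self):
        peaks = _peaks([("chr1", 100, 200)])
        barcodes = np.array(["BC0"])
        asg = _assignment([0], s=1)
        # start inside the peak, end outside: counted once
        frags = _fragments([("chr1", 150, 400, "BC0", 1)])
        counts, totals, dropped = atac.count_peak_fragments(frags, peaks, asg, barcodes)
        assert counts[0, 0] == 1 and totals[0] == 1 and dropped == 0
        # both sites inside: still counted once
        frags = _fragments([("chr1", 150, 180, "BC0", 1)])
        counts, _, _ = atac.count_peak_fragments(frags, peaks, asg, barcodes)
        assert counts[0, 0] == 1
        # both sites outside: not counted (fragment spans the peak)
        frags = _fragments([("chr1", 50, 400, "BC0", 1)])
        counts, totals, _ = atac.count_peak_fragments(frags, peaks, asg, barcodes)
        assert counts[0, 0] == 0 and totals[0] == 1

    def test_two_peaks_both_hit(self):
        peaks = _peaks([("chr1", 100, 200), ("chr1", 300, 400)])
        frags = _fragments([("chr1", 150, 351, "BC0", 1)])
        counts, _, _ = atac.count_peak_fragments(
            frags, peaks, _assignment([0], 1), np.array(["BC0"])
        )
        assert counts[0, 0] == 1 and counts[0, 1] == 1

    def test_no_fragments_zero_matrix(self):
        peaks = _peaks([("chr1", 0, 500)])
        counts, totals, _ = atac.count_peak_fragments(
            _fragments([]), peaks, _assignment([0, 1], 2), np.array(["a", "b"])
        )
        assert counts.sum() == 0 and totals.sum() == 0

    def test_unknown_barcodes_dropped_and_counted(self):
        peaks = _peaks([("chr1", 0, 500)])
        frags = _fragments([("chr1", 10, 100, "??", 1), ("chr1", 10, 100, "BC0", 2)])
        counts, totals, dropped = atac.count_peak_fragments(
            frags, peaks, _assignment([0], 1), np.array(["BC0"])
        )
        assert dropped == 1 and counts[0, 0] == 2

    def test_augmentation_pools_two_nearest(self):
        peaks = _peaks([("chr1", 0, 500)])
        barcodes = np.array(["a", "b", "c", "d"])
        asg = _assignment([0, 1, 2, 3], 4)
        frags = _fragments([("chr1", 10, 100, bc, i + 1) for i, bc in enumerate(barcodes)])
        centroids = np.array([[0.0], [1.0], [2.0], [10.0]])
        plain, tot_plain, _ = atac.count_peak_fragments(frags, peaks, asg, barcodes)
        aug, tot_aug, _ = atac.count_peak_fragments(
            frags, peaks, asg, barcodes, dcs_metacell=centroids, augment=True
        )
        # metacell 0 pools with 1 and 2: 1 + 2 + 3 = 6
        assert aug[0, 0] == 6
        assert np.array_equal(
            tot_aug, [tot_plain[0] + tot_plain[1] + tot_plain[2],
                      tot_plain[1] + tot_plain[0] + tot_plain[2],
                      tot_plain[2] + tot_plain[1] + tot_plain[0],
                      tot_plain[3] + tot_plain[2] + tot_plain[1]]
        )


class TestOpenPeaks:
    def test_lambda_formula(self):
        # 1,000 peaks, 100,000 fragments: lambda = 500*100000/(1000*5000) = 10
        counts = np.zeros((1, 1000), dtype=int)
        res = atac.call_open_peaks(counts, totals=np.array([100_000]))
        assert res.lam[0] == pytest.approx(10.0)

    def test_zero_count_peak_closed_at_lambda_10(self):
        counts = np.zeros((1, 1000), dtype=int)
        res = atac.call_open_peaks(counts, totals=np.array([100_000]))
        # P(X > 0) = 1 - e^(-10) ~ 0.99995: closed
        assert res.pvalues[0, 0] == pytest.approx(1 - np.exp(-10), rel=1e-9)
        assert not res.is_open[0, 0]

    def test_survival_matches_bruteforce_pmf_summation(self):
        # oracle: P(X > n) = 1 - sum_{k<=n} pmf(k)
        for lam in (0.1, 1.0, 10.0, 50.0):
            n = np.arange(0, 201)
            sf = stats.poisson.sf(n, lam)
            k = np.arange(0, 201)
            pmf = np.exp(-lam) * lam**k / [np.math.factorial(int(x)) for x in k] \
                if False else stats.poisson.pmf(k, lam)
            brute = 1.0 - np.cumsum(pmf)
            assert np.abs(sf - brute).max() < 1e-12

    def test_open_calls_threshold(self):
        counts = np.array([[30, 0, 11]])
        res = atac.call_open_peaks(
            counts, totals=np.array([10_000]), eff_length_multiplier=5000,
            peak_width=500,
        )
        lam = 500 * 10_000 / (3 * 5000)
        assert res.lam[0] == pytest.approx(lam)
        expect_open = stats.poisson.sf(counts[0], lam) < 0.01
        assert np.array_equal(res.is_open[0], expect_open)

    def test_zero_total_metacell_all_closed_with_warning(self):
        counts = np.zeros((2, 5), dtype=int)
        counts[1, 0] = 3
        with pytest.warns(UserWarning, match="zero total"):
            res = atac.call_open_peaks(counts, totals=np.array([0, 100000]))
        assert not res.is_open[0].any()

    def test_defaults(self):
        assert atac.DEFAULT_PEAK_WIDTH == 500
        assert atac.DEFAULT_EFF_LENGTH_MULTIPLIER == 5000
        assert atac.DEFAULT_OPEN_P_THRESHOLD == 0.01


def _link_setup(n_mc=20, n_peaks=120, seed=0):
    rng = np.random.default_rng(seed)
    acc = rng.normal(size=(n_mc, n_peaks))
    peaks = _peaks(
        [("chr1", 2000 * i, 2000 * i + 500) for i in range(n_peaks)],
        gc=rng.uniform(0.3, 0.7, n_peaks),
    )
    genes = pd.DataFrame(
        {"gene": ["gene_0"], "chrom": ["chr1"], "start": [50_000], "end": [51_000]}
    )
    return rng, acc, peaks, genes


class TestPeakGeneLinks:
    def test_perfect_correlation_and_add_one_p(self):
        rng, acc, peaks, genes = _link_setup()
        gi = 25  # peak inside the window of gene_0
        expr = acc[:, [gi]].copy()  # expression == accessibility of peak 25
        links = atac.correlate_peaks_genes(
            expr, np.array(["gene_0"]), acc, peaks, genes, seed=1
        )
        row = links[links["peak"] == "peak_25"].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-12)
        # r = 1 beats every background draw: p = 1/101
        assert row["p"] == pytest.approx(1 / 101, abs=1e-12)
        assert bool(row["significant"])

    def test_window_restricts_candidates(self):
        rng, acc, peaks, genes = _link_setup()
        expr = rng.normal(size=(20, 1))
        links = atac.correlate_peaks_genes(
            expr, np.array(["gene_0"]), acc, peaks, genes, window_kb=10, seed=0
        )
        starts = peaks.intervals.set_index("peak_id").loc[links["peak"], "start"]
        assert starts.min() >= 50_000 - 10_000 - 500
        assert starts.max() <= 51_000 + 10_000

    def test_empirical_p_never_zero_and_in_range(self):
        rng, acc, peaks, genes = _link_setup(seed=3)
        expr = rng.normal(size=(20, 1))
        links = atac.correlate_peaks_genes(
            expr, np.array(["gene_0"]), acc, peaks, genes, seed=5
        )
        assert (links["p"] > 0).all() and (links["p"] <= 1).all()
        assert (links["p"] >= 1 / 101).all()

    def test_zero_variance_excluded_with_reason(self):
        rng, acc, peaks, genes = _link_setup(seed=4)
        acc[:, 25] = 0.0  # constant accessibility
        expr = rng.normal(size=(20, 1))
        links = atac.correlate_peaks_genes(
            expr, np.array(["gene_0"]), acc, peaks, genes, seed=0
        )
        assert "peak_25" not in set(links["peak"])
        excl = links.attrs["excluded"]
        assert ((excl["peak"] == "peak_25") & (excl["reason"] == "zero variance")).any()

    def test_defaults(self):
        assert atac.DEFAULT_WINDOW_KB == 100
        assert atac.DEFAULT_N_BACKGROUND == 100
        assert atac.DEFAULT_N_BINS == 100
        assert atac.DEFAULT_LINK_P_THRESHOLD == 0.1

    def test_gc_required(self):
        rng, acc, peaks, genes = _link_setup()
        peaks.gc_content = None
        with pytest.raises(ValueError, match="GC"):
            atac.correlate_peaks_genes(
                rng.normal(size=(20, 1)), np.array(["gene_0"]), acc, peaks, genes
            )


class TestGeneScoresAndAccessibility:
    def _links(self):
        return pd.DataFrame(
            {
                "gene": ["g1", "g1", "g1", "g1", "g2"],
                "peak": ["p0", "p1", "p2", "p3", "p0"],
                "r": [0.9, 0.8, 0.7, 0.6, 0.5],
                "p": [0.01, 0.01, 0.01, 0.01, 0.5],
                "significant": [True, True, True, True, False],
            }
        )

    def test_gene_score_is_sum_over_linked_peaks(self):
        acc = np.array([[0.3, 0.7, 0.0, 0.0]])
        scores = atac.compute_gene_scores(
            self._links(), acc, np.array(["p0", "p1", "p2", "p3"])
        )
        assert scores.loc[0, "g1"] == pytest.approx(1.0)
        assert scores.loc[0, "g2"] == 0.0
        assert "g2" in scores.attrs["no_significant_links"]

    def test_score_monotone_in_linked_accessibility(self):
        acc = np.array([[0.3, 0.7, 0.2, 0.0]])
        base = atac.compute_gene_scores(
            self._links(), acc[:, :4], np.array(["p0", "p1", "p2", "p3"])
        )
        assert base.loc[0, "g1"] >= 1.0

    def test_gene_accessibility_fraction(self):
        open_mat = OpenPeakMatrix(
            is_open=np.array([[True, True, False, False]]),
            pvalues=np.zeros((1, 4)),
            lam=np.array([1.0]),
            peak_ids=np.array(["p0", "p1", "p2", "p3"]),
        )
        ga = atac.compute_gene_accessibility(open_mat, self._links())
        assert ga.loc[0, "g1"] == pytest.approx(0.5)  # 2 of 4 linked peaks open
        assert "g2" not in ga.columns  # no significant links

    def test_bounds_all_open_all_closed(self):
        links = self._links()
        for is_open, expected in ((np.ones((1, 4), bool), 1.0), (np.zeros((1, 4), bool), 0.0)):
            om = OpenPeakMatrix(
                is_open=is_open, pvalues=np.zeros((1, 4)), lam=np.array([1.0]),
                peak_ids=np.array(["p0", "p1", "p2", "p3"]),
            )
            ga = atac.compute_gene_accessibility(om, links)
            assert ga.loc[0, "g1"] == expected


class TestPlantedLinkRecovery:
    def test_planted_links_recovered_and_control_calibrated(self):
        """Metacell-level peak-gene association recovers >= 90% of planted
        couplings as significant, while a permuted-metacell control calls
        ~10% (the nominal rate at p < 0.1)."""
        import warnings

        from metacellkit.archetypes import (
            aggregate_metacell_counts,
            normalize_metacell_counts,
        )
        from metacellkit.pipeline import compute_metacells
        from metacellkit.synthetic import simulate_multiome

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = simulate_multiome(
                n_cells=2_000, n_genes=250, n_peaks=350, n_states=8,
                n_planted_links=30, with_fragments=False, seed=0,
            )
            res = compute_metacells(counts=sim.atac, seed=0)
            rna_mc = aggregate_metacell_counts(sim.rna, res.assignment)
            expr = normalize_metacell_counts(rna_mc)
            acc = normalize_metacell_counts(res.counts)
            links = atac.correlate_peaks_genes(
                expr, rna_mc.feature_ids, acc, sim.peaks, sim.genes, seed=0
            )
        sig = set(zip(links.loc[links["significant"], "gene"],
                      links.loc[links["significant"], "peak"]))
        planted = list(zip(sim.truth.planted_links["gene"],
                           sim.truth.planted_links["peak"]))
        recovered = np.mean([pair in sig for pair in planted])
        assert recovered >= 0.9

        # permuted-metacell control: break the pairing between modalities
        rng = np.random.default_rng(1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_links = atac.correlate_peaks_genes(
                expr[rng.permutation(expr.shape[0])], rna_mc.feature_ids,
                acc, sim.peaks, sim.genes, seed=2,
            )
        null_rate = null_links["significant"].mean()
        se = np.sqrt(0.1 * 0.9 / max(len(null_links), 1))
        assert null_rate <= 0.10 + 5 * se
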