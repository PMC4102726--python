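"""Distance-profile moments, TSS histograms, group comparisons and rankings."""

import numpy as np
import pandas as pd
import pytest

from eqtlatlas import (
    GeneModel,
    compare_category_shares,
    compare_housekeeping,
    distance_profile,
    rank_chromosomes,
    tss_histogram,
)


def _bests(rows, cols=("dataset_id", "rsid", "gene_key", "pvalue", "chrom", "pos", "distance_bp")):
    return pd.DataFrame(rows, columns=list(cols))


class TestDistanceProfile:
    def test_symmetric_two_point_moments(self):
        rows = [("d", f"s{i}", "g", 0.1, "chr1", 1, d) for i, d in enumerate([-1, 1, -1, 1])]
        prof = distance_profile(_bests(rows))
        assert prof.skewness == pytest.approx(0.0)
        assert prof.excess_kurtosis == pytest.approx(-2.0)
        assert prof.mean_distance_bp == 0.0

    def test_zero_variance_flagged(self):
        rows = [("d", f"s{i}", "g", 0.1, "chr1", 1, 5) for i in range(4)]
        assert not distance_profile(_bests(rows)).defined

    def test_cross_chromosome_distances_excluded(self):
        rows = [("d", "s1", "g", 0.1, "chr1", 1, None)] * 3
        assert distance_profile(_bests(rows)).n == 0

    def test_laplace_excess_kurtosis_near_three(self):
        # n = 1e5 keeps the sampling sd of the kurtosis estimate near 0.1
        rng = np.random.default_rng(17)
        d = rng.laplace(0, 5000, size=100_000)
        rows = [("d", f"s{i}", "g", 0.1, "chr1", 1, float(x)) for i, x in enumerate(d)]
        prof = distance_profile(_bests(rows))
        assert prof.excess_kurtosis == pytest.approx(3.0, abs=0.3)

    def test_planted_decay_is_leptokurtic(self, harmonized):
        """The distance-decay placement model yields heavy-tailed profiles."""
        best, _, _ = harmonized
        kurts = []
        for d in best["dataset_id"].unique():
            prof = distance_profile(best, d)
            if prof.defined:
                kurts.append(prof.excess_kurtosis)
        assert np.median(kurts) > 3


class TestTssHistogram:
    genes = [
        GeneModel("gp", "GP", frozenset(), "chr1", 100_000, 120_000, "+"),
        GeneModel("gm", "GM", frozenset(), "chr1", 300_000, 320_000, "-"),
    ]

    def _row(self, gene_key, pos):
        return ("d", "s", gene_key, 0.1, "chr1", pos, 0)

    def test_eqtl_at_tss_lands_in_center_bin(self):
        bests = _bests([self._row("gp", 100_001)])  # 1-based TSS of the + gene
        hist = tss_histogram(bests, self.genes, window_bp=10_000, bin_bp=1000)
        assert hist.loc[0] == 1 and hist.sum() == 1

    def test_minus_strand_mirrored_downstream(self):
        # 3 kb genomically left of the minus gene's span end = 3 kb downstream
        pos = 320_000 - 3000  # 1-based: 0-based 316999, TSS at 319999
        bests = _bests([self._row("gm", pos)])
        hist = tss_histogram(bests, self.genes, window_bp=10_000, bin_bp=1000)
        assert hist.loc[3000] == 1

    def test_counts_sum_to_in_window_eqtls(self):
        rows = [self._row("gp", 100_001 + k) for k in (-20_000, -5_000, 0, 2_000, 9_999)]
        bests = _bests(rows)
        hist = tss_histogram(bests, self.genes, window_bp=10_000, bin_bp=1000)
        assert hist.sum() == 4  # the -20 kb SNP is outside the window

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError):
            tss_histogram(_bests([]), self.genes, window_bp=10_000, bin_bp=3000)

    def test_mirror_symmetry_under_reflection(self):
        """Reflecting the genome (coords and strands) mirrors the histogram."""
        L = 1_000_000
        gene = GeneModel("g", "G", frozenset(), "chr1", 100_000, 120_000, "+")
        mirrored = GeneModel(
            "g", "G", frozenset(), "chr1", L - 120_000, L - 100_000, "-"
        )
        offsets = [-7_500, -200, 0, 3_300, 9_000]
        rows = [self._row("g", 100_001 + o) for o in offsets]
        h1 = tss_histogram(_bests(rows), [gene], 10_000, 1000)
        rows_m = [
            ("d", "s", "g", 0.1, "chr1", L - (100_001 + o) + 1, 0) for o in offsets
        ]
        h2 = tss_histogram(_bests(rows_m), [mirrored], 10_000, 1000)
        assert h1.tolist() == h2.tolist()


class TestCategoryShares:
    def _meta(self):
        return pd.DataFrame(
            {
                "dataset_id": ["b1", "b2", "w1", "w2"],
                "tissue": ["brain", "brain", "blood", "blood"],
                "tissue_group": ["brain", "brain", "blood", "blood"],
                "sample_size": [100, 100, 100, 100],
            }
        )

    def _best_with_classes(self, per_dataset):
        rows = []
        for d, classes in per_dataset.items():
            for i, c in enumerate(classes):
                rows.append((d, f"s{d}{i}", f"g{i}", 1e-5, "chr1", 100, 0, c))
        return _bests(
            rows,
            cols=(
                "dataset_id", "rsid", "gene_key", "pvalue", "chrom", "pos",
                "distance_bp", "location_class",
            ),
        )

    def test_hand_chi_square(self):
        per = {
            "b1": ["trans_diff_chr"] * 10 + ["cis"] * 90,
            "w1": ["trans_diff_chr"] * 30 + ["cis"] * 70,
        }
        best = self._best_with_classes(per)
        props, p, test = compare_category_shares(
            best, self._meta(), "trans_diff_chr", "brain", "blood"
        )
        # chi2 = N (ad - bc)^2 / (row1 row2 col1 col2) = 12.5 -> p ~ 4.1e-4
        from scipy.stats import chi2 as chi2_dist

        assert test == "chi2"
        assert p == pytest.approx(float(chi2_dist.sf(12.5, 1)), rel=1e-9)
        assert props["brain"] == pytest.approx(0.1)

    def test_identical_proportions_p_near_one(self):
        per = {"b1": ["cis"] * 50 + ["trans_diff_chr"] * 50,
               "w1": ["cis"] * 50 + ["trans_diff_chr"] * 50}
        _, p, _ = compare_category_shares(
            self._best_with_classes(per), self._meta(), "trans_diff_chr", "brain", "blood"
        )
        assert p == pytest.approx(1.0)

    def test_small_counts_route_to_fisher(self):
        from scipy.stats import fisher_exact

        per = {"b1": ["trans_diff_chr"] * 3 + ["cis"] * 4,
               "w1": ["trans_diff_chr"] * 1 + ["cis"] * 6}
        _, p, test = compare_category_shares(
            self._best_with_classes(per), self._meta(), "trans_diff_chr", "brain", "blood"
        )
        assert test == "fisher"
        assert p == pytest.approx(float(fisher_exact([[3, 4], [1, 6]])[1]), rel=1e-9)

    def test_symmetric_in_group_order(self):
        per = {"b1": ["trans_diff_chr"] * 10 + ["cis"] * 90,
               "w1": ["trans_diff_chr"] * 25 + ["cis"] * 75}
        best = self._best_with_classes(per)
        _, p_ab, _ = compare_category_shares(best, self._meta(), "trans_diff_chr", "brain", "blood")
        _, p_ba, _ = compare_category_shares(best, self._meta(), "trans_diff_chr", "blood", "brain")
        assert p_ab == pytest.approx(p_ba)

    def test_brain_trans_enrichment_planted(self, study, harmonized):
        """The generator plants extra different-chromosome trans in brain."""
        best, _, _ = harmonized
        props, p, _ = compare_category_shares(
            best, study.meta, "trans_diff_chr", "brain", "blood"
        )
        assert props["brain"] > props["blood"]

    def test_empty_group_rejected(self):
        per = {"b1": ["cis"] * 5}
        with pytest.raises(ValueError):
            compare_category_shares(
                self._best_with_classes(per), self._meta(), "cis", "brain", "blood"
            )


class TestRankChromosomes:
    def _metrics(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "length_bp", "n_genes", "rna_bp", "n_variants"]
        )

    def _cis(self, counts):
        rows = []
        for chrom, k in counts.items():
            rows += [("d", f"s{chrom}{i}", "g", 1e-5, chrom, 100, 0) for i in range(k)]
        return _bests(rows)

    def test_equal_metrics_rank_by_count(self):
        met = self._metrics([("chr1", 10, 10, 10, 10), ("chr2", 10, 10, 10, 10)])
        table = rank_chromosomes(self._cis({"chr1": 10, "chr2": 20}), met)
        assert table.loc["chr2", "mean_rank"] == 1.0
        assert table.loc["chr1", "mean_rank"] == 2.0

    def test_metrics_proportional_to_counts_all_tied(self):
        met = self._metrics([("chr1", 10, 20, 30, 40), ("chr2", 20, 40, 60, 80)])
        table = rank_chromosomes(self._cis({"chr1": 5, "chr2": 10}), met)
        assert (table["mean_rank"] == 1.5).all()

    def test_hand_ranked_three_chromosomes(self):
        met = self._metrics(
            [("chr1", 100, 10, 50, 10), ("chr2", 50, 10, 100, 20), ("chr3", 100, 5, 50, 40)]
        )
        counts = {"chr1": 10, "chr2": 10, "chr3": 10}
        table = rank_chromosomes(self._cis(counts), met)
        # densities per length: .1, .2, .1 -> ranks 2.5, 1, 2.5
        # per genes: 1, 1, 2 -> ranks 2.5, 2.5, 1
        # per rna: .2, .1, .2 -> ranks 1.5, 3, 1.5
        # per variants: 1, .5, .25 -> ranks 1, 2, 3
        assert table.loc["chr1", "mean_rank"] == pytest.approx((2.5 + 2.5 + 1.5 + 1) / 4)
        assert table.loc["chr2", "mean_rank"] == pytest.approx((1 + 2.5 + 3 + 2) / 4)
        assert table.loc["chr3", "mean_rank"] == pytest.approx((2.5 + 1 + 1.5 + 3) / 4)

    def test_rank_columns_are_permutations(self, study, harmonized):
        best, _, _ = harmonized
        cis = best[best["location_class"].isin(["in_gene", "cis"])]
        table = rank_chromosomes(cis, study.genome.metrics)
        n = len(table)
        for col in table.columns:
            if col.startswith("rank_"):
                assert table[col].sum() == pytest.approx(n * (n + 1) / 2)

    def test_scaling_a_metric_preserves_ranks(self):
        met1 = self._metrics([("chr1", 100, 10, 50, 10), ("chr2", 50, 10, 100, 20)])
        met2 = met1.copy()
        met2["length_bp"] *= 7
        cis = self._cis({"chr1": 10, "chr2": 13})
        t1 = rank_chromosomes(cis, met1)
        t2 = rank_chromosomes(cis, met2)
        assert t1["mean_rank"].tolist() == t2["mean_rank"].tolist()

    def test_missing_metric_rejected(self):
        met = self._metrics([("chr1", 10, 10, 10, 10)])
        with pytest.raises(ValueError):
            rank_chromosomes(self._cis({"chr1": 1, "chr2": 1}), met)


class TestHousekeeping:
    def test_pooled_t_hand_example(self):
        freqs = pd.Series([1, 2, 3, 3, 4, 5], index=list("abcdef"))
        rep = compare_housekeeping(freqs, housekeeping={"a", "b", "c"})
        assert rep.t_statistic == pytest.approx(-2.449, abs=1e-3)
        assert rep.df == 4
        assert rep.p_value == pytest.approx(0.0705, abs=1e-3)

    def test_identical_groups_t_zero(self):
        freqs = pd.Series([2, 3, 2, 3], index=list("abcd"))
        rep = compare_housekeeping(freqs, housekeeping={"a", "b"})
        assert rep.t_statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_group_sizes_partition(self):
        freqs = pd.Series([1, 2, 3, 4], index=list("abcd"))
        rep = compare_housekeeping(freqs, housekeeping={"a", "b"})
        assert rep.n_housekeeping + rep.n_other == len(freqs)

    def test_planted_shift_detected(self):
        """A +5-dataset sharing shift in the housekeeping group is detected."""
        rng = np.random.default_rng(29)
        other = 1 + rng.poisson(2.0, size=200)
        hk = 1 + rng.poisson(2.0, size=200) + 5
        freqs = pd.Series(
            np.concatenate([hk, other]),
            index=[f"h{i}" for i in range(200)] + [f"o{i}" for i in range(200)],
        )
        rep = compare_housekeeping(freqs, {f"h{i}" for i in range(200)})
        assert rep.p_value < 1e-6

    def test_planted_housekeeping_boost_raises_group_mean(self, study, harmonized):
        """In the full synthetic study, housekeeping eGenes are shared more.

        The mean comparison is directional only: the master-gene stratum sits
        in the non-housekeeping group and dominates its variance, so the
        pooled t-test is not powered at this scale.
        """
        from eqtlatlas import build_occurrence

        best, _, _ = harmonized
        mat = build_occurrence(best, "gene")
        freqs = mat.sum(axis=1)
        rep = compare_housekeeping(freqs, set(study.truth.housekeeping_genes))
        assert rep.mean_housekeeping > rep.mean_other

    def test_tiny_group_rejected(self):
        freqs = pd.Series([1, 2, 3], index=list("abc"))
        with pytest.raises(ValueError):
            compare_housekeeping(freqs, housekeeping={"a"})
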