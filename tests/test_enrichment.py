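import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from epifootprint import enrichment_annotation as ea
from epifootprint.footprint_clustering import FootprintClusters
from epifootprint.io_formats import GenomicInterval, RegionSet


def regions(triples, roi="lincRNA_TSS", strand="."):
    return RegionSet(
        roi,
        [
            GenomicInterval(c, s, e, f"{roi}_{i}", strand)
            for i, (c, s, e) in enumerate(triples)
        ],
    )


def sites(tf, positions, width=10):
    return RegionSet(
        "tfbs",
        [GenomicInterval("chr1", p, p + width, f"{tf}_{i}") for i, p in enumerate(positions)],
    )


class TestTfbsEnrichment:
    def test_exact_hypergeometric_example(self):
        # N=10, K=4, n=5, k=4 -> p = C(4,4) C(6,1) / C(10,5)
        roi = regions([("chr1", 0, 1000)])
        tf_a = sites("A", [10, 100, 200, 300])  # 4 sites, all inside ROI
        tf_b = sites("B", [500, 2000, 3000, 4000, 5000, 6000])  # 1 inside
        df = ea.tfbs_enrichment(roi, {"A": tf_a, "B": tf_b})
        row = df[df["tf"] == "A"].iloc[0]
        assert (row["k"], row["K"], row["n"], row["N"]) == (4, 4, 5, 10)
        expected = comb(4, 4) * comb(6, 1) / comb(10, 5)
        assert row["p"] == pytest.approx(expected)

    def test_agrees_with_exhaustive_enumeration_all_small_n(self):
        """Upper-tail hypergeometric probability equals brute-force
        enumeration over all n-subsets for every N <= 12."""
        from scipy import stats

        for N in range(2, 13):
            for K in range(1, N):
                for n in range(1, N):
                    for k in range(0, min(K, n) + 1):
                        # enumerate all subsets of size n from N items, K marked
                        hits = sum(
                            1
                            for subset in itertools.combinations(range(N), n)
                            if sum(1 for x in subset if x < K) >= k
                        )
                        brute = hits / comb(N, n)
                        p = float(stats.hypergeom.sf(k - 1, N, K, n))
                        assert p == pytest.approx(brute, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        roi = regions([("chr1", 0, 100)])
        tf_a = sites("A", [5000, 6000])
        tf_b = sites("B", [50, 7000])
        df = ea.tfbs_enrichment(roi, {"A": tf_a, "B": tf_b})
        assert df[df["tf"] == "A"].iloc[0]["p"] == pytest.approx(1.0)

    def test_single_bp_overlap_counts(self):
        roi = regions([("chr1", 100, 200)])
        df = ea.tfbs_enrichment(roi, {"A": sites("A", [91], width=10), "B": sites("B", [500])})
        assert df[df["tf"] == "A"].iloc[0]["k"] == 1

    def test_site_in_two_rois_counted_once(self):
        roi = regions([("chr1", 0, 105), ("chr1", 103, 200)])
        df = ea.tfbs_enrichment(roi, {"A": sites("A", [100]), "B": sites("B", [5000])})
        assert df[df["tf"] == "A"].iloc[0]["k"] == 1

    def test_empty_tf_skipped_with_warning(self):
        roi = regions([("chr1", 0, 100)])
        df = ea.tfbs_enrichment(roi, {"A": sites("A", [50]), "B": RegionSet("tfbs", [])})
        assert list(df["tf"]) == ["A"]


class TestGeneAssociation:
    def gene(self, tss_pos, name, strand="+", chrom="chr1"):
        return GenomicInterval(chrom, tss_pos, tss_pos + 2000, name, strand)

    def test_isolated_gene_reaches_200kb(self):
        genes = RegionSet("gene_tss", [self.gene(1_000_000, "g1")])
        query = regions([("chr1", 1_200_000, 1_201_000)])
        assoc = ea.associate_regions_to_genes(query, genes)
        assert assoc.associations["lincRNA_TSS_0"] == {"g1"}

    def test_600kb_beyond_cap_not_associated(self):
        genes = RegionSet("gene_tss", [self.gene(1_000_000, "g1")])
        query = regions([("chr1", 1_600_000, 1_601_000)])
        assoc = ea.associate_regions_to_genes(query, genes)
        assert assoc.associations["lincRNA_TSS_0"] == set()

    def test_region_midway_between_two_genes_hits_both(self):
        # two plus-strand genes 300 kb apart: each extension reaches the
        # other's basal boundary, so a midway region belongs to both domains
        genes = RegionSet(
            "gene_tss", [self.gene(1_000_000, "g1"), self.gene(1_300_000, "g2")]
        )
        query = regions([("chr1", 1_150_000, 1_151_000)])
        assoc = ea.associate_regions_to_genes(query, genes)
        assert assoc.associations["lincRNA_TSS_0"] == {"g1", "g2"}

    def test_basal_domain_strand_orientation(self):
        # minus-strand gene: 5 kb upstream lies to the right of the TSS
        genes = RegionSet(
            "gene_tss", [GenomicInterval("chr1", 998_001, 1_000_001, "g1", "-")]
        )
        # TSS = 1_000_000; basal = [TSS-1000+1, TSS+5000+1)
        near_up = regions([("chr1", 1_004_000, 1_004_500)])
        assoc = ea.associate_regions_to_genes(near_up, genes, max_ext=0)
        assert assoc.associations["lincRNA_TSS_0"] == {"g1"}

    def test_monotone_in_extension_cap(self):
        genes = RegionSet(
            "gene_tss", [self.gene(1_000_000, "g1"), self.gene(2_000_000, "g2")]
        )
        query = regions([("chr1", 1_400_000, 1_401_000), ("chr1", 1_900_000, 1_901_000)])
        small = ea.associate_regions_to_genes(query, genes, max_ext=50_000)
        large = ea.associate_regions_to_genes(query, genes, max_ext=500_000)
        for region in small.associations:
            assert small.associations[region] <= large.associations[region]

    def test_unstranded_gene_rejected(self):
        genes = RegionSet(
            "gene_tss", [GenomicInterval("chr1", 0, 100, "g1", ".")]
        )
        with pytest.raises(ValueError, match="strand"):
            ea.associate_regions_to_genes(regions([("chr1", 0, 50)]), genes)


class TestDistanceBins:
    def gene_set(self, positions):
        return RegionSet(
            "gene_tss",
            [
                GenomicInterval("chr1", p, p + 100, f"g{i}", "+")
                for i, p in enumerate(positions)
            ],
        )

    def query_at(self, positions):
        return RegionSet(
            "lincRNA_TSS",
            [
                GenomicInterval("chr1", p, p + 3000, f"q{i}", "+")
                for i, p in enumerate(positions)
            ],
        )

    def test_coincident_tss_in_first_bin(self):
        report = ea.distance_bins(self.query_at([1000]), self.gene_set([1000]))
        assert report.counts["<5kb"] == 1

    def test_exact_5kb_boundary_goes_to_second_bin(self):
        report = ea.distance_bins(self.query_at([6000]), self.gene_set([1000]))
        assert report.counts["5-50kb"] == 1 and report.counts["<5kb"] == 0

    def test_hand_placed_distances_partition(self):
        genes = self.gene_set([1_000_000])
        query = self.query_at([1_001_000, 1_010_000, 1_100_000, 1_600_000])
        report = ea.distance_bins(query, genes)
        assert report.counts == {"<5kb": 1, "5-50kb": 1, "50-500kb": 1, ">500kb": 1}
        assert sum(report.counts.values()) == len(query)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ea.distance_bins(RegionSet("lincRNA_TSS", []), self.gene_set([0]))


class TestExpressionByCluster:
    def clusters(self, mapping):
        k = max(mapping.values())
        return FootprintClusters(mapping, np.zeros((k, 1)), k, 0.0)

    def test_constant_rpkm_median_and_zero_iqr(self):
        expr = pd.DataFrame({"name": ["a", "b"], "rpkm": [3.0, 3.0]})
        out = ea.expression_by_cluster(self.clusters({"a": 1, "b": 1}), expr)
        row = out[out["kind"] == "element"].iloc[0]
        assert row["median_rpkm"] == 3.0 and row["iqr_rpkm"] == 0.0

    def test_planted_high_low_ordering(self, rng):
        names = [f"t{i}" for i in range(20)]
        mapping = {n: 1 if i < 10 else 2 for i, n in enumerate(names)}
        rpkm = np.r_[rng.uniform(50, 60, 10), rng.uniform(1, 2, 10)]
        expr = pd.DataFrame({"name": names, "rpkm": rpkm})
        out = ea.expression_by_cluster(self.clusters(mapping), expr)
        med = out[out["kind"] == "element"].set_index("cluster")["median_rpkm"]
        assert med[1] > med[2]

    def test_row_order_invariance(self, rng):
        names = [f"t{i}" for i in range(10)]
        expr = pd.DataFrame({"name": names, "rpkm": rng.uniform(0, 5, 10)})
        mapping = {n: 1 + i % 2 for i, n in enumerate(names)}
        a = ea.expression_by_cluster(self.clusters(mapping), expr)
        b = ea.expression_by_cluster(
            self.clusters(mapping), expr.sample(frac=1.0, random_state=0)
        )
        pd.testing.assert_frame_equal(a, b)

    def test_empty_intersection_rejected(self):
        expr = pd.DataFrame({"name": ["zzz"], "rpkm": [1.0]})
        with pytest.raises(ValueError, match="no assigned"):
            ea.expression_by_cluster(self.clusters({"a": 1}), expr)
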