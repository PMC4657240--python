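"""Feature assignment, expression binning, overlaps, correlations, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crmclass as cc
from crmclass.annotate import random_regions

from conftest import make_track


@pytest.fixture
def annotation():
    genes = pd.DataFrame([
        {"gene_id": "gA", "chrom": "chrA", "strand": "+", "start": 1000, "end": 5000},
        {"gene_id": "gB", "chrom": "chrA", "strand": "-", "start": 10_000, "end": 14_000},
    ])
    exons = pd.DataFrame([
        {"gene_id": "gA", "chrom": "chrA", "start": 1000, "end": 1400},
        {"gene_id": "gA", "chrom": "chrA", "start": 4500, "end": 5000},
        {"gene_id": "gB", "chrom": "chrA", "start": 10_000, "end": 10_500},
    ])
    return cc.GeneAnnotation(genes, exons)


def peak_at(centre, chrom="chrA"):
    return cc.Peak(chrom, centre - 50, centre + 50, centre, 1.0, 1.0)


class TestAssignFeature:
    @pytest.mark.parametrize("centre,expected", [
        (950, "promoter"),       # 50 bp upstream of gA's TSS
        (1200, "exon"),          # inside gA exon 1 (also promoter? no: TSS+100=1100)
        (2000, "intron"),        # inside gA, not exon, not promoter
        (120_000, "intergenic"),
        (14_040, "promoter"),    # 41 bp upstream of gB (minus strand, TSS=13999)
    ])
    def test_feature_by_centre(self, annotation, centre, expected):
        assert cc.assign_feature(peak_at(centre), annotation) == expected

    def test_promoter_takes_precedence_over_exon(self, annotation):
        # gA exon bases within [TSS-500, TSS+100) are promoter, not exon
        assert cc.assign_feature(peak_at(1050), annotation) == "promoter"

    def test_fractions_sum_to_one(self, annotation, rng):
        peaks = [peak_at(int(c)) for c in rng.integers(100, 20_000, 60)]
        labels = rng.integers(1, 4, size=60)
        fr = cc.feature_fractions(peaks, labels, annotation)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)


class TestExpressionBins:
    def test_nine_genes_split_three_ways(self):
        s = pd.Series(range(9), index=[f"g{i}" for i in range(9)])
        bins = cc.expression_bins(s)
        assert bins.value_counts().tolist() == [3, 3, 3]
        assert bins.loc["g0"] == "low" and bins.loc["g8"] == "high"

    def test_ten_genes_remainder_policy(self):
        s = pd.Series(range(10), index=[f"g{i}" for i in range(10)])
        sizes = cc.expression_bins(s).value_counts()
        assert sizes["low"] == 4 and sizes["mid"] == 3 and sizes["high"] == 3

    def test_all_equal_values_split_deterministically_by_id(self):
        s = pd.Series(1.0, index=[f"g{i}" for i in range(6)])
        bins = cc.expression_bins(s)
        assert bins.loc["g0"] == "low" and bins.loc["g5"] == "high"

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            cc.expression_bins(pd.Series([1.0, 2.0], index=["a", "b"]))


class TestNearestGene:
    def test_closest_tss_wins(self, annotation):
        assert cc.nearest_gene(peak_at(2000), annotation) == "gA"  # TSS 1000 vs 13999

    def test_equidistant_tie_takes_smaller_id(self):
        genes = pd.DataFrame([
            {"gene_id": "gZ", "chrom": "c", "strand": "+", "start": 1000, "end": 2000},
            {"gene_id": "gB", "chrom": "c", "strand": "+", "start": 3000, "end": 4000},
        ])
        ann = cc.GeneAnnotation(genes, pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]))
        assert cc.nearest_gene(peak_at(2000, "c"), ann) == "gB"

    def test_single_gene_always_wins(self):
        genes = pd.DataFrame([{"gene_id": "g1", "chrom": "c", "strand": "+",
                               "start": 0, "end": 100}])
        ann = cc.GeneAnnotation(genes, pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]))
        assert cc.nearest_gene(peak_at(99_000, "c"), ann) == "g1"


class TestOverlapFraction:
    def test_self_overlap_is_one_and_disjoint_zero(self, rng):
        g = cc.GenomeModel(("c",), {"c": 100_000}, 10)
        a = cc.RegionSet.from_records([("c", 100, 200), ("c", 5000, 5100)])
        b = cc.RegionSet.from_records([("c", 50_000, 50_100)])
        f, _, _ = cc.overlap_fraction(a, a, g, n_draws=5, rng=rng)
        assert f == 1.0
        f, _, _ = cc.overlap_fraction(a, b, g, n_draws=5, rng=rng)
        assert f == 0.0

    def test_empty_class_rejected(self, rng):
        g = cc.GenomeModel(("c",), {"c": 1000}, 10)
        empty = cc.RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        ref = cc.RegionSet.from_records([("c", 0, 10)])
        with pytest.raises(ValueError):
            cc.overlap_fraction(empty, ref, g, rng=rng)

    def test_rgr_matches_binomial_closed_form(self, rng):
        # reference covers fraction c of the genome; 1-bp random regions hit
        # it with probability ≈ c
        g = cc.GenomeModel(("c",), {"c": 100_000}, 10)
        ref = cc.RegionSet.from_records([("c", 0, 30_000)])  # c = 0.3
        n = 400
        cls = cc.RegionSet.from_records(
            [("c", int(s), int(s) + 1) for s in rng.integers(0, 99_999, n)])
        _, rgr, _ = cc.overlap_fraction(cls, ref, g, n_draws=50, rng=rng)
        se = np.sqrt(0.3 * 0.7 / (n * 50))
        assert abs(rgr - 0.3) < 4 * se

    def test_random_regions_match_length_distribution(self, rng):
        g = cc.GenomeModel(("c",), {"c": 100_000}, 10)
        lengths = np.array([10, 200, 3000])
        rr = random_regions(g, lengths, rng)
        assert sorted(rr.lengths().tolist()) == sorted(lengths.tolist())


class TestGeneOverlapMatrix:
    def test_diagonal_disjoint_and_asymmetry(self):
        M = cc.gene_overlap_matrix([{"a", "b", "c", "d"}, {"a"}, {"x"}])
        assert M[0, 0] == M[1, 1] == M[2, 2] == 100.0
        assert M[0, 1] == 25.0 and M[1, 0] == 100.0
        assert M[0, 2] == M[2, 0] == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cc.gene_overlap_matrix([{"a"}, set()])


class TestFactorCorrelation:
    def matrix(self, rng, n=40):
        a = rng.normal(size=n)
        return pd.DataFrame({"CBP": a, "same": a, "mono": np.exp(a),
                             "noise": rng.normal(size=n)})

    def test_identical_and_monotone_columns_give_rho_one(self, rng):
        df = self.matrix(rng)
        res = cc.factor_correlation(df, np.ones(len(df), dtype=int), "CBP")
        rho = res.set_index("factor")["rho"]
        assert rho["same"] == pytest.approx(1.0)
        assert rho["mono"] == pytest.approx(1.0)

    def test_constant_column_reported_missing(self, rng, caplog):
        df = self.matrix(rng)
        df["flat"] = 2.0
        res = cc.factor_correlation(df, np.ones(len(df), dtype=int), "CBP")
        assert np.isnan(res.set_index("factor").loc["flat", "rho"])

    def test_small_classes_skipped(self, rng):
        df = self.matrix(rng, n=3)
        res = cc.factor_correlation(df, np.ones(3, dtype=int), "CBP")
        assert res.empty

    def test_bh_adjustment_present_when_requested(self, rng):
        df = self.matrix(rng)
        res = cc.factor_correlation(df, np.ones(len(df), dtype=int), "CBP", adjust=True)
        assert "p_adj" in res.columns and (res["p_adj"] >= res["p"] - 1e-12).all()


class TestDevExpressionProfile:
    def test_constant_expression_gives_zero_profile(self):
        tc = pd.DataFrame(3.0, index=["g1", "g2"], columns=list("abcd"))
        prof = cc.dev_expression_profile(tc, ["g1", "g2"])
        assert np.allclose(prof, 0.0)

    def test_profile_always_means_zero(self, rng):
        tc = pd.DataFrame(rng.normal(size=(10, 6)),
                          index=[f"g{i}" for i in range(10)])
        prof = cc.dev_expression_profile(tc, [f"g{i}" for i in range(5)])
        assert prof.mean() == pytest.approx(0.0, abs=1e-12)

    def test_linear_riser_centres_to_zero(self):
        tc = pd.DataFrame([np.arange(5.0)], index=["g1"])
        prof = cc.dev_expression_profile(tc, ["g1"])
        assert np.allclose(prof, 0.0)  # Δ ≡ 1 before centering


class TestFractionEnriched:
    def make(self, values):
        g = cc.GenomeModel(("c",), {"c": len(values) * 10}, 10)
        return make_track(g, {"c": np.asarray(values, float)})

    def test_all_regions_over_threshold(self):
        t = self.make([1.5] * 100)
        regs = cc.RegionSet.from_records([("c", 0, 100), ("c", 500, 600)])
        assert cc.fraction_enriched(regs, t, fold=2) == 1.0

    def test_zero_track_gives_zero(self):
        t = self.make([0.0] * 100)
        regs = cc.RegionSet.from_records([("c", 0, 100)])
        assert cc.fraction_enriched(regs, t, fold=2) == 0.0

    def test_constructed_thirty_percent(self):
        v = np.zeros(1000)
        regs = []
        for i in range(10):
            s = i * 100
            regs.append(("c", s * 10, (s + 5) * 10))
            if i < 3:
                v[s + 2] = 1.5  # ≥ log2(2) only for the first three regions
        t = self.make(v)
        assert cc.fraction_enriched(cc.RegionSet.from_records(regs), t, 2) == 0.30


class TestDistanceToDomains:
    def test_inside_and_left_distances(self):
        dom = cc.RegionSet.from_records([("c", 10_000, 20_000)])
        inside = [cc.Peak("c", 14_000, 14_100, 14_050, 1, 1)]
        left = [cc.Peak("c", 4_950, 5_050, 5_000, 1, 1)]
        d1, d2, _ = cc.distance_to_domains(inside, dom, left)
        assert d1[0] == 0.0
        assert d2[0] == 5000.0

    def test_separated_sets_detected_by_test(self, rng):
        dom = cc.RegionSet.from_records([("c", 0, 1000)])
        near = [cc.Peak("c", int(c), int(c) + 100, int(c) + 50, 1, 1)
                for c in rng.normal(20_000, 2000, 60)]
        far = [cc.Peak("c", int(c), int(c) + 100, int(c) + 50, 1, 1)
               for c in rng.normal(35_000, 2000, 60)]
        _, _, p = cc.distance_to_domains(near, dom, far)
        assert p < 0.05
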