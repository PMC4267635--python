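import numpy as np
import pytest

from cclamp import integrate as integ
from cclamp.io import ExpressionRecord, GeneModel, Peak
from cclamp.motifs import PeakMotifProfile
from oracles import enum_gsea, enum_hypergeom_sf


def rec(gene, lfc, p):
    return ExpressionRecord(gene, lfc, p)


class TestSelectRegulated:
    def test_downregulated_below_cutoff(self):
        sets = integ.select_regulated([rec("AXIN2", -0.77, 0.001)], 0.02)
        assert sets.down == {"AXIN2"} and sets.up == set()

    def test_non_significant_excluded(self):
        sets = integ.select_regulated([rec("AXIN2", -0.77, 0.05)], 0.02)
        assert sets.down == set() and sets.up == set()

    def test_zero_fold_change_in_neither(self):
        sets = integ.select_regulated([rec("g", 0.0, 0.0001)], 0.02)
        assert sets.down == set() and sets.up == set()

    def test_sets_disjoint(self, rng):
        records = [rec(f"g{i}", float(l), float(p))
                   for i, (l, p) in enumerate(zip(rng.normal(0, 1, 200), rng.random(200)))]
        sets = integ.select_regulated(records, 0.1)
        assert sets.down & sets.up == set()


class TestLinkPeaksToGenes:
    GENES = [GeneModel("g1", "chr1", "+", 100_000, 104_000, [])]

    def peak(self, center, score=100.0, pid="p"):
        return Peak("chr1", center - 100, center + 100, score, peak_id=pid)

    @pytest.mark.parametrize("offset,linked", [(29_999, True), (30_000, True), (30_001, False)])
    def test_distance_boundary_inclusive(self, offset, linked):
        links = integ.link_peaks_to_genes([self.peak(100_000 + offset)], self.GENES)
        assert bool(links) is linked

    @pytest.mark.parametrize("score,linked", [(66.9, False), (67.0, False), (67.1, True)])
    def test_score_cutoff_strict(self, score, linked):
        links = integ.link_peaks_to_genes([self.peak(100_500, score)], self.GENES, min_score=67)
        assert bool(links) is linked

    def test_distance_sign_follows_strand(self):
        gene_minus = GeneModel("gm", "chr1", "-", 100_000, 96_000, [])
        (link,) = integ.link_peaks_to_genes([self.peak(99_000)], [gene_minus])
        assert link.linked_peaks[0][1] == 1000  # left of a minus-strand TSS = downstream

    def test_matches_quadratic_oracle(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", "+", int(t), int(t) + 1000, [])
                 for i, t in enumerate(rng.integers(0, 500_000, 30))]
        peaks = [Peak("chr1", int(s), int(s) + 200, 100.0, peak_id=f"p{i}")
                 for i, s in enumerate(rng.integers(0, 500_000, 60))]
        links = {l.gene_id: {p for p, _, _ in l.linked_peaks}
                 for l in integ.link_peaks_to_genes(peaks, genes, max_distance=20_000)}
        for g in genes:
            expected = {p.peak_id for p in peaks if abs(p.center - g.tss) <= 20_000}
            assert links.get(g.gene_id, set()) == expected

    def test_gene_class_from_best_linked_peak(self):
        profiles = {
            "p1": PeakMotifProfile("p1", 200, {"WRE": 1, "Helper": 0}),
            "p2": PeakMotifProfile("p2", 200, {"WRE": 1, "Helper": 2}),
        }
        peaks = [self.peak(100_500, pid="p1"), self.peak(101_500, pid="p2")]
        (link,) = integ.link_peaks_to_genes(peaks, self.GENES, profiles)
        assert link.motif_class == "both_multi_helper"


class TestMotifClass:
    @pytest.mark.parametrize(
        "wre,helper,expected",
        [(0, 0, "none"), (0, 3, "helper_only"), (2, 0, "wre_only"),
         (1, 1, "both"), (1, 2, "both_multi_helper")],
    )
    def test_classification(self, wre, helper, expected):
        assert integ.motif_class(wre, helper) == expected


class TestHypergeometricOverlap:
    def test_full_overlap_worked_case(self):
        a = {f"g{i}" for i in range(10)}
        overlap, p = integ.hypergeometric_overlap(a, a, 20)
        assert overlap == 10
        assert p == pytest.approx(1 / 184_756)  # 1 / C(20,10)

    def test_empty_set_trivial(self):
        overlap, p = integ.hypergeometric_overlap(set(), {"a"}, 10)
        assert (overlap, p) == (0, 1.0)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            integ.hypergeometric_overlap({"a", "b"}, {"c"}, 1)

    def test_matches_enumeration_small_universes(self, rng):
        for _ in range(20):
            universe = int(rng.integers(2, 13))
            n_a = int(rng.integers(0, universe + 1))
            n_b = int(rng.integers(0, universe + 1))
            pool = [f"g{i}" for i in range(universe)]
            a = set(rng.choice(pool, n_a, replace=False))
            b = set(rng.choice(pool, n_b, replace=False))
            overlap, p = integ.hypergeometric_overlap(a, b, universe)
            if a and b:
                assert p == pytest.approx(enum_hypergeom_sf(universe, n_a, n_b, overlap))


class TestGsea:
    RANKED = ["g1", "g2", "g3", "g4"]  # scores descending

    def test_top_half_es_is_one(self):
        assert integ.running_sum_es(self.RANKED, {"g1", "g2"}) == pytest.approx(1.0)

    def test_bottom_half_mirrors_negative(self):
        assert integ.running_sum_es(self.RANKED, {"g3", "g4"}) == pytest.approx(-1.0)

    def test_exact_four_choose_two_null(self):
        # exactly one of the six 2-subsets attains ES = 1.0
        table = enum_gsea(self.RANKED, 2)
        assert sum(es >= 1.0 - 1e-12 for _, es in table) == 1
        res = integ.peak_score_gsea(self.RANKED, {"g1", "g2"}, n_permutations=6000, seed=5)
        assert res.enrichment_score == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 6, abs=0.02)

    def test_es_matches_exhaustive_enumeration(self, rng):
        ranked = [f"g{i}" for i in range(8)]
        for _, k in [(0, 2), (1, 3), (2, 4)]:
            for subset, es in enum_gsea(ranked, k):
                assert integ.running_sum_es(ranked, set(subset)) == pytest.approx(es)

    @pytest.mark.parametrize("subset", [set(), {"g1", "g2", "g3", "g4"}])
    def test_degenerate_subsets_rejected(self, subset):
        with pytest.raises(ValueError):
            integ.peak_score_gsea(self.RANKED, subset, n_permutations=100, seed=0)

    def test_seeded_permutations_reproducible(self):
        r1 = integ.peak_score_gsea(self.RANKED, {"g1"}, n_permutations=200, seed=3)
        r2 = integ.peak_score_gsea(self.RANKED, {"g1"}, n_permutations=200, seed=3)
        assert r1.p_value == r2.p_value


class TestMotifClassAssociation:
    def links(self, classes):
        return [integ.GeneLink(f"g{i}", [(f"p{i}", 100, 80.0)], 80.0, c)
                for i, c in enumerate(classes)]

    def records(self, n, lfc=-0.5):
        return [rec(f"g{i}", lfc, 0.01) for i in range(n)]

    def test_single_class_no_tests(self):
        assoc = integ.motif_class_association(self.links(["both"] * 5), self.records(5))
        assert assoc.pairwise_p == {}

    def test_small_classes_reported_untested(self):
        classes = ["wre_only"] * 2 + ["both"] * 5
        assoc = integ.motif_class_association(self.links(classes), self.records(7))
        summary = assoc.summary.set_index("motif_class")
        assert summary.loc["wre_only", "n_genes"] == 2
        assert all("wre_only" not in pair for pair in assoc.pairwise_p)

    def test_shifted_class_detected(self, rng):
        classes = ["wre_only"] * 50 + ["both_multi_helper"] * 50
        records = [rec(f"g{i}", float(rng.normal(-0.3, 0.3)), 0.01) for i in range(50)]
        records += [rec(f"g{i}", float(rng.normal(-1.0, 0.3)), 0.01) for i in range(50, 100)]
        assoc = integ.motif_class_association(self.links(classes), records)
        assert assoc.pairwise_p[("wre_only", "both_multi_helper")] < 1e-6
        summary = assoc.summary.set_index("motif_class")["median_log2fc"]
        assert summary["both_multi_helper"] < summary["wre_only"]


class TestTargetGeneReport:
    def test_distances_comma_joined_ascending(self):
        link = integ.GeneLink("AXIN2", [("p2", 4234, 70.0), ("p1", 483, 90.0)], 90.0, "both")
        df = integ.target_gene_report([link], {"AXIN2"}, [rec("AXIN2", -0.77, 0.001)])
        assert df.iloc[0]["tss_distances"] == "483, 4234"

    def test_unregulated_and_unlinked_absent(self):
        links = [integ.GeneLink("g1", [("p1", 100, 80.0)], 80.0, "none")]
        df = integ.target_gene_report(links, {"other_gene"}, [rec("g1", -0.5, 0.001)])
        assert df.empty

    def test_known_target_flag(self):
        link = integ.GeneLink("SP5", [("p1", -176, 90.0)], 90.0, "both")
        df = integ.target_gene_report([link], {"SP5"}, [rec("SP5", -2.2, 0.001)], {"SP5"})
        assert bool(df.iloc[0]["known_target"]) is True
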