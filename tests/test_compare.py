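import numpy as np
import pytest
from scipy import stats

from cclamp import compare as cmp
from cclamp.io import Peak
from cclamp.motifs import MotifHit, PeakMotifProfile
from oracles import enum_mannwhitney_p, enum_signrank_p


def peak(chrom, start, end, score=10.0, pid=None):
    return Peak(chrom, start, end, score, peak_id=pid or f"{chrom}:{start}-{end}")


class TestOverlapRegions:
    def test_single_base_overlap_counts(self):
        pairs = cmp.overlap_regions([peak("c", 100, 200)], [peak("c", 199, 300)])
        assert len(pairs) == 1 and pairs[0].overlap_bp == 1

    def test_half_open_adjacency_does_not(self):
        assert cmp.overlap_regions([peak("c", 100, 200)], [peak("c", 200, 300)]) == []

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(25):
            a = [peak("c", s, s + l, pid=f"a{i}")
                 for i, (s, l) in enumerate(zip(rng.integers(0, 900, 25), rng.integers(1, 80, 25)))]
            b = [peak("c", s, s + l, pid=f"b{i}")
                 for i, (s, l) in enumerate(zip(rng.integers(0, 900, 25), rng.integers(1, 80, 25)))]
            got = {(p.peak_a.peak_id, p.peak_b.peak_id, p.overlap_bp)
                   for p in cmp.overlap_regions(a, b)}
            want = set()
            for x in a:
                for y in b:
                    ov = min(x.end, y.end) - max(x.start, y.start)
                    if ov >= 1:
                        want.add((x.peak_id, y.peak_id, ov))
            assert got == want


class TestReciprocalOverlap:
    def test_identical_sets(self):
        peaks = [peak("c", i * 100, i * 100 + 50, score=i + 1, pid=f"p{i}") for i in range(10)]
        assert cmp.reciprocal_overlap_fraction(peaks, peaks, 0.2) == (1.0, 1.0)

    def test_disjoint_sets(self):
        a = [peak("c", i * 100, i * 100 + 40, pid=f"a{i}") for i in range(10)]
        b = [peak("c", i * 100 + 50, i * 100 + 90, pid=f"b{i}") for i in range(10)]
        assert cmp.reciprocal_overlap_fraction(a, b, 0.2) == (0.0, 0.0)

    def test_recovers_planted_shared_fraction(self):
        from cclamp.simulate import SyntheticConfig, simulate

        fractions = []
        for seed in range(5):
            cfg = SyntheticConfig(
                seed=seed, n_chromosomes=1, chrom_length=2_000_000, n_genes=10,
                n_peaks_wt=500, n_peaks_mut=500, peak_length_range=(150, 250),
                shared_region_fraction=0.6, gene_peak_fraction=0.0,
            )
            fx = simulate(cfg)
            f_wt, f_mut = cmp.reciprocal_overlap_fraction(fx.peaks_wt, fx.peaks_mut, 0.2)
            fractions += [f_wt, f_mut]
        assert abs(np.mean(fractions) - 0.6) < 0.05


class TestClassifyStrength:
    def pairs(self, scores):
        return [
            cmp.MatchedRegionPair(peak("c", i * 10, i * 10 + 5, a, pid=f"a{i}"),
                                  peak("c", i * 10, i * 10 + 5, b, pid=f"b{i}"), 5, a, b)
            for i, (a, b) in enumerate(scores)
        ]

    def test_ratio_classification(self):
        res = cmp.classify_strength(self.pairs([(30, 10), (10, 10), (10, 30)]))
        assert [p.strength_class for p in res.pairs] == ["a_stronger", "similar", "b_stronger"]

    def test_swap_symmetry(self, rng):
        scores = [(float(a), float(b)) for a, b in rng.integers(1, 100, size=(40, 2))]
        fwd = cmp.classify_strength(self.pairs(scores))
        rev = cmp.classify_strength(self.pairs([(b, a) for a, b in scores]))
        assert fwd.n_a_stronger == rev.n_b_stronger
        assert fwd.n_similar == rev.n_similar

    def test_signed_rank_matches_sign_flip_enumeration(self, rng):
        for _ in range(10):
            a = rng.uniform(1, 100, 5)
            b = rng.uniform(1, 100, 5)
            res = cmp.classify_strength(self.pairs(list(zip(a, b))))
            assert res.p_value == pytest.approx(enum_signrank_p(list(a), list(b)))

    def test_zero_scores_rejected(self):
        with pytest.raises(ValueError):
            cmp.classify_strength(
                [cmp.MatchedRegionPair(peak("c", 0, 5, 1), peak("c", 0, 5, 1), 5, 0.0, 1.0)]
            )


class TestMannWhitney:
    def test_exact_small_sample_example(self):
        _, p = cmp.mann_whitney([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    def test_matches_enumeration_with_ties(self, rng):
        for _ in range(15):
            n_x = int(rng.integers(1, 5))
            n_y = int(rng.integers(1, 5))
            x = rng.integers(0, 4, n_x).astype(float).tolist()
            y = rng.integers(0, 4, n_y).astype(float).tolist()
            _, p = cmp.mann_whitney(x, y)
            assert p == pytest.approx(enum_mannwhitney_p(x, y))

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.8, 1, 60)
        _, p = cmp.mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))


class TestStratifyByCopyNumber:
    def make_inputs(self, counts, diffs):
        pairs, profiles = [], {}
        for i, (c, d) in enumerate(zip(counts, diffs)):
            a = peak("c", i * 100, i * 100 + 50, 50.0 + d, pid=f"a{i}")
            b = peak("c", i * 100, i * 100 + 50, 50.0, pid=f"b{i}")
            pairs.append(cmp.MatchedRegionPair(a, b, 50, a.score, b.score))
            profiles[a.peak_id] = PeakMotifProfile(a.peak_id, 50, {"shortHelper": c})
        return pairs, profiles

    def test_all_zero_counts_single_bin_no_tests(self):
        pairs, profiles = self.make_inputs([0, 0, 0], [1, 2, 3])
        strata = cmp.stratify_by_copy_number(pairs, profiles)
        assert strata.bin_sizes == {"0": 3, "1": 0, "2-3": 0, "4+": 0}
        assert strata.pairwise_p == {}

    def test_additive_effect_gives_monotone_medians(self, rng):
        counts = rng.integers(0, 6, 200)
        diffs = 5.0 * counts + rng.normal(0, 1, 200)
        pairs, profiles = self.make_inputs(counts.tolist(), diffs.tolist())
        strata = cmp.stratify_by_copy_number(pairs, profiles)
        med = [strata.median_diff[b] for b in strata.bin_labels]
        assert med == sorted(med)

    def test_two_by_two_matches_enumeration(self):
        pairs, profiles = self.make_inputs([0, 0, 1, 1], [1.0, 2.0, 5.0, 6.0])
        strata = cmp.stratify_by_copy_number(pairs, profiles, bins=((0, 0), (1, 1)))
        assert strata.pairwise_p[("0", "1")] == pytest.approx(
            enum_mannwhitney_p([1.0, 2.0], [5.0, 6.0])
        )


class TestMotifCenterProfile:
    def test_centered_hit_offset_zero(self):
        p = peak("c", 0, 200, pid="p")
        hit = MotifHit("m", 96, "+", peak_id="p")
        edges, counts = cmp.motif_center_profile([hit], {"p": p}, motif_length=8)
        bin_of_zero = np.searchsorted(edges, 0, side="right") - 1
        assert counts[bin_of_zero] == 1 and counts.sum() == 1

    def test_uniform_positions_flat_histogram(self, rng):
        p = peak("c", 0, 2000, pid="p")
        starts = rng.integers(0, 2000 - 8, 4000)
        hits = [MotifHit("m", int(s), "+", peak_id="p") for s in starts]
        _, counts = cmp.motif_center_profile(hits, {"p": p}, motif_length=8, window=1800)
        chi2 = stats.chisquare(counts).pvalue
        assert chi2 > 0.001


class TestSpacingOrientation:
    W, H = 8, 6

    def records(self, wre, helpers):
        hits = {"p": [MotifHit("WRE", *wre, peak_id="p")]
                + [MotifHit("Helper", s, st, peak_id="p") for s, st in helpers]}
        return cmp.spacing_orientation(hits, wre_length=self.W, helper_length=self.H)

    def test_downstream_gap_positive(self):
        (rec,) = self.records((10, "+"), [(30, "+")])
        assert rec.signed_gap == 12 and rec.relative_orientation == "same"

    def test_upstream_gap_negative(self):
        (rec,) = self.records((30, "+"), [(10, "+")])
        assert rec.signed_gap == -14

    def test_opposite_strand_orientation(self):
        (rec,) = self.records((10, "-"), [(30, "+")])
        assert rec.relative_orientation == "opposite"
        assert rec.signed_gap == -12  # 3' of a minus-strand WRE is the left side

    def test_record_count_is_product_of_hits(self, rng):
        hits = {"p": [MotifHit("WRE", int(s), "+", peak_id="p") for s in rng.integers(0, 100, 3)]
                + [MotifHit("Helper", int(s), "-", peak_id="p") for s in rng.integers(0, 100, 4)]}
        assert len(cmp.spacing_orientation(hits)) == 12


class TestIncidence:
    def prof(self, incidences, length=100):
        return [PeakMotifProfile(f"p{i}", length, {"m": int(v * length)})
                for i, v in enumerate(incidences)]

    def test_identical_vectors_null(self):
        a = self.prof([0.1, 0.2, 0.3])
        res = cmp.compare_incidence(a, a, "m")
        assert res.p_value == 1.0

    def test_exact_small_sample(self):
        res = cmp.compare_incidence(self.prof([0.01, 0.02]), self.prof([0.03, 0.04]), "m")
        assert res.p_value == pytest.approx(2 / 6)

    def test_planted_shift_detected(self, rng):
        a = self.prof((rng.random(400) * 0.02 + 0.02).tolist())
        b = self.prof((rng.random(400) * 0.02).tolist())
        res = cmp.compare_incidence(a, b, "m")
        assert res.p_value < 1e-6 and res.mean_a > res.mean_b


class TestFractionWithMotif:
    def test_zero_when_absent(self):
        profiles = [PeakMotifProfile("p", 10, {"m": 0})]
        assert cmp.fraction_with_motif(profiles, "m") == 0.0

    def test_min_count_zero_is_everything(self):
        profiles = [PeakMotifProfile("p", 10, {"m": 0})]
        assert cmp.fraction_with_motif(profiles, "m", min_count=0) == 1.0

    def test_counts_threshold(self):
        profiles = [PeakMotifProfile(f"p{i}", 10, {"m": i}) for i in range(4)]
        assert cmp.fraction_with_motif(profiles, "m", min_count=2) == 0.5
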