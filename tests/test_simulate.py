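import json

import numpy as np
import pytest

from cclamp import io as cio
from cclamp.motifs import BUILTIN_MOTIFS, profile_peaks, scan_sequence
from cclamp.simulate import SyntheticConfig, make_fixture, simulate

FAST = dict(n_chromosomes=1, chrom_length=300_000, n_genes=20,
            n_peaks_wt=80, n_peaks_mut=80, peak_length_range=(150, 250))


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path):
        p1 = make_fixture(SyntheticConfig(seed=3, **FAST), tmp_path / "a")
        p2 = make_fixture(SyntheticConfig(seed=3, **FAST), tmp_path / "b")
        for key in ("genome", "genes", "peaks_wt", "peaks_mut", "expression", "manifest"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        p1 = make_fixture(SyntheticConfig(seed=3, **FAST), tmp_path / "a")
        p2 = make_fixture(SyntheticConfig(seed=4, **FAST), tmp_path / "b")
        assert p1["manifest"].read_bytes() != p2["manifest"].read_bytes()


class TestGenome:
    def test_gc_content_calibrated(self):
        fx = simulate(SyntheticConfig(seed=1, gc_content=0.5, n_chromosomes=1,
                                      chrom_length=1_000_000, n_genes=5,
                                      n_peaks_wt=1, n_peaks_mut=1,
                                      p_plant_wre_wt=0, p_plant_helper_wt=0,
                                      p_plant_wre_mut=0, p_plant_helper_mut=0))
        seq = fx.genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.003

    def test_zero_gc_is_at_only(self):
        fx = simulate(SyntheticConfig(seed=1, gc_content=0.0, **FAST,
                                      p_plant_wre_wt=0, p_plant_helper_wt=0,
                                      p_plant_wre_mut=0, p_plant_helper_mut=0))
        assert set(fx.genome["chr1"]) <= {"A", "T"}

    def test_genes_non_overlapping_sorted(self, small_fixture):
        by_chrom = {}
        for g in small_fixture.genes:
            by_chrom.setdefault(g.chrom, []).append((g.left, g.right))
        for spans in by_chrom.values():
            spans.sort()
            assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))

    def test_too_many_genes_rejected(self):
        with pytest.raises(ValueError):
            simulate(SyntheticConfig(seed=0, n_chromosomes=1, chrom_length=50_000, n_genes=50))


class TestPlanting:
    def test_manifest_motifs_fully_recoverable(self, small_fixture):
        for pl in small_fixture.plantings:
            motif = BUILTIN_MOTIFS[pl.motif]
            window = small_fixture.genome[pl.chrom][pl.position : pl.position + motif.length]
            hits = scan_sequence(window, motif)
            assert any(h.start == 0 and h.strand == pl.strand for h in hits), pl

    def test_certain_planting_gives_two_helpers_everywhere(self):
        cfg = SyntheticConfig(seed=5, **FAST, p_plant_wre_wt=1.0, p_plant_helper_wt=1.0,
                              helper_copy_distribution={2: 1.0})
        fx = simulate(cfg)
        seqs = cio.extract_peak_sequences(fx.peaks_wt, fx.genome)
        profiles = profile_peaks(seqs, [BUILTIN_MOTIFS["Helper"]])
        assert all(p.counts["Helper"] >= 2 for p in profiles)

    def test_score_decoupled_without_copy_effect(self):
        cfg = SyntheticConfig(seed=5, n_chromosomes=1, chrom_length=2_000_000, n_genes=10,
                              n_peaks_wt=500, n_peaks_mut=1, peak_length_range=(150, 250),
                              p_plant_wre_wt=0.5, p_plant_helper_wt=1.0,
                              helper_copy_distribution={1: 0.5, 3: 0.5},
                              score_per_helper_copy=0.0)
        fx = simulate(cfg)
        copies = np.array([fx.planted_counts[p.peak_id][1] for p in fx.peaks_wt])
        scores = np.array([p.score for p in fx.peaks_wt])
        from scipy.stats import spearmanr

        rho = spearmanr(copies, scores).statistic
        assert abs(rho) < 0.15

    def test_null_planting_matches_background_model(self):
        from cclamp.background import BackgroundModel, containment_probability

        cfg = SyntheticConfig(seed=11, n_chromosomes=1, chrom_length=2_000_000, n_genes=10,
                              n_peaks_wt=800, n_peaks_mut=1, peak_length_range=(300, 300),
                              p_plant_wre_wt=0, p_plant_helper_wt=0,
                              p_plant_wre_mut=0, p_plant_helper_mut=0)
        fx = simulate(cfg)
        seqs = cio.extract_peak_sequences(fx.peaks_wt, fx.genome)
        profiles = profile_peaks(seqs, [BUILTIN_MOTIFS["Helper"]])
        observed = np.mean([p.counts["Helper"] >= 1 for p in profiles])
        model = BackgroundModel.from_sequences(seqs.values())
        expected = containment_probability(300, BUILTIN_MOTIFS["Helper"], 1, model)
        se = np.sqrt(expected * (1 - expected) / len(profiles))
        assert abs(observed - expected) < 4 * se + 0.01


class TestExpression:
    def test_null_p_values_calibrated(self):
        fractions = []
        for seed in range(5):
            cfg = SyntheticConfig(seed=seed, n_chromosomes=1, chrom_length=2_000_000, n_genes=200,
                                  n_peaks_wt=5, n_peaks_mut=5,
                                  effect_log2fc_by_class={c: 0.0 for c in
                                                          ("none", "helper_only", "wre_only",
                                                           "both", "both_multi_helper")})
            fx = simulate(cfg)
            fractions.append((fx.expression["pvalue"] < 0.05).mean())
        assert 0.03 <= np.mean(fractions) <= 0.07

    def test_strong_effect_class_selected(self):
        cfg = SyntheticConfig(seed=9, n_chromosomes=1, chrom_length=3_000_000, n_genes=120,
                              n_peaks_wt=130, n_peaks_mut=1, peak_length_range=(200, 300),
                              shared_region_fraction=0.0, gene_peak_fraction=0.0,
                              p_plant_wre_wt=0.0, p_plant_helper_wt=0.0,
                              genes_per_class={"both_multi_helper": 100},
                              effect_log2fc_by_class={"both_multi_helper": -1.0, "none": 0.0,
                                                      "helper_only": 0.0, "wre_only": 0.0,
                                                      "both": 0.0},
                              expression_noise_sd=0.3, link_distance=10_000)
        fx = simulate(cfg)
        effect_genes = [g for g, c in fx.gene_classes.items() if c == "both_multi_helper"]
        table = fx.expression.set_index("gene")
        selected = ((table.loc[effect_genes, "pvalue"] < 0.02)
                    & (table.loc[effect_genes, "log2fc"] < 0)).mean()
        # closed-form Gaussian power: P(lfc < -sd * z_{0.01} | mean -1, sd 0.3)
        from scipy.stats import norm

        power = norm.cdf((1.0 - 0.3 * norm.isf(0.01)) / 0.3)
        assert selected == pytest.approx(power, abs=0.12)
        assert selected > 0.7

    def test_same_seed_identical_table(self):
        a = simulate(SyntheticConfig(seed=2, **FAST)).expression
        b = simulate(SyntheticConfig(seed=2, **FAST)).expression
        assert a.equals(b)


class TestFixtureFiles:
    def test_everything_parses_back(self, small_fixture_dir):
        genome = cio.read_fasta(small_fixture_dir["genome"])
        genes = cio.read_gene_models(small_fixture_dir["genes"])
        wt = cio.read_bed(small_fixture_dir["peaks_wt"])
        mut = cio.read_bed(small_fixture_dir["peaks_mut"])
        expr = cio.read_expression_table(small_fixture_dir["expression"])
        manifest = json.loads(small_fixture_dir["manifest"].read_text())
        assert len(wt) == len(mut) == 120
        assert len(genes) == 40 and len(expr) == 40
        assert manifest["schema"] == "cclamp-fixture-v1"
        seqs = cio.extract_peak_sequences(wt + mut, genome)
        assert all(len(seqs[p.peak_id]) == p.length for p in wt + mut)
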