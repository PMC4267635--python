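"""Matched-region strength comparison between WT and mutant peak sets.

The synthetic WT factor gains +5 score per planted Helper copy; the
DNA-binding mutant does not. Regions bound by both are paired by
overlap, classified by score ratio, and the score difference is
stratified by Helper copy number.
"""

from cclamp import BUILTIN_MOTIFS, extract_peak_sequences, profile_peaks
from cclamp.compare import classify_strength, overlap_regions, stratify_by_copy_number
from cclamp.simulate import SyntheticConfig, simulate

cfg = SyntheticConfig(
    seed=5, n_chromosomes=1, chrom_length=2_000_000, n_genes=10,
    n_peaks_wt=500, n_peaks_mut=500, peak_length_range=(200, 300),
    shared_region_fraction=1.0, gene_peak_fraction=0.0,
    p_plant_wre_wt=0.5, p_plant_helper_wt=1.0,
    helper_copy_distribution={1: 0.3, 2: 0.2, 3: 0.2, 4: 0.15, 5: 0.15},
    score_per_helper_copy=5.0, score_noise_sd=3.0, score_shift_mut=0.0,
)
fixture = simulate(cfg)
pairs = overlap_regions(fixture.peaks_wt, fixture.peaks_mut)
result = classify_strength(pairs)
print(f"matched regions: {result.n_tested}")
print(f"  WT stronger: {result.n_a_stronger}, mut stronger: {result.n_b_stronger}, "
      f"similar: {result.n_similar}")
print(f"  paired signed-rank p = {result.p_value:.3g}")

seqs = extract_peak_sequences(fixture.peaks_wt, fixture.genome)
profiles = {p.peak_id: p for p in profile_peaks(seqs, [BUILTIN_MOTIFS["Helper"]])}
strata = stratify_by_copy_number(result.pairs, profiles, "Helper",
                                 bins=((0, 0), (1, 1), (2, 3), (4, None)))
print("\nmedian score difference (WT - mut) by Helper copy number:")
print(strata.to_frame().to_string(index=False))
print("\nThe median difference climbs with copy number: each extra Helper")
print("site buys the C-clamp-bearing factor additional occupancy strength.")
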