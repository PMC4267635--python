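"""WRE-Helper co-occurrence against a sequence background model.

Builds a synthetic peak set in which 20% of peaks carry a planted
WRE + 2 Helper composite, then asks how many peaks with at least one
WRE and at least N Helper sites would be expected by chance alone
(binomial window model per peak, exact Poisson-binomial tail for the
p-value).
"""

from cclamp import BUILTIN_MOTIFS, BackgroundModel, extract_peak_sequences, profile_peaks
from cclamp.background import cooccurrence_frame, cooccurrence_table
from cclamp.simulate import SyntheticConfig, simulate

cfg = SyntheticConfig(
    seed=42, n_chromosomes=1, chrom_length=1_000_000, n_genes=10,
    n_peaks_wt=1000, n_peaks_mut=1, peak_length_range=(150, 250),
    p_plant_wre_wt=0.2, p_plant_helper_wt=0.2, helper_copy_distribution={2: 1.0},
    gene_peak_fraction=0.0, shared_region_fraction=0.0,
)
fixture = simulate(cfg)
seqs = extract_peak_sequences(fixture.peaks_wt, fixture.genome)
profiles = profile_peaks(seqs, [BUILTIN_MOTIFS["WRE"], BUILTIN_MOTIFS["Helper"]])
background = BackgroundModel.from_sequences(seqs.values())

rows = cooccurrence_table(profiles, background, BUILTIN_MOTIFS["WRE"],
                          BUILTIN_MOTIFS["Helper"], condition_label="WT")
print(cooccurrence_frame(rows).to_string(index=False))
print("\nObserved counts far above the background expectation (tiny p-values)")
print("mean the two motifs co-occur in the same peaks more often than chance,")
print("the signature of composite WRE-Helper elements.")
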