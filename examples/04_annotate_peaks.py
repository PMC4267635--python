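"""Assign peaks to genomic features and test promoter Helper enrichment.

Categories are decided on the peak center with a 4 kb promoter window
centered on the TSS; the enrichment analysis uses the narrower
-1000/+100 bp promoter definition and compares per-promoter Helper
incidence (per kb) between bound and all promoters.
"""

from cclamp import BUILTIN_MOTIFS, extract_peak_sequences
from cclamp.annotate import (assign_features, feature_distribution,
                             promoter_incidence_enrichment, promoter_windows)
from cclamp.compare import overlap_regions
from cclamp.simulate import SyntheticConfig, simulate

fixture = simulate(SyntheticConfig(seed=3))
assignments = assign_features(fixture.peaks_wt, fixture.genes)
print("feature distribution of WT peaks:")
for category, count in feature_distribution(assignments).items():
    print(f"  {category:10s} {count}")

chrom_lengths = {c: len(s) for c, s in fixture.genome.items()}
promoters = promoter_windows(fixture.genes, chrom_lengths)
bound_ids = {pair.peak_b.peak_id for pair in overlap_regions(fixture.peaks_wt, promoters)}
promoter_seqs = extract_peak_sequences(promoters, fixture.genome)
bound_seqs = {pid: promoter_seqs[pid] for pid in sorted(bound_ids)}
enr = promoter_incidence_enrichment(bound_seqs, promoter_seqs, BUILTIN_MOTIFS["Helper"])
print(f"\nHelper incidence: bound promoters {enr.mean_bound:.2f}/kb "
      f"vs all promoters {enr.mean_background:.2f}/kb (p = {enr.p_value:.3g})")
print("\nA p-value near 1 here means the bound promoters are not Helper-")
print("enriched beyond the GC-rich promoter background; planted fixtures")
print("with Helper-rich promoter peaks drive it small.")
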