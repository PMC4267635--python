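# Methods

## Scanning model

Motifs are IUPAC patterns; a window matches when every base is in the
symbol's admitted set, and `N` in the sequence matches no symbol (assembly
gaps are conservatively unscannable). Both strands are scanned: minus-strand
occurrences are found by matching the reverse complement of the pattern and
reported at the leftmost base on the forward sequence, so that all positions
share one coordinate system for spacing and center-profile analyses.
Overlapping occurrences are counted — incidence is defined as a plain
per-window quantity (count / peak length), and collapsing overlaps would
make it depend on an arbitrary tiling choice. A window that matches on both
strands (palindromic instance) counts twice in scan counts (two per-strand
binding events) but once per reverse-complement-unified class in the k-mer
table (one physical site); `collapse_palindromic=True` switches the scanner
to the per-site convention for users who prefer it.

PWM scanning scores each window by log-odds against a background nucleotide
model (estimated from the scanned sequences when not supplied) and calls a
hit at ≥ `threshold_fraction` of the maximum attainable score
(default 0.8 — a conventional relaxed-consensus cutoff, exposed as
configuration). With a tiny pseudocount and threshold 1.0 the PWM scan
reproduces the exact scanner on non-degenerate patterns, which the suite
pins as an invariant.

## Background co-occurrence model

For a peak of length `L` and a motif of length `m`, the per-position match
probability under an i.i.d. background is the product over pattern positions
of the summed frequencies of the admitted bases; the occurrence count is
approximated as Binomial over the `2*(L-m+1)` strand-windows. Window
overlap dependence is ignored. For the motifs shipped here the
approximation error is negligible: neither the WRE nor the Helper can
overlap itself or its reverse complement at small lags (the test suite
confirms closed form vs. Monte Carlo agreement within three standard errors
at L = 1000), and the type-I calibration check bounds the residual effect.

The expected number of peaks containing ≥1 WRE and ≥N Helpers sums the
per-peak joint probabilities over the actual peak-length distribution, and
the p-value is the exact upper tail of the Poisson-binomial over those
per-peak probabilities, computed by an O(K²) convolution DP with clipping
for numerical stability. A `method="binomial"` switch instead uses a
binomial tail on the mean per-peak probability (the
fixed-representative-length reading of the model); with equal peak lengths
the two coincide, which is pinned in a test. The background defaults to the
nucleotide frequencies of the analysed peak set (GC-aware), overridable to
uniform or user-supplied frequencies — GC content is the dominant nuisance
for a GC-rich motif like the Helper, so the peak-set default is the
conservative choice.

## Rank tests

Mann–Whitney comparisons use exact enumeration of label assignments (with
midranks for ties) when the pooled sample size is ≤ 12 and the tie-corrected
normal approximation otherwise; the exact path's two-sided p is the
probability of a U at least as far from its null mean as observed. Matched
score comparisons default to the Wilcoxon signed-rank test (the regions are
paired); the unpaired rank-sum variant is available behind a flag since the
choice is genuinely ambiguous for this design. When one peak overlaps
several partners, all pairs are kept for overlap/spacing outputs but only
the maximum-overlap partner enters the paired test, avoiding
pseudo-replication. The "similarly enriched" band in strength
classification is a symmetric score-ratio threshold (default 1.5),
configurable because no principled value exists.

## Spacing and position conventions

Peak center is `floor((start+end)/2)`; motif center is
`start + floor(m/2)`. WRE–Helper gaps are measured edge-to-edge and signed
relative to the WRE hit's strand (positive = Helper 3' of the WRE), with
overlapping pairs taking negative gaps from the same edges; every
(WRE hit, Helper hit) pair in a peak yields one record. Edge gaps rather
than center distances are used because composite-element spacing is
conventionally quoted in intervening nucleotides.

## Annotation

Two promoter definitions coexist deliberately: a 4 kb window centered on
the TSS for feature categorisation, and a −1000/+100 bp window for the
promoter incidence-enrichment analysis; both are pinned by unit tests. The
category is decided on the peak center with precedence
promoter > exon > intron > other (a ±1 kb TES window) > intergenic, so each
peak gets exactly one category and the distribution conserves the peak
count. `tss_distance` is signed along the gene's strand (negative =
upstream). The precedence order is a declared convention of this package,
not a claim of equivalence with any particular published annotator.

## Expression integration

Regulated genes are selected by strict inequalities (p < cutoff and
log2FC ≠ 0 with the matching sign). Peaks link to every gene whose TSS is
within the distance cutoff of the peak center; the score filter is a strict
`score > cutoff` (default 67, the convention of the motivating analysis).
The hypergeometric universe is the set of genes present in the expression
table — a detected-gene universe avoids inflating significance. GSEA uses
the unweighted running-sum statistic (+1/|S| on hits, −1/(n−|S|) on misses;
ES = the running sum at its maximum absolute excursion) with a seeded
gene-set permutation null and add-one smoothing,
p = (1 + #{ES* ≥ ES}) / (1 + n_perm); the unweighted gene-set-permutation
variant is the simplest defensible choice where the original procedure is
underdetermined, and it admits an exact enumeration oracle. A gene linked
to several peaks takes the highest motif class in the order
none < helper_only < wre_only < both < both_multi_helper, so multi-Helper
composite peaks dominate the gene's label.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
read-level data: an i.i.d. genome at configurable GC content (default 0.41,
a mammalian-like value), non-overlapping alternating-strand gene models,
and two peak sets. WRE and Helper planting are independent per-peak coins;
when both fire, the Helper copies are placed at signed gaps drawn from the
gap distribution (default uniform over ±1..11 nt, the flexibility range
reported for composite elements) around the WRE — a composite element —
otherwise Helper copies are placed uniformly in the peak. Planting
overwrites genome bases and planted intervals are protected from later
overwrites, so the manifest's motifs are recoverable by the scanner at
exactly their recorded positions (a 100% round-trip the suite enforces).
Only the designated shared fraction of regions overlaps between the two
sets; independent placements avoid the other set's intervals so the shared
fraction is exact by construction.

Default study conditions: 1000 peaks per set of 200–400 bp on a 2 × 5 Mb
genome with 200 genes; WT WRE planting 0.45 and Helper planting 0.10
(yielding ≈50% of WT peaks with a WRE and ≈19% with a Helper over
background); the mutant keeps the WRE rate (0.37 → ≈42% with background),
gains no planted Helpers, and is restricted to single Helper copies where
planting is enabled — the C-clamp-null factor neither selects nor clusters
Helper sites. WT scores are `base + 5 × (planted Helper copies) + N(0, 10)`
with the mutant at a −5 global shift and no copy-number term, so
copy-number stratification has recoverable structure. Expression:
log2FC = class effect + N(0, sd) with defaults none 0, helper_only −0.1,
wre_only −0.3, both −0.6, both_multi_helper −1.0 and sd 0.3; p-values are
two-sided Gaussian tests of log2FC against the noise sd, so null genes are
uniform and effect genes small. An optional `genes_per_class` mapping
places one class-determined peak at each targeted gene's TSS for exact
class counts in recovery studies.

What the generator does **not** emulate — read-count noise, peak-caller
artefacts, chromatin context, real promoter CpG islands, linkage between
neighbouring genes — bounds what passing tests show: they demonstrate that
the statistics recover planted structure at realistic effect sizes and stay
calibrated under the null, not that the pipeline reproduces any particular
experimental dataset.

## Problem sizes and numerical choices

The suite's simulation studies are sized to be decisive yet quick: 500 null
replicates of 400 peaks for type-I calibration, 100 replicates of 1000
short peaks for the co-occurrence power/specificity study, and 100
replicates each for the copy-number and motif-class recovery studies.
Exhaustive oracles cap at 2^15 outcomes (Poisson-binomial), pooled n = 10
(rank tests), universe 12 (hypergeometric) and list length 8 (GSEA).
Probabilities in the DP are clipped to [0, 1] each step; Fisher tests use
scipy's exact implementation and BH correction comes from statsmodels. Peak
ranking breaks score ties by (chrom, start) so "top K" selections are
deterministic; all randomness flows through `numpy.random.default_rng`
seeded from the configuration.

## Known limitations

The background model is zeroth-order (no dinucleotide structure) and
ignores window dependence; an overlap-corrected occurrence distribution
(Goulden–Jackson style) is noted as future work. The annotator supports a
minimal gene-model table, BED12 and plain GTF, not exotic attribute
dialects. Distal regulation is out of reach of TSS-window linking — genes
regulated by enhancers beyond the distance cutoff are invisible to the
integration stage, as they are to any proximity-based assignment.
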