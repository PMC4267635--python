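# cclamp

Occupancy analytics for transcription factors with **two** DNA-binding
domains. The motivating system is the E-tail isoform of TCF1/TCF7: its HMG
box reads the Wnt Response Element (WRE, `5'-CTTTGWWS-3'`) while a second,
zinc-binding **C-clamp** domain reads the GC-rich **Helper site**
(`5'-RCCGCC-3'`; short form `5'-RCCG-3'`). Comparing ChIP-seq peak sets from
a wild-type factor and a C-clamp point mutant — and joining them to
nascent-transcription changes — reveals how the second domain reshapes
genome-wide binding and target-gene regulation. `cclamp` packages that whole
analysis as a tested, seeded, reusable library for anyone studying
composite-element transcription factors.

## What it computes

* **Degenerate-motif scanning** (`cclamp.motifs`) — IUPAC patterns and
  positional weight matrices scanned on both strands with overlapping
  occurrences; per-peak counts and incidence *I = count / L*; a differential
  k-mer (Fisher exact + Benjamini–Hochberg) comparison of two peak sets.
* **Background co-occurrence model** (`cclamp.background`) — for a peak of
  length *L* and motif of length *m*, the number of occurrences is modelled
  as Binomial(*n* = 2(*L* − *m* + 1), *p*), where *p* is the product over
  pattern positions of the summed background base frequencies. The expected
  number of peaks carrying ≥1 WRE **and** ≥N Helper sites is
  E = Σᵢ P(WRE ≥ 1 | Lᵢ) · P(Helper ≥ N | Lᵢ), and the observed count gets
  an exact Poisson-binomial upper-tail p-value (O(K²) convolution DP).
* **Peak-set comparison** (`cclamp.compare`) — matched-region pairing by any
  overlap, strength classes at a configurable score ratio, Wilcoxon /
  Mann–Whitney tests (exact enumeration for small n, tie-corrected normal
  otherwise), Helper-copy-number stratification of score differences,
  motif-position histograms around peak centers, and WRE–Helper
  spacing/orientation tables.
* **Annotation** (`cclamp.annotate`) — promoter/exon/intron/other/intergenic
  assignment on the peak center (promoter = TSS ± 2 kb) and Helper incidence
  in bound promoters versus all promoters (−1000/+100 bp windows, per kb).
* **Expression integration** (`cclamp.integrate`) — regulated-gene selection,
  peak-to-gene linking by TSS distance (30/50 kb, score cutoff), exact
  hypergeometric overlap tests, an unweighted GSEA on peak scores with a
  seeded gene-set permutation null, motif-class association with
  downregulation and a target-gene report.
* **Synthetic data** (`cclamp.simulate`) — seeded toy genomes, gene models,
  two peak sets with planted WRE/Helper composites at controlled
  probabilities, copy-number/spacing distributions, scores coupled to Helper
  copy number, class-dependent expression tables, and a ground-truth
  manifest whose planted motifs are 100% recoverable by the scanner.

## Worked example

`examples/02_cooccurrence.py` plants a WRE + 2-Helper composite in 20% of
1000 synthetic peaks and runs the co-occurrence model:

```
condition  n_peaks_with_wre  helper_threshold  n_peaks_with_n_helpers  expected_both  observed_both       p_value
       WT               235                 1                     233       4.239927             59  2.272232e-46
       WT               235                 2                     190       0.163148             51 8.445663e-108
       WT               235                 3                      11       0.004281              6  8.350561e-18
```

59 peaks carry both elements where the background model expects ~4 — the
signature of composite WRE–Helper elements. `examples/03_compare_peak_sets.py`
shows the occupancy-strength side: with a +5 score gain per planted Helper
copy, the median matched-region score difference climbs from 5.1 (one copy)
through 11.4 (2–3 copies) to 22.5 (4+), and the paired signed-rank test on
500 shared regions gives p = 7.3e-82.

Each `examples/*.py` script is a narrative walk through one capability; the
`cclamp` command exposes the same stages as subcommands
(`simulate | scan | cooccur | compare | annotate | integrate | run`).

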