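"""Peak-to-feature annotation and promoter-background motif enrichment.

Two distinct promoter definitions coexist on purpose: a 4 kb window
centred on the TSS for feature categorisation, and a -1000/+100 bp
window for the promoter incidence-enrichment analysis. Category is
decided on the peak center with precedence
promoter > exon > intron > other > intergenic, where "other" is a
window around the transcript end site.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GeneModel, Peak
from .motifs import DegenerateMotif, scan_sequence
from .compare import mann_whitney

__all__ = [
    "FeatureAssignment",
    "CATEGORIES",
    "PROMOTER_HALFWIDTH",
    "ENRICHMENT_UPSTREAM",
    "ENRICHMENT_DOWNSTREAM",
    "assign_feature",
    "assign_features",
    "feature_distribution",
    "promoter_windows",
    "promoter_incidence_enrichment",
]

CATEGORIES = ("promoter", "exon", "intron", "other", "intergenic")

# 4 kb centered promoter for categorisation; -1000/+100 for enrichment.
PROMOTER_HALFWIDTH = 2000
TES_HALFWIDTH = 1000
ENRICHMENT_UPSTREAM = 1000
ENRICHMENT_DOWNSTREAM = 100


@dataclass
class FeatureAssignment:
    peak_id: str
    category: str
    gene_id: str | None
    tss_distance: int | None


class _ChromIndex:
    """Per-chromosome sorted gene lookup for nearest-TSS queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        order = sorted(range(len(genes)), key=lambda i: genes[i].tss)
        self.genes = [genes[i] for i in order]
        self.tss = [g.tss for g in self.genes]

    def nearest(self, pos: int) -> GeneModel:
        i = bisect_left(self.tss, pos)
        candidates = [j for j in (i - 1, i) if 0 <= j < len(self.genes)]
        return min((self.genes[j] for j in candidates), key=lambda g: abs(pos - g.tss))


def _build_index(gene_models: Sequence[GeneModel]) -> dict[str, _ChromIndex]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    return {chrom: _ChromIndex(genes) for chrom, genes in by_chrom.items()}


def assign_feature(
    peak: Peak,
    gene_models: Sequence[GeneModel] | dict[str, _ChromIndex],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    tes_halfwidth: int = TES_HALFWIDTH,
) -> FeatureAssignment:
    """Single feature category for a peak, decided on its center.

    Promoter is the half-open window [tss - hw, tss + hw); "other" is
    the analogous window around the TES. ``tss_distance`` is
    center - TSS of the nearest gene, sign flipped for minus-strand
    genes so positive always means downstream of the TSS.
    """
    index = gene_models if isinstance(gene_models, dict) else _build_index(gene_models)
    if not index:
        warnings.warn("no gene models given; every peak is intergenic")
        return FeatureAssignment(peak.peak_id, "intergenic", None, None)
    center = peak.center
    chrom_idx = index.get(peak.chrom)
    if chrom_idx is None:
        return FeatureAssignment(peak.peak_id, "intergenic", None, None)
    nearest = chrom_idx.nearest(center)
    distance = center - nearest.tss
    if nearest.strand == "-":
        distance = -distance

    category = "intergenic"
    for gene in chrom_idx.genes:
        if gene.tss - promoter_halfwidth <= center < gene.tss + promoter_halfwidth:
            category = "promoter"
            break
    if category == "intergenic":
        ranks = {"exon": 1, "intron": 2, "other": 3}
        best = None
        for gene in chrom_idx.genes:
            if any(s <= center < e for s, e in gene.exons):
                cand = "exon"
            elif gene.left <= center < gene.right:
                cand = "intron"
            elif gene.tes - tes_halfwidth <= center < gene.tes + tes_halfwidth:
                cand = "other"
            else:
                continue
            if best is None or ranks[cand] < ranks[best]:
                best = cand
        if best is not None:
            category = best
    return FeatureAssignment(peak.peak_id, category, nearest.gene_id, int(distance))


def assign_features(
    peaks: Iterable[Peak],
    gene_models: Sequence[GeneModel],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    tes_halfwidth: int = TES_HALFWIDTH,
) -> list[FeatureAssignment]:
    index = _build_index(gene_models)
    if not index:
        warnings.warn("no gene models given; every peak is intergenic")
        return [FeatureAssignment(p.peak_id, "intergenic", None, None) for p in peaks]
    return [assign_feature(p, index, promoter_halfwidth, tes_halfwidth) for p in peaks]


def feature_distribution(assignments: Iterable[FeatureAssignment]) -> dict[str, int]:
    """Category counts; always contains every category and sums to n peaks."""
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    return counts


def promoter_windows(
    gene_models: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    upstream: int = ENRICHMENT_UPSTREAM,
    downstream: int = ENRICHMENT_DOWNSTREAM,
) -> list[Peak]:
    """Strand-aware -upstream/+downstream TSS windows as Peak intervals.

    Windows truncated at chromosome edges are shortened (analyses
    length-normalise).
    """
    windows = []
    for g in gene_models:
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        else:
            start, end = g.tss - downstream, g.tss + upstream
        limit = chrom_lengths.get(g.chrom)
        if limit is None:
            raise KeyError(f"gene {g.gene_id}: no chromosome length for {g.chrom}")
        start, end = max(0, start), min(limit, end)
        if end > start:
            windows.append(Peak(g.chrom, start, end, peak_id=f"promoter_{g.gene_id}"))
    return windows


@dataclass
class PromoterEnrichment:
    motif: str
    bound_per_kb: np.ndarray
    background_per_kb: np.ndarray
    mean_bound: float
    mean_background: float
    p_value: float


def promoter_incidence_enrichment(
    bound_promoter_seqs: Mapping[str, str] | Sequence[str],
    all_promoter_seqs: Mapping[str, str] | Sequence[str],
    motif: DegenerateMotif,
) -> PromoterEnrichment:
    """Per-promoter motif incidence per kb, bound set versus background.

    The bound set is the promoters overlapped by peaks; the background
    is the full promoter complement. Compared by two-sided rank-sum.
    """

    def per_kb(seqs) -> np.ndarray:
        values = seqs.values() if isinstance(seqs, Mapping) else seqs
        out = []
        for seq in values:
            if len(seq) == 0:
                continue
            out.append(len(scan_sequence(seq, motif)) / len(seq) * 1000.0)
        return np.array(out)

    bound = per_kb(bound_promoter_seqs)
    background = per_kb(all_promoter_seqs)
    if bound.size == 0 or background.size == 0:
        raise ValueError("both promoter sets must contain sequences")
    _, p = mann_whitney(bound, background)
    return PromoterEnrichment(
        motif.name,
        bound,
        background,
        float(bound.mean()),
        float(background.mean()),
        p,
    )
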