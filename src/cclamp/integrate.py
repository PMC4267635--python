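"""Join peak occupancy with nascent-transcription changes.

Selects regulated genes from a per-gene fold-change table, links peaks
to genes by TSS distance, tests gene-set overlaps (hypergeometric),
runs an unweighted GSEA on peak scores, stratifies downregulation by
the motif class of linked peaks, and emits a target-gene report.

Motif classes per peak: none / wre_only (>=1 WRE, 0 Helper) /
helper_only / both (>=1 each) / both_multi_helper (>=1 WRE, >=2
Helper). A gene linked to several peaks takes the highest class in
that order (multi-Helper composite peaks dominate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compare import mann_whitney
from .io import ExpressionRecord, GeneModel, Peak
from .motifs import PeakMotifProfile

__all__ = [
    "MOTIF_CLASS_ORDER",
    "GeneLink",
    "motif_class",
    "select_regulated",
    "link_peaks_to_genes",
    "hypergeometric_overlap",
    "running_sum_es",
    "peak_score_gsea",
    "motif_class_association",
    "target_gene_report",
]

MOTIF_CLASS_ORDER = ("none", "helper_only", "wre_only", "both", "both_multi_helper")
_CLASS_RANK = {c: i for i, c in enumerate(MOTIF_CLASS_ORDER)}


def motif_class(wre_count: int, helper_count: int) -> str:
    """Per-peak motif class from WRE and Helper occurrence counts."""
    if wre_count >= 1 and helper_count >= 2:
        return "both_multi_helper"
    if wre_count >= 1 and helper_count >= 1:
        return "both"
    if wre_count >= 1:
        return "wre_only"
    if helper_count >= 1:
        return "helper_only"
    return "none"


@dataclass
class GeneLink:
    """Peaks linked to one gene by TSS distance."""

    gene_id: str
    linked_peaks: list[tuple[str, int, float]]  # (peak_id, tss_distance, score)
    max_peak_score: float
    motif_class: str = "none"


@dataclass
class RegulatedSets:
    down: set[str]
    up: set[str]


def select_regulated(
    expression_records: Iterable[ExpressionRecord],
    p_cutoff: float,
) -> RegulatedSets:
    """Down- and up-regulated gene sets at a strict p cutoff.

    down = {p < cutoff and log2fc < 0}; up analogous; a gene with
    log2fc exactly 0 belongs to neither (strict inequalities).
    """
    if not 0 < p_cutoff < 1:
        raise ValueError("p_cutoff must be in (0, 1)")
    down, up = set(), set()
    for rec in expression_records:
        if rec.p_value < p_cutoff:
            if rec.log2_fold_change < 0:
                down.add(rec.gene_id)
            elif rec.log2_fold_change > 0:
                up.add(rec.gene_id)
    return RegulatedSets(down, up)


def link_peaks_to_genes(
    peaks: Sequence[Peak],
    gene_models: Sequence[GeneModel],
    profiles: Mapping[str, PeakMotifProfile] | Sequence[PeakMotifProfile] | None = None,
    max_distance: int = 30_000,
    min_score: float | None = None,
    wre_name: str = "WRE",
    helper_name: str = "Helper",
) -> list[GeneLink]:
    """Link every peak to every gene whose TSS is within ``max_distance``
    of the peak center; genes with zero links are omitted.

    ``min_score`` filters with a strict inequality (score > min_score),
    matching the "peak score > 67" convention. ``tss_distance`` is
    signed along the gene's strand (negative = upstream).
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    if profiles is not None and not isinstance(profiles, Mapping):
        profiles = {p.peak_id: p for p in profiles}
    usable = [p for p in peaks if min_score is None or p.score > min_score]
    by_chrom: dict[str, list[Peak]] = {}
    for p in usable:
        by_chrom.setdefault(p.chrom, []).append(p)
    links = []
    for gene in gene_models:
        hits = []
        for p in by_chrom.get(gene.chrom, []):
            if abs(p.center - gene.tss) <= max_distance:
                distance = p.center - gene.tss
                if gene.strand == "-":
                    distance = -distance
                hits.append((p.peak_id, int(distance), p.score))
        if not hits:
            continue
        hits.sort(key=lambda t: (abs(t[1]), t[0]))
        cls = "none"
        if profiles is not None:
            rank = 0
            for peak_id, _, _ in hits:
                prof = profiles.get(peak_id)
                if prof is None:
                    continue
                c = motif_class(prof.counts.get(wre_name, 0), prof.counts.get(helper_name, 0))
                if _CLASS_RANK[c] > rank:
                    rank = _CLASS_RANK[c]
            cls = MOTIF_CLASS_ORDER[rank]
        links.append(GeneLink(gene.gene_id, hits, max(h[2] for h in hits), cls))
    return links


def hypergeometric_overlap(
    set_a: set[str],
    set_b: set[str],
    universe_size: int,
) -> tuple[int, float]:
    """Upper-tail hypergeometric P(overlap >= observed)."""
    if universe_size < max(len(set_a), len(set_b)):
        raise ValueError("universe smaller than one of the sets")
    overlap = len(set_a & set_b)
    if not set_a or not set_b:
        return overlap, 1.0
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(set_a), len(set_b)))
    return overlap, min(p, 1.0)


def running_sum_es(ranked_genes: Sequence[str], gene_subset: set[str]) -> float:
    """Unweighted GSEA enrichment score.

    Walk the ranked list adding 1/|subset| at hits and subtracting
    1/(n - |subset|) at misses; the ES is the running sum's value at its
    maximum absolute deviation from zero (signed).
    """
    n = len(ranked_genes)
    k = len(gene_subset)
    if k == 0 or k >= n:
        raise ValueError("subset must be a nonempty proper subset of the ranked list")
    hit_step = 1.0 / k
    miss_step = 1.0 / (n - k)
    running = 0.0
    es = 0.0
    for gene in ranked_genes:
        running += hit_step if gene in gene_subset else -miss_step
        if abs(running) > abs(es):
            es = running
    return es


@dataclass
class GseaResult:
    enrichment_score: float
    p_value: float
    n_permutations: int
    subset_size: int


def peak_score_gsea(
    ranked_genes: Sequence[str],
    gene_subset: set[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Gene-set permutation p for the unweighted enrichment score.

    Random same-size subsets of the ranked list form the null;
    p = (1 + #{ES_perm at least as extreme}) / (1 + n_permutations).
    For a positive observed ES "as extreme" means ES_perm >= ES_obs,
    mirrored for a negative ES.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    missing = gene_subset - set(ranked_genes)
    if missing:
        raise ValueError(f"subset genes absent from ranked list: {sorted(missing)[:5]}")
    es_obs = running_sum_es(ranked_genes, gene_subset)
    rng = np.random.default_rng(seed)
    genes = np.array(ranked_genes, dtype=object)
    k = len(gene_subset)
    hits = 0
    for _ in range(n_permutations):
        perm = set(rng.choice(genes, size=k, replace=False))
        es = running_sum_es(ranked_genes, perm)
        if (es_obs >= 0 and es >= es_obs - 1e-12) or (es_obs < 0 and es <= es_obs + 1e-12):
            hits += 1
    return GseaResult(es_obs, (1 + hits) / (1 + n_permutations), n_permutations, k)


@dataclass
class ClassAssociation:
    summary: pd.DataFrame
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def motif_class_association(
    gene_links: Sequence[GeneLink],
    expression_records: Iterable[ExpressionRecord],
    min_class_size: int = 3,
) -> ClassAssociation:
    """Per-motif-class log2 fold-change summaries and pairwise rank tests.

    Classes with fewer than ``min_class_size`` genes are reported but
    excluded from testing.
    """
    lfc = {r.gene_id: r.log2_fold_change for r in expression_records}
    values: dict[str, list[float]] = {c: [] for c in MOTIF_CLASS_ORDER}
    for link in gene_links:
        if link.gene_id in lfc:
            values[link.motif_class].append(lfc[link.gene_id])
    summary = pd.DataFrame(
        {
            "motif_class": list(MOTIF_CLASS_ORDER),
            "n_genes": [len(values[c]) for c in MOTIF_CLASS_ORDER],
            "median_log2fc": [
                float(np.median(values[c])) if values[c] else float("nan")
                for c in MOTIF_CLASS_ORDER
            ],
        }
    )
    pairwise: dict[tuple[str, str], float] = {}
    for c1, c2 in combinations(MOTIF_CLASS_ORDER, 2):
        if len(values[c1]) >= min_class_size and len(values[c2]) >= min_class_size:
            _, p = mann_whitney(values[c1], values[c2])
            pairwise[(c1, c2)] = p
    return ClassAssociation(summary, pairwise)


def target_gene_report(
    gene_links: Sequence[GeneLink],
    regulated: set[str],
    expression_records: Iterable[ExpressionRecord],
    known_targets: set[str] | None = None,
) -> pd.DataFrame:
    """One row per regulated gene with at least one linked peak.

    TSS distances are comma-joined in ascending order (e.g.
    ``"483, 4234"``); unregulated genes and genes without links are
    absent.
    """
    expr = {r.gene_id: r for r in expression_records}
    rows = []
    for link in sorted(gene_links, key=lambda l: l.gene_id):
        if link.gene_id not in regulated:
            continue
        rec = expr.get(link.gene_id)
        distances = sorted(d for _, d, _ in link.linked_peaks)
        rows.append(
            {
                "gene": link.gene_id,
                "log2_fold_change": rec.log2_fold_change if rec else float("nan"),
                "p_value": rec.p_value if rec else float("nan"),
                "tss_distances": ", ".join(str(d) for d in distances),
                "max_peak_score": link.max_peak_score,
                "motif_class": link.motif_class,
                "known_target": (link.gene_id in known_targets) if known_targets else False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "log2_fold_change",
            "p_value",
            "tss_distances",
            "max_peak_score",
            "motif_class",
            "known_target",
        ],
    )
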