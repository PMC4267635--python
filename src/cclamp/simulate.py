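"""Seeded synthetic fixtures with planted motifs and known ground truth.

The generator emulates the statistical structure every pipeline stage
assumes: a toy genome at a configurable GC content, gene models, two
peak sets ("WT" and "mut") with WRE/Helper motifs planted at controlled
per-peak probabilities, Helper copy-number and WRE-Helper gap
distributions, peak scores that grow with planted Helper copy number
in the WT set only (the C-clamp-dependent strength gain), and an
expression table whose downregulation magnitude depends on the motif
class of peaks near each gene's TSS.

Planting overwrites genome bases, so ground truth is exact: every
planted motif is recoverable by the scanner at its recorded position
(planted intervals are protected from later overwrites). Background
occurrences arising by chance are permitted and are accounted for by
the closed-form background model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .io import GeneModel, Peak, write_bed, write_fasta
from .motifs import BUILTIN_MOTIFS, DegenerateMotif, reverse_complement
from .integrate import MOTIF_CLASS_ORDER, motif_class

__all__ = ["SyntheticConfig", "Fixture", "Planting", "simulate", "make_fixture",
           "generate_genome", "generate_peaks", "generate_expression"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# deterministic per-class planting used for targeted (genes_per_class) peaks
_CLASS_PLANTING = {
    "none": (0, 0),
    "wre_only": (1, 0),
    "helper_only": (0, 1),
    "both": (1, 1),
    "both_multi_helper": (1, 2),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic fixtures.

    Defaults approximate the scale of a top-1000-peak ChIP-seq analysis
    on a desk-sized toy genome: ~41% GC, 1000 peaks per condition of
    200-400 bp, WT planting rates chosen so roughly half the WT peaks
    carry a WRE and ~20% a Helper while the mutant keeps the WRE rate
    but gains no Helper planting, single-copy Helper planting in the
    mutant, and class effects ordered none < wre_only < both <
    both_multi_helper in downregulation strength.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    gc_content: float = 0.41
    n_genes: int = 200
    gene_length: int = 4000
    n_exons: int = 3
    n_peaks_wt: int = 1000
    n_peaks_mut: int = 1000
    peak_length_range: tuple[int, int] = (200, 400)
    shared_region_fraction: float = 0.6
    gene_peak_fraction: float = 0.5
    p_plant_wre_wt: float = 0.45
    p_plant_helper_wt: float = 0.10
    p_plant_wre_mut: float = 0.37
    p_plant_helper_mut: float = 0.0
    helper_copy_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.1, 4: 0.05}
    )
    helper_copy_distribution_mut: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    gap_distribution: dict[int, float] | None = None  # None => uniform over +-(1..11)
    score_base: float = 65.0
    score_per_helper_copy: float = 5.0
    score_shift_mut: float = -5.0
    score_noise_sd: float = 10.0
    genes_per_class: dict[str, int] | None = None
    effect_log2fc_by_class: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.0,
            "helper_only": -0.1,
            "wre_only": -0.3,
            "both": -0.6,
            "both_multi_helper": -1.0,
        }
    )
    expression_noise_sd: float = 0.3
    link_distance: int = 30_000

    def __post_init__(self) -> None:
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")
        for name in ("p_plant_wre_wt", "p_plant_helper_wt", "p_plant_wre_mut", "p_plant_helper_mut",
                     "shared_region_fraction", "gene_peak_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.peak_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("peak_length_range must be a positive, ordered pair")
        for dist_name in ("helper_copy_distribution", "helper_copy_distribution_mut"):
            dist = getattr(self, dist_name)
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{dist_name} must be normalised")
        if self.genes_per_class:
            bad = set(self.genes_per_class) - set(MOTIF_CLASS_ORDER)
            if bad:
                raise ValueError(f"unknown motif classes in genes_per_class: {sorted(bad)}")


@dataclass
class Planting:
    peak_id: str
    motif: str
    chrom: str
    position: int  # genome coordinate of the leftmost base
    strand: str
    realized: str  # instance on the motif's own strand


@dataclass
class Fixture:
    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    peaks_wt: list[Peak]
    peaks_mut: list[Peak]
    plantings: list[Planting]
    planted_counts: dict[str, tuple[int, int]]  # peak_id -> (wre, helper copies)
    gene_classes: dict[str, str]
    expression: pd.DataFrame

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        for key in ("helper_copy_distribution", "helper_copy_distribution_mut",
                    "gap_distribution", "genes_per_class", "effect_log2fc_by_class"):
            if cfg[key] is not None:
                cfg[key] = {str(k): v for k, v in cfg[key].items()}
        cfg["peak_length_range"] = list(cfg["peak_length_range"])
        return {
            "schema": "cclamp-fixture-v1",
            "config": cfg,
            "plantings": [asdict(p) for p in self.plantings],
            "planted_counts": {k: list(v) for k, v in self.planted_counts.items()},
            "gene_classes": self.gene_classes,
        }


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> bytearray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytearray(rng.choice(_BASES, size=n, p=probs).tobytes())


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, bytearray], list[GeneModel]]:
    """I.i.d. genome at the configured GC content plus non-overlapping
    gene models with alternating strands."""
    chroms = {
        f"chr{i + 1}": _random_bases(rng, config.chrom_length, config.gc_content)
        for i in range(config.n_chromosomes)
    }
    total_span = config.n_chromosomes * config.chrom_length
    if config.n_genes * (config.gene_length + 2000) > total_span:
        raise ValueError("genes do not fit in the configured genome")
    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    gene_idx = 0
    for chrom_i, chrom in enumerate(sorted(chroms)):
        n_here = min(per_chrom, config.n_genes - gene_idx)
        if n_here <= 0:
            break
        slot = config.chrom_length // max(n_here, 1)
        if slot <= config.gene_length + 200:
            raise ValueError("genes do not fit on a chromosome")
        for j in range(n_here):
            lo = j * slot + 100
            hi = (j + 1) * slot - config.gene_length - 100
            start = int(rng.integers(lo, max(hi, lo + 1)))
            end = start + config.gene_length
            strand = "+" if (gene_idx % 2 == 0) else "-"
            exon_span = config.gene_length // (2 * config.n_exons)
            exons = []
            for e in range(config.n_exons):
                es = start + e * (config.gene_length // config.n_exons)
                exons.append((es, min(es + exon_span, end)))
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(GeneModel(f"gene_{gene_idx:04d}", chrom, strand, tss, tes, exons))
            gene_idx += 1
    return chroms, genes


def _sample_from_dist(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def _sample_gap(rng: np.random.Generator, dist: Mapping[int, float] | None) -> int:
    if dist is None:
        gaps = [g for g in range(-11, 12) if g != 0]
        return int(gaps[rng.integers(0, len(gaps))])
    return _sample_from_dist(rng, dist)


def _realize(rng: np.random.Generator, motif: DegenerateMotif) -> str:
    return "".join(sorted(motif.admitted(i))[rng.integers(0, len(motif.admitted(i)))]
                   for i in range(motif.length))


class _Occupancy:
    """Protects planted intervals from being overwritten later."""

    def __init__(self) -> None:
        self.used: dict[str, set[int]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        used = self.used.setdefault(chrom, set())
        return not any(pos in used for pos in range(start, end))

    def claim(self, chrom: str, start: int, end: int) -> None:
        self.used.setdefault(chrom, set()).update(range(start, end))


def _write_motif(
    chroms: dict[str, bytearray], chrom: str, pos: int, realized: str, strand: str
) -> None:
    seq = realized if strand == "+" else reverse_complement(realized)
    chroms[chrom][pos : pos + len(seq)] = seq.encode()


def _plant_in_peak(
    rng: np.random.Generator,
    chroms: dict[str, bytearray],
    occupancy: _Occupancy,
    peak: Peak,
    plant_wre: bool,
    helper_copies: int,
    gap_dist: Mapping[int, float] | None,
    plantings: list[Planting],
) -> tuple[int, int]:
    """Plant the requested motifs inside a peak; returns planted counts."""
    wre = BUILTIN_MOTIFS["WRE"]
    helper = BUILTIN_MOTIFS["Helper"]
    wre_planted = 0
    helper_planted = 0
    margin = 18  # room for gap-linked Helper copies beside the WRE
    wre_start = None
    wre_strand = "+"
    if plant_wre:
        L = peak.length
        lo = peak.start + min(margin, L // 4)
        hi = peak.end - wre.length - min(margin, L // 4)
        for _ in range(40):
            jitter = int(rng.integers(-L // 6, L // 6 + 1))
            pos = peak.center - wre.length // 2 + jitter
            pos = max(lo, min(pos, hi))
            if pos < peak.start or pos + wre.length > peak.end:
                break
            if occupancy.free(peak.chrom, pos, pos + wre.length):
                wre_strand = "+" if rng.integers(0, 2) == 0 else "-"
                realized = _realize(rng, wre)
                _write_motif(chroms, peak.chrom, pos, realized, wre_strand)
                occupancy.claim(peak.chrom, pos, pos + wre.length)
                plantings.append(Planting(peak.peak_id, "WRE", peak.chrom, pos, wre_strand, realized))
                wre_start = pos
                wre_planted = 1
                break
    for _ in range(helper_copies):
        placed = False
        for _ in range(40):
            if wre_start is not None:
                gap = _sample_gap(rng, gap_dist)
                if wre_strand == "-":
                    gap = -gap
                if gap > 0:
                    pos = wre_start + wre.length + gap
                else:
                    pos = wre_start + gap - helper.length
            else:
                pos = int(rng.integers(peak.start, peak.end - helper.length + 1))
            if pos < peak.start or pos + helper.length > peak.end:
                continue
            if occupancy.free(peak.chrom, pos, pos + helper.length):
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                realized = _realize(rng, helper)
                _write_motif(chroms, peak.chrom, pos, realized, strand)
                occupancy.claim(peak.chrom, pos, pos + helper.length)
                plantings.append(Planting(peak.peak_id, "Helper", peak.chrom, pos, strand, realized))
                helper_planted += 1
                placed = True
                break
        if not placed and wre_start is not None:
            # fall back to an unlinked position inside the peak
            for _ in range(40):
                pos = int(rng.integers(peak.start, peak.end - helper.length + 1))
                if occupancy.free(peak.chrom, pos, pos + helper.length):
                    strand = "+" if rng.integers(0, 2) == 0 else "-"
                    realized = _realize(rng, helper)
                    _write_motif(chroms, peak.chrom, pos, realized, strand)
                    occupancy.claim(peak.chrom, pos, pos + helper.length)
                    plantings.append(
                        Planting(peak.peak_id, "Helper", peak.chrom, pos, strand, realized)
                    )
                    helper_planted += 1
                    break
    return wre_planted, helper_planted


def _place_interval(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    taken: dict[str, list[tuple[int, int]]],
    length: int,
    chrom: str | None = None,
    center: int | None = None,
    max_tries: int = 60,
    fallback: bool = True,
    avoid: Mapping[str, list[tuple[int, int]]] | None = None,
) -> Peak | None:
    """Sample a peak interval that does not overlap others of its set.

    With a requested ``center`` the first half of the tries stay near
    it (+-30 bp); afterwards, unless ``fallback`` is disabled, the peak
    is placed anywhere on the chromosome. ``avoid`` lists additional
    intervals the placement must keep clear of (used so that only the
    designated shared regions overlap between the two peak sets).
    """
    chrom_names = sorted(chrom_lengths)
    for attempt in range(max_tries):
        c = chrom if chrom is not None else chrom_names[rng.integers(0, len(chrom_names))]
        limit = chrom_lengths[c]
        if center is not None:
            start = center - length // 2 + int(rng.integers(-30, 31))
        else:
            start = int(rng.integers(0, max(limit - length, 1)))
        start = max(0, min(start, limit - length))
        end = start + length
        blocked = list(taken.get(c, []))
        if avoid is not None:
            blocked += avoid.get(c, [])
        if all(end <= s or start >= e for s, e in blocked):
            taken.setdefault(c, []).append((start, end))
            return Peak(c, start, end, score=0.1, peak_id="pending")
        if center is not None and attempt >= max_tries // 2 - 1:
            if not fallback:
                return None
            center = None  # give up on the requested locus, place anywhere
    return None


def generate_peaks(
    config: SyntheticConfig,
    chroms: dict[str, bytearray],
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> tuple[list[Peak], list[Peak], list[Planting], dict[str, tuple[int, int]], dict[str, str]]:
    """Two peak sets with planted motifs, scores and a ground-truth map.

    WRE and Helper planting are independent per-peak coins; when both
    fire, Helper copies are placed at signed gaps from the WRE
    (composite element). A configurable fraction of regions is shared
    between the two sets; WT scores gain ``score_per_helper_copy`` per
    planted Helper copy, mutant scores do not.
    """
    chrom_lengths = {c: len(b) for c, b in chroms.items()}
    occupancy = _Occupancy()
    plantings: list[Planting] = []
    planted_counts: dict[str, tuple[int, int]] = {}
    lo, hi = config.peak_length_range

    targeted: list[tuple[str, str]] = []  # (gene_id, class)
    gene_classes_forced: dict[str, str] = {}
    if config.genes_per_class:
        total = sum(config.genes_per_class.values())
        if total > len(genes):
            raise ValueError("genes_per_class asks for more genes than exist")
        if total > config.n_peaks_wt:
            raise ValueError("genes_per_class asks for more targeted peaks than n_peaks_wt")
        order = rng.permutation(len(genes))[:total]
        k = 0
        for cls in MOTIF_CLASS_ORDER:
            for _ in range(config.genes_per_class.get(cls, 0)):
                gene = genes[order[k]]
                targeted.append((gene.gene_id, cls))
                gene_classes_forced[gene.gene_id] = cls
                k += 1

    gene_list = list(genes)
    taken_wt: dict[str, list[tuple[int, int]]] = {}
    taken_mut: dict[str, list[tuple[int, int]]] = {}
    peaks_wt: list[Peak] = []
    peaks_mut: list[Peak] = []

    def wt_score(copies: int) -> float:
        return max(0.1, config.score_base + config.score_per_helper_copy * copies
                   + float(rng.normal(0.0, config.score_noise_sd)))

    def mut_score() -> float:
        return max(0.1, config.score_base + config.score_shift_mut
                   + float(rng.normal(0.0, config.score_noise_sd)))

    gene_by_id = {g.gene_id: g for g in gene_list}

    # --- targeted WT peaks (deterministic per-class planting) ---
    for i, (gene_id, cls) in enumerate(targeted):
        gene = gene_by_id[gene_id]
        length = int(rng.integers(lo, hi + 1))
        peak = None
        for _ in range(30):  # stay near the gene's TSS so the class link holds
            center = gene.tss + int(rng.integers(-5000, 5001))
            peak = _place_interval(rng, chrom_lengths, taken_wt, length,
                                   chrom=gene.chrom, center=center, max_tries=8, fallback=False)
            if peak is not None:
                break
        if peak is None:
            raise RuntimeError("could not place a targeted peak; genome too crowded")
        peak.peak_id = f"WT_{i:05d}"
        n_wre, n_helper = _CLASS_PLANTING[cls]
        pw, ph = _plant_in_peak(rng, chroms, occupancy, peak, n_wre > 0, n_helper,
                                config.gap_distribution, plantings)
        peak.score = wt_score(ph)
        planted_counts[peak.peak_id] = (pw, ph)
        peaks_wt.append(peak)

    # --- remaining WT peaks ---
    n_rest = config.n_peaks_wt - len(targeted)
    n_shared = int(round(config.shared_region_fraction * min(n_rest, config.n_peaks_mut)))
    shared_partners: list[Peak] = []
    for i in range(n_rest):
        idx = len(targeted) + i
        length = int(rng.integers(lo, hi + 1))
        if rng.random() < config.gene_peak_fraction and gene_list:
            gene = gene_list[rng.integers(0, len(gene_list))]
            center = gene.tss + int(rng.integers(-25_000, 25_001))
            center = max(length, min(center, chrom_lengths[gene.chrom] - length))
            peak = _place_interval(rng, chrom_lengths, taken_wt, length, chrom=gene.chrom, center=center)
        else:
            peak = _place_interval(rng, chrom_lengths, taken_wt, length)
        if peak is None:
            raise RuntimeError("could not place a WT peak; genome too crowded")
        peak.peak_id = f"WT_{idx:05d}"
        plant_wre = rng.random() < config.p_plant_wre_wt
        copies = 0
        if rng.random() < config.p_plant_helper_wt:
            copies = _sample_from_dist(rng, config.helper_copy_distribution)
        pw, ph = _plant_in_peak(rng, chroms, occupancy, peak, plant_wre, copies,
                                config.gap_distribution, plantings)
        peak.score = wt_score(ph)
        planted_counts[peak.peak_id] = (pw, ph)
        peaks_wt.append(peak)
        if i < n_shared:
            shared_partners.append(peak)

    # --- mut peaks: shared partners first, then independent placements ---
    for j, partner in enumerate(shared_partners):
        length = int(rng.integers(lo, hi + 1))
        peak = _place_interval(rng, chrom_lengths, taken_mut, length,
                               chrom=partner.chrom, center=partner.center, fallback=False)
        if peak is None:
            continue
        peak.peak_id = f"mut_{j:05d}"
        peak.score = mut_score()
        # the shared genomic region already carries whatever was planted
        # for its WT partner; mut-specific planting is skipped here.
        planted_counts[peak.peak_id] = (0, 0)
        peaks_mut.append(peak)
    j = len(peaks_mut)
    while len(peaks_mut) < config.n_peaks_mut:
        length = int(rng.integers(lo, hi + 1))
        peak = _place_interval(rng, chrom_lengths, taken_mut, length, avoid=taken_wt)
        if peak is None:
            raise RuntimeError("could not place a mut peak; genome too crowded")
        peak.peak_id = f"mut_{j:05d}"
        plant_wre = rng.random() < config.p_plant_wre_mut
        copies = 0
        if rng.random() < config.p_plant_helper_mut:
            copies = _sample_from_dist(rng, config.helper_copy_distribution_mut)
        pw, ph = _plant_in_peak(rng, chroms, occupancy, peak, plant_wre, copies,
                                config.gap_distribution, plantings)
        peak.score = mut_score()
        planted_counts[peak.peak_id] = (pw, ph)
        peaks_mut.append(peak)
        j += 1

    gene_classes = _derive_gene_classes(config, gene_list, peaks_wt, planted_counts)
    gene_classes.update(gene_classes_forced)
    return peaks_wt, peaks_mut, plantings, planted_counts, gene_classes


def _derive_gene_classes(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    peaks_wt: Sequence[Peak],
    planted_counts: Mapping[str, tuple[int, int]],
) -> dict[str, str]:
    """Ground-truth per-gene class from planted WT peaks near the TSS."""
    rank = {c: i for i, c in enumerate(MOTIF_CLASS_ORDER)}
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks_wt:
        by_chrom.setdefault(p.chrom, []).append(p)
    classes = {}
    for gene in genes:
        best = "none"
        for p in by_chrom.get(gene.chrom, []):
            if abs(p.center - gene.tss) <= config.link_distance:
                pw, ph = planted_counts.get(p.peak_id, (0, 0))
                cls = motif_class(pw, ph)
                if rank[cls] > rank[best]:
                    best = cls
        classes[gene.gene_id] = best
    return classes


def generate_expression(
    config: SyntheticConfig,
    gene_classes: Mapping[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-gene log2 fold change and p-value with class-dependent shifts.

    log2fc = class mean effect + Gaussian(0, expression_noise_sd);
    p is the two-sided Gaussian test of log2fc against the noise sd, so
    null genes get uniform p-values and effect genes get small ones.
    """
    sd = config.expression_noise_sd
    rows = []
    for gene_id in sorted(gene_classes):
        effect = config.effect_log2fc_by_class.get(gene_classes[gene_id], 0.0)
        lfc = effect + float(rng.normal(0.0, sd))
        p = float(2.0 * _sstats.norm.sf(abs(lfc) / sd))
        rows.append({"gene": gene_id, "log2fc": lfc, "pvalue": min(p, 1.0)})
    return pd.DataFrame(rows)


def simulate(config: SyntheticConfig) -> Fixture:
    """Full in-memory fixture: genome, genes, peaks, plantings, expression."""
    rng = np.random.default_rng(config.seed)
    chroms, genes = generate_genome(config, rng)
    peaks_wt, peaks_mut, plantings, planted_counts, gene_classes = generate_peaks(
        config, chroms, genes, rng
    )
    expression = generate_expression(config, gene_classes, rng)
    genome = {c: chroms[c].decode() for c in sorted(chroms)}
    return Fixture(
        config=config,
        genome=genome,
        genes=genes,
        peaks_wt=peaks_wt,
        peaks_mut=peaks_mut,
        plantings=plantings,
        planted_counts=planted_counts,
        gene_classes=gene_classes,
        expression=expression,
    )


def make_fixture(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete fixture directory; returns the file paths.

    Files: genome.fa, genes.tsv, peaks_wt.bed, peaks_mut.bed,
    expression.tsv, manifest.json — all in the formats the readers
    consume.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = simulate(config)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.tsv",
        "peaks_wt": outdir / "peaks_wt.bed",
        "peaks_mut": outdir / "peaks_mut.bed",
        "expression": outdir / "expression.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(fx.genome, paths["genome"])
    with open(paths["genes"], "w") as handle:
        handle.write("gene_id\tchrom\tstrand\ttss\ttes\texon_starts\texon_ends\n")
        for g in fx.genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            handle.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\t{starts}\t{ends}\n")
    write_bed(fx.peaks_wt, paths["peaks_wt"])
    write_bed(fx.peaks_mut, paths["peaks_mut"])
    fx.expression.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6g")
    with open(paths["manifest"], "w") as handle:
        json.dump(fx.manifest(), handle, indent=1)
    return paths
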