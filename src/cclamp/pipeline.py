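"""End-to-end orchestration: scan -> co-occurrence -> comparison ->
annotation -> expression integration, with TSV outputs and an
auditable plain-text summary.

Every intermediate file is plain TSV with a one-line schema-version
header comment so stages can be re-run individually and chained runs
reproduce the monolithic run byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import annotate as ann
from . import background as bg
from . import compare as cmp
from . import integrate as integ
from . import io as cio
from . import motifs as mot

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_tsv", "read_tsv"]

SCHEMA_HEADER = "# cclamp-schema: v1\n"


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(SCHEMA_HEADER)
        df.to_csv(handle, sep="\t", index=False, float_format="%.6g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as handle:
        first = handle.readline()
        if not first.startswith("# cclamp-schema:"):
            raise ValueError(f"{path}: missing or incompatible schema header")
        if first.strip() != SCHEMA_HEADER.strip():
            raise ValueError(f"{path}: unsupported schema version {first.strip()!r}")
        return pd.read_csv(handle, sep="\t")


@dataclass
class RunConfig:
    """Inputs, motif set and cutoffs for a full pipeline run."""

    genome_fasta: str
    peaks_wt_bed: str
    peaks_mut_bed: str
    gene_table: str
    expression_table: str | None = None
    output_dir: str = "cclamp_out"
    motifs: dict[str, str] = field(default_factory=dict)  # extra NAME=PATTERN entries
    top_k: int = 1000
    promoter_halfwidth: int = ann.PROMOTER_HALFWIDTH
    enrichment_upstream: int = ann.ENRICHMENT_UPSTREAM
    enrichment_downstream: int = ann.ENRICHMENT_DOWNSTREAM
    link_distance: int = 30_000
    count_distance: int = 50_000
    score_cutoff: float = 67.0
    p_cutoff: float = 0.02
    background: str = "peak_set"  # peak_set | uniform
    cooccurrence_method: str = "poisson_binomial"
    gsea_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k <= 0 or self.link_distance <= 0 or self.count_distance <= 0:
            raise ValueError("top_k and distance cutoffs must be positive")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.background not in {"peak_set", "uniform"}:
            raise ValueError("background must be 'peak_set' or 'uniform'")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls(**json.load(handle))

    def motif_set(self) -> dict[str, mot.DegenerateMotif]:
        motifs = dict(mot.BUILTIN_MOTIFS)
        for name, pattern in self.motifs.items():
            motifs[name] = mot.DegenerateMotif(name, pattern)
        return motifs


@dataclass
class PipelineResult:
    output_dir: Path
    files: dict[str, Path]
    summary_lines: list[str]
    stats: dict[str, float]


def _scan_hits(
    sequences: Mapping[str, str], motif: mot.DegenerateMotif
) -> dict[str, list[mot.MotifHit]]:
    return {
        pid: mot.scan_sequence(seq, motif, peak_id=pid) for pid, seq in sequences.items()
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write all report TSVs plus summary.txt."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    lines: list[str] = [f"cclamp pipeline v{__version__}", f"seed: {config.seed}", "parameters:"]
    for key, value in asdict(config).items():
        if key == "output_dir":  # the one knob that may differ between identical analyses
            continue
        lines.append(f"  {key} = {value}")
    stats: dict[str, float] = {}

    if config.expression_table is not None and not Path(config.expression_table).exists():
        raise FileNotFoundError(f"expression table not found: {config.expression_table}")

    genome = cio.read_fasta(config.genome_fasta)
    genes = cio.read_gene_models(config.gene_table)
    peaks_wt_all = cio.read_bed(config.peaks_wt_bed)
    peaks_mut_all = cio.read_bed(config.peaks_mut_bed)
    wt_top = cio.top_peaks(peaks_wt_all, config.top_k)
    mut_top = cio.top_peaks(peaks_mut_all, config.top_k)
    motifs = config.motif_set()

    # ---- scan & profile ----
    seqs_wt = cio.extract_peak_sequences(wt_top, genome)
    seqs_mut = cio.extract_peak_sequences(mut_top, genome)
    prof_wt = mot.profile_peaks(seqs_wt, motifs.values())
    prof_mut = mot.profile_peaks(seqs_mut, motifs.values())
    prof_wt_map = {p.peak_id: p for p in prof_wt}
    for label, prof in (("wt", prof_wt), ("mut", prof_mut)):
        path = outdir / f"profiles_{label}.tsv"
        write_tsv(mot.profiles_to_frame(prof), path)
        files[f"profiles_{label}"] = path

    # ---- co-occurrence ----
    if config.background == "uniform":
        model = bg.BackgroundModel.uniform()
    else:
        model = bg.BackgroundModel.from_sequences(seqs_wt.values())
    lines.append(
        "background: " + ", ".join(f"{b}={model.frequencies[b]:.4f}" for b in "ACGT")
        + f" ({model.source})"
    )
    rows = []
    for label, prof in (("WT", prof_wt), ("mut", prof_mut)):
        rows += bg.cooccurrence_table(
            prof, model, motifs["WRE"], motifs["Helper"],
            condition_label=label, method=config.cooccurrence_method,
        )
    cooccur_df = bg.cooccurrence_frame(rows)
    files["cooccurrence"] = outdir / "cooccurrence.tsv"
    write_tsv(cooccur_df, files["cooccurrence"])
    wt_n1 = rows[0]
    stats["cooccur_wt_observed_n1"] = wt_n1.observed_both
    stats["cooccur_wt_expected_n1"] = wt_n1.expected_both
    stats["cooccur_wt_p_n1"] = wt_n1.p_value
    lines.append(
        f"co-occurrence WT N=1: observed={wt_n1.observed_both} expected={wt_n1.expected_both:.2f} "
        f"p={wt_n1.p_value:.3g} (n={len(prof_wt)})"
    )

    # ---- comparative analytics ----
    pairs = cmp.overlap_regions(wt_top, mut_top)
    strength = cmp.classify_strength(pairs) if pairs else None
    if strength is not None:
        pair_df = pd.DataFrame(
            {
                "peak_wt": [p.peak_a.peak_id for p in strength.pairs],
                "chrom": [p.peak_a.chrom for p in strength.pairs],
                "start_wt": [p.peak_a.start for p in strength.pairs],
                "end_wt": [p.peak_a.end for p in strength.pairs],
                "peak_mut": [p.peak_b.peak_id for p in strength.pairs],
                "overlap_bp": [p.overlap_bp for p in strength.pairs],
                "score_wt": [p.score_a for p in strength.pairs],
                "score_mut": [p.score_b for p in strength.pairs],
                "class": [p.strength_class for p in strength.pairs],
            }
        )
        files["matched_pairs"] = outdir / "matched_pairs.tsv"
        write_tsv(pair_df, files["matched_pairs"])
        stats["n_matched_regions"] = strength.n_tested
        stats["strength_p"] = strength.p_value
        lines.append(
            f"matched regions: n={strength.n_tested} wt_stronger={strength.n_a_stronger} "
            f"mut_stronger={strength.n_b_stronger} similar={strength.n_similar} "
            f"signed-rank p={strength.p_value:.3g}"
        )
        strata = cmp.stratify_by_copy_number(strength.pairs, prof_wt_map, "shortHelper")
        files["copy_number_strata"] = outdir / "copy_number_strata.tsv"
        write_tsv(strata.to_frame(), files["copy_number_strata"])
        for (b1, b2), p in sorted(strata.pairwise_p.items()):
            lines.append(
                f"copy-number bins {b1} vs {b2}: n={strata.bin_sizes[b1]}/{strata.bin_sizes[b2]} "
                f"Mann-Whitney p={p:.3g}"
            )

    # motif position profiles around peak centers
    center_rows = []
    for label, seqs, peaks in (("wt", seqs_wt, wt_top), ("mut", seqs_mut, mut_top)):
        hits = [h for hs in _scan_hits(seqs, motifs["shortHelper"]).values() for h in hs]
        edges, counts = cmp.motif_center_profile(
            hits, {p.peak_id: p for p in peaks}, motifs["shortHelper"].length
        )
        for left, count in zip(edges[:-1], counts):
            center_rows.append({"condition": label, "bin_left": int(left), "count": int(count)})
    files["center_profile"] = outdir / "center_profile.tsv"
    write_tsv(pd.DataFrame(center_rows), files["center_profile"])

    # WRE-Helper spacing and orientation in the WT set
    hits_by_peak = {
        pid: mot.scan_sequence(seq, motifs["WRE"], peak_id=pid)
        + mot.scan_sequence(seq, motifs["Helper"], peak_id=pid)
        for pid, seq in seqs_wt.items()
    }
    spacing = cmp.spacing_orientation(
        hits_by_peak, wre_length=motifs["WRE"].length, helper_length=motifs["Helper"].length
    )
    files["spacing"] = outdir / "spacing.tsv"
    write_tsv(cmp.spacing_summary(spacing), files["spacing"])
    stats["n_spacing_pairs"] = len(spacing)

    # incidence comparison and motif fractions
    inc_rows = []
    for name in ("WRE", "Helper"):
        res = cmp.compare_incidence(prof_wt, prof_mut, name)
        inc_rows.append(
            {
                "motif": name,
                "mean_incidence_wt": res.mean_a,
                "mean_incidence_mut": res.mean_b,
                "p_value": res.p_value,
            }
        )
        stats[f"incidence_p_{name}"] = res.p_value
        lines.append(
            f"incidence {name}: WT={res.mean_a:.3g} mut={res.mean_b:.3g} "
            f"Mann-Whitney p={res.p_value:.3g} (n={res.n_a}+{res.n_b})"
        )
    files["incidence"] = outdir / "incidence_comparison.tsv"
    write_tsv(pd.DataFrame(inc_rows), files["incidence"])
    frac_rows = []
    for name in motifs:
        for label, prof in (("wt", prof_wt), ("mut", prof_mut)):
            frac = cmp.fraction_with_motif(prof, name)
            frac_rows.append({"motif": name, "condition": label, "fraction_with_motif": frac})
            stats[f"fraction_{name}_{label}"] = frac
    files["motif_fractions"] = outdir / "motif_fractions.tsv"
    write_tsv(pd.DataFrame(frac_rows), files["motif_fractions"])
    rec_wt, rec_mut = cmp.reciprocal_overlap_fraction(peaks_wt_all, peaks_mut_all, 0.2)
    stats["reciprocal_overlap_wt"] = rec_wt
    stats["reciprocal_overlap_mut"] = rec_mut
    lines.append(f"reciprocal overlap of top 20%: WT={rec_wt:.3f} mut={rec_mut:.3f}")

    # ---- annotation ----
    dist_rows = []
    for label, peaks in (("wt", wt_top), ("mut", mut_top)):
        assignments = ann.assign_features(peaks, genes, config.promoter_halfwidth)
        adf = pd.DataFrame(
            {
                "peak_id": [a.peak_id for a in assignments],
                "category": [a.category for a in assignments],
                "gene_id": [a.gene_id for a in assignments],
                "tss_distance": [a.tss_distance for a in assignments],
            }
        )
        path = outdir / f"annotation_{label}.tsv"
        write_tsv(adf, path)
        files[f"annotation_{label}"] = path
        dist = ann.feature_distribution(assignments)
        for cat in ann.CATEGORIES:
            dist_rows.append({"condition": label, "category": cat, "count": dist[cat]})
        stats[f"promoter_peaks_{label}"] = dist["promoter"]
    files["feature_distribution"] = outdir / "feature_distribution.tsv"
    write_tsv(pd.DataFrame(dist_rows), files["feature_distribution"])

    chrom_lengths = {name: len(rec) for name, rec in genome.items()}
    promoters = ann.promoter_windows(
        genes, chrom_lengths, config.enrichment_upstream, config.enrichment_downstream
    )
    bound_ids = {
        pair.peak_b.peak_id for pair in cmp.overlap_regions(wt_top, promoters)
    }
    if bound_ids and len(bound_ids) < len(promoters):
        prom_seqs = cio.extract_peak_sequences(promoters, genome)
        bound_seqs = {pid: prom_seqs[pid] for pid in sorted(bound_ids)}
        enr = ann.promoter_incidence_enrichment(bound_seqs, prom_seqs, motifs["Helper"])
        files["promoter_enrichment"] = outdir / "promoter_enrichment.tsv"
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "motif": enr.motif,
                        "n_bound": len(enr.bound_per_kb),
                        "n_background": len(enr.background_per_kb),
                        "mean_per_kb_bound": enr.mean_bound,
                        "mean_per_kb_background": enr.mean_background,
                        "p_value": enr.p_value,
                    }
                ]
            ),
            files["promoter_enrichment"],
        )
        stats["promoter_enrichment_p"] = enr.p_value
        lines.append(
            f"promoter Helper incidence: bound={enr.mean_bound:.3f}/kb "
            f"background={enr.mean_background:.3f}/kb p={enr.p_value:.3g}"
        )

    # ---- expression integration ----
    if config.expression_table is not None:
        expression = cio.read_expression_table(config.expression_table)
        regulated = integ.select_regulated(expression, config.p_cutoff)
        links = integ.link_peaks_to_genes(
            wt_top, genes, prof_wt_map,
            max_distance=config.link_distance, min_score=config.score_cutoff,
        )
        links50 = integ.link_peaks_to_genes(
            wt_top, genes, max_distance=config.count_distance, min_score=config.score_cutoff
        )
        counts50 = {l.gene_id: len(l.linked_peaks) for l in links50}
        link_df = pd.DataFrame(
            {
                "gene": [l.gene_id for l in links],
                "n_peaks_within_link_distance": [len(l.linked_peaks) for l in links],
                "n_peaks_within_count_distance": [counts50.get(l.gene_id, 0) for l in links],
                "max_peak_score": [l.max_peak_score for l in links],
                "motif_class": [l.motif_class for l in links],
            }
        )
        files["gene_links"] = outdir / "gene_links.tsv"
        write_tsv(link_df, files["gene_links"])

        universe = len(expression)
        expressed = {r.gene_id for r in expression}
        linked = {l.gene_id for l in links} & expressed
        down = regulated.down & expressed
        overlap, p_hyper = integ.hypergeometric_overlap(down, linked, universe)
        files["overlap_test"] = outdir / "overlap_test.tsv"
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "n_down": len(down),
                        "n_linked": len(linked),
                        "universe": universe,
                        "overlap": overlap,
                        "hypergeometric_p": p_hyper,
                    }
                ]
            ),
            files["overlap_test"],
        )
        stats["n_down_genes"] = len(down)
        stats["n_down_with_peak"] = overlap
        stats["overlap_p"] = p_hyper
        lines.append(
            f"downregulated genes (p<{config.p_cutoff}): {len(down)}; with linked peak: {overlap}; "
            f"hypergeometric p={p_hyper:.3g} (universe {universe})"
        )

        ranked = [
            l.gene_id
            for l in sorted(links, key=lambda l: (-l.max_peak_score, l.gene_id))
            if l.gene_id in expressed
        ]
        subset = down & set(ranked)
        if 0 < len(subset) < len(ranked):
            gsea = integ.peak_score_gsea(
                ranked, subset, n_permutations=config.gsea_permutations, seed=config.seed
            )
            files["gsea"] = outdir / "gsea.tsv"
            write_tsv(
                pd.DataFrame(
                    [
                        {
                            "subset_size": gsea.subset_size,
                            "ranked_size": len(ranked),
                            "enrichment_score": gsea.enrichment_score,
                            "permutation_p": gsea.p_value,
                            "n_permutations": gsea.n_permutations,
                        }
                    ]
                ),
                files["gsea"],
            )
            stats["gsea_es"] = gsea.enrichment_score
            stats["gsea_p"] = gsea.p_value
            lines.append(
                f"GSEA of peak scores: ES={gsea.enrichment_score:.3f} p={gsea.p_value:.3g} "
                f"({gsea.subset_size}/{len(ranked)} genes)"
            )

        assoc = integ.motif_class_association(links, expression)
        files["class_association"] = outdir / "class_association.tsv"
        write_tsv(assoc.summary, files["class_association"])
        for (c1, c2), p in sorted(assoc.pairwise_p.items()):
            lines.append(f"class {c1} vs {c2}: Mann-Whitney p={p:.3g}")

        report = integ.target_gene_report(links, regulated.down, expression)
        files["target_report"] = outdir / "target_report.tsv"
        write_tsv(report, files["target_report"])
        stats["n_target_genes"] = len(report)

    files["summary"] = outdir / "summary.txt"
    with open(files["summary"], "w") as handle:
        handle.write("\n".join(lines) + "\n")
    return PipelineResult(outdir, files, lines, stats)
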