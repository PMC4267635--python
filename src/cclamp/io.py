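"""Readers/writers for the formats the pipeline touches.

Peaks are BED3/BED5 intervals (0-based half-open), genomes are FASTA,
gene models come from a minimal tab-delimited table (or BED12/GTF), and
nascent-transcription changes arrive as a per-gene fold-change/p-value
table. All coordinates are kept 0-based half-open internally; 1-based
values in reports are labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Peak",
    "SequenceRecord",
    "GeneModel",
    "ExpressionRecord",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "extract_peak_sequences",
    "read_expression_table",
    "read_gene_models",
    "read_gtf",
    "top_peaks",
]

_VALID_ALPHABET = set("ACGTN")


@dataclass
class Peak:
    """A scored genomic interval, the unit of all occupancy statistics.

    ``score`` is the (unitless) peak-caller enrichment; ``summit_offset``
    is measured from ``start`` when present.
    """

    chrom: str
    start: int
    end: int
    score: float = 0.0
    summit_offset: int | None = None
    peak_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"peak {self.peak_id or self.chrom}: end ({self.end}) must be > start ({self.start})"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.peak_id}: score must be non-negative")
        if self.summit_offset is not None and not (0 <= self.summit_offset < self.length):
            raise ValueError(f"peak {self.peak_id}: summit_offset outside interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SequenceRecord:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - _VALID_ALPHABET
        if bad:
            raise ValueError(f"sequence {self.name}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """TSS-anchored gene structure.

    ``tss`` is the leftmost coordinate for ``+`` strand genes and the
    rightmost (exclusive end minus one is *not* used; the raw rightmost
    bound is kept) for ``-`` strand genes, so ``tss``/``tes`` always face
    the direction of transcription.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        self.exons = exons

    @property
    def left(self) -> int:
        return min(self.tss, self.tes)

    @property
    def right(self) -> int:
        return max(self.tss, self.tes)


@dataclass
class ExpressionRecord:
    gene_id: str
    log2_fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"gene {self.gene_id}: p_value {self.p_value} outside [0, 1]")


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED5 peaks, preserving file order.

    Column 4 (when present) is the peak id, column 5 the score. Missing
    scores default to 0 and missing names to ``peak_<n>``.
    """
    peaks: list[Peak] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] else f"peak_{lineno}"
            score = 0.0
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed score {fields[4]!r}") from exc
            try:
                peaks.append(Peak(chrom, start, end, score=score, peak_id=name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write BED5 rows; round-trips coordinates and scores exactly."""
    with open(path, "w") as handle:
        for p in peaks:
            handle.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.score:g}\n")


def read_fasta(path: str | Path) -> dict[str, SequenceRecord]:
    """Read FASTA into a name->record mapping (uppercased, U->T)."""
    records: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA header {rec.id!r}")
        records[rec.id] = SequenceRecord(rec.id, str(rec.seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Mapping[str, str | SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, rec in records.items():
            seq = rec.sequence if isinstance(rec, SequenceRecord) else rec
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def extract_peak_sequences(
    peaks: Iterable[Peak],
    genome: Mapping[str, SequenceRecord | str],
) -> dict[str, str]:
    """Plus-strand genome sequence for every peak (peaks are strandless).

    The returned string always has length ``end - start``; out-of-bounds
    intervals raise, naming the offending peak.
    """
    out: dict[str, str] = {}
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"peak {p.peak_id}: chromosome {p.chrom!r} absent from genome")
        entry = genome[p.chrom]
        seq = entry.sequence if isinstance(entry, SequenceRecord) else entry
        if p.start < 0 or p.end > len(seq):
            raise ValueError(
                f"peak {p.peak_id}: interval [{p.start}, {p.end}) outside {p.chrom} (length {len(seq)})"
            )
        out[p.peak_id] = seq[p.start : p.end]
    return out


def read_expression_table(
    path: str | Path,
    gene_col: str = "gene",
    lfc_col: str = "log2fc",
    p_col: str = "pvalue",
    sep: str | None = None,
) -> list[ExpressionRecord]:
    """Read a per-gene fold-change table (tab- or comma-delimited).

    The header must contain the three configured column names; duplicate
    gene ids and out-of-range p-values are rejected.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = {gene_col, lfc_col, p_col} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[ExpressionRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based incl. header
        gene = str(getattr(row, gene_col))
        if gene in seen:
            raise ValueError(f"{path}: duplicate gene_id {gene!r} at row {idx}")
        seen.add(gene)
        try:
            lfc = float(getattr(row, lfc_col))
            pval = float(getattr(row, p_col))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: unparseable numeric value at row {idx}") from exc
        try:
            records.append(ExpressionRecord(gene, lfc, pval))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
    return records


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in str(text).rstrip(",").split(",") if x != ""]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from the minimal table or BED12.

    The table format is tab-delimited with a header:
    ``gene_id chrom strand tss tes exon_starts exon_ends`` where the exon
    columns are comma-joined absolute coordinates. Files whose first
    non-comment line has 12 columns and no header are parsed as BED12.
    """
    path = Path(path)
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip() and not line.startswith("#"):
                first = line.rstrip("\n")
                break
    fields = first.split("\t")
    if len(fields) == 12 and not first.startswith("gene_id"):
        return _read_bed12(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "strand", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing gene-model columns {sorted(missing)}")
    genes = []
    has_exons = {"exon_starts", "exon_ends"} <= set(df.columns)
    for row in df.itertuples(index=False):
        exons: list[tuple[int, int]] = []
        if has_exons and not pd.isna(row.exon_starts):
            starts = _parse_int_list(row.exon_starts)
            ends = _parse_int_list(row.exon_ends)
            exons = list(zip(starts, ends))
        genes.append(
            GeneModel(str(row.gene_id), str(row.chrom), str(row.strand), int(row.tss), int(row.tes), exons)
        )
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = _parse_int_list(f[10])
            offsets = _parse_int_list(f[11])
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(GeneModel(name, chrom, strand, tss, tes, exons))
    return genes


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Minimal GTF reader: gene and exon features, gene_id attribute only.

    Exotic attribute dialects are unsupported; coordinates are converted
    from GTF 1-based closed to 0-based half-open.
    """
    bodies: dict[str, dict] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(" ", 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                continue
            entry = bodies.setdefault(
                gene_id, {"chrom": chrom, "strand": strand, "left": None, "right": None, "exons": []}
            )
            s0, e0 = int(start) - 1, int(end)
            if feature == "gene" or entry["left"] is None:
                entry["left"] = s0 if entry["left"] is None else min(entry["left"], s0)
                entry["right"] = e0 if entry["right"] is None else max(entry["right"], e0)
            if feature == "exon":
                entry["exons"].append((s0, e0))
                entry["left"] = min(entry["left"], s0)
                entry["right"] = max(entry["right"], e0)
    genes = []
    for gene_id, entry in bodies.items():
        tss, tes = (
            (entry["left"], entry["right"]) if entry["strand"] == "+" else (entry["right"], entry["left"])
        )
        genes.append(GeneModel(gene_id, entry["chrom"], entry["strand"], tss, tes, sorted(entry["exons"])))
    return genes


def top_peaks(peaks: Sequence[Peak], k: int) -> list[Peak]:
    """Top ``k`` peaks by descending score; ties broken by (chrom, start)."""
    ranked = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))
    return ranked[: max(k, 0)]
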