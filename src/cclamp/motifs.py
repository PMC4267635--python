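"""Degenerate (IUPAC) motif and weight-matrix scanning of peak sequences.

The two DNA-binding domains of E-tail TCF isoforms recognise distinct
elements: the HMG box binds the Wnt Response Element (WRE, CTTTGWWS)
and the C-clamp binds the GC-rich Helper site (RCCGCC; short form
RCCG). This module scans sequences on both strands for such degenerate
patterns, summarises per-peak counts and incidence (count / peak
length), derives positional weight matrices from aligned hits, and runs
a differential k-mer enrichment between two peak sets (a simplified
stand-in for differential de novo motif discovery).

Conventions
-----------
* Overlapping occurrences are counted.
* Minus-strand occurrences are found by scanning the sequence against
  the reverse complement of the pattern and reported with ``start`` at
  the leftmost base on the forward sequence.
* A window matching on both strands counts twice in ``scan_sequence``
  (per-strand events) but once per unified reverse-complement class in
  the k-mer table (per-site events); ``collapse_palindromic=True``
  switches the scanner to the per-site behaviour.
* ``N`` bases never match any symbol.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IUPAC_SETS",
    "DegenerateMotif",
    "MotifHit",
    "PeakMotifProfile",
    "WeightMatrix",
    "BUILTIN_MOTIFS",
    "iupac_match",
    "reverse_complement",
    "scan_sequence",
    "profile_peaks",
    "pwm_from_hits",
    "pwm_scan",
    "differential_kmer_enrichment",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(symbol: str, base: str) -> bool:
    """True iff ``base`` is in the degenerate symbol's set; N matches nothing."""
    if symbol not in IUPAC_SETS:
        raise ValueError(f"invalid IUPAC symbol {symbol!r}")
    if base == "N":
        return False
    if base not in _BASE_INDEX:
        raise ValueError(f"invalid base {base!r}")
    return base in IUPAC_SETS[symbol]


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC pattern, e.g. the WRE ``CTTTGWWS`` or Helper ``RCCGCC``."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError(f"motif {self.name}: pattern must have length >= 2")
        bad = set(self.pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    def admitted(self, i: int) -> frozenset[str]:
        return IUPAC_SETS[self.pattern[i]]


BUILTIN_MOTIFS: dict[str, DegenerateMotif] = {
    "WRE": DegenerateMotif("WRE", "CTTTGWWS"),
    "relaxedWRE": DegenerateMotif("relaxedWRE", "CTTTGW"),
    "Helper": DegenerateMotif("Helper", "RCCGCC"),
    "shortHelper": DegenerateMotif("shortHelper", "RCCG"),
}


@dataclass(frozen=True)
class MotifHit:
    """A located occurrence; ``start`` is the leftmost base on the forward
    coordinates of the scanned sequence regardless of strand."""

    motif_name: str
    start: int
    strand: str
    peak_id: str | None = None
    score: float | None = None


_REGEX_CACHE: dict[str, re.Pattern] = {}


def _pattern_regex(pattern: str) -> re.Pattern:
    rx = _REGEX_CACHE.get(pattern)
    if rx is None:
        body = "".join("[%s]" % "".join(sorted(IUPAC_SETS[s])) for s in pattern)
        rx = re.compile(f"(?={body})")  # lookahead => overlapping occurrences
        _REGEX_CACHE[pattern] = rx
    return rx


def scan_sequence(
    sequence: str,
    motif: DegenerateMotif,
    strands: Sequence[str] = ("+", "-"),
    peak_id: str | None = None,
    collapse_palindromic: bool = False,
) -> list[MotifHit]:
    """All overlapping occurrences of ``motif`` on the requested strands.

    Hits are sorted by start then strand (+ before -). With
    ``collapse_palindromic`` a window matching on both strands yields a
    single ``+`` hit.
    """
    sequence = sequence.upper()
    hits: list[MotifHit] = []
    plus_starts: set[int] = set()
    if "+" in strands:
        for m in _pattern_regex(motif.pattern).finditer(sequence):
            hits.append(MotifHit(motif.name, m.start(), "+", peak_id))
            plus_starts.add(m.start())
    if "-" in strands:
        rc = reverse_complement(motif.pattern)
        for m in _pattern_regex(rc).finditer(sequence):
            if collapse_palindromic and m.start() in plus_starts:
                continue
            hits.append(MotifHit(motif.name, m.start(), "-", peak_id))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass
class PeakMotifProfile:
    """Per-peak motif counts and incidence (count / peak length)."""

    peak_id: str
    length: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def incidence(self) -> dict[str, float]:
        return {name: c / self.length for name, c in self.counts.items()}


def profile_peaks(
    peak_sequences: Mapping[str, str],
    motifs: Iterable[DegenerateMotif],
    collapse_palindromic: bool = False,
) -> list[PeakMotifProfile]:
    """Scan every peak sequence for every motif; order follows the input."""
    motifs = list(motifs)
    if not motifs:
        raise ValueError("motif set must be nonempty")
    profiles = []
    for peak_id, seq in peak_sequences.items():
        if len(seq) == 0:
            raise ValueError(f"peak {peak_id}: zero-length sequence")
        counts = {
            m.name: len(scan_sequence(seq, m, collapse_palindromic=collapse_palindromic))
            for m in motifs
        }
        profiles.append(PeakMotifProfile(peak_id, len(seq), counts))
    return profiles


def profiles_to_frame(profiles: Sequence[PeakMotifProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict = {"peak_id": p.peak_id, "length": p.length}
        for name, c in p.counts.items():
            row[f"count_{name}"] = c
            row[f"incidence_{name}"] = c / p.length
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class WeightMatrix:
    """Positional weight matrix; ``columns`` has shape (m, 4) in A,C,G,T order."""

    name: str
    columns: np.ndarray
    pseudocount: float
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError("columns must be an (m, 4) array")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each column must sum to 1 within 1e-9")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.columns.shape[0]


def pwm_from_hits(
    aligned_hit_sequences: Sequence[str],
    pseudocount: float,
    name: str = "pwm",
    threshold_fraction: float = 0.8,
) -> WeightMatrix:
    """Probability matrix from equal-length aligned hit sequences.

    Column j: (count of base b at j + pseudocount) / (n + 4 * pseudocount).
    """
    if not aligned_hit_sequences:
        raise ValueError("no hit sequences given")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    m = len(aligned_hit_sequences[0])
    if any(len(s) != m for s in aligned_hit_sequences):
        raise ValueError("hit sequences must all have equal length")
    n = len(aligned_hit_sequences)
    counts = np.zeros((m, 4))
    for seq in aligned_hit_sequences:
        for j, base in enumerate(seq.upper()):
            if base in _BASE_INDEX:
                counts[j, _BASE_INDEX[base]] += 1
    cols = (counts + pseudocount) / (n + 4 * pseudocount)
    cols /= cols.sum(axis=1, keepdims=True)  # guard vs Ns reducing column mass
    return WeightMatrix(name, cols, pseudocount, threshold_fraction)


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def pwm_scan(
    sequence: str,
    wm: WeightMatrix,
    background: Mapping[str, float] | None = None,
    strands: Sequence[str] = ("+", "-"),
) -> list[MotifHit]:
    """Log-odds scan on both strands.

    A window is a hit iff its log-odds score against the background
    nucleotide model reaches ``threshold_fraction`` of the maximum
    attainable score. ``background=None`` estimates base frequencies
    from the scanned sequence itself. Windows containing N are skipped.
    """
    m = wm.length
    if len(sequence) < m:
        return []
    codes = _encode(sequence)
    if background is None:
        valid = codes[codes >= 0]
        if valid.size == 0:
            return []
        freqs = np.bincount(valid, minlength=4).astype(float)
        freqs = (freqs + 1.0) / (freqs.sum() + 4.0)
    else:
        freqs = np.array([background[b] for b in "ACGT"], dtype=float)
        freqs = freqs / freqs.sum()
    logodds = np.log(wm.columns) - np.log(freqs)[None, :]
    max_score = logodds.max(axis=1).sum()
    threshold = wm.threshold_fraction * max_score

    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    ok = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    hits: list[MotifHit] = []
    if "+" in strands:
        scores = logodds[np.arange(m)[None, :], safe].sum(axis=1)
        for i in np.nonzero(ok & (scores >= threshold - 1e-12))[0]:
            hits.append(MotifHit(wm.name, int(i), "+", score=float(scores[i])))
    if "-" in strands:
        # score of the reverse-complemented window against the matrix
        logodds_rc = logodds[::-1, ::-1]
        scores = logodds_rc[np.arange(m)[None, :], safe].sum(axis=1)
        for i in np.nonzero(ok & (scores >= threshold - 1e-12))[0]:
            hits.append(MotifHit(wm.name, int(i), "-", score=float(scores[i])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _count_canonical_kmers(seqs: Iterable[str], k: int) -> tuple[Counter, int]:
    counts: Counter = Counter()
    total = 0
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            canon = min(kmer, reverse_complement(kmer))
            counts[canon] += 1
            total += 1
    return counts, total


def differential_kmer_enrichment(
    seqs_a: Sequence[str],
    seqs_b: Sequence[str],
    k: int,
) -> pd.DataFrame:
    """Per-k-mer Fisher exact comparison of two sequence sets.

    Each k-mer is unified with its reverse complement (one count per
    window, so a palindromic window still counts once). Columns:
    kmer, count_a, count_b, odds_ratio, p_value, q_value; rows sorted by
    q then descending odds ratio.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if not seqs_a or not seqs_b:
        raise ValueError("both sequence sets must be nonempty")
    counts_a, total_a = _count_canonical_kmers(seqs_a, k)
    counts_b, total_b = _count_canonical_kmers(seqs_b, k)
    if total_a == 0 or total_b == 0:
        raise ValueError(f"k={k} is larger than every scannable sequence")
    rows = []
    for kmer in sorted(set(counts_a) | set(counts_b)):
        ca, cb = counts_a.get(kmer, 0), counts_b.get(kmer, 0)
        table = [[ca, total_a - ca], [cb, total_b - cb]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"kmer": kmer, "count_a": ca, "count_b": cb, "odds_ratio": odds, "p_value": p})
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(
        ["q_value", "odds_ratio", "kmer"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df[["kmer", "count_a", "count_b", "odds_ratio", "p_value", "q_value"]]
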