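"""Comparative occupancy analytics between two peak sets.

Compares a wild-type factor against a DNA-binding-domain mutant:
replicate/region overlap, matched-region strength classification,
Helper-copy-number stratification of score differences, motif-position
profiles around peak centers, WRE-Helper spacing/orientation, and
incidence comparisons.

Rank tests use exact enumeration for small samples (total n <= 12 by
default) with midrank tie handling, and the normal approximation with
tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import Peak, top_peaks
from .motifs import MotifHit, PeakMotifProfile

__all__ = [
    "MatchedRegionPair",
    "SpacingRecord",
    "overlap_regions",
    "reciprocal_overlap_fraction",
    "classify_strength",
    "stratify_by_copy_number",
    "motif_center_profile",
    "spacing_orientation",
    "spacing_summary",
    "compare_incidence",
    "fraction_with_motif",
    "mann_whitney",
]

EXACT_MAX_N = 12


@dataclass
class MatchedRegionPair:
    peak_a: Peak
    peak_b: Peak
    overlap_bp: int
    score_a: float
    score_b: float
    strength_class: str | None = None

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("matched pairs require >= 1 bp of overlap")


@dataclass
class SpacingRecord:
    """One WRE-Helper hit pair within a peak.

    ``signed_gap`` is the edge-to-edge distance, positive when the
    Helper lies 3' of the WRE in the WRE hit's strand orientation.
    """

    peak_id: str
    wre_hit: MotifHit
    helper_hit: MotifHit
    signed_gap: int
    relative_orientation: str


def overlap_regions(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    min_overlap: int = 1,
) -> list[MatchedRegionPair]:
    """All (a, b) pairs sharing >= min_overlap bases (any overlap rule).

    A peak may appear in multiple pairs; order is deterministic
    (by a's coordinates then b's).
    """
    trees: dict[str, IntervalTree] = {}
    for b in peaks_b:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b)
    pairs: list[MatchedRegionPair] = []
    for a in sorted(peaks_a, key=lambda p: (p.chrom, p.start, p.end, p.peak_id)):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        matches = sorted(tree.overlap(a.start, a.end), key=lambda iv: (iv.begin, iv.end, iv.data.peak_id))
        for iv in matches:
            b = iv.data
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= min_overlap:
                pairs.append(MatchedRegionPair(a, b, ov, a.score, b.score))
    return pairs


def reciprocal_overlap_fraction(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    top_fraction: float,
) -> tuple[float, float]:
    """Fraction of each set's top-ranked peaks overlapping the other full set."""
    if not peaks_a or not peaks_b:
        raise ValueError("both peak sets must be nonempty")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")

    def frac(top_set: Sequence[Peak], full_other: Sequence[Peak]) -> float:
        k = max(1, round(top_fraction * len(top_set)))
        top = top_peaks(top_set, k)
        hit_ids = {p.peak_a.peak_id for p in overlap_regions(top, full_other)}
        return len(hit_ids) / len(top)

    return frac(peaks_a, peaks_b), frac(peaks_b, peaks_a)


def _dedupe_max_overlap(pairs: Sequence[MatchedRegionPair]) -> list[MatchedRegionPair]:
    """Keep the maximum-overlap partner per peak_a (avoids pseudo-replication)."""
    best: dict[str, MatchedRegionPair] = {}
    for pair in pairs:
        cur = best.get(pair.peak_a.peak_id)
        if cur is None or (pair.overlap_bp, -pair.peak_b.start) > (cur.overlap_bp, -cur.peak_b.start):
            best[pair.peak_a.peak_id] = pair
    return [best[k] for k in sorted(best)]


@dataclass
class StrengthComparison:
    pairs: list[MatchedRegionPair]
    n_a_stronger: int
    n_b_stronger: int
    n_similar: int
    test: str
    n_tested: int
    p_value: float


def classify_strength(
    pairs: Sequence[MatchedRegionPair],
    ratio_threshold: float = 1.5,
    test: str = "signed_rank",
) -> StrengthComparison:
    """Classify matched regions by score ratio and test the paired scores.

    class = a_stronger iff score_a/score_b >= ratio_threshold,
    b_stronger iff <= 1/ratio_threshold, else similar. The default test
    is the two-sided Wilcoxon signed-rank on the (deduplicated)
    max-overlap pairs; ``test='mann_whitney'`` gives the unpaired
    rank-sum variant.
    """
    if ratio_threshold < 1:
        raise ValueError("ratio_threshold must be >= 1")
    if any(p.score_a <= 0 or p.score_b <= 0 for p in pairs):
        raise ValueError("scores must be positive enrichment values")
    classified = []
    for p in pairs:
        ratio = p.score_a / p.score_b
        if ratio >= ratio_threshold:
            cls = "a_stronger"
        elif ratio <= 1.0 / ratio_threshold:
            cls = "b_stronger"
        else:
            cls = "similar"
        classified.append(replace(p, strength_class=cls))
    unique = _dedupe_max_overlap(classified)
    a = np.array([p.score_a for p in unique])
    b = np.array([p.score_b for p in unique])
    if len(unique) == 0:
        pval = 1.0
    elif test == "signed_rank":
        if np.all(a == b):
            pval = 1.0
        else:
            pval = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    elif test == "mann_whitney":
        _, pval = mann_whitney(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return StrengthComparison(
        pairs=classified,
        n_a_stronger=sum(p.strength_class == "a_stronger" for p in classified),
        n_b_stronger=sum(p.strength_class == "b_stronger" for p in classified),
        n_similar=sum(p.strength_class == "similar" for p in classified),
        test=test,
        n_tested=len(unique),
        p_value=pval,
    )


def _exact_mannwhitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating group assignments.

    Midranks handle ties; the p-value is the probability of a U at
    least as far from its null mean as observed.
    """
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n_x = len(x)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mu = n_x * (n - n_x) / 2.0
    u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n_x):
        u = ranks[list(idx)].sum() - n_x * (n_x + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = EXACT_MAX_N
) -> tuple[float, float]:
    """(U, two-sided p); exact enumeration when n_x + n_y <= exact_max_n."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)
    if len(x) + len(y) <= exact_max_n:
        return u, _exact_mannwhitney_p(x, y)
    if np.unique(np.concatenate([x, y])).size == 1:
        return u, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


DEFAULT_COPY_BINS: tuple[tuple[int, int | None], ...] = ((0, 0), (1, 1), (2, 3), (4, None))


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f"{lo}+"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


@dataclass
class CopyNumberStrata:
    motif: str
    bin_labels: list[str]
    bin_sizes: dict[str, int]
    median_diff: dict[str, float]
    diffs: dict[str, np.ndarray]
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bin_labels,
                "n": [self.bin_sizes[b] for b in self.bin_labels],
                "median_score_diff": [self.median_diff.get(b, float("nan")) for b in self.bin_labels],
            }
        )


def stratify_by_copy_number(
    pairs: Sequence[MatchedRegionPair],
    profiles: Mapping[str, PeakMotifProfile] | Sequence[PeakMotifProfile],
    motif_name: str = "shortHelper",
    bins: Sequence[tuple[int, int | None]] = DEFAULT_COPY_BINS,
) -> CopyNumberStrata:
    """Score differences (a - b) stratified by motif copy number in peak_a.

    Per-bin medians and between-bin rank-sum p-values; empty bins are
    reported with size 0 and excluded from testing.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.peak_id: p for p in profiles}
    unique = _dedupe_max_overlap(list(pairs))
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    diffs: dict[str, list[float]] = {lab: [] for lab in labels}
    for pair in unique:
        prof = profiles.get(pair.peak_a.peak_id)
        if prof is None:
            raise KeyError(f"no motif profile for peak {pair.peak_a.peak_id}")
        count = prof.counts.get(motif_name, 0)
        for (lo, hi), lab in zip(bins, labels):
            if count >= lo and (hi is None or count <= hi):
                diffs[lab].append(pair.score_a - pair.score_b)
                break
    arr = {lab: np.array(v) for lab, v in diffs.items()}
    strata = CopyNumberStrata(
        motif=motif_name,
        bin_labels=labels,
        bin_sizes={lab: len(v) for lab, v in arr.items()},
        median_diff={lab: float(np.median(v)) for lab, v in arr.items() if len(v)},
        diffs=arr,
    )
    for l1, l2 in combinations(labels, 2):
        if len(arr[l1]) and len(arr[l2]):
            _, p = mann_whitney(arr[l1], arr[l2])
            strata.pairwise_p[(l1, l2)] = p
    return strata


def motif_center_profile(
    hits: Sequence[MotifHit],
    peaks: Mapping[str, Peak] | Sequence[Peak],
    motif_length: int,
    window: int = 2000,
    bin_width: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of motif-center offsets from peak centers.

    offset = (peak.start + hit.start + floor(m/2)) - floor((start+end)/2),
    binned over [-window/2, window/2). Returns (bin_edges, counts).
    """
    if not isinstance(peaks, Mapping):
        peaks = {p.peak_id: p for p in peaks}
    offsets = []
    for h in hits:
        if h.peak_id is None or h.peak_id not in peaks:
            continue
        peak = peaks[h.peak_id]
        offsets.append(peak.start + h.start + motif_length // 2 - peak.center)
    edges = np.arange(-window // 2, window // 2 + bin_width, bin_width)
    counts, _ = np.histogram(offsets, bins=edges)
    return edges, counts


def spacing_orientation(
    hits_by_peak: Mapping[str, Sequence[MotifHit]],
    wre_name: str = "WRE",
    helper_name: str = "Helper",
    wre_length: int = 8,
    helper_length: int = 6,
) -> list[SpacingRecord]:
    """All (WRE hit, Helper hit) pairs per peak with signed edge gaps.

    The gap is measured edge-to-edge and signed relative to the WRE
    hit's strand: positive when the Helper lies on the WRE's 3' side.
    Overlapping motif pairs get negative gaps computed from the same
    edges. Orientation is ``same`` when strands agree.
    """
    records: list[SpacingRecord] = []
    for peak_id in sorted(hits_by_peak):
        hits = hits_by_peak[peak_id]
        wre_hits = [h for h in hits if h.motif_name == wre_name]
        helper_hits = [h for h in hits if h.motif_name == helper_name]
        for w in wre_hits:
            w_start, w_end = w.start, w.start + wre_length
            for h in helper_hits:
                h_start, h_end = h.start, h.start + helper_length
                if h_start + h_end >= w_start + w_end:  # Helper center at/right of WRE center
                    gap = h_start - w_end
                else:
                    gap = -(w_start - h_end)
                if w.strand == "-":
                    gap = -gap
                orientation = "same" if w.strand == h.strand else "opposite"
                records.append(SpacingRecord(peak_id, w, h, gap, orientation))
    return records


def spacing_summary(records: Sequence[SpacingRecord]) -> pd.DataFrame:
    """Gap x orientation count table (long format)."""
    if not records:
        return pd.DataFrame(columns=["signed_gap", "orientation", "count"])
    df = pd.DataFrame(
        {
            "signed_gap": [r.signed_gap for r in records],
            "orientation": [r.relative_orientation for r in records],
        }
    )
    out = df.value_counts(["signed_gap", "orientation"]).reset_index(name="count")
    return out.sort_values(["signed_gap", "orientation"]).reset_index(drop=True)


@dataclass
class IncidenceComparison:
    motif: str
    mean_a: float
    mean_b: float
    p_value: float
    n_a: int
    n_b: int


def compare_incidence(
    profiles_a: Sequence[PeakMotifProfile],
    profiles_b: Sequence[PeakMotifProfile],
    motif_name: str,
) -> IncidenceComparison:
    """Two-sided rank-sum comparison of per-peak motif incidence."""
    if not profiles_a or not profiles_b:
        raise ValueError("both profile sets must be nonempty")
    inc_a = np.array([p.incidence.get(motif_name, 0.0) for p in profiles_a])
    inc_b = np.array([p.incidence.get(motif_name, 0.0) for p in profiles_b])
    _, p = mann_whitney(inc_a, inc_b)
    return IncidenceComparison(motif_name, float(inc_a.mean()), float(inc_b.mean()), p, len(inc_a), len(inc_b))


def fraction_with_motif(
    profiles: Sequence[PeakMotifProfile],
    motif_name: str,
    min_count: int = 1,
) -> float:
    """Proportion of peaks with at least ``min_count`` motif occurrences."""
    if not profiles:
        raise ValueError("profile set must be nonempty")
    return sum(p.counts.get(motif_name, 0) >= min_count for p in profiles) / len(profiles)
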