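"""Background sequence model for WRE/Helper co-occurrence statistics.

For each peak of length L, the chance that a degenerate motif of length
m occurs at a given position under an i.i.d. nucleotide background is
the product over pattern positions of the summed background frequencies
of the admitted bases. Treating the 2*(L - m + 1) strand-windows as
independent Bernoulli trials gives a binomial model for the number of
occurrences per peak, and hence the probability that a peak contains at
least N copies. Summing the per-peak joint probabilities

    q_i = P(>=1 WRE in peak i) * P(>=N Helper in peak i)

yields the expected number of peaks containing both elements, and the
exact Poisson-binomial upper tail of the observed count gives the
p-value. Window overlap dependence is ignored (a documented
approximation validated by Monte Carlo in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import DegenerateMotif, PeakMotifProfile

__all__ = [
    "BackgroundModel",
    "CooccurrenceRow",
    "position_match_probability",
    "containment_probability",
    "poisson_binomial_sf",
    "cooccurrence_table",
    "cooccurrence_frame",
]


@dataclass
class BackgroundModel:
    """Per-base background frequencies (A, C, G, T)."""

    frequencies: dict[str, float]
    source: str = "user"

    def __post_init__(self) -> None:
        missing = set("ACGT") - set(self.frequencies)
        if missing:
            raise ValueError(f"background missing frequencies for {sorted(missing)}")
        vals = np.array([self.frequencies[b] for b in "ACGT"], dtype=float)
        if (vals < 0).any():
            raise ValueError("background frequencies must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1 within 1e-9")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls({b: 0.25 for b in "ACGT"}, source="uniform")

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "BackgroundModel":
        """GC-content-aware background estimated from the analysed peak set."""
        counts = {b: 0 for b in "ACGT"}
        for seq in sequences:
            for base in "ACGT":
                counts[base] += seq.upper().count(base)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no A/C/G/T bases in the given sequences")
        return cls({b: counts[b] / total for b in "ACGT"}, source="peak_set")


def position_match_probability(motif: DegenerateMotif, background: BackgroundModel) -> float:
    """Probability a background window matches the motif at one position."""
    p = 1.0
    for i in range(motif.length):
        p *= sum(background.frequencies[b] for b in motif.admitted(i))
    return p


def containment_probability(
    L: int,
    motif: DegenerateMotif,
    n_min: int = 1,
    background: BackgroundModel | None = None,
) -> float:
    """P(peak of length L contains >= n_min motif occurrences).

    X ~ Binomial(n = 2*(L - m + 1), p = position match probability);
    window independence is assumed. Peaks shorter than the motif return
    0 with a warning.
    """
    if background is None:
        background = BackgroundModel.uniform()
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    if L < motif.length:
        warnings.warn(f"peak length {L} shorter than motif {motif.name}; containment = 0")
        return 0.0
    n = 2 * (L - motif.length + 1)
    p = position_match_probability(motif, background)
    return float(stats.binom.sf(n_min - 1, n, p))


def poisson_binomial_sf(probabilities: Sequence[float], threshold: int) -> float:
    """Exact P(X >= threshold) for X a sum of independent Bernoulli(q_i).

    O(K^2) convolution dynamic programme; the running distribution is
    clipped to [0, 1] after each step for numerical stability.
    """
    q = np.asarray(probabilities, dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("all probabilities must lie in [0, 1]")
    if threshold <= 0:
        return 1.0
    K = q.size
    if threshold > K:
        return 0.0
    dist = np.zeros(K + 1)
    dist[0] = 1.0
    for qi in q:
        dist[1:] = dist[1:] * (1.0 - qi) + dist[:-1] * qi
        dist[0] *= 1.0 - qi
        np.clip(dist, 0.0, 1.0, out=dist)
    return float(dist[threshold:].sum())


@dataclass
class CooccurrenceRow:
    """One row of the observed/expected co-occurrence table."""

    condition_label: str
    n_peaks_with_wre: int
    helper_threshold: int
    n_peaks_with_n_helpers: int
    expected_both: float
    observed_both: int
    p_value: float

    def __post_init__(self) -> None:
        if self.observed_both > min(self.n_peaks_with_wre, self.n_peaks_with_n_helpers):
            raise ValueError("observed_both exceeds its marginal counts")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def cooccurrence_table(
    peak_profiles: Sequence[PeakMotifProfile],
    background: BackgroundModel,
    wre: DegenerateMotif,
    helper: DegenerateMotif,
    n_values: Iterable[int] = range(1, 6),
    condition_label: str = "",
    method: str = "poisson_binomial",
) -> list[CooccurrenceRow]:
    """Observed vs expected number of peaks with >=1 WRE and >=N Helpers.

    ``method='poisson_binomial'`` computes the exact tail over the
    per-peak joint probabilities; ``method='binomial'`` uses a binomial
    tail on the mean per-peak probability (fixed-representative-length
    style approximation).
    """
    if not peak_profiles:
        raise ValueError("empty peak set")
    if method not in {"poisson_binomial", "binomial"}:
        raise ValueError(f"unknown method {method!r}")
    lengths = np.array([p.length for p in peak_profiles])
    wre_counts = np.array([p.counts.get(wre.name, 0) for p in peak_profiles])
    helper_counts = np.array([p.counts.get(helper.name, 0) for p in peak_profiles])
    # memoise per distinct length: fixtures often share peak lengths
    uniq = np.unique(lengths)
    p_wre = {int(L): containment_probability(int(L), wre, 1, background) for L in uniq}
    rows = []
    n_with_wre = int((wre_counts >= 1).sum())
    for N in n_values:
        p_helper = {int(L): containment_probability(int(L), helper, N, background) for L in uniq}
        q = np.array([p_wre[int(L)] * p_helper[int(L)] for L in lengths])
        expected = float(q.sum())
        observed = int(((wre_counts >= 1) & (helper_counts >= N)).sum())
        if method == "poisson_binomial":
            p_value = poisson_binomial_sf(q, observed)
        else:
            p_value = float(stats.binom.sf(observed - 1, q.size, q.mean()))
        rows.append(
            CooccurrenceRow(
                condition_label=condition_label,
                n_peaks_with_wre=n_with_wre,
                helper_threshold=int(N),
                n_peaks_with_n_helpers=int((helper_counts >= N).sum()),
                expected_both=expected,
                observed_both=observed,
                p_value=p_value,
            )
        )
    return rows


def cooccurrence_frame(rows: Sequence[CooccurrenceRow]) -> pd.DataFrame:
    """TSV-ready frame mirroring the seven-column observed/expected table."""
    return pd.DataFrame(
        {
            "condition": [r.condition_label for r in rows],
            "n_peaks_with_wre": [r.n_peaks_with_wre for r in rows],
            "helper_threshold": [r.helper_threshold for r in rows],
            "n_peaks_with_n_helpers": [r.n_peaks_with_n_helpers for r in rows],
            "expected_both": [r.expected_both for r in rows],
            "observed_both": [r.observed_both for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
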