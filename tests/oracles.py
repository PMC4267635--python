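"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reusing the package's
implementation paths: the scanner oracle matches windows symbol by
symbol, the rank-test oracles enumerate label assignments or sign
flips directly, and the tail-probability oracles enumerate outcomes.
"""

from __future__ import annotations

from itertools import combinations, product
from math import comb

# An independent IUPAC table (do not import from the package).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def window_matches(window: str, pattern: str) -> bool:
    if len(window) != len(pattern):
        return False
    for base, sym in zip(window, pattern):
        if base == "N" or base not in "ACGT":
            return False
        if base not in IUPAC[sym]:
            return False
    return True


def naive_hits(sequence: str, pattern: str) -> list[tuple[int, str]]:
    """(start, strand) of every overlapping occurrence on both strands."""
    m = len(pattern)
    rc = revcomp(pattern)
    hits = []
    for i in range(len(sequence) - m + 1):
        window = sequence[i : i + m]
        if window_matches(window, pattern):
            hits.append((i, "+"))
        if window_matches(window, rc):
            hits.append((i, "-"))
    return sorted(hits)


def enum_poisson_binomial_sf(probs: list[float], t: int) -> float:
    """P(X >= t) by summing over all 2^K outcomes."""
    total = 0.0
    for outcome in product((0, 1), repeat=len(probs)):
        if sum(outcome) >= t:
            weight = 1.0
            for q, o in zip(probs, outcome):
                weight *= q if o else (1.0 - q)
            total += weight
    return total


def _pairwise_u(x_vals: list[float], y_vals: list[float]) -> float:
    """U statistic by direct pairwise comparison (ties count half)."""
    u = 0.0
    for xv in x_vals:
        for yv in y_vals:
            if xv > yv:
                u += 1.0
            elif xv == yv:
                u += 0.5
    return u


def enum_mannwhitney_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact p: fraction of label assignments with U at least
    as far from its null mean as observed."""
    pooled = list(x) + list(y)
    n, n_x = len(pooled), len(x)
    mu = n_x * (n - n_x) / 2.0
    u_obs = _pairwise_u(list(x), list(y))
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n_x):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(_pairwise_u(chosen, rest) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def enum_signrank_p(a: list[float], b: list[float]) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all sign
    flips of the (assumed nonzero, tie-free) paired differences."""
    diffs = [ai - bi for ai, bi in zip(a, b)]
    assert all(d != 0 for d in diffs)
    mags = sorted(abs(d) for d in diffs)
    assert len(set(mags)) == len(mags), "oracle assumes tie-free magnitudes"
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    n = len(diffs)
    mu = n * (n + 1) / 4.0
    w_obs = sum(ranks[abs(d)] for d in diffs if d > 0)
    dev = abs(w_obs - mu)
    hits = 0
    for signs in product((1, -1), repeat=n):
        w = sum(ranks[abs(d)] for d, s in zip(diffs, signs) if s > 0)
        if abs(w - mu) >= dev - 1e-9:
            hits += 1
    return hits / 2 ** n


def enum_hypergeom_sf(universe: int, n_a: int, n_b: int, observed: int) -> float:
    """P(overlap >= observed) by summing the hypergeometric pmf terms
    built from binomial coefficients."""
    total = comb(universe, n_b)
    acc = 0
    for j in range(observed, min(n_a, n_b) + 1):
        acc += comb(n_a, j) * comb(universe - n_a, n_b - j)
    return acc / total


def enum_gsea(ranked: list[str], k: int) -> list[tuple[frozenset, float]]:
    """(subset, ES) for every k-subset, with an independently coded
    running sum."""
    out = []
    n = len(ranked)
    for idx in combinations(range(n), k):
        chosen = frozenset(ranked[i] for i in idx)
        run = best = 0.0
        for gene in ranked:
            run += 1.0 / k if gene in chosen else -1.0 / (n - k)
            if abs(run) > abs(best):
                best = run
        out.append((chosen, best))
    return out
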