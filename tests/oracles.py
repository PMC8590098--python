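"""Brute-force reference procedures, independent of the package internals.

Each oracle restates a definition in its most literal form (enumeration,
all-pairs scans, explicit step procedures) so the vectorised or library
-backed implementations can be checked against first principles.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the literal step-up walk."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, pvals[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def holm_stepdown(pvals: list[float]) -> list[float]:
    """Holm adjusted p-values by the literal step-down walk."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_max = 0.0
    for rank, i in enumerate(order):
        value = min(1.0, (m - rank) * pvals[i])
        running_max = max(running_max, value)
        adjusted[i] = running_max
    return adjusted


def hypergeom_tails(k: int, big_k: int, m: int, big_n: int) -> tuple[float, float]:
    """(P[X >= k], P[X <= k]) for X ~ Hypergeom(N=big_n, m successes, K draws)."""
    denom = math.comb(big_n, big_k)
    lo = max(0, big_k - (big_n - m))
    hi = min(big_k, m)
    pmf = {
        x: math.comb(m, x) * math.comb(big_n - m, big_k - x) / denom
        for x in range(lo, hi + 1)
    }
    over = sum(p for x, p in pmf.items() if x >= k)
    under = sum(p for x, p in pmf.items() if x <= k)
    return over, under


def knn_impute_bruteforce(values: np.ndarray, k: int) -> np.ndarray:
    """All-pairs KNN imputation over locus rows with NaN-aware distances.

    Distance between locus rows u, v: sqrt(n_samples / n_valid *
    sum over mutually observed samples of (u - v)^2).  Each missing entry
    is the uniform mean of the k nearest donor loci observed in that
    sample.
    """
    out = values.copy()
    n_loci, n_samples = values.shape
    dist = np.full((n_loci, n_loci), np.nan)
    for i in range(n_loci):
        for j in range(n_loci):
            both = ~np.isnan(values[i]) & ~np.isnan(values[j])
            if both.sum() == 0:
                continue
            d2 = np.sum((values[i, both] - values[j, both]) ** 2)
            dist[i, j] = math.sqrt(d2 * n_samples / both.sum())
    for i in range(n_loci):
        for j in range(n_samples):
            if not np.isnan(values[i, j]):
                continue
            donors = [
                (dist[i, l], l)
                for l in range(n_loci)
                if l != i and not np.isnan(values[l, j]) and not np.isnan(dist[i, l])
            ]
            donors.sort()
            chosen = [l for _, l in donors[:k]]
            out[i, j] = np.mean([values[l, j] for l in chosen])
    return out


def exclusive_overlap_counts(locus_sets: list[set]) -> dict[tuple[bool, ...], int]:
    """Count loci belonging to exactly each nonempty subset of the sets."""
    union = set().union(*locus_sets)
    counts: dict[tuple[bool, ...], int] = {}
    for locus in union:
        pattern = tuple(locus in s for s in locus_sets)
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def point_in_intervals_scan(
    chrom: str, pos: int, intervals: list[tuple[str, int, int]]
) -> bool:
    """Literal all-pairs membership scan, half-open [start, end)."""
    return any(c == chrom and s <= pos < e for c, s, e in intervals)
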