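"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, O(n*m) dynamic
programming, sliding windows) and shares no code with the library paths it
verifies.
"""

from __future__ import annotations

import itertools
from collections import Counter
from math import comb


def naive_scan(seq: str, kmer: str) -> list[int]:
    """Sliding-window exact match, overlapping occurrences included."""
    k = len(kmer)
    return [i for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer]


def gotoh_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Optimal global affine-gap alignment score; a length-L gap costs
    gap_open + L*gap_extend."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend, X[i - 1][j] + gap_extend
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend, Y[i][j - 1] + gap_extend
            )
    return max(M[n][m], X[n][m], Y[n][m])


def walk_conserved(aligned_ref: str, aligned_orth: str, pos_ref: int, kmer: str) -> bool:
    """Re-derive the homologous window by walking the alignment column by column."""
    k = len(kmer)
    start_col = None
    end_col = None
    residue = -1
    for col in range(len(aligned_ref)):
        if aligned_ref[col] != "-":
            residue += 1
            if residue == pos_ref:
                start_col = col
            if residue == pos_ref + k - 1:
                end_col = col
    assert start_col is not None and end_col is not None
    window_ref = aligned_ref[start_col : end_col + 1]
    window_orth = aligned_orth[start_col : end_col + 1]
    if "-" in window_ref or "-" in window_orth:
        return False
    return window_ref == kmer and window_orth == kmer


def dinucleotide_permutations(s: str) -> set[str]:
    """All letter permutations of s preserving the dinucleotide multiset
    (brute force over multiset permutations)."""
    target = Counter(s[i : i + 2] for i in range(len(s) - 1))
    out: set[str] = set()
    for perm in set(itertools.permutations(s)):
        cand = "".join(perm)
        if Counter(cand[i : i + 2] for i in range(len(cand) - 1)) == target:
            out.add(cand)
    return out


def exact_mannwhitney_p(x: list[float], y: list[float]) -> float:
    """Exact two-sided Mann-Whitney p-value by enumerating all group
    assignments of the pooled (tie-free) values."""
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)

    def u_of(group: tuple[float, ...]) -> float:
        other = list(pooled)
        for v in group:
            other.remove(v)
        return sum(1 for xi in group for yj in other if xi > yj)

    mu = n1 * (len(y)) / 2
    observed = abs(u_of(tuple(x)) - mu)
    total = 0
    extreme = 0
    for combo in itertools.combinations(pooled, n1):
        total += 1
        if abs(u_of(combo) - mu) >= observed - 1e-12:
            extreme += 1
    return extreme / total


def kmer_unique_counts(junctions: list[str], k: int = 50) -> dict[str, int]:
    """Brute-force dictionary of all contained k-mers with occurrence totals."""
    d: Counter = Counter()
    for j in junctions:
        for i in range(len(j) - k + 1):
            d[j[i : i + k]] += 1
    return dict(d)
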