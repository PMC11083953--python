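"""Independent brute-force oracles used to cross-check the implementation.

These are written as plain top-down recursions and single-pass counters,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import sys
from collections import Counter
from functools import lru_cache

sys.setrecursionlimit(100000)


def fitting_alignment_score(
    ref: str, query: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2
) -> int:
    """Optimal fitting-alignment score by memoized recursion: the reference
    is consumed end to end, query prefix/suffix are free, affine gaps."""
    m, n = len(ref), len(query)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # i ref chars and j query chars remain; state: 0 free/diag, 1 gap in
        # ref open, 2 gap in query open
        if i == 0:
            return 0.0  # remaining query is a free overhang
        options = []
        if j > 0:
            s = match if ref[-i] == query[-j] and ref[-i] != "N" else mismatch
            options.append(s + best(i - 1, j - 1, 0))
            cost = gap_extend if state == 1 else gap_open + gap_extend
            options.append(cost + best(i, j - 1, 1))
        cost = gap_extend if state == 2 else gap_open + gap_extend
        options.append(cost + best(i - 1, j, 2))
        return max(options)

    result = max(best(m, n - j, 0) for j in range(n + 1))
    best.cache_clear()
    return int(result)


def rescore_alignment(
    pairs, ref: str, query: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2
) -> int:
    """Score an aligned_pairs column list independently."""
    score = 0
    prev_gap = None  # which side the open gap run is on
    for q, r in pairs:
        if q is not None and r is not None:
            score += match if query[q] == ref[r] and ref[r] != "N" else mismatch
            prev_gap = None
        else:
            side = "q" if r is None else "r"
            score += gap_extend if prev_gap == side else gap_open + gap_extend
            prev_gap = side
    return score


def merge_best_offset(r1: str, rc2: str, min_overlap: int):
    """Best overlap by literal per-offset scanning; returns
    (overlap, matches, score) or None."""
    best = None
    for ov in range(min_overlap, min(len(r1), len(rc2)) + 1):
        matches = 0
        for a, b in zip(r1[len(r1) - ov :], rc2[:ov]):
            if a == b:
                matches += 1
        score = matches - (ov - matches)
        if best is None or score > best[2] or (score == best[2] and ov > best[0]):
            best = (ov, matches, score)
    return best


def redundancy_counts(keys: list[str]) -> dict[str, float]:
    mult = Counter(keys)
    out: dict[str, float] = {}
    for k in keys:
        b = str(mult[k]) if mult[k] < 10 else "10+"
        out[b] = out.get(b, 0.0) + 1
    return {b: 100.0 * c / len(keys) for b, c in out.items()}


def pairing_fractions(calls: list[tuple[str, str]]) -> dict[tuple[str, str], float]:
    counts = Counter(c for c in calls if c[0] and c[1])
    total = sum(counts.values())
    return {pair: n / total for pair, n in counts.items()}


def column_compositions(columns: dict[str, list[str]]) -> dict[str, dict[str, float]]:
    out = {}
    for label, residues in columns.items():
        if residues:
            c = Counter(residues)
            out[label] = {aa: n / len(residues) for aa, n in c.items()}
    return out


def wu_kabat(residues: list[str]) -> float:
    c = Counter(residues)
    return len(c) / (max(c.values()) / len(residues))
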