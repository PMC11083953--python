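"""Semi-global (fitting) nucleotide alignment with affine gaps.

The reference is aligned end to end; query overhangs outside the reference
are free.  Scoring defaults: match +2, mismatch -3, gap open -5, gap extend
-2 (a gap of length k costs 5 + 2k).  Ties are broken deterministically:
the traceback prefers substitution columns over gap columns (fewer gaps),
and among equal-scoring end points the smallest query end is taken, which
pushes the alignment toward the leftmost start.

The dynamic program is a standard three-state Gotoh recursion, JIT-compiled
with numba; callers ranking many references use the score-only variant and
run the full traceback for the winner only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG = -(10**9)


def encode_nt(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class AlignmentResult:
    """An alignment of a query against one reference.

    ``aligned_pairs`` lists (query index | None, reference index | None)
    per column, monotone in both coordinates; ``identity`` is matches over
    aligned columns (gap columns included).
    """

    score: int
    aligned_pairs: list[tuple[int | None, int | None]]
    identity: float
    reference_name: str = ""
    query_start: int = 0
    query_end: int = 0  # exclusive
    ref_start: int = 0
    ref_end: int = 0  # exclusive
    n_gap_columns: int = 0

    def query_to_ref(self) -> dict[int, int]:
        return {q: r for q, r in self.aligned_pairs if q is not None and r is not None}

    def ref_to_query(self) -> dict[int, int]:
        return {r: q for q, r in self.aligned_pairs if q is not None and r is not None}


@njit(cache=True)
def _fill_score(t, q, match, mismatch, go, ge):
    """Best fitting-alignment score (reference t consumed fully)."""
    m = t.shape[0]
    n = q.shape[0]
    neg = -(10**9)
    h_prev = np.empty(n + 1, dtype=np.int64)
    e_prev = np.empty(n + 1, dtype=np.int64)
    f_prev = np.empty(n + 1, dtype=np.int64)
    for j in range(n + 1):
        h_prev[j] = 0  # free query prefix
        e_prev[j] = neg
        f_prev[j] = neg
    h_cur = np.empty(n + 1, dtype=np.int64)
    e_cur = np.empty(n + 1, dtype=np.int64)
    f_cur = np.empty(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        h_cur[0] = neg
        e_cur[0] = neg
        # gap in query (reference consumed with no query)
        fp = f_prev[0] if i > 1 else neg
        hp = h_prev[0]
        f_cur[0] = max(fp + ge, hp + go + ge)
        for j in range(1, n + 1):
            diag = max(h_prev[j - 1], max(e_prev[j - 1], f_prev[j - 1]))
            s = match if (t[i - 1] == q[j - 1] and t[i - 1] != 78) else mismatch
            h_cur[j] = diag + s
            best_up = max(h_prev[j], e_prev[j])
            f_cur[j] = max(f_prev[j] + ge, best_up + go + ge)
            best_left = max(h_cur[j - 1], f_cur[j - 1])
            e_cur[j] = max(e_cur[j - 1] + ge, best_left + go + ge)
        h_prev, h_cur = h_cur, h_prev
        e_prev, e_cur = e_cur, e_prev
        f_prev, f_cur = f_cur, f_prev
    best = neg
    for j in range(n + 1):
        v = max(h_prev[j], max(e_prev[j], f_prev[j]))
        if v > best:
            best = v
    return best


@njit(cache=True)
def _fill_full(t, q, match, mismatch, go, ge):
    m = t.shape[0]
    n = q.shape[0]
    neg = -(10**9)
    H = np.full((m + 1, n + 1), neg, dtype=np.int64)
    E = np.full((m + 1, n + 1), neg, dtype=np.int64)
    F = np.full((m + 1, n + 1), neg, dtype=np.int64)
    for j in range(n + 1):
        H[0, j] = 0
    for i in range(1, m + 1):
        F[i, 0] = (H[i - 1, 0] + go + ge) if i == 1 else (F[i - 1, 0] + ge)
        for j in range(1, n + 1):
            diag = max(H[i - 1, j - 1], max(E[i - 1, j - 1], F[i - 1, j - 1]))
            s = match if (t[i - 1] == q[j - 1] and t[i - 1] != 78) else mismatch
            H[i, j] = diag + s
            best_up = max(H[i - 1, j], E[i - 1, j])
            F[i, j] = max(F[i - 1, j] + ge, best_up + go + ge)
            best_left = max(H[i, j - 1], F[i, j - 1])
            E[i, j] = max(E[i, j - 1] + ge, best_left + go + ge)
    return H, E, F


def align_semiglobal(
    query_nt: str,
    reference_nt: str,
    scoring: Scoring | None = None,
    reference_name: str = "",
) -> AlignmentResult:
    """Optimal fitting alignment of ``reference_nt`` inside ``query_nt``.

    Raises ``ValueError`` on an empty query or reference.
    """
    if not query_nt:
        raise ValueError("empty query")
    if not reference_nt:
        raise ValueError("empty reference")
    sc = scoring or Scoring()
    t = encode_nt(reference_nt)
    q = encode_nt(query_nt)
    H, E, F = _fill_full(t, q, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
    m, n = len(t), len(q)
    # termination: reference fully consumed, free query suffix; smallest query
    # end among score ties (leftmost alignment)
    best = NEG
    j_end = 0
    for j in range(n + 1):
        v = max(H[m, j], E[m, j], F[m, j])
        if v > best:
            best = v
            j_end = j
    pairs_rev: list[tuple[int | None, int | None]] = []
    i, j = m, j_end
    # state preference at equal score: H (diagonal) first -> fewer gap columns
    if H[i, j] == best:
        state = 0
    elif F[i, j] == best:
        state = 2
    else:
        state = 1
    sc_open = sc.gap_open + sc.gap_extend
    while i > 0:
        if state == 0:  # H: substitution column
            pairs_rev.append((j - 1, i - 1))
            val = H[i, j]
            s = sc.match if (t[i - 1] == q[j - 1] and t[i - 1] != 78) else sc.mismatch
            target = val - s
            i -= 1
            j -= 1
            if i == 0:
                break
            if H[i, j] == target:
                state = 0
            elif F[i, j] == target:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: gap in reference (consumes query)
            pairs_rev.append((j - 1, None))
            val = E[i, j]
            j -= 1
            if H[i, j] + sc_open == val:
                state = 0
            elif F[i, j] + sc_open == val:
                state = 2
            else:
                state = 1
        else:  # F: gap in query (consumes reference)
            pairs_rev.append((None, i - 1))
            val = F[i, j]
            i -= 1
            if i == 0:
                break
            if H[i, j] + sc_open == val:
                state = 0
            elif E[i, j] + sc_open == val:
                state = 1
            else:
                state = 2
    pairs = pairs_rev[::-1]
    matches = sum(
        1
        for qq, rr in pairs
        if qq is not None and rr is not None and q[qq] == t[rr] and t[rr] != 78
    )
    n_gap = sum(1 for qq, rr in pairs if qq is None or rr is None)
    identity = matches / len(pairs) if pairs else 0.0
    q_idx = [qq for qq, _ in pairs if qq is not None]
    r_idx = [rr for _, rr in pairs if rr is not None]
    return AlignmentResult(
        score=int(best),
        aligned_pairs=pairs,
        identity=identity,
        reference_name=reference_name,
        query_start=q_idx[0] if q_idx else 0,
        query_end=(q_idx[-1] + 1) if q_idx else 0,
        ref_start=r_idx[0] if r_idx else 0,
        ref_end=(r_idx[-1] + 1) if r_idx else 0,
        n_gap_columns=n_gap,
    )


def score_semiglobal(query_nt: str, reference_nt: str, scoring: Scoring | None = None) -> int:
    """Score-only variant of :func:`align_semiglobal` (rolling rows)."""
    if not query_nt:
        raise ValueError("empty query")
    if not reference_nt:
        raise ValueError("empty reference")
    sc = scoring or Scoring()
    return int(
        _fill_score(
            encode_nt(reference_nt),
            encode_nt(query_nt),
            sc.match,
            sc.mismatch,
            sc.gap_open,
            sc.gap_extend,
        )
    )
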