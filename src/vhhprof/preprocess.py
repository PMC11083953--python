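"""Read-pair merging and primer filtering.

Overlapping R1/R2 mates are merged by scanning every overlap offset of at
least ``min_overlap`` bases and keeping the offset maximizing
(matches - mismatches); the merge succeeds when the best offset's mismatch
fraction is at most ``max_mismatch_frac``.  Within the overlap each position
takes the base of the read with the higher Phred quality (ties go to R1,
with the maximum of the two qualities).  Merged sequences are then kept only
when both amplification primers — the Sfi I-containing motifs used to clone
the VHH genes — are found near the ends, in either strand orientation; the
output is normalized to the forward strand with primer bases retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .align import encode_nt
from .records import SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Sfi I-containing cloning primer motifs
SFI_FORWARD = "GGCCCAGGCGGCC"
SFI_REVERSE = "GGCCAGGCCGGCC"


def reverse_complement(nucleotides: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    bad = set(nucleotides) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid bases for reverse complement: {sorted(bad)}")
    return nucleotides.translate(_COMPLEMENT)[::-1]


@dataclass
class PrimerSpec:
    forward: str = SFI_FORWARD
    reverse: str = SFI_REVERSE
    max_mismatches: int = 1
    search_window: int = 60  # motif must sit within this many nt of either end

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primer motifs must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class MergeResult:
    status: str  # merged | no_overlap | too_many_mismatches
    merged: SequenceRecord | None = None
    overlap_length: int = 0
    mismatches_in_overlap: int = 0


def merge_pair(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergeResult:
    """Merge an R1/R2 pair; R2 is reverse-complemented before the overlap scan.

    Failures are statuses, never exceptions.
    """
    fwd2 = reverse_complement(r2.nucleotides)
    q2 = list(reversed(r2.qualities)) if r2.qualities is not None else [0] * len(r2)
    q1 = r1.qualities if r1.qualities is not None else [0] * len(r1)
    a = encode_nt(r1.nucleotides).astype(np.int16)
    b = encode_nt(fwd2).astype(np.int16)
    l1, l2 = len(a), len(b)
    max_ov = min(l1, l2)
    if max_ov < min_overlap:
        return MergeResult("no_overlap")
    best_score = None
    best_ov = 0
    best_matches = 0
    # overlap of length ov: r1 suffix vs reverse-complemented r2 prefix
    for ov in range(min_overlap, max_ov + 1):
        matches = int(np.count_nonzero(a[l1 - ov :] == b[:ov]))
        score = 2 * matches - ov
        if best_score is None or score > best_score or (
            score == best_score and ov > best_ov
        ):
            best_score, best_ov, best_matches = score, ov, matches
    mismatches = best_ov - best_matches
    if mismatches / best_ov > max_mismatch_frac:
        return MergeResult(
            "too_many_mismatches", overlap_length=best_ov, mismatches_in_overlap=mismatches
        )
    ov = best_ov
    prefix = r1.nucleotides[: l1 - ov]
    suffix = fwd2[ov:]
    mid_nt = []
    mid_q = []
    for k in range(ov):
        b1, b2 = r1.nucleotides[l1 - ov + k], fwd2[k]
        s1, s2 = q1[l1 - ov + k], q2[k]
        if b1 == b2 or s1 >= s2:
            mid_nt.append(b1)
        else:
            mid_nt.append(b2)
        mid_q.append(max(s1, s2))
    quals = q1[: l1 - ov] + mid_q + q2[ov:]
    merged = SequenceRecord(r1.id, prefix + "".join(mid_nt) + suffix, quals)
    return MergeResult("merged", merged, overlap_length=ov, mismatches_in_overlap=mismatches)


@dataclass
class PrimerHit:
    found: bool
    orientation: str = "as-is"  # or "reverse-complement"
    insert_start: int = 0  # first base of the forward-primer match
    insert_end: int = 0  # one past the last base of the reverse-primer match


def _hamming_find(seq: str, motif: str, lo: int, hi: int, max_mm: int) -> int | None:
    """Leftmost start in [lo, hi) where motif matches with <= max_mm mismatches."""
    k = len(motif)
    best = None
    for start in range(lo, min(hi, len(seq) - k + 1)):
        mm = sum(1 for x, y in zip(seq[start : start + k], motif) if x != y)
        if mm <= max_mm:
            return start
    return best


def locate_primers(seq: str, primers: PrimerSpec) -> PrimerHit:
    """Find the forward motif near the 5' end and the reverse-complemented
    reverse motif near the 3' end, trying both strand orientations."""
    rc_rev = reverse_complement(primers.reverse)
    for orientation, s in (("as-is", seq), ("reverse-complement", reverse_complement(seq))):
        w = primers.search_window
        f = _hamming_find(s, primers.forward, 0, w, primers.max_mismatches)
        if f is None:
            continue
        k = len(rc_rev)
        lo = max(0, len(s) - w)
        # rightmost admissible match of the reverse-primer RC near the 3' end
        r = None
        for start in range(len(s) - k, lo - 1, -1):
            if start <= f:
                break
            mm = sum(1 for x, y in zip(s[start : start + k], rc_rev) if x != y)
            if mm <= primers.max_mismatches:
                r = start
                break
        if r is None:
            continue
        return PrimerHit(True, orientation, f, r + k)
    return PrimerHit(False)


@dataclass
class FunnelCounts:
    total_pairs: int = 0
    merged: int = 0
    primer_pass: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total_pairs": self.total_pairs,
            "merged": self.merged,
            "primer_pass": self.primer_pass,
        }


@dataclass
class PreprocessParams:
    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    primers: PrimerSpec = field(default_factory=PrimerSpec)
    trim_primers: bool = False


def _apply_primer_filter(
    merged: SequenceRecord, params: PreprocessParams
) -> SequenceRecord | None:
    hit = locate_primers(merged.nucleotides, params.primers)
    if not hit.found:
        return None
    seq = merged.nucleotides
    quals = merged.qualities
    if hit.orientation == "reverse-complement":
        seq = reverse_complement(seq)
        quals = list(reversed(quals)) if quals is not None else None
    start, end = hit.insert_start, hit.insert_end
    if params.trim_primers:
        start += len(params.primers.forward)
        end -= len(params.primers.reverse)
    if start >= end:
        return None
    return SequenceRecord(
        merged.id, seq[start:end], quals[start:end] if quals is not None else None
    )


def preprocess_pair(
    r1: SequenceRecord, r2: SequenceRecord, params: PreprocessParams
) -> SequenceRecord | None:
    """Merge one pair and apply the primer filter; None when dropped."""
    res = merge_pair(r1, r2, params.min_overlap, params.max_mismatch_frac)
    if res.status != "merged":
        return None
    assert res.merged is not None
    return _apply_primer_filter(res.merged, params)


def preprocess_pairs(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    params: PreprocessParams | None = None,
    counts: FunnelCounts | None = None,
) -> Iterator[SequenceRecord]:
    """Stream kept, orientation-normalized merged sequences; fills ``counts``.

    The two merge/primer stages are tallied separately so the funnel
    (kept <= merged <= total) can be reported.
    """
    params = params or PreprocessParams()
    counts = counts if counts is not None else FunnelCounts()
    for r1, r2 in pairs:
        counts.total_pairs += 1
        res = merge_pair(r1, r2, params.min_overlap, params.max_mismatch_frac)
        if res.status != "merged":
            continue
        counts.merged += 1
        assert res.merged is not None
        kept = _apply_primer_filter(res.merged, params)
        if kept is None:
            continue
        counts.primer_pass += 1
        yield kept


def pair_streams(
    r1_records: Iterable[SequenceRecord], r2_records: Iterable[SequenceRecord]
) -> Iterator[tuple[SequenceRecord, SequenceRecord]]:
    """Zip two read streams, erroring on unequal lengths."""
    it1, it2 = iter(r1_records), iter(r2_records)
    while True:
        a = next(it1, None)
        b = next(it2, None)
        if a is None and b is None:
            return
        if a is None or b is None:
            raise ValueError("R1 and R2 streams have unequal lengths")
        yield a, b
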