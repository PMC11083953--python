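"""IMGT unique-numbering utilities for VHH domains.

The V domain spans IMGT positions 1-104 (FR1 1-26, CDR1 27-38, FR2 39-55,
CDR2 56-65, FR3 66-104), CDR3 spans 105-117 and FR4 starts at the conserved
Trp/Phe 118.  Position labels are 1-based strings; CDR3 loops longer than 13
residues receive insertion labels between 111 and 112 ("111.1", "112.1", ...)
following the IMGT convention: labels ascend after 111 (111.1, 111.2, ...)
and descend before 112 (..., 112.2, 112.1).
"""

from __future__ import annotations

CDR1_SPAN = tuple(range(27, 39))
CDR2_SPAN = tuple(range(56, 66))
CDR3_SPAN = tuple(range(105, 118))
FR2_TETRAD = (42, 49, 50, 52)
CYS_104 = 104
TRP_118 = 118
V_REGION_END = 104

#: positions whose occupancy defines each region string
REGION_SPANS = {"cdr1": CDR1_SPAN, "cdr2": CDR2_SPAN, "cdr3": CDR3_SPAN}


def parse_label(label: str) -> tuple[int, int]:
    """Split an IMGT label into (base position, insertion index).

    "59" -> (59, 0); "111.2" -> (111, 2).
    """
    if "." in label:
        base, sub = label.split(".", 1)
        return int(base), int(sub)
    return int(label), 0


def format_label(base: int, sub: int = 0) -> str:
    return f"{base}.{sub}" if sub else str(base)


def label_sort_key(label: str) -> tuple[int, int]:
    """Total order over IMGT labels.

    Insertion labels after 111 ascend (111 < 111.1 < 111.2); insertion labels
    before 112 descend (112.2 < 112.1 < 112), so the key flips the insertion
    index sign for bases >= 112.
    """
    base, sub = parse_label(label)
    return (base, sub) if base <= 111 else (base, -sub)


def cdr3_labels(length: int) -> list[str]:
    """IMGT labels for a CDR3 (junction minus anchors) of ``length`` residues.

    Outside-in fill from 105 and 117.  Shorter than 13: gaps open at the top
    of the loop (111/112 side), the 5' half keeping ceil(length/2) positions.
    Longer than 13: extra residues get insertion labels between 111 and 112,
    the first extra on the 111 side.
    """
    if length < 0:
        raise ValueError("CDR3 length must be >= 0")
    if length <= 13:
        n_left = (length + 1) // 2
        n_right = length - n_left
        left = [str(p) for p in range(105, 105 + n_left)]
        right = [str(p) for p in range(118 - n_right, 118)]
        return left + right
    extra = length - 13
    n_left_ins = (extra + 1) // 2
    n_right_ins = extra - n_left_ins
    left = [str(p) for p in range(105, 112)]
    left += [format_label(111, k) for k in range(1, n_left_ins + 1)]
    right = [format_label(112, k) for k in range(n_right_ins, 0, -1)]
    right += [str(p) for p in range(112, 118)]
    return left + right


def in_span(label: str, span: tuple[int, ...]) -> bool:
    """True when the label's base position lies in the span."""
    return parse_label(label)[0] in span


def in_cdr12(label: str) -> bool:
    base = parse_label(label)[0]
    return base in CDR1_SPAN or base in CDR2_SPAN
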