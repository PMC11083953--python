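"""Germline assignment, IMGT numbering, region extraction and mutation calls.

The stage mirrors an IgBLAST-style workflow with a fully specified contract:

1. nucleotide fitting alignment of the query against every germline V;
   best hit by score, then identity, then lexicographically smallest name;
2. the region 3' of the V alignment is aligned against every J the same way;
3. the reading frame is the codon phase of the best V alignment, the V
   alignment is lifted to amino acids and query residues inherit the IMGT
   label of their aligned gapped-reference column; CDR3 (between the
   conserved Cys104 and the J's Trp/Phe 118) is numbered outside-in;
4. per-position comparison against the germline V (IMGT 1-104) yields
   substitution / insertion / deletion events;
5. productivity flags: stop codons, out-of-frame junction, missing CDRs or
   anchors, low V identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import imgt
from .align import AlignmentResult, Scoring, align_semiglobal, score_semiglobal
from .records import (
    CODON_TABLE,
    GAP,
    GermlineGene,
    MutationEvent,
    RearrangementRecord,
    SequenceRecord,
)


def translate(nucleotides: str, frame_offset: int = 0) -> str:
    """Translate with the standard code; trailing partial codon dropped,
    stops rendered '*', codons containing N rendered 'X'."""
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    seq = nucleotides[frame_offset:]
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


@dataclass
class AnnotationParams:
    scoring: Scoring = field(default_factory=Scoring)
    v_identity_floor: float = 0.60
    min_j_suffix: int = 15


def _best_hit(
    query: str, genes: list[GermlineGene], scoring: Scoring
) -> tuple[GermlineGene, AlignmentResult]:
    """Best-scoring gene; ties by higher identity then smallest name."""
    scores = [(score_semiglobal(query, g.ungapped, scoring), g) for g in genes]
    top = max(s for s, _ in scores)
    tied = [g for s, g in scores if s == top]
    best: tuple[float, str, GermlineGene, AlignmentResult] | None = None
    for g in sorted(tied, key=lambda g: g.name):
        aln = align_semiglobal(query, g.ungapped, scoring, reference_name=g.name)
        key = (-aln.identity, g.name)
        if best is None or key < (best[0], best[1]):
            best = (-aln.identity, g.name, g, aln)
    assert best is not None
    return best[2], best[3]


def assign_v(
    query_nt: str, v_genes: list[GermlineGene], params: AnnotationParams | None = None
) -> tuple[str, str, AlignmentResult]:
    params = params or AnnotationParams()
    if not v_genes:
        raise ValueError("empty V reference")
    gene, aln = _best_hit(query_nt, v_genes, params.scoring)
    return gene.name, gene.family, aln


def assign_j(
    query_suffix_nt: str,
    j_genes: list[GermlineGene],
    params: AnnotationParams | None = None,
) -> tuple[str, str, AlignmentResult] | None:
    """J assignment on the region 3' of the V alignment; None = no_j_call."""
    params = params or AnnotationParams()
    if not j_genes:
        raise ValueError("empty J reference")
    if len(query_suffix_nt) < params.min_j_suffix:
        return None
    gene, aln = _best_hit(query_suffix_nt, j_genes, params.scoring)
    return gene.name, gene.family, aln


@dataclass
class NumberingResult:
    residues: dict[str, str]  # IMGT label -> amino acid, in IMGT order
    frame: int
    cys104_codon_start: int | None  # query nt index of the codon at IMGT 104
    trp118_codon_start: int | None
    junction_nt_length: int | None
    failed: bool = False


def _v_frame(v_aln: AlignmentResult) -> int:
    """Reading frame implied by the majority codon phase of the V alignment
    (the reference's frame 0 is codon-aligned)."""
    counts = [0, 0, 0]
    for q, r in v_aln.aligned_pairs:
        if q is not None and r is not None:
            counts[(q - r) % 3] += 1
    return max(range(3), key=lambda p: (counts[p], -p))


def imgt_number(
    query_nt: str,
    v_gene: GermlineGene,
    v_aln: AlignmentResult,
    j_gene: GermlineGene | None,
    j_aln: AlignmentResult | None,
    j_query_offset: int = 0,
) -> NumberingResult:
    """Impose IMGT numbers on the query using the gapped V and the J anchor.

    ``j_aln`` is an alignment of ``query_nt[j_query_offset:]`` against the
    ungapped J; the J's first codon is its conserved Trp/Phe 118.
    """
    frame = _v_frame(v_aln)
    aa = translate(query_nt, frame)

    def codon_of(q_nt_index: int) -> int | None:
        k, phase = divmod(q_nt_index - frame, 3)
        if k < 0 or k >= len(aa):
            return None
        return k

    gapped_aa = v_gene.aa_gapped
    codon_labels = [str(c + 1) for c, a in enumerate(gapped_aa) if a != GAP]
    ref2query = v_aln.ref_to_query()

    residues: dict[str, str] = {}
    label_codon: dict[str, int] = {}
    assigned_codons: set[int] = set()
    # framework and FR3 positions: lift via the middle nucleotide of each
    # codon; CDR1/CDR2 are numbered positionally below, the way IMGT numbers
    # hypervariable loops, so alignment ambiguity inside a loop cannot move
    # residues between labels
    cdr12_bases = set(imgt.CDR1_SPAN) | set(imgt.CDR2_SPAN)
    for c, label in enumerate(codon_labels):
        if int(label) in cdr12_bases:
            continue
        q_mid = ref2query.get(3 * c + 1)
        if q_mid is None:
            continue
        k = codon_of(q_mid)
        if k is None or k in assigned_codons:
            continue
        residues[label] = aa[k]
        label_codon[label] = k
        assigned_codons.add(k)

    # V start: when the first codons are mutated the fitting alignment can
    # slide the reference 5' end; re-lift labels 1-3 from a consensus over
    # the next framework codons (FR1 is contiguous over labels 1-9)
    start_candidates = [
        label_codon[str(p)] - (p - 1)
        for p in (4, 5, 6, 7)
        if str(p) in label_codon
    ]
    if start_candidates:
        best = None
        for value in reversed(start_candidates):
            count = start_candidates.count(value)
            if best is None or count > best[0]:
                best = (count, value)
        k0 = best[1]
        for c in range(3):
            k = k0 + c
            if 0 <= k < len(aa):
                residues[str(c + 1)] = aa[k]
                label_codon[str(c + 1)] = k
                assigned_codons.add(k)
            elif str(c + 1) in residues:
                del residues[str(c + 1)]

    # V end: the same slide can move the Cys104 anchor when positions
    # 102/103 are mutated; re-lift labels 102-104 from a consensus over the
    # preceding FR3 codons (FR3 is contiguous over labels 66-104)
    end_candidates = [
        label_codon[str(p)] + (104 - p)
        for p in (98, 99, 100, 101)
        if str(p) in label_codon
    ]
    if end_candidates:
        best = None
        for value in end_candidates:  # furthest-from-104 first on ties
            count = end_candidates.count(value)
            if best is None or count > best[0]:
                best = (count, value)
        k104 = best[1]
        for back in range(3):
            label, k = 104 - back, k104 - back
            if 0 <= k < len(aa):
                residues[str(label)] = aa[k]
                label_codon[str(label)] = k
                assigned_codons.add(k)
            elif str(label) in residues:
                del residues[str(label)]

    # CDR1/CDR2: the query codons between the flanking framework anchors are
    # the loop; the last R residues keep the gene's trailing occupied labels
    # (the loop's 3' stem is germline-anchored) and the rest fill from the
    # span start through the germline gap stretch, left to right.
    gene_positions = set(v_gene.occupied_positions())

    def _anchor_codon(labels_outward: list[int], offset_sign: int) -> int | None:
        # Each framework label p implies a boundary codon k(p) +/- step.  A
        # single anchor can be mis-lifted when the alignment wobbles next to
        # a hypervariable stretch, so three anchors vote; ties prefer the
        # anchor deepest in the framework.  Assumes no indel between the
        # anchors and the span.
        candidates = []
        for step, p in enumerate(labels_outward):
            k = label_codon.get(str(p))
            if k is not None:
                candidates.append(k + offset_sign * step)
        if not candidates:
            return None
        best = None
        for value in reversed(candidates):  # furthest-from-span first
            count = candidates.count(value)
            if best is None or count > best[0]:
                best = (count, value)
        return best[1]

    for span in (imgt.CDR1_SPAN, imgt.CDR2_SPAN):
        lo, hi = span[0], span[-1]
        k_left = _anchor_codon([lo - d for d in range(1, 7)], 1)
        k_right = _anchor_codon([hi + d for d in range(1, 7)], -1)
        if k_left is None or k_right is None:
            continue
        # re-lift the anchor labels from the consensus, undoing any wobble
        # of a single alignment column next to the hypervariable stretch
        for step in range(4):
            for label, k in ((lo - 1 - step, k_left - step), (hi + 1 + step, k_right + step)):
                if label < 1 or label > 104 or not 0 <= k < len(aa):
                    continue
                if gapped_aa[label - 1] != GAP:
                    residues[str(label)] = aa[k]
                    label_codon[str(label)] = k
                    assigned_codons.add(k)
        loop = [k for k in range(k_left + 1, k_right) if 0 <= k < len(aa)]
        trailing = []
        for p in range(hi, lo - 1, -1):
            if p in gene_positions:
                trailing.append(p)
            else:
                break
        trailing.reverse()
        leading_labels = [p for p in range(lo, hi + 1) if p not in trailing]
        n_right = min(len(trailing), len(loop))
        right_codons = loop[len(loop) - n_right :]
        left_codons = loop[: len(loop) - n_right]
        for label, k in zip(trailing[len(trailing) - n_right :], right_codons):
            residues[str(label)] = aa[k]
            label_codon[str(label)] = k
            assigned_codons.add(k)
        for label, k in zip(leading_labels, left_codons):
            residues[str(label)] = aa[k]
            label_codon[str(label)] = k
            assigned_codons.add(k)

    cys_start = None
    if residues.get("104") == "C":
        k = label_codon.get("104")
        if k is not None:
            cys_start = frame + 3 * k

    trp_start = None
    junction_len = None
    if j_aln is not None and j_gene is not None:
        j_r2q = j_aln.ref_to_query()
        q_mid = j_r2q.get(1)  # middle nt of the J's first codon (118)
        if q_mid is not None:
            trp_start = j_query_offset + q_mid - 1
    if cys_start is not None and trp_start is not None and trp_start > cys_start:
        junction_len = trp_start + 3 - cys_start
        if junction_len % 3 == 0:
            n_cdr3 = (trp_start - cys_start) // 3 - 1
            labels = imgt.cdr3_labels(n_cdr3)
            for i, label in enumerate(labels):
                k = (cys_start - frame) // 3 + 1 + i
                if 0 <= k < len(aa):
                    residues[label] = aa[k]
        # J-encoded positions from 118 on (FR4)
        j_r2q = j_aln.ref_to_query()
        for c in range(len(j_gene.aa_gapped)):
            q_mid = j_r2q.get(3 * c + 1)
            if q_mid is None:
                continue
            qi = j_query_offset + q_mid - 1  # codon start in query coordinates
            if (qi - trp_start) % 3 != 0:
                continue
            k = codon_of(qi)
            if k is not None:
                residues[str(imgt.TRP_118 + c)] = aa[k]

    failed = cys_start is None or trp_start is None
    ordered = dict(sorted(residues.items(), key=lambda kv: imgt.label_sort_key(kv[0])))
    return NumberingResult(
        residues=ordered,
        frame=frame,
        cys104_codon_start=cys_start,
        trp118_codon_start=trp_start,
        junction_nt_length=junction_len,
        failed=failed,
    )


@dataclass
class Regions:
    cdr1_aa: str
    cdr2_aa: str
    cdr3_aa: str
    fr2_tetrad: str
    junction_aa: str


def extract_regions(numbered: NumberingResult) -> Regions:
    """Concatenate occupied positions within each CDR span, in IMGT order."""
    res = numbered.residues

    def span_string(span: tuple[int, ...]) -> str:
        labels = [
            lab for lab in res if imgt.parse_label(lab)[0] in span
        ]
        labels.sort(key=imgt.label_sort_key)
        return "".join(res[lab] for lab in labels)

    cdr3 = span_string(imgt.CDR3_SPAN)
    tetrad = "".join(res.get(str(p), "-") for p in imgt.FR2_TETRAD)
    junction = ""
    if "104" in res and "118" in res:
        junction = res["104"] + cdr3 + res["118"]
    return Regions(
        cdr1_aa=span_string(imgt.CDR1_SPAN),
        cdr2_aa=span_string(imgt.CDR2_SPAN),
        cdr3_aa=cdr3,
        fr2_tetrad=tetrad,
        junction_aa=junction,
    )


def classify_mutations(
    numbered: NumberingResult | dict[str, str], v_gene: GermlineGene
) -> list[MutationEvent]:
    """Per-position events against the germline V, IMGT 1-104 only.

    Both occupied and different -> substitution; query-only at a germline gap
    -> insertion; germline-only -> deletion.
    """
    residues = numbered.residues if isinstance(numbered, NumberingResult) else numbered
    gapped = v_gene.aa_gapped
    events: list[MutationEvent] = []
    for col in range(imgt.V_REGION_END):
        label = str(col + 1)
        germ = gapped[col]
        obs = residues.get(label)
        if germ != GAP and obs is not None and obs != germ:
            events.append(MutationEvent(label, "substitution", germ, obs))
        elif germ == GAP and obs is not None:
            events.append(MutationEvent(label, "insertion", "-", obs))
        elif germ != GAP and obs is None:
            events.append(MutationEvent(label, "deletion", germ, "-"))
    return events


@dataclass
class ProductivityReport:
    productive: bool
    reasons: list[str]


def check_productivity(
    numbered: NumberingResult,
    regions: Regions,
    sequence_aa: str,
    junction_nt_length: int | None,
    v_identity: float,
    params: AnnotationParams | None = None,
) -> ProductivityReport:
    params = params or AnnotationParams()
    reasons = []
    if "*" in sequence_aa:
        reasons.append("stop_codon")
    if junction_nt_length is None or junction_nt_length % 3 != 0:
        reasons.append("out_of_frame_junction")
    if not (regions.cdr1_aa and regions.cdr2_aa and regions.cdr3_aa):
        reasons.append("missing_cdr")
    if numbered.residues.get("104") != "C":
        reasons.append("missing_anchor_104")
    if numbered.residues.get("118") not in ("W", "F"):
        reasons.append("missing_anchor_118")
    if v_identity < params.v_identity_floor:
        reasons.append("low_v_identity")
    return ProductivityReport(productive=not reasons, reasons=reasons)


def annotate_sequence(
    record: SequenceRecord,
    v_genes: list[GermlineGene],
    j_genes: list[GermlineGene],
    params: AnnotationParams | None = None,
) -> RearrangementRecord:
    """Full annotation of one kept (merged, primer-filtered) sequence."""
    params = params or AnnotationParams()
    query = record.nucleotides
    out = RearrangementRecord(sequence_id=record.id, sequence=query)
    v_call, v_family, v_aln = assign_v(query, v_genes, params)
    out.v_call, out.v_family = v_call, v_family
    v_gene = next(g for g in v_genes if g.name == v_call)
    frame = _v_frame(v_aln)
    out.sequence_aa = translate(query, frame)
    if v_aln.identity < params.v_identity_floor:
        out.fail_reasons = ["low_v_identity"]
        out.productive = False
        return out

    j_offset = v_aln.query_end
    j_hit = assign_j(query[j_offset:], j_genes, params)
    if j_hit is None:
        numbered = imgt_number(query, v_gene, v_aln, None, None)
        regions = extract_regions(numbered)
        report = ProductivityReport(False, ["no_j_call"])
        j_gene = None
    else:
        out.j_call, out.j_family, j_aln = j_hit[0], j_hit[1], j_hit[2]
        j_gene = next(g for g in j_genes if g.name == out.j_call)
        numbered = imgt_number(query, v_gene, v_aln, j_gene, j_aln, j_offset)
        regions = extract_regions(numbered)
        report = check_productivity(
            numbered,
            regions,
            out.sequence_aa,
            numbered.junction_nt_length,
            v_aln.identity,
            params,
        )
        if numbered.failed:
            report = ProductivityReport(False, report.reasons or ["numbering_failed"])
    events = classify_mutations(numbered, v_gene)
    out.cdr1_aa = regions.cdr1_aa
    out.cdr2_aa = regions.cdr2_aa
    out.cdr3_aa = regions.cdr3_aa
    out.junction_aa = regions.junction_aa
    out.fr2_tetrad = regions.fr2_tetrad
    out.numbered_residues = numbered.residues
    out.mutation_events = events
    out.n_nongermline_cdr12 = sum(
        1
        for ev in events
        if ev.kind in ("substitution", "insertion") and imgt.in_cdr12(ev.position)
    )
    out.productive = report.productive
    out.fail_reasons = report.reasons
    return out


def annotate_all(
    records,
    v_genes: list[GermlineGene],
    j_genes: list[GermlineGene],
    params: AnnotationParams | None = None,
) -> list[RearrangementRecord]:
    """Annotate a stream, memoizing identical nucleotide sequences."""
    from dataclasses import replace

    params = params or AnnotationParams()
    cache: dict[str, RearrangementRecord] = {}
    out = []
    for rec in records:
        hit = cache.get(rec.nucleotides)
        if hit is None:
            hit = annotate_sequence(rec, v_genes, j_genes, params)
            cache[rec.nucleotides] = hit
            out.append(hit)
        else:
            out.append(
                replace(
                    hit,
                    sequence_id=rec.id,
                    fail_reasons=list(hit.fail_reasons),
                    numbered_residues=dict(hit.numbered_residues),
                    mutation_events=list(hit.mutation_events),
                )
            )
    return out
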