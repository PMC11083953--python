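"""On-disk formats: FASTQ, (gapped) FASTA, AIRR Rearrangement TSV, JSON summaries.

FASTQ is read and written by hand so that malformed records can be rejected
with the offending line number; only Phred+33 is accepted.  FASTA goes
through Bio.SeqIO.  The rearrangement table is an AIRR Rearrangement TSV
using standard column names where one exists plus ``vhh_``-namespaced
extension columns; the round trip is lossless for every field.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import warnings
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .records import GermlineGene, MutationEvent, RearrangementRecord, SequenceRecord

PHRED_OFFSET = 33


class ParseError(ValueError):
    pass


class ReferenceError(ValueError):
    pass


def _open_text(source, mode: str = "rt"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode), True
    return open(path, mode), True


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(source) -> Iterator[SequenceRecord]:
    """Lazily yield records from a 4-line-per-record, Phred+33 FASTQ.

    ``source`` may be a path (``.gz`` allowed) or an open text stream.
    Malformed records raise :class:`ParseError` naming the line number.
    """
    handle, owned = _open_text(source)
    seen: set[str] = set()
    try:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"line {lineno}: expected '@' header, got {header[:20]!r}")
            tokens = header[1:].split()
            rid = tokens[0] if tokens else ""
            if not rid:
                raise ParseError(f"line {lineno}: empty read id")
            if rid in seen:
                raise ParseError(f"line {lineno}: duplicate read id {rid!r}")
            seen.add(rid)
            seq = handle.readline().strip().upper()
            lineno += 1
            plus = handle.readline()
            lineno += 1
            if not plus.startswith("+"):
                raise ParseError(f"line {lineno}: expected '+' separator")
            qual = handle.readline().strip()
            lineno += 1
            if len(qual) != len(seq):
                raise ParseError(
                    f"line {lineno}: {len(qual)} quality symbols for {len(seq)} bases"
                )
            scores = []
            for ch in qual:
                q = ord(ch) - PHRED_OFFSET
                if q < 0 or q > 93:
                    raise ParseError(
                        f"line {lineno}: quality symbol {ch!r} outside Phred+33 range"
                    )
                scores.append(q)
            try:
                yield SequenceRecord(rid, seq, scores)
            except ValueError as exc:
                raise ParseError(f"line {lineno - 2}: {exc}") from exc
    finally:
        if owned:
            handle.close()


def write_fastq(records: Iterable[SequenceRecord], dest) -> None:
    handle, owned = _open_text(dest, "wt")
    try:
        for rec in records:
            quals = rec.qualities
            if quals is None:
                quals = [40] * len(rec)
            qline = "".join(chr(q + PHRED_OFFSET) for q in quals)
            handle.write(f"@{rec.id}\n{rec.nucleotides}\n+\n{qline}\n")
    finally:
        if owned:
            handle.close()


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(source) -> Iterator[SequenceRecord]:
    handle, owned = _open_text(source)
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SequenceRecord(rec.id, str(rec.seq).upper())
    finally:
        if owned:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], dest) -> None:
    handle, owned = _open_text(dest, "wt")
    try:
        SeqIO.write(
            (_BioSeqRecord(Seq(r.nucleotides), id=r.id, description="") for r in records),
            handle,
            "fasta",
        )
    finally:
        if owned:
            handle.close()


# ---------------------------------------------------------------------------
# Germline reference

def read_germline_reference(source) -> list[GermlineGene]:
    """Load IMGT-gapped germline genes from a FASTA file or a directory of them.

    Header dialect: ``>NAME|SEGMENT|FAMILY`` (e.g. ``>IGHV3S53|V|IGHV3``).
    '.' gap characters are preserved verbatim.
    """
    path = Path(source) if not hasattr(source, "read") else None
    if path is not None and path.is_dir():
        files = sorted(path.glob("*.fasta")) + sorted(path.glob("*.fa"))
        if not files:
            raise ReferenceError(f"no FASTA files in {path}")
        genes: list[GermlineGene] = []
        for f in files:
            genes.extend(read_germline_reference(f))
    else:
        handle, owned = _open_text(source)
        genes = []
        try:
            for rec in SeqIO.parse(handle, "fasta"):
                parts = rec.id.split("|")
                if len(parts) != 3:
                    raise ReferenceError(
                        f"header {rec.id!r}: expected 'NAME|SEGMENT|FAMILY'"
                    )
                name, segment, family = parts
                try:
                    genes.append(GermlineGene(name, family, segment, str(rec.seq)))
                except ValueError as exc:
                    raise ReferenceError(str(exc)) from exc
        finally:
            if owned:
                handle.close()
    names = [g.name for g in genes]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ReferenceError(f"duplicate gene names: {sorted(dupes)}")
    return genes


def write_germline_reference(genes: Iterable[GermlineGene], dest) -> None:
    handle, owned = _open_text(dest, "wt")
    try:
        for g in genes:
            handle.write(f">{g.name}|{g.segment_type}|{g.family}\n{g.gapped_sequence}\n")
    finally:
        if owned:
            handle.close()


# ---------------------------------------------------------------------------
# AIRR Rearrangement TSV

#: column -> (getter, setter-decoder); order defines the file layout
AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "sequence_aa",
    "v_call",
    "j_call",
    "productive",
    "cdr1_aa",
    "cdr2_aa",
    "cdr3_aa",
    "junction_aa",
    "vhh_v_family",
    "vhh_j_family",
    "vhh_fail_reasons",
    "vhh_fr2_tetrad",
    "vhh_numbered_residues",
    "vhh_mutation_events",
    "vhh_n_nongermline_cdr12",
]


def _encode_numbered(residues: dict[str, str]) -> str:
    return " ".join(f"{label}:{aa}" for label, aa in residues.items())


def _decode_numbered(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in text.split():
        label, aa = token.split(":", 1)
        out[label] = aa
    return out


def write_rearrangements(records: Iterable[RearrangementRecord], path) -> None:
    rows = []
    for rec in records:
        rec.validate()
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "sequence": rec.sequence,
                "sequence_aa": rec.sequence_aa,
                "v_call": rec.v_call,
                "j_call": rec.j_call,
                "productive": "T" if rec.productive else "F",
                "cdr1_aa": rec.cdr1_aa,
                "cdr2_aa": rec.cdr2_aa,
                "cdr3_aa": rec.cdr3_aa,
                "junction_aa": rec.junction_aa,
                "vhh_v_family": rec.v_family,
                "vhh_j_family": rec.j_family,
                "vhh_fail_reasons": ",".join(rec.fail_reasons),
                "vhh_fr2_tetrad": rec.fr2_tetrad,
                "vhh_numbered_residues": _encode_numbered(rec.numbered_residues),
                "vhh_mutation_events": ";".join(ev.encode() for ev in rec.mutation_events),
                "vhh_n_nongermline_cdr12": rec.n_nongermline_cdr12,
            }
        )
    df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_rearrangements(path) -> list[RearrangementRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in AIRR_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown rearrangement columns: {unknown}")
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"rearrangement table is missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        rec = RearrangementRecord(
            sequence_id=row.sequence_id,
            sequence=row.sequence,
            sequence_aa=row.sequence_aa,
            v_call=row.v_call,
            j_call=row.j_call,
            v_family=row.vhh_v_family,
            j_family=row.vhh_j_family,
            productive=row.productive == "T",
            fail_reasons=[r for r in row.vhh_fail_reasons.split(",") if r],
            cdr1_aa=row.cdr1_aa,
            cdr2_aa=row.cdr2_aa,
            cdr3_aa=row.cdr3_aa,
            junction_aa=row.junction_aa,
            fr2_tetrad=row.vhh_fr2_tetrad,
            numbered_residues=_decode_numbered(row.vhh_numbered_residues),
            mutation_events=[
                MutationEvent.decode(t)
                for t in row.vhh_mutation_events.split(";")
                if t
            ],
            n_nongermline_cdr12=int(row.vhh_n_nongermline_cdr12),
        )
        rec.validate()
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# JSON summaries

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
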