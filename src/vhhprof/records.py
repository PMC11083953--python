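"""Domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import imgt

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "."  # IMGT gap character in gapped references; '-' is alignment output

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class SequenceRecord:
    """A nucleotide sequence, optionally with Phred qualities."""

    id: str
    nucleotides: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.nucleotides) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid bases {sorted(bad)!r} "
                "(alphabet is A/C/G/T/N)"
            )
        if self.qualities is not None:
            if len(self.qualities) != len(self.nucleotides):
                raise ValueError(
                    f"record {self.id!r}: {len(self.qualities)} quality values "
                    f"for {len(self.nucleotides)} bases"
                )
            if any(q < 0 or q > 93 for q in self.qualities):
                raise ValueError(f"record {self.id!r}: Phred scores must be in [0, 93]")

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class GermlineGene:
    """An IMGT-gapped germline V or J segment.

    ``gapped_sequence`` carries '.' at IMGT-empty codon positions (three dots
    per empty codon); for V genes the gapped amino-acid coordinate system
    spans IMGT positions 1-104.
    """

    name: str
    family: str
    segment_type: str  # "V" or "J"
    gapped_sequence: str

    def __post_init__(self) -> None:
        if self.segment_type not in ("V", "J"):
            raise ValueError(f"{self.name}: segment_type must be V or J")
        if not self.family or not self.name.startswith(self.family):
            raise ValueError(f"{self.name}: family {self.family!r} is not a name prefix")
        seq = self.gapped_sequence.upper()
        bad = set(seq) - NT_ALPHABET - {GAP}
        if bad:
            raise ValueError(f"{self.name}: invalid characters {sorted(bad)!r}")
        self.gapped_sequence = seq
        if len(seq) % 3 != 0:
            raise ValueError(f"{self.name}: gapped length {len(seq)} not a multiple of 3")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if GAP in codon and codon != GAP * 3:
                raise ValueError(f"{self.name}: partial gap codon {codon!r} at nt {i}")
        if self.segment_type == "V" and len(seq) != 104 * 3:
            raise ValueError(
                f"{self.name}: V genes must span IMGT 1-104 "
                f"(312 gapped nt, got {len(seq)})"
            )
        if "*" in self.aa_ungapped:
            raise ValueError(f"{self.name}: ungapped translation contains a stop codon")

    @property
    def ungapped(self) -> str:
        return self.gapped_sequence.replace(GAP, "")

    @property
    def aa_gapped(self) -> str:
        """Amino acids with '.' at gapped codons."""
        seq = self.gapped_sequence
        out = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            out.append(GAP if codon == GAP * 3 else CODON_TABLE.get(codon, "X"))
        return "".join(out)

    @property
    def aa_ungapped(self) -> str:
        return self.aa_gapped.replace(GAP, "")

    def imgt_label_of_codon(self, codon_index: int) -> str:
        """IMGT position label of the ``codon_index``-th ungapped codon."""
        count = -1
        for col, aa in enumerate(self.aa_gapped):
            if aa != GAP:
                count += 1
                if count == codon_index:
                    return str(col + 1)
        raise IndexError(codon_index)

    def occupied_positions(self) -> list[int]:
        """IMGT base positions occupied (non-gap) in this gene."""
        return [col + 1 for col, aa in enumerate(self.aa_gapped) if aa != GAP]


@dataclass
class MutationEvent:
    """A per-position difference between a rearrangement and its germline V."""

    position: str  # IMGT label
    kind: str  # substitution | insertion | deletion
    germline_aa: str  # '-' for insertions
    observed_aa: str  # '-' for deletions

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if "-" in (self.germline_aa, self.observed_aa) or (
                self.germline_aa == self.observed_aa
            ):
                raise ValueError(f"bad substitution event at {self.position}")
        elif self.kind == "insertion":
            if self.germline_aa != "-" or self.observed_aa == "-":
                raise ValueError(f"bad insertion event at {self.position}")
        elif self.kind == "deletion":
            if self.observed_aa != "-" or self.germline_aa == "-":
                raise ValueError(f"bad deletion event at {self.position}")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")

    def encode(self) -> str:
        return f"{self.position}:{self.germline_aa}>{self.observed_aa}"

    @classmethod
    def decode(cls, text: str) -> "MutationEvent":
        position, rest = text.split(":", 1)
        germ, obs = rest.split(">", 1)
        if germ == "-":
            kind = "insertion"
        elif obs == "-":
            kind = "deletion"
        else:
            kind = "substitution"
        return cls(position, kind, germ, obs)


PRODUCTIVITY_FLAGS = (
    "stop_codon",
    "out_of_frame_junction",
    "missing_cdr",
    "missing_anchor_104",
    "missing_anchor_118",
    "low_v_identity",
    "no_v_call",
    "no_j_call",
    "numbering_failed",
)


@dataclass
class RearrangementRecord:
    """One annotated VHH rearrangement (AIRR-style row)."""

    sequence_id: str
    sequence: str = ""
    sequence_aa: str = ""
    v_call: str = ""
    j_call: str = ""
    v_family: str = ""
    j_family: str = ""
    productive: bool = False
    fail_reasons: list[str] = field(default_factory=list)
    cdr1_aa: str = ""
    cdr2_aa: str = ""
    cdr3_aa: str = ""
    junction_aa: str = ""
    fr2_tetrad: str = ""
    numbered_residues: dict[str, str] = field(default_factory=dict)
    mutation_events: list[MutationEvent] = field(default_factory=list)
    n_nongermline_cdr12: int = 0

    def validate(self) -> None:
        if "\t" in self.sequence_id:
            raise ValueError("sequence_id must be tab-free")
        if self.productive:
            if self.fail_reasons:
                raise ValueError(f"{self.sequence_id}: productive with fail reasons")
            if not (self.cdr1_aa and self.cdr2_aa and self.cdr3_aa):
                raise ValueError(f"{self.sequence_id}: productive with a missing CDR")
            if "*" in self.sequence_aa:
                raise ValueError(f"{self.sequence_id}: productive with a stop codon")
        n = sum(
            1
            for ev in self.mutation_events
            if ev.kind in ("substitution", "insertion") and imgt.in_cdr12(ev.position)
        )
        if n != self.n_nongermline_cdr12:
            raise ValueError(
                f"{self.sequence_id}: n_nongermline_cdr12={self.n_nongermline_cdr12} "
                f"but events give {n}"
            )
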