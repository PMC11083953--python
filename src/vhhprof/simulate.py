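"""Synthetic VHH repertoire generator with per-clone ground truth.

The generator emulates the statistical structure of a naive camelid VHH
phage-display library as seen by amplicon sequencing:

* V/J recombination with configurable gene-usage laws (IGHV3-dominated,
  IGHJ4-dominated by default);
* CDR3 junctions of 5-31 residues drawn from a length law with mode 9,
  filled from a junction residue law, flanked by the conserved Cys104 and
  the J-encoded Trp118;
* somatic hypermutation as per-position substitution probabilities over
  IMGT 1-104 plus insertion-count laws at the germline-gap CDR stretches,
  scaled by a per-clone mutability factor (mean CDR1+CDR2 non-germline
  count ~= 7 by default) with a small exactly-germline clone fraction;
* a clone-size law putting ~92% of reads in singleton clones;
* Sfi I primer-flanked amplicons and paired 300-nt reads with a constant-
  quality, substitution-only sequencing error model.

Every clone carries a TruthRecord from which regions and mutation events
can be re-derived by direct comparison with the germline, without any
aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgt
from .preprocess import PrimerSpec, reverse_complement
from .records import AA_ALPHABET, GAP, GermlineGene, MutationEvent, SequenceRecord

# codon used for mutated/inserted/junction residues
AA_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

# alternative (synonymous) codons; each germline gene mixes the two tables in
# its own deterministic pattern so that sibling genes differ by many silent
# sites, as real germline alleles do — this keeps gene assignment stable
# under heavy somatic hypermutation
AA_CODON_ALT = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTC",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "CGC",
    "S": "TCC", "T": "ACG", "V": "GTC", "W": "TGG", "Y": "TAT",
}

#: two pad bases after the forward primer keep the VHH ORF in frame 0
#: relative to the first primer base (13 + 2 = 15 nt)
FRAME_PAD = "AG"

_FR1 = "QVQLVESGG.GLVQPGGSLRLSCAAS"
_FR1_V2 = "QVQLVESGG.GLVQAGGSLRLSCVAS"
_FR1_V1 = "QVQLVQSGA.EVKKPGASVKVSCKAS"
_FR3 = "YADSVKGRFTISRDNAKNTLYLQMNSLKPEAADTAVYYC"
_FR3_V2 = "YAESVKGRFTISRDNAKNTLYLQMNSLKPEAADTGVYYC"
_FR3_V1 = "YAQKFQGRVTISADKSTSTAYMELSSLRSEAADTAVYYC"


def _fr2(t42: str, t49: str, t52: str) -> str:
    # 39 M, 40 A, 41 W(conserved), 42, 43-48 RQAPGK, 49, 50 R(conserved),
    # 51 E, 52, 53-55 VAA
    return "MAW" + t42 + "RQAPGK" + t49 + "R" + "E" + t52 + "VAA"


#: name -> (family, FR1, CDR1 (12 gapped slots), FR2 tetrad 42/49/52, CDR2
#: (10 gapped slots), FR3); hallmark position 50 is Arg throughout
_V_GENES = {
    "IGHV3S53": ("IGHV3", _FR1, "GRTFS....SYA", ("Y", "E", "L"), "INSG..GSTY", _FR3),
    "IGHV3S65": ("IGHV3", _FR1, "GFTFD....DYA", ("F", "E", "L"), "ISSG..GSTY", _FR3),
    "IGHV3S1": ("IGHV3", _FR1, "GSIFS....INA", ("Y", "Q", "L"), "ITSG..GSTN", _FR3),
    "IGHV3-3": ("IGHV3", _FR1, "GRTFS....NYV", ("F", "Q", "G"), "INWS...STY", _FR3),
    "IGHV2S1": ("IGHV2", _FR1_V2, "GGSLS....SNA", ("Y", "E", "G"), "IDSD...GTT", _FR3_V2),
    "IGHV1S1": ("IGHV1", _FR1_V1, "GYTFT....GYY", ("F", "Q", "G"), "INPN..SGGT", _FR3_V1),
}

_J_GENES = {
    "IGHJ4": ("IGHJ4", "WGQGTQVTVSS"),
    "IGHJ6": ("IGHJ6", "WGKGTLVTVSS"),
    "IGHJ7": ("IGHJ7", "WGRGTQVTVES"),
    "IGHJ2": ("IGHJ2", "WGPGTQVTVSA"),
}


def _aa_to_gapped_nt(aa_gapped: str, gene_index: int = 0) -> str:
    out = []
    for col, a in enumerate(aa_gapped):
        if a == GAP:
            out.append(GAP * 3)
        elif (col + 2 * gene_index) % 5 < 2:  # per-gene silent-site pattern
            out.append(AA_CODON_ALT[a])
        else:
            out.append(AA_CODON[a])
    return "".join(out)


def toy_reference() -> tuple[list[GermlineGene], list[GermlineGene]]:
    """The packaged toy germline set: 6 IMGT-gapped V genes (3 families),
    4 J genes, hallmark FR2 tetrad residues at 42/49/50/52."""
    v_genes = []
    for i, (name, (family, fr1, cdr1, (t42, t49, t52), cdr2, fr3)) in enumerate(
        _V_GENES.items()
    ):
        aa = fr1 + cdr1 + _fr2(t42, t49, t52) + cdr2 + fr3
        v_genes.append(GermlineGene(name, family, "V", _aa_to_gapped_nt(aa, i)))
    j_genes = [
        GermlineGene(name, family, "J", _aa_to_gapped_nt(aa, i))
        for i, (name, (family, aa)) in enumerate(_J_GENES.items())
    ]
    return v_genes, j_genes


def build_toy_reference(out_dir) -> Path:
    """Write the toy reference as germline FASTA; returns the file path."""
    from .io import write_germline_reference

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "germline.fasta"
    v_genes, j_genes = toy_reference()
    write_germline_reference(v_genes + j_genes, path)
    return path


# ---------------------------------------------------------------------------
# Configuration


def default_v_usage() -> dict[str, float]:
    return {
        "IGHV3S53": 0.575,
        "IGHV3S65": 0.17,
        "IGHV3S1": 0.115,
        "IGHV3-3": 0.10,
        "IGHV2S1": 0.025,
        "IGHV1S1": 0.015,
    }


def default_j_usage() -> dict[str, float]:
    return {"IGHJ4": 0.75, "IGHJ6": 0.149, "IGHJ7": 0.096, "IGHJ2": 0.005}


def default_cdr3_length_law() -> dict[int, float]:
    law = {5: 0.01, 6: 0.02, 7: 0.04, 8: 0.07, 9: 0.09}
    law.update({length: 0.06 for length in range(10, 22)})
    law.update(
        {22: 0.015, 23: 0.01, 24: 0.007, 25: 0.005, 26: 0.004,
         27: 0.003, 28: 0.0025, 29: 0.0015, 30: 0.001, 31: 0.001}
    )
    return law


def default_junction_residue_law() -> dict[str, float]:
    return {
        "A": 0.105, "Y": 0.100, "G": 0.095, "R": 0.085, "S": 0.080,
        "D": 0.075, "T": 0.060, "L": 0.050, "V": 0.050, "P": 0.045,
        "N": 0.040, "E": 0.040, "W": 0.030, "F": 0.030, "Q": 0.030,
        "I": 0.025, "K": 0.025, "H": 0.020, "M": 0.010, "C": 0.005,
    }


def default_substitution_rates() -> dict[int, float]:
    rates = {p: 0.02 for p in range(1, 105)}
    for p in (10, 23, 41, 50, 104):  # FR1 gap, 1st-CYS, conserved Trp, Arg50, 2nd-CYS
        rates[p] = 0.0
    for p in (32, 33, 34, 35, 60, 61):  # germline gap slots
        rates[p] = 0.0
    rates.update({27: 0.3, 28: 0.3, 29: 0.3, 30: 0.3, 31: 0.4, 36: 0.5, 37: 0.5, 38: 0.5})
    rates.update({56: 0.3, 57: 0.3, 58: 0.5, 59: 0.5, 62: 0.3, 63: 0.3, 64: 0.5, 65: 0.4})
    return rates


def default_insertion_count_laws() -> dict[str, dict[int, float]]:
    return {
        "cdr1": {0: 0.55, 1: 0.36, 2: 0.05, 3: 0.03, 4: 0.01},
        "cdr2": {0: 0.80, 1: 0.18, 2: 0.02},
    }


def default_inserted_residue_law() -> dict[str, float]:
    return {"G": 0.40, "S": 0.15, "R": 0.10, "D": 0.10,
            "T": 0.08, "A": 0.07, "Y": 0.05, "N": 0.05}


def default_mutability_law() -> dict[float, float]:
    return {0.4: 0.15, 0.8: 0.40, 1.2: 0.35, 2.0: 0.10}


@dataclass
class ShmConfig:
    substitution_rates: dict[int, float] = field(default_factory=default_substitution_rates)
    substitution_residue_law: dict[str, float] | None = None  # None = uniform over 19
    insertion_count_laws: dict[str, dict[int, float]] = field(
        default_factory=default_insertion_count_laws
    )
    inserted_residue_law: dict[str, float] = field(
        default_factory=default_inserted_residue_law
    )
    mutability_law: dict[float, float] = field(default_factory=default_mutability_law)
    unmutated_fraction: float = 0.004
    max_rate: float = 0.95  # cap on mutability-scaled per-position rates

    def zeroed(self) -> "ShmConfig":
        """A copy with all mutation processes switched off."""
        return ShmConfig(
            substitution_rates={p: 0.0 for p in range(1, 105)},
            insertion_count_laws={"cdr1": {0: 1.0}, "cdr2": {0: 1.0}},
            inserted_residue_law=dict(self.inserted_residue_law),
            mutability_law={1.0: 1.0},
            unmutated_fraction=0.0,
        )


@dataclass
class CloneSizeConfig:
    singleton_prob: float = 0.9664  # puts ~92% of reads in singleton clones
    extra_poisson_mean: float = 0.5  # multi-copy clones: 2 + Poisson(mean)


@dataclass
class SequencingConfig:
    read_length: int = 300
    error_rate: float = 0.001  # substitution-only, per base
    base_quality: int = 30


@dataclass
class SimulationConfig:
    n_clones: int = 1000
    v_usage: dict[str, float] = field(default_factory=default_v_usage)
    j_usage: dict[str, float] = field(default_factory=default_j_usage)
    cdr3_length_law: dict[int, float] = field(default_factory=default_cdr3_length_law)
    junction_residue_law: dict[str, float] = field(
        default_factory=default_junction_residue_law
    )
    shm: ShmConfig = field(default_factory=ShmConfig)
    clone_size: CloneSizeConfig = field(default_factory=CloneSizeConfig)
    sequencing: SequencingConfig = field(default_factory=SequencingConfig)
    primers: PrimerSpec = field(default_factory=PrimerSpec)
    nonproductive_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name, law in (
            ("v_usage", self.v_usage),
            ("j_usage", self.j_usage),
            ("cdr3_length_law", self.cdr3_length_law),
            ("junction_residue_law", self.junction_residue_law),
            ("inserted_residue_law", self.shm.inserted_residue_law),
            ("mutability_law", self.shm.mutability_law),
        ):
            total = sum(law.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in law.values()):
                raise ValueError(f"{name} has negative probabilities")
        for region, law in self.shm.insertion_count_laws.items():
            if abs(sum(law.values()) - 1.0) > 1e-9:
                raise ValueError(f"insertion_count_laws[{region}] does not sum to 1")
        if any(l < 5 or l > 31 for l in self.cdr3_length_law):
            raise ValueError("cdr3_length_law support must lie within [5, 31]")
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")

    # -- config-implied marginals, used by recovery checks ------------------

    def expected_substitution_rate(self, position: int) -> float:
        """Marginal substitution probability at an occupied position."""
        theta = self.shm.substitution_rates.get(position, 0.0)
        shm = self.shm
        marg = sum(
            p * min(f * theta, shm.max_rate) for f, p in shm.mutability_law.items()
        )
        return (1.0 - shm.unmutated_fraction) * marg

    def _gene_cdr12_mean(self, gene: GermlineGene) -> float:
        occupied = set(gene.occupied_positions())
        subs = sum(
            self.expected_substitution_rate(p)
            for p in occupied
            if p in imgt.CDR1_SPAN or p in imgt.CDR2_SPAN
        )
        ins = 0.0
        for region, span in (("cdr1", imgt.CDR1_SPAN), ("cdr2", imgt.CDR2_SPAN)):
            law = self.shm.insertion_count_laws[region]
            slots = len([p for p in span if p not in occupied])
            mean = sum(min(k, slots) * p for k, p in law.items())
            ins += mean
        return subs + (1.0 - self.shm.unmutated_fraction) * ins

    def expected_nongermline_mean(self) -> float:
        """V-usage-weighted expected CDR1+CDR2 non-germline residue count."""
        v_genes, _ = toy_reference()
        by_name = {g.name: g for g in v_genes}
        return sum(
            w * self._gene_cdr12_mean(by_name[name])
            for name, w in self.v_usage.items()
        )

    def expected_singleton_read_fraction(self) -> float:
        s = self.clone_size.singleton_prob
        multi_mean = 2.0 + self.clone_size.extra_poisson_mean
        return s / (s + (1.0 - s) * multi_mean)


# ---------------------------------------------------------------------------
# Truth records


@dataclass
class TruthRecord:
    clone_id: str
    v_call: str
    j_call: str
    productive: bool
    cdr1_aa: str
    cdr2_aa: str
    cdr3_aa: str
    junction_aa: str
    fr2_tetrad: str
    mutation_events: list[MutationEvent]
    n_nongermline_cdr12: int
    cdr3_length: int
    copy_number: int
    sequence: str  # full amplicon, forward strand


def _choice(rng: np.random.Generator, law: dict) -> object:
    keys = list(law.keys())
    probs = np.asarray([law[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def simulate_repertoire(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Draw clones; returns (amplicon records, truth records), deterministic
    for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    v_genes, j_genes = toy_reference()
    v_by_name = {g.name: g for g in v_genes}
    j_by_name = {g.name: g for g in j_genes}
    for name in config.v_usage:
        if name not in v_by_name:
            raise ValueError(f"v_usage references unknown gene {name!r}")
    for name in config.j_usage:
        if name not in j_by_name:
            raise ValueError(f"j_usage references unknown gene {name!r}")

    aa_pool = list(AA_ALPHABET)
    clones: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    fwd = config.primers.forward
    rc_rev = reverse_complement(config.primers.reverse)

    for i in range(config.n_clones):
        clone_id = f"clone{i:06d}"
        v_gene = v_by_name[str(_choice(rng, config.v_usage))]
        j_gene = j_by_name[str(_choice(rng, config.j_usage))]
        cdr3_len = int(_choice(rng, config.cdr3_length_law))
        cdr3 = "".join(
            str(_choice(rng, config.junction_residue_law)) for _ in range(cdr3_len)
        )

        residues = {
            str(c + 1): aa for c, aa in enumerate(v_gene.aa_gapped) if aa != GAP
        }
        occupied = set(v_gene.occupied_positions())
        events: list[MutationEvent] = []

        mutated = rng.random() >= config.shm.unmutated_fraction
        if mutated:
            f = float(_choice(rng, config.shm.mutability_law))
            for p in sorted(occupied):
                theta = config.shm.substitution_rates.get(p, 0.0)
                rate = min(f * theta, config.shm.max_rate)
                if rate > 0 and rng.random() < rate:
                    germ = residues[str(p)]
                    if config.shm.substitution_residue_law is not None:
                        law = {
                            aa: w
                            for aa, w in config.shm.substitution_residue_law.items()
                            if aa != germ
                        }
                        new = str(_choice(rng, law))
                    else:
                        alternatives = [aa for aa in aa_pool if aa != germ]
                        new = alternatives[int(rng.integers(len(alternatives)))]
                    residues[str(p)] = new
                    events.append(MutationEvent(str(p), "substitution", germ, new))
            for region, span in (("cdr1", imgt.CDR1_SPAN), ("cdr2", imgt.CDR2_SPAN)):
                law = config.shm.insertion_count_laws[region]
                slots = [p for p in span if p not in occupied]
                k = min(int(_choice(rng, law)), len(slots))
                for label in slots[:k]:
                    aa = str(_choice(rng, config.shm.inserted_residue_law))
                    residues[str(label)] = aa
                    events.append(MutationEvent(str(label), "insertion", "-", aa))
        events.sort(key=lambda ev: imgt.label_sort_key(ev.position))

        # unmutated positions keep the gene's own codon (silent sites intact);
        # mutated and inserted residues are re-encoded with the default table
        germ_codons = {
            str(col + 1): v_gene.gapped_sequence[3 * col : 3 * col + 3]
            for col, aa in enumerate(v_gene.aa_gapped)
            if aa != GAP
        }
        germ_aa = {str(col + 1): aa for col, aa in enumerate(v_gene.aa_gapped) if aa != GAP}
        ordered_labels = sorted(residues, key=imgt.label_sort_key)
        v_nt = "".join(
            germ_codons[lab]
            if lab in germ_codons and residues[lab] == germ_aa[lab]
            else AA_CODON[residues[lab]]
            for lab in ordered_labels
        )
        cdr3_nt = "".join(AA_CODON[aa] for aa in cdr3)
        j_nt = j_gene.ungapped
        amplicon = fwd + FRAME_PAD + v_nt + cdr3_nt + j_nt + rc_rev

        productive = True
        if config.nonproductive_rate > 0 and rng.random() < config.nonproductive_rate:
            productive = False
            start = len(fwd + FRAME_PAD) + len(v_nt)
            if rng.random() < 0.5:  # internal stop codon in CDR3
                mid = start + 3 * (cdr3_len // 2)
                amplicon = amplicon[:mid] + "TAA" + amplicon[mid + 3 :]
            else:  # 1-nt deletion frameshift in the junction
                amplicon = amplicon[:start] + amplicon[start + 1 :]

        if config.clone_size.singleton_prob >= 1.0 or (
            rng.random() < config.clone_size.singleton_prob
        ):
            copies = 1
        else:
            copies = 2 + int(rng.poisson(config.clone_size.extra_poisson_mean))

        def span_string(span: tuple[int, ...]) -> str:
            return "".join(
                residues[str(p)] for p in span if str(p) in residues
            )

        truths.append(
            TruthRecord(
                clone_id=clone_id,
                v_call=v_gene.name,
                j_call=j_gene.name,
                productive=productive,
                cdr1_aa=span_string(imgt.CDR1_SPAN),
                cdr2_aa=span_string(imgt.CDR2_SPAN),
                cdr3_aa=cdr3,
                junction_aa=residues["104"] + cdr3 + j_gene.aa_ungapped[0],
                fr2_tetrad="".join(residues.get(str(p), "-") for p in imgt.FR2_TETRAD),
                mutation_events=events,
                n_nongermline_cdr12=sum(
                    1 for ev in events if imgt.in_cdr12(ev.position)
                ),
                cdr3_length=cdr3_len,
                copy_number=copies,
                sequence=amplicon,
            )
        )
        clones.append(SequenceRecord(clone_id, amplicon))
    return clones, truths


def add_substitution_noise(nt: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution noise; used for noisy-recovery checks."""
    bases = "ACGT"
    out = list(nt)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        alternatives = [b for b in bases if b != out[i]]
        out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def emit_read_pairs(
    truths: list[TruthRecord],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Paired reads for every clone copy, plus a read->clone mapping table.

    R1 is the first ``read_length`` bases of the amplicon, R2 the reverse
    complement of the last ``read_length`` bases (both full-length when the
    amplicon is shorter); substitution errors are injected at the configured
    rate with a constant base quality.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rl = config.sequencing.read_length
    err = config.sequencing.error_rate
    q = config.sequencing.base_quality
    r1_out: list[SequenceRecord] = []
    r2_out: list[SequenceRecord] = []
    mapping = []
    for truth in truths:
        amp = truth.sequence
        rc = reverse_complement(amp)
        for c in range(truth.copy_number):
            read_id = f"{truth.clone_id}.{c}"
            r1 = amp[:rl]
            r2 = rc[:rl]
            if err > 0:
                r1 = add_substitution_noise(r1, err, rng)
                r2 = add_substitution_noise(r2, err, rng)
            r1_out.append(SequenceRecord(read_id, r1, [q] * len(r1)))
            r2_out.append(SequenceRecord(read_id, r2, [q] * len(r2)))
            mapping.append({"read_id": read_id, "clone_id": truth.clone_id})
    return r1_out, r2_out, pd.DataFrame(mapping, columns=["read_id", "clone_id"])


# ---------------------------------------------------------------------------
# Truth table I/O

_TRUTH_COLUMNS = [
    "clone_id", "v_call", "j_call", "productive", "cdr1_aa", "cdr2_aa",
    "cdr3_aa", "junction_aa", "fr2_tetrad", "mutation_events",
    "n_nongermline_cdr12", "cdr3_length", "copy_number", "sequence",
]


def write_truth(truths: list[TruthRecord], path) -> None:
    rows = []
    for t in truths:
        row = asdict(t)
        row["productive"] = "T" if t.productive else "F"
        row["mutation_events"] = ";".join(ev.encode() for ev in t.mutation_events)
        rows.append(row)
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TruthRecord(
                clone_id=row.clone_id,
                v_call=row.v_call,
                j_call=row.j_call,
                productive=row.productive == "T",
                cdr1_aa=row.cdr1_aa,
                cdr2_aa=row.cdr2_aa,
                cdr3_aa=row.cdr3_aa,
                junction_aa=row.junction_aa,
                fr2_tetrad=row.fr2_tetrad,
                mutation_events=[
                    MutationEvent.decode(t) for t in row.mutation_events.split(";") if t
                ],
                n_nongermline_cdr12=int(row.n_nongermline_cdr12),
                cdr3_length=int(row.cdr3_length),
                copy_number=int(row.copy_number),
                sequence=row.sequence,
            )
        )
    return out
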