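"""Repertoire statistics over annotated rearrangements.

All statistics are computed over the productive subset (the caller filters)
and every frequency table normalizes to 1 (or 100 for percentage outputs)
up to machine precision.  Per-position tables use only canonical IMGT
labels; CDR3 insertion labels (111.1, ...) contribute to CDR3 length but
not to positional tables.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from . import imgt
from .records import GAP, GermlineGene, RearrangementRecord

REDUNDANCY_BINS = [str(n) for n in range(1, 10)] + ["10+"]


def redundancy_histogram(
    records: list[RearrangementRecord], key: str = "nucleotide"
) -> dict[str, float]:
    """Percentage of reads whose sequence occurs exactly n times (n pooled
    at >=10).  Computed over reads, not unique sequences."""
    if not records:
        raise ValueError("redundancy_histogram needs at least one record")
    if key == "nucleotide":
        keys = [r.sequence for r in records]
    elif key == "amino_acid":
        keys = [r.sequence_aa for r in records]
    else:
        raise ValueError(f"unknown redundancy key {key!r}")
    mult = Counter(keys)
    out = {b: 0.0 for b in REDUNDANCY_BINS}
    total = len(keys)
    for k in keys:
        n = mult[k]
        b = str(n) if n < 10 else "10+"
        out[b] += 100.0 / total
    return out


def vj_pairing_matrix(
    records: list[RearrangementRecord], v_level: str = "family"
) -> tuple[pd.DataFrame, int]:
    """Fraction of records per (V label, J family) cell; also the number of
    records dropped for missing calls."""
    if v_level not in ("family", "gene"):
        raise ValueError(f"unknown v_level {v_level!r}")
    counts: Counter = Counter()
    dropped = 0
    for r in records:
        v = r.v_family if v_level == "family" else r.v_call
        j = r.j_family
        if not v or not j:
            dropped += 1
            continue
        counts[(v, j)] += 1
    total = sum(counts.values())
    rows = sorted({v for v, _ in counts})
    cols = sorted({j for _, j in counts})
    df = pd.DataFrame(0.0, index=rows, columns=cols)
    for (v, j), n in counts.items():
        df.loc[v, j] = n / total
    return df, dropped


def cdr_length_distribution(
    records: list[RearrangementRecord], region: str = "cdr3"
) -> dict[int, float]:
    """Length -> percentage of records, for cdr1/cdr2/cdr3."""
    if region not in ("cdr1", "cdr2", "cdr3"):
        raise ValueError(f"unknown region {region!r}")
    if not records:
        raise ValueError("cdr_length_distribution needs at least one record")
    lengths = [len(getattr(r, f"{region}_aa")) for r in records]
    counts = Counter(lengths)
    total = len(lengths)
    return {length: 100.0 * n / total for length, n in sorted(counts.items())}


def positional_composition(
    records: list[RearrangementRecord], span: tuple[int, ...]
) -> dict[str, tuple[dict[str, float], float]]:
    """Per IMGT label in ``span``: (amino acid -> frequency among occupied
    records, coverage).  Gap (unoccupied) records are excluded per position."""
    total = len(records)
    out: dict[str, tuple[dict[str, float], float]] = {}
    for p in span:
        label = str(p)
        observed = [r.numbered_residues[label] for r in records if label in r.numbered_residues]
        if not observed:
            out[label] = ({}, 0.0)
            continue
        counts = Counter(observed)
        n = len(observed)
        out[label] = (
            {aa: c / n for aa, c in sorted(counts.items())},
            n / total if total else 0.0,
        )
    return out


def fr2_tetrad_composition(
    records: list[RearrangementRecord],
) -> dict[str, tuple[dict[str, float], float]]:
    """Composition at the FR2 hallmark positions 42, 49, 50, 52."""
    return positional_composition(records, imgt.FR2_TETRAD)


def nongermline_count_distribution(records: list[RearrangementRecord]) -> dict[str, float]:
    """CDR1+CDR2 non-germline residue counts in classes {0, 1-10, >10}
    (percentages) plus the mean count."""
    if not records:
        raise ValueError("nongermline_count_distribution needs at least one record")
    counts = [r.n_nongermline_cdr12 for r in records]
    n = len(counts)
    zero = sum(1 for c in counts if c == 0)
    low = sum(1 for c in counts if 1 <= c <= 10)
    high = sum(1 for c in counts if c > 10)
    return {
        "pct_zero": 100.0 * zero / n,
        "pct_1_10": 100.0 * low / n,
        "pct_gt10": 100.0 * high / n,
        "mean": sum(counts) / n,
    }


@dataclass
class VariabilityProfile:
    """Wu-Kabat positional variability: V_p = k_p / f_max_p with k_p the
    number of distinct residues and f_max_p the modal residue frequency."""

    positions: dict[str, float]
    k: dict[str, int]
    f_max: dict[str, float]
    n: dict[str, int]


def wu_kabat_profile(
    columns: dict[str, list[str]], min_coverage_n: int = 1
) -> VariabilityProfile:
    """Wu-Kabat index per position from residue columns (gaps excluded
    beforehand); positions observed fewer than ``min_coverage_n`` times are
    reported as undefined (absent)."""
    if not any(columns.values()):
        raise ValueError("wu_kabat_profile needs at least one observation")
    v: dict[str, float] = {}
    kk: dict[str, int] = {}
    fm: dict[str, float] = {}
    nn: dict[str, int] = {}
    for label, residues in columns.items():
        if len(residues) < min_coverage_n:
            continue
        counts = Counter(residues)
        k = len(counts)
        f_max = max(counts.values()) / len(residues)
        v[label] = k / f_max
        kk[label] = k
        fm[label] = f_max
        nn[label] = len(residues)
    return VariabilityProfile(v, kk, fm, nn)


def residue_columns(
    records: list[RearrangementRecord], min_coverage: float = 0.01
) -> dict[str, list[str]]:
    """Residue columns per canonical IMGT label over a record table;
    positions occupied in fewer than ``min_coverage`` of records dropped."""
    cols: dict[str, list[str]] = defaultdict(list)
    for r in records:
        for label, aa in r.numbered_residues.items():
            if "." not in label:
                cols[label].append(aa)
    n = len(records)
    return {
        label: v
        for label, v in cols.items()
        if n == 0 or len(v) / n >= min_coverage
    }


def germline_columns(v_genes: list[GermlineGene]) -> dict[str, list[str]]:
    """Residue columns of the germline V set (IMGT 1-104, gaps excluded)."""
    cols: dict[str, list[str]] = defaultdict(list)
    for g in v_genes:
        for col, aa in enumerate(g.aa_gapped):
            if aa != GAP:
                cols[str(col + 1)].append(aa)
    return dict(cols)


def mutation_frequency_profile(
    records: list[RearrangementRecord],
) -> dict[str, dict[str, float]]:
    """Per canonical position: substitution frequency (events / records
    occupying the position) and insertion frequency (events / total records
    — germline gap positions have no occupancy in the germline)."""
    total = len(records)
    sub_events: Counter = Counter()
    ins_events: Counter = Counter()
    occupancy: Counter = Counter()
    for r in records:
        for label in r.numbered_residues:
            if "." not in label:
                occupancy[label] += 1
        for ev in r.mutation_events:
            if ev.kind == "substitution":
                sub_events[ev.position] += 1
            elif ev.kind == "insertion":
                ins_events[ev.position] += 1
    out: dict[str, dict[str, float]] = {}
    labels = set(sub_events) | set(ins_events) | set(occupancy)
    for label in sorted(labels, key=imgt.label_sort_key):
        sub = sub_events[label] / occupancy[label] if occupancy[label] else 0.0
        ins = ins_events[label] / total if total else 0.0
        out[label] = {"substitution": sub, "insertion": ins}
    return out


def mutated_residue_composition(
    records: list[RearrangementRecord], kind: str = "substitution"
) -> dict[str, dict[str, float]]:
    """Per position, amino-acid frequencies among events of one kind; zero
    events yield an empty table."""
    if kind not in ("substitution", "insertion"):
        raise ValueError(f"unknown mutation kind {kind!r}")
    per_pos: dict[str, Counter] = defaultdict(Counter)
    for r in records:
        for ev in r.mutation_events:
            if ev.kind == kind:
                per_pos[ev.position][ev.observed_aa] += 1
    out: dict[str, dict[str, float]] = {}
    for label in sorted(per_pos, key=imgt.label_sort_key):
        counts = per_pos[label]
        n = sum(counts.values())
        out[label] = {aa: c / n for aa, c in sorted(counts.items())}
    return out


# ---------------------------------------------------------------------------
# Consolidated profile


@dataclass
class RepertoireProfile:
    """The statistics bundle for one productive-record table."""

    n_records: int
    redundancy: dict[str, float]
    vj_family: pd.DataFrame
    vj_gene: pd.DataFrame
    vj_dropped: int
    cdr_lengths: dict[str, dict[int, float]]
    cdr_composition: dict[str, dict[str, tuple[dict[str, float], float]]]
    fr2_tetrad: dict[str, tuple[dict[str, float], float]]
    nongermline: dict[str, float]
    variability_library: VariabilityProfile
    variability_germline: VariabilityProfile
    mutation_frequency: dict[str, dict[str, float]]
    substituted_composition: dict[str, dict[str, float]]
    inserted_composition: dict[str, dict[str, float]]

    def to_json_dict(self) -> dict:
        def comp(table):
            return {
                label: {"composition": freqs, "coverage": cov}
                for label, (freqs, cov) in table.items()
            }

        return {
            "n_records": self.n_records,
            "redundancy_pct": self.redundancy,
            "vj_family_fraction": {
                v: {j: self.vj_family.loc[v, j] for j in self.vj_family.columns}
                for v in self.vj_family.index
            },
            "vj_gene_fraction": {
                v: {j: self.vj_gene.loc[v, j] for j in self.vj_gene.columns}
                for v in self.vj_gene.index
            },
            "vj_dropped": self.vj_dropped,
            "cdr_length_pct": self.cdr_lengths,
            "cdr_composition": {k: comp(v) for k, v in self.cdr_composition.items()},
            "fr2_tetrad": comp(self.fr2_tetrad),
            "nongermline_cdr12": self.nongermline,
            "variability_library": self.variability_library.positions,
            "variability_germline": self.variability_germline.positions,
            "mutation_frequency": self.mutation_frequency,
            "substituted_residue_composition": self.substituted_composition,
            "inserted_residue_composition": self.inserted_composition,
        }

    def write_tsvs(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.Series(self.redundancy, name="pct_reads").rename_axis("multiplicity").to_csv(
            outdir / "redundancy.tsv", sep="\t"
        )
        self.vj_family.rename_axis("v_family").to_csv(outdir / "vj_family.tsv", sep="\t")
        self.vj_gene.rename_axis("v_call").to_csv(outdir / "vj_gene.tsv", sep="\t")
        rows = []
        for region, table in self.cdr_lengths.items():
            for length, pct in table.items():
                rows.append({"region": region, "length": length, "pct": pct})
        pd.DataFrame(rows).to_csv(outdir / "cdr_lengths.tsv", sep="\t", index=False)
        rows = []
        for region, table in self.cdr_composition.items():
            for label, (freqs, cov) in table.items():
                for aa, f in freqs.items():
                    rows.append(
                        {"region": region, "position": label, "aa": aa,
                         "frequency": f, "coverage": cov}
                    )
        for label, (freqs, cov) in self.fr2_tetrad.items():
            for aa, f in freqs.items():
                rows.append(
                    {"region": "fr2_tetrad", "position": label, "aa": aa,
                     "frequency": f, "coverage": cov}
                )
        pd.DataFrame(rows).to_csv(outdir / "positional_composition.tsv", sep="\t", index=False)
        rows = [
            {"position": label,
             "substitution_frequency": v["substitution"],
             "insertion_frequency": v["insertion"]}
            for label, v in self.mutation_frequency.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "mutation_frequency.tsv", sep="\t", index=False)
        rows = []
        for kind, table in (
            ("substitution", self.substituted_composition),
            ("insertion", self.inserted_composition),
        ):
            for label, freqs in table.items():
                for aa, f in freqs.items():
                    rows.append({"kind": kind, "position": label, "aa": aa, "frequency": f})
        pd.DataFrame(rows).to_csv(outdir / "mutated_residue_composition.tsv", sep="\t", index=False)
        lib = self.variability_library
        germ = self.variability_germline
        rows = [
            {"position": label, "set": "library", "k": lib.k[label],
             "f_max": lib.f_max[label], "variability": lib.positions[label]}
            for label in lib.positions
        ] + [
            {"position": label, "set": "germline", "k": germ.k[label],
             "f_max": germ.f_max[label], "variability": germ.positions[label]}
            for label in germ.positions
        ]
        pd.DataFrame(rows).to_csv(outdir / "variability.tsv", sep="\t", index=False)


def compute_profile(
    productive: list[RearrangementRecord],
    v_genes: list[GermlineGene],
    redundancy_key: str = "nucleotide",
) -> RepertoireProfile:
    """All repertoire statistics for a productive record table."""
    if not productive:
        raise ValueError("compute_profile needs at least one productive record")
    vj_family, dropped = vj_pairing_matrix(productive, "family")
    vj_gene, _ = vj_pairing_matrix(productive, "gene")
    n = len(productive)
    min_cov_n = max(1, int(0.01 * n))
    return RepertoireProfile(
        n_records=n,
        redundancy=redundancy_histogram(productive, redundancy_key),
        vj_family=vj_family,
        vj_gene=vj_gene,
        vj_dropped=dropped,
        cdr_lengths={
            region: cdr_length_distribution(productive, region)
            for region in ("cdr1", "cdr2", "cdr3")
        },
        cdr_composition={
            "cdr1": positional_composition(productive, imgt.CDR1_SPAN),
            "cdr2": positional_composition(productive, imgt.CDR2_SPAN),
            "cdr3": positional_composition(productive, imgt.CDR3_SPAN),
        },
        fr2_tetrad=fr2_tetrad_composition(productive),
        nongermline=nongermline_count_distribution(productive),
        variability_library=wu_kabat_profile(
            residue_columns(productive), min_coverage_n=min_cov_n
        ),
        variability_germline=wu_kabat_profile(germline_columns(v_genes)),
        mutation_frequency=mutation_frequency_profile(productive),
        substituted_composition=mutated_residue_composition(productive, "substitution"),
        inserted_composition=mutated_residue_composition(productive, "insertion"),
    )
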