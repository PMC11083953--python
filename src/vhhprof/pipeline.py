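"""End-to-end orchestration: simulate -> preprocess -> annotate -> repstats.

Each run writes an AIRR rearrangement table for every annotated read, the
statistics bundle computed from the productive subset, a funnel summary and
the effective configuration, so any stage can be re-run or audited from its
on-disk outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io, repstats
from .annotate import AnnotationParams, annotate_all
from .preprocess import FunnelCounts, PreprocessParams, PrimerSpec, pair_streams, preprocess_pairs
from .records import GermlineGene, RearrangementRecord
from .simulate import SimulationConfig, build_toy_reference, emit_read_pairs, simulate_repertoire, write_truth

logger = logging.getLogger("vhhprof")


@dataclass
class RunConfig:
    r1: str | None = None
    r2: str | None = None
    merged: str | None = None  # pre-merged FASTA alternative to r1/r2
    germline: str | None = None  # None = packaged toy reference
    out_dir: str = "vhhprof_out"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    redundancy_key: str = "nucleotide"
    include_nonproductive_stats: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.merged is None and (self.r1 is None or self.r2 is None):
            raise ValueError("either --r1/--r2 or a pre-merged FASTA is required")
        for path in (self.r1, self.r2, self.merged, self.germline):
            if path is not None and not Path(path).exists():
                raise ValueError(f"input path does not exist: {path}")

    def effective_dict(self) -> dict:
        return {
            "r1": self.r1,
            "r2": self.r2,
            "merged": self.merged,
            "germline": self.germline,
            "out_dir": self.out_dir,
            "min_overlap": self.preprocess.min_overlap,
            "max_mismatch_frac": self.preprocess.max_mismatch_frac,
            "primer_forward": self.preprocess.primers.forward,
            "primer_reverse": self.preprocess.primers.reverse,
            "primer_max_mismatches": self.preprocess.primers.max_mismatches,
            "trim_primers": self.preprocess.trim_primers,
            "v_identity_floor": self.annotation.v_identity_floor,
            "redundancy_key": self.redundancy_key,
            "include_nonproductive_stats": self.include_nonproductive_stats,
            "seed": self.seed,
        }


@dataclass
class SummaryReport:
    total_pairs: int = 0
    merged: int = 0
    primer_pass: int = 0
    annotated: int = 0
    productive: int = 0
    used_in_statistics: int = 0
    outputs: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "funnel": {
                "total_pairs": self.total_pairs,
                "merged": self.merged,
                "primer_pass": self.primer_pass,
                "annotated": self.annotated,
                "productive": self.productive,
                "used_in_statistics": self.used_in_statistics,
            },
            "outputs": self.outputs,
            "seed": self.seed,
        }


def _load_germline(path: str | None) -> tuple[list[GermlineGene], list[GermlineGene]]:
    if path is None:
        from .simulate import toy_reference

        return toy_reference()
    genes = io.read_germline_reference(path)
    v = [g for g in genes if g.segment_type == "V"]
    j = [g for g in genes if g.segment_type == "J"]
    if not v or not j:
        raise io.ReferenceError("germline reference needs at least one V and one J gene")
    return v, j


def _write_statistics(
    records: list[RearrangementRecord],
    v_genes: list[GermlineGene],
    out_dir: Path,
    redundancy_key: str,
) -> dict[str, str]:
    stats_dir = out_dir / "stats"
    profile = repstats.compute_profile(records, v_genes, redundancy_key)
    profile.write_tsvs(stats_dir)
    io.write_json(profile.to_json_dict(), stats_dir / "profile.json")
    return {"stats_dir": str(stats_dir), "profile_json": str(stats_dir / "profile.json")}


def run_profile(config: RunConfig) -> SummaryReport:
    """Full analysis of a sequenced library: merge, filter, annotate, profile."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_json(config.effective_dict(), out_dir / "config.json")
    v_genes, j_genes = _load_germline(config.germline)

    counts = FunnelCounts()
    if config.merged is not None:
        kept = list(io.read_fasta(config.merged))
        counts.total_pairs = counts.merged = counts.primer_pass = len(kept)
    else:
        pairs = pair_streams(io.read_fastq(config.r1), io.read_fastq(config.r2))
        kept = list(preprocess_pairs(pairs, config.preprocess, counts))
    logger.info(
        "preprocess: %d pairs, %d merged, %d primer-pass",
        counts.total_pairs, counts.merged, counts.primer_pass,
    )

    kept_path = out_dir / "kept.fasta"
    io.write_fasta(kept, kept_path)

    annotated = annotate_all(kept, v_genes, j_genes, config.annotation)
    rearr_path = out_dir / "rearrangements.tsv"
    io.write_rearrangements(annotated, rearr_path)
    productive = [r for r in annotated if r.productive]
    logger.info("annotate: %d records, %d productive", len(annotated), len(productive))

    report = SummaryReport(
        total_pairs=counts.total_pairs,
        merged=counts.merged,
        primer_pass=counts.primer_pass,
        annotated=len(annotated),
        productive=len(productive),
        used_in_statistics=0,
        outputs={"rearrangements": str(rearr_path), "kept": str(kept_path)},
        seed=config.seed,
    )
    stats_input = annotated if config.include_nonproductive_stats else productive
    if stats_input:
        report.outputs.update(
            _write_statistics(stats_input, v_genes, out_dir, config.redundancy_key)
        )
        report.used_in_statistics = len(stats_input)
    else:
        logger.warning("no productive records: statistics skipped")
        report.outputs["statistics"] = "skipped: no productive records"
    io.write_json(report.as_dict(), out_dir / "summary.json")
    return report


def run_simulate(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Simulate a repertoire and write FASTQ pairs + truth + config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clones, truths = simulate_repertoire(config)
    r1, r2, mapping = emit_read_pairs(truths, config)
    paths = {
        "r1": str(out_dir / "reads_R1.fastq.gz"),
        "r2": str(out_dir / "reads_R2.fastq.gz"),
        "truth": str(out_dir / "truth.tsv"),
        "read_map": str(out_dir / "read_map.tsv"),
        "germline": str(build_toy_reference(out_dir)),
        "config": str(out_dir / "sim_config.json"),
    }
    io.write_fastq(r1, paths["r1"])
    io.write_fastq(r2, paths["r2"])
    write_truth(truths, paths["truth"])
    mapping.to_csv(paths["read_map"], sep="\t", index=False)
    io.write_json(_config_echo(config), paths["config"])
    logger.info("simulated %d clones -> %d read pairs", len(truths), len(r1))
    return paths


def _config_echo(config: SimulationConfig) -> dict:
    return {
        "n_clones": config.n_clones,
        "v_usage": config.v_usage,
        "j_usage": config.j_usage,
        "cdr3_length_law": {str(k): v for k, v in config.cdr3_length_law.items()},
        "junction_residue_law": config.junction_residue_law,
        "substitution_rates": {
            str(k): v for k, v in config.shm.substitution_rates.items()
        },
        "insertion_count_laws": {
            r: {str(k): v for k, v in law.items()}
            for r, law in config.shm.insertion_count_laws.items()
        },
        "inserted_residue_law": config.shm.inserted_residue_law,
        "mutability_law": {str(k): v for k, v in config.shm.mutability_law.items()},
        "unmutated_fraction": config.shm.unmutated_fraction,
        "singleton_prob": config.clone_size.singleton_prob,
        "extra_poisson_mean": config.clone_size.extra_poisson_mean,
        "read_length": config.sequencing.read_length,
        "error_rate": config.sequencing.error_rate,
        "base_quality": config.sequencing.base_quality,
        "nonproductive_rate": config.nonproductive_rate,
        "seed": config.seed,
    }


def run_report(rearrangements_path, out_dir, germline: str | None = None,
               include_nonproductive: bool = False,
               redundancy_key: str = "nucleotide") -> dict[str, str]:
    """Recompute the statistics bundle from an existing annotation table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = io.read_rearrangements(rearrangements_path)
    v_genes, _ = _load_germline(germline)
    subset = records if include_nonproductive else [r for r in records if r.productive]
    if not subset:
        logger.warning("no productive records: statistics skipped")
        io.write_json({"statistics": "skipped: no productive records"}, out_dir / "summary.json")
        return {}
    return _write_statistics(subset, v_genes, out_dir, redundancy_key)
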