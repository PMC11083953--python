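# Methods

`vhhprof` reconstructs, at desk scale, the analysis path used to profile a
camelid VHH (nanobody) phage-display library by amplicon sequencing: paired
reads are merged, filtered for the Sfi I cloning-primer motifs, assigned to
germline V and J genes, numbered in the IMGT scheme, and summarized into the
repertoire statistics of such a study (redundancy, V/J pairing, CDR length
and composition, FR2 hallmark tetrad, positional variability, somatic
hypermutation hotspots). Because raw reads from real libraries of this kind
are rarely deposited, the package ships a generative simulator whose ground
truth makes every stage testable.

## Read merging

R1/R2 mates are merged by scanning every overlap offset of at least
`min_overlap` (default 20 nt) and maximizing `matches − mismatches`; ties
prefer the longer overlap. The merge succeeds when the best offset's
mismatch fraction is ≤ `max_mismatch_frac` (default 0.1). Within the
overlap each column takes the base with the higher Phred quality (ties go
to R1; the consensus quality is the maximum of the two). These two
parameters are stated, configurable stand-ins for a read merger's defaults;
no overlap-significance test is performed — the score threshold replaces
it. Pairs that fail to merge are counted and discarded.

## Primer filtering

A merged sequence is kept only when the forward Sfi I motif
(`GGCCCAGGCGGCC`) occurs within the first 60 nt and the reverse complement
of the reverse motif (`GGCCAGGCCGGCC`) within the last 60 nt, each with at
most one mismatch (configurable); both strand orientations are tried and
the output is normalized to the forward strand. Primer bases are retained
by default — they are part of the cloned amplicon and anchor the reading
frame — with a flag to trim them.

## Germline assignment and alignment

V and J genes are called by nucleotide fitting alignment (reference
consumed end to end, query overhangs free) with affine gaps: match +2,
mismatch −3, gap open −5, gap extend −2 (a gap of length k costs 5 + 2k).
Best score wins; ties resolve by higher identity, then lexicographically
smallest gene name, so output is independent of reference order. The J
search runs on the region 3′ of the V alignment and requires at least 15 nt
of suffix. A V identity below 0.60 flags the record and stops further
interpretation, an IgBLAST-like permissiveness floor. The dynamic program
is JIT-compiled with numba; candidate ranking uses a score-only rolling-row
variant and only the winner is traced back.

## Frame selection

The reading frame is the majority codon phase `(q − r) mod 3` over the
aligned columns of the best V hit. When the amplicon begins at the
in-frame forward primer this equals the primer-implied frame; it stays well
defined when primers were trimmed or mismatched, and a majority vote is
robust to a few columns aligned out of phase.

## IMGT numbering

Germline-occupied framework and FR3 positions take the IMGT label of the
reference codon their middle nucleotide aligns to. The hypervariable
regions are numbered positionally, as IMGT numbers loops, not by alignment
columns:

* **CDR1/CDR2** — the query codons between the flanking framework anchors
  form the loop; its last R residues keep the gene's trailing occupied
  labels (the 3′ stem), and the remainder fills from the span start through
  the germline gap stretch left to right. Each boundary anchor is a
  majority vote over six framework positions, and the V terminal labels
  (1–3, 102–104) are re-lifted the same way, because a single alignment
  column next to a hypervariable stretch (or a mutated terminal codon) can
  slide. Numbering loops positionally is what makes mutation calls
  well-defined: a parsimony alignment inside a loop can otherwise
  reinterpret an insertion next to a substitution.
* **CDR3** — the residues between the conserved Cys104 and the J-encoded
  Trp118 fill outside-in from 105 and 117; the 5′ half keeps
  ⌈L/2⌉ positions, and loops longer than 13 receive insertion labels
  between 111 and 112 (111.1 first, then 112.1, …).

Mutation events are per-position comparisons against the gapped germline V
over IMGT 1–104: both occupied and different → substitution; query-only at
a germline gap → insertion; germline-only → deletion. Deletions are
recorded but excluded from the non-germline CDR1+CDR2 count, which covers
substitutions and insertions only. CDR3 is excluded from germline
comparison, and CDR3 insertion labels contribute to length but not to
positional tables.

## Productivity

A record is productive iff no flag fires: stop codon in the translation,
junction length not divisible by 3, a missing CDR, a missing/incorrect
Cys104 or Trp/Phe118 anchor, or V identity below the floor. This flag set
is a stated approximation of an annotator's internal productivity rules.
Only productive records enter statistics (a diagnostics flag includes the
rest).

## Statistics

All frequency tables normalize to 1 (or 100%) to machine precision.
Redundancy is computed over reads (not unique clones), keyed by the trimmed
nucleotide sequence by default (amino-acid mode available). The
variability index is the Wu–Kabat index k/f_max — the standard positional
index on a 1–400 scale, matching the magnitudes such studies report —
computed for both the library and the germline set; positions covered in
fewer than 1% of records are undefined. Substitution frequency at a
position divides by the records occupying it; insertion frequency divides
by all records, since germline gap positions have no occupancy — the
denominators are stated because figure conventions in the literature often
are not.

## The simulator

Each clone draws a V and J gene from usage laws (IGHV3 ≈ 96%, IGHJ4 = 75%
by default, putting ≈72% of clones in the IGHV3×IGHJ4 cell), a CDR3 length
from a law supported on [5, 31] with mode 9 and a ~6% plateau over 10–21,
and junction residues from a 20-letter law (A/Y/G/R-rich). Somatic
hypermutation applies per-position substitution probabilities over IMGT
1–104 (0.3–0.5 in the CDRs, 0.02 in frameworks, 0 at Cys23/Trp41/Arg50/
Cys104), insertion-count laws at the germline gap stretches (CDR1 32–35,
mean 0.59; CDR2 60–61(62), mean 0.22) with residues from a glycine-rich
law, a per-clone mutability factor f ∈ {0.4, 0.8, 1.2, 2.0} (E[f] = 1,
rates capped at 0.95) giving the over-dispersed mutation-count distribution
real repertoires show, and a 0.4% exactly-germline clone fraction. The
config-implied marginals (per-position rates, mean non-germline count
≈ 6.9, singleton read fraction = 92%) are computed in code
(`expected_substitution_rate`, `expected_nongermline_mean`,
`expected_singleton_read_fraction`) and are what recovery tests compare
against. Clone sizes are 1 with probability 0.9664, else 2 + Poisson(0.5),
which puts 92% of reads in singleton clones. Inserted residues are placed
left-to-right from the start of their gap stretch, the same convention the
annotator uses, so truth labels are recoverable.

The toy germline reference is 6 IMGT-gapped V genes in 3 families and 4 J
genes. Sibling genes differ both at a handful of amino acids and at many
silent codon positions (each gene mixes two synonymous codon tables in its
own pattern, as real alleles differ), which keeps gene-level assignment
stable under heavy hypermutation; the simulator copies unmutated codons
from the gene so silent sites stay intact.

Sequencing is modelled as substitution-only errors at 10⁻³ per base with
constant Q30 (a coherent MiSeq-like figure) on 300-nt paired reads; no
indel errors, quality-by-cycle profiles, chimeras, or PCR bias. Parameter-
recovery runs and the acceptance script set the error rate to 0 so that
read-level redundancy and per-position mutation estimates measure the
generative repertoire rather than sequencing noise — with errors on,
nucleotide-level duplicate classes splinter and the measured singleton
fraction exceeds the generating one, exactly as it would on real data.

## Problem sizes and numerical choices

The standard verification sizes are: 1,000 random merge instances and 500
alignment instances against brute-force oracles; 5,000 clones for exact
recovery at zero mutation/error; 1,000 clones at 5% per-base noise for
family-level recovery (≥99%); 100 random tables for statistic-oracle
equivalence; and one 20,000-clone end-to-end run for parameter recovery,
with binomial/CLT 99% intervals computed at clone level (reads within a
clone are duplicates, not independent draws). Where a family of quantities
is checked simultaneously — per-position rates, per-length probabilities,
pairing cells — the intervals carry family-wise 99% coverage
(Šidák-corrected per comparison); marginal 99% intervals over ~65
simultaneous comparisons would be missed by about half of all seeds even
for a perfect implementation. The pipeline's per-clone CDR mutation events
are additionally required to equal the generator's ground truth for at
least 99.8% of clones, a sharper check than any interval. All randomness flows through
seeded numpy generators; simulation output is byte-identical across runs
for a fixed seed.

## Known limitations

* Event-level mutation recovery is exact for ~99.8% of heavily mutated
  clones; the residue cases are substituted framework codons that the
  alignment renders as a gap pair (e.g. a deletion plus a shifted
  substitution), confined to framework positions with 0.02 rates.
* D segments are not modelled or called; junction nucleotides are treated
  as a residue-level law, with no templated/non-templated decomposition.
* Allele-level (*01-style) resolution, clonal lineage inference and
  phylogenetic SHM analysis are out of scope.
* The toy reference is a packaged fixture; a user-supplied IMGT-gapped
  reference in the same dialect is supported but not bundled.
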