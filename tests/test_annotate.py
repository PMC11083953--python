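import numpy as np
import pytest

from vhhprof import imgt
from vhhprof.annotate import (
    AnnotationParams,
    NumberingResult,
    Regions,
    annotate_all,
    annotate_sequence,
    assign_j,
    assign_v,
    check_productivity,
    classify_mutations,
    extract_regions,
    translate,
)
from vhhprof.records import GermlineGene, SequenceRecord
from vhhprof.simulate import (
    SimulationConfig,
    add_substitution_noise,
    simulate_repertoire,
)


class TestTranslate:
    @pytest.mark.parametrize(
        "nt, frame, expected",
        [
            ("ATGTAA", 0, "M*"),
            ("ATGGCC", 0, "MA"),
            ("AATGGCC", 1, "MA"),
            ("ATGGC", 0, "M"),  # trailing partial codon dropped
            ("ATNGCC", 0, "XA"),
            ("", 0, ""),
        ],
    )
    def test_known_values(self, nt, frame, expected):
        assert translate(nt, frame) == expected

    def test_bad_frame_rejected(self):
        with pytest.raises(ValueError):
            translate("ATG", 3)


class TestImgtLabels:
    def test_cdr3_length_9_outside_in(self):
        assert imgt.cdr3_labels(9) == [
            "105", "106", "107", "108", "109", "114", "115", "116", "117",
        ]

    def test_cdr3_length_13_exact_capacity(self):
        assert imgt.cdr3_labels(13) == [str(p) for p in range(105, 118)]

    def test_cdr3_length_15_insertion_labels(self):
        labels = imgt.cdr3_labels(15)
        assert labels == (
            [str(p) for p in range(105, 112)]
            + ["111.1", "112.1"]
            + [str(p) for p in range(112, 118)]
        )

    def test_label_order_is_total_and_consistent(self):
        labels = imgt.cdr3_labels(31)
        assert sorted(labels, key=imgt.label_sort_key) == labels


class TestAssignGenes:
    def test_exact_match_recovery(self, germline):
        v_genes, j_genes = germline
        for g in v_genes:
            call, family, aln = assign_v(g.ungapped, v_genes)
            assert call == g.name and family == g.family
            assert aln.identity == 1.0
        for g in j_genes:
            hit = assign_j(g.ungapped + "GCCGGC", j_genes)
            assert hit is not None and hit[0] == g.name

    def test_tie_broken_to_lexicographically_smaller_name(self, germline):
        v_genes, _ = germline
        twin_b = GermlineGene("IGHV9B", "IGHV9", "V", v_genes[0].gapped_sequence)
        twin_a = GermlineGene("IGHV9A", "IGHV9", "V", v_genes[0].gapped_sequence)
        call, _, _ = assign_v(v_genes[0].ungapped, [twin_b, twin_a])
        assert call == "IGHV9A"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            assign_v("ACGT", [])

    def test_short_suffix_gives_no_j_call(self, germline):
        _, j_genes = germline
        assert assign_j("ACGTACGTAC", j_genes) is None

    def test_family_recovery_under_noise(self, germline, rng):
        v_genes, j_genes = germline
        ok = 0
        n = 60
        for i in range(n):
            g = v_genes[i % len(v_genes)]
            noisy = add_substitution_noise(g.ungapped, 0.05, rng)
            _, family, _ = assign_v(noisy, v_genes)
            ok += family == g.family
        assert ok == n


class TestClassifyMutations:
    def test_identity_gives_no_events(self, germline):
        v_genes, _ = germline
        g = v_genes[0]
        residues = {
            str(c + 1): aa for c, aa in enumerate(g.aa_gapped) if aa != "."
        }
        assert classify_mutations(residues, g) == []

    def test_insertion_at_germline_gap(self, germline):
        v_genes, _ = germline
        g = v_genes[0]  # CDR1 gaps at 32-35
        residues = {
            str(c + 1): aa for c, aa in enumerate(g.aa_gapped) if aa != "."
        }
        residues["33"] = "G"
        events = classify_mutations(residues, g)
        assert len(events) == 1
        ev = events[0]
        assert (ev.position, ev.kind, ev.germline_aa, ev.observed_aa) == (
            "33", "insertion", "-", "G"
        )

    def test_substitution_and_deletion(self, germline):
        v_genes, _ = germline
        g = v_genes[0]
        residues = {
            str(c + 1): aa for c, aa in enumerate(g.aa_gapped) if aa != "."
        }
        germ_59 = residues["59"]
        residues["59"] = "D"
        del residues["72"]
        events = classify_mutations(residues, g)
        kinds = {(ev.position, ev.kind) for ev in events}
        assert ("59", "substitution") in kinds
        assert ("72", "deletion") in kinds
        sub = next(ev for ev in events if ev.position == "59")
        assert (sub.germline_aa, sub.observed_aa) == (germ_59, "D")


class TestExtractRegions:
    def _numbered(self, residues):
        return NumberingResult(residues, 0, None, None, None)

    def test_eight_residue_cdr1(self):
        residues = {str(p): "A" for p in (27, 28, 29, 30, 31, 32, 33, 34)}
        regions = extract_regions(self._numbered(residues))
        assert len(regions.cdr1_aa) == 8

    def test_empty_spans_give_empty_strings(self):
        regions = extract_regions(self._numbered({"1": "Q"}))
        assert regions.cdr1_aa == regions.cdr2_aa == regions.cdr3_aa == ""

    def test_tetrad_string(self):
        residues = {"42": "Y", "49": "E", "50": "R", "52": "L"}
        assert extract_regions(self._numbered(residues)).fr2_tetrad == "YERL"

    def test_tetrad_reports_dash_for_unoccupied(self):
        residues = {"42": "Y", "50": "R"}
        assert extract_regions(self._numbered(residues)).fr2_tetrad == "Y-R-"


class TestProductivity:
    def _regions(self, **kw):
        base = dict(cdr1_aa="GRTFSSYA", cdr2_aa="INSGGSTY", cdr3_aa="AKDY",
                    fr2_tetrad="YERL", junction_aa="CAKDYW")
        base.update(kw)
        return Regions(**base)

    def _numbered(self):
        return NumberingResult({"104": "C", "118": "W"}, 0, 300, 330, 33)

    def test_clean_record_is_productive(self):
        rep = check_productivity(self._numbered(), self._regions(), "MAQ", 33, 0.95)
        assert rep.productive and rep.reasons == []

    def test_stop_codon_flagged(self):
        rep = check_productivity(self._numbered(), self._regions(), "MA*Q", 33, 0.95)
        assert "stop_codon" in rep.reasons and not rep.productive

    def test_out_of_frame_junction_flagged(self):
        rep = check_productivity(self._numbered(), self._regions(), "MAQ", 32, 0.95)
        assert "out_of_frame_junction" in rep.reasons

    def test_missing_cdr_flagged(self):
        rep = check_productivity(
            self._numbered(), self._regions(cdr2_aa=""), "MAQ", 33, 0.95
        )
        assert "missing_cdr" in rep.reasons

    def test_low_v_identity_flagged(self):
        rep = check_productivity(self._numbered(), self._regions(), "MAQ", 33, 0.5)
        assert "low_v_identity" in rep.reasons


class TestAnnotateSequence:
    def test_random_garbage_fails_v_identity(self, germline, rng):
        v_genes, j_genes = germline
        garbage = "".join(rng.choice(list("ACGT"), 400))
        rec = annotate_sequence(SequenceRecord("g", garbage), v_genes, j_genes)
        assert not rec.productive
        assert "low_v_identity" in rec.fail_reasons

    def test_simulated_clones_match_truth(self, small_repertoire, germline):
        _, clones, truths, records = small_repertoire
        for rec, truth in zip(records, truths):
            assert rec.v_call == truth.v_call
            assert rec.j_call == truth.j_call
            assert rec.cdr1_aa == truth.cdr1_aa
            assert rec.cdr2_aa == truth.cdr2_aa
            assert rec.cdr3_aa == truth.cdr3_aa
            assert rec.junction_aa == truth.junction_aa
            assert rec.fr2_tetrad == truth.fr2_tetrad
            assert rec.productive == truth.productive
            assert rec.n_nongermline_cdr12 == truth.n_nongermline_cdr12

    def test_numbering_order_consistency(self, small_repertoire):
        """Concatenating residues in IMGT order reproduces the translation
        over the numbered span."""
        _, _, _, records = small_repertoire
        for rec in records[:100]:
            if not rec.productive:
                continue
            labels = sorted(rec.numbered_residues, key=imgt.label_sort_key)
            concat = "".join(rec.numbered_residues[lab] for lab in labels)
            assert concat in rec.sequence_aa

    def test_mutation_event_conservation(self, small_repertoire):
        _, _, _, records = small_repertoire
        for rec in records:
            subs = sum(1 for e in rec.mutation_events if e.kind == "substitution")
            ins = sum(1 for e in rec.mutation_events if e.kind == "insertion")
            dels = sum(1 for e in rec.mutation_events if e.kind == "deletion")
            assert subs + ins + dels == len(rec.mutation_events)
            assert rec.n_nongermline_cdr12 == sum(
                1
                for e in rec.mutation_events
                if e.kind in ("substitution", "insertion") and imgt.in_cdr12(e.position)
            )

    def test_cdr3_insertion_labels_for_long_junctions(self, germline):
        v_genes, j_genes = germline
        cfg = SimulationConfig(n_clones=6, seed=21)
        cfg.shm = cfg.shm.zeroed()
        cfg.sequencing.error_rate = 0.0
        cfg.cdr3_length_law = {15: 1.0}
        clones, truths = simulate_repertoire(cfg)
        recs = annotate_all(clones, v_genes, j_genes)
        for rec, truth in zip(recs, truths):
            assert rec.cdr3_aa == truth.cdr3_aa
            assert "111.1" in rec.numbered_residues
            assert "112.1" in rec.numbered_residues

    def test_injected_nonproductive_clones_flagged(self, germline):
        v_genes, j_genes = germline
        cfg = SimulationConfig(n_clones=40, seed=17, nonproductive_rate=1.0)
        cfg.sequencing.error_rate = 0.0
        clones, truths = simulate_repertoire(cfg)
        recs = annotate_all(clones, v_genes, j_genes)
        assert all(not t.productive for t in truths)
        for rec in recs:
            assert not rec.productive
            assert set(rec.fail_reasons) & {
                "stop_codon", "out_of_frame_junction", "missing_cdr",
                "missing_anchor_104", "missing_anchor_118", "numbering_failed",
            }
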