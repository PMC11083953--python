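import math
import random

import numpy as np
import pytest

from vhhprof import imgt, repstats
from vhhprof.records import MutationEvent, RearrangementRecord

from . import oracles


def _record(i, sequence="A", v_call="IGHV3S53", v_family="IGHV3",
            j_call="IGHJ4", j_family="IGHJ4", cdr3_aa="AKDY",
            numbered=None, events=None, n_cdr12=0):
    return RearrangementRecord(
        sequence_id=f"r{i}",
        sequence=sequence,
        sequence_aa="M",
        v_call=v_call,
        j_call=j_call,
        v_family=v_family,
        j_family=j_family,
        productive=True,
        cdr1_aa="GRTFSSYA",
        cdr2_aa="INSGGSTY",
        cdr3_aa=cdr3_aa,
        junction_aa="C" + cdr3_aa + "W",
        fr2_tetrad="YERL",
        numbered_residues=numbered or {},
        mutation_events=events or [],
        n_nongermline_cdr12=n_cdr12,
    )


class TestRedundancy:
    def test_hand_count(self):
        recs = [_record(0, "A"), _record(1, "A"), _record(2, "B")]
        hist = repstats.redundancy_histogram(recs)
        assert hist["1"] == pytest.approx(100 / 3)
        assert hist["2"] == pytest.approx(200 / 3)

    def test_all_distinct(self):
        recs = [_record(i, f"A{'C' * i}") for i in range(5)]
        assert repstats.redundancy_histogram(recs)["1"] == pytest.approx(100.0)

    def test_pooled_bin(self):
        recs = [_record(i, "ACGT") for i in range(12)]
        assert repstats.redundancy_histogram(recs)["10+"] == pytest.approx(100.0)

    def test_amino_acid_key(self):
        recs = [_record(0, "GCT"), _record(1, "GCC")]
        for r in recs:
            r.sequence_aa = "A"
        assert repstats.redundancy_histogram(recs, "amino_acid")["2"] == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            repstats.redundancy_histogram([])


class TestVjPairing:
    def test_hand_count_gene_level(self):
        recs = [
            _record(0, v_call="V3a"), _record(1, v_call="V3a"),
            _record(2, v_call="V3a", j_call="J6", j_family="IGHJ6"),
            _record(3, v_call="V1a"),
        ]
        df, dropped = repstats.vj_pairing_matrix(recs, "gene")
        assert dropped == 0
        assert df.loc["V3a", "IGHJ4"] == pytest.approx(0.5)
        assert df.loc["V3a", "IGHJ6"] == pytest.approx(0.25)
        assert df.loc["V1a", "IGHJ4"] == pytest.approx(0.25)
        assert df.values.sum() == pytest.approx(1.0)

    def test_family_rollup(self):
        recs = [
            _record(0), _record(1),
            _record(2, j_call="J6", j_family="IGHJ6"),
            _record(3, v_family="IGHV1"),
        ]
        df, _ = repstats.vj_pairing_matrix(recs, "family")
        assert df.loc["IGHV3"].sum() == pytest.approx(0.75)

    def test_single_record(self):
        df, _ = repstats.vj_pairing_matrix([_record(0)], "gene")
        assert df.values.sum() == pytest.approx(1.0)
        assert df.shape == (1, 1)

    def test_missing_calls_dropped_and_counted(self):
        recs = [_record(0), _record(1, j_family="")]
        df, dropped = repstats.vj_pairing_matrix(recs, "family")
        assert dropped == 1
        assert df.values.sum() == pytest.approx(1.0)


class TestCdrLengths:
    def test_hand_count(self):
        recs = [_record(0, cdr3_aa="A" * 8), _record(1, cdr3_aa="A" * 8),
                _record(2, cdr3_aa="A" * 19)]
        dist = repstats.cdr_length_distribution(recs, "cdr3")
        assert dist[8] == pytest.approx(200 / 3)
        assert dist[19] == pytest.approx(100 / 3)

    def test_uniform(self):
        recs = [_record(0, cdr3_aa="AAKDYRVW"), _record(1, cdr3_aa="GGKDYRVW")]
        assert repstats.cdr_length_distribution(recs, "cdr3") == {8: 100.0}

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            repstats.cdr_length_distribution([_record(0)], "cdr4")


class TestPositionalComposition:
    def test_two_residues_half_each(self):
        recs = [
            _record(0, numbered={"105": "A"}),
            _record(1, numbered={"105": "G"}),
        ]
        table = repstats.positional_composition(recs, (105,))
        freqs, cov = table["105"]
        assert freqs == {"A": 0.5, "G": 0.5}
        assert cov == 1.0

    def test_coverage_excludes_unoccupied(self):
        recs = [
            _record(0, numbered={"112": "A"}),
            _record(1, numbered={"105": "G"}),
        ]
        freqs, cov = repstats.positional_composition(recs, (112,))["112"]
        assert freqs == {"A": 1.0}
        assert cov == 0.5

    def test_tetrad_hand_split(self):
        recs = [_record(i, numbered={"42": "Y", "49": "E", "50": "R", "52": "L"})
                for i in range(2)]
        recs += [_record(i + 2, numbered={"42": "F", "49": "Q", "50": "R", "52": "G"})
                 for i in range(2)]
        table = repstats.fr2_tetrad_composition(recs)
        assert table["42"][0] == {"F": 0.5, "Y": 0.5}
        assert table["50"][0] == {"R": 1.0}


class TestNongermlineCounts:
    def test_hand_values(self):
        recs = [_record(0, n_cdr12=0), _record(1, n_cdr12=0), _record(2, n_cdr12=5)]
        out = repstats.nongermline_count_distribution(recs)
        assert out["pct_zero"] == pytest.approx(200 / 3)
        assert out["pct_1_10"] == pytest.approx(100 / 3)
        assert out["pct_gt10"] == 0.0
        assert out["mean"] == pytest.approx(5 / 3)
        assert out["pct_zero"] + out["pct_1_10"] + out["pct_gt10"] == pytest.approx(100.0)

    def test_all_zero(self):
        out = repstats.nongermline_count_distribution([_record(0), _record(1)])
        assert out["pct_zero"] == 100.0 and out["mean"] == 0.0


class TestWuKabat:
    def test_conserved_column_floor(self):
        prof = repstats.wu_kabat_profile({"30": ["A"] * 10})
        assert prof.positions["30"] == pytest.approx(1.0)

    def test_hand_value(self):
        prof = repstats.wu_kabat_profile({"30": ["A", "A", "A", "G"]})
        assert prof.positions["30"] == pytest.approx(2 / 0.75)

    def test_ceiling_twenty_distinct(self):
        prof = repstats.wu_kabat_profile({"30": list("ACDEFGHIKLMNPQRSTVWY")})
        assert prof.positions["30"] == pytest.approx(400.0)

    def test_germline_set_profile(self, germline):
        v_genes, _ = germline
        cols = repstats.germline_columns(v_genes)
        prof = repstats.wu_kabat_profile(cols)
        assert all(v >= 1.0 for v in prof.positions.values())
        assert prof.positions["23"] == pytest.approx(1.0)  # conserved Cys
        assert prof.positions["41"] == pytest.approx(1.0)  # conserved Trp
        assert prof.positions["50"] == pytest.approx(1.0)  # hallmark Arg

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            repstats.wu_kabat_profile({})


class TestMutationProfiles:
    def test_no_events_all_zero(self):
        recs = [_record(i, numbered={"59": "S"}) for i in range(4)]
        prof = repstats.mutation_frequency_profile(recs)
        assert all(v["substitution"] == 0 and v["insertion"] == 0 for v in prof.values())

    def test_substitution_denominator_is_occupancy(self):
        recs = [
            _record(i, numbered={"59": "D"},
                    events=[MutationEvent("59", "substitution", "S", "D")])
            for i in range(4)
        ] + [_record(i + 4, numbered={"59": "S"}) for i in range(6)]
        prof = repstats.mutation_frequency_profile(recs)
        assert prof["59"]["substitution"] == pytest.approx(0.4)

    def test_insertion_denominator_is_total_records(self):
        recs = [
            _record(0, events=[MutationEvent("33", "insertion", "-", "G")],
                    n_cdr12=1),
        ] + [_record(i + 1) for i in range(3)]
        prof = repstats.mutation_frequency_profile(recs)
        assert prof["33"]["insertion"] == pytest.approx(0.25)

    def test_mutated_residue_composition_hand_count(self):
        recs = [
            _record(0, events=[MutationEvent("33", "insertion", "-", "G")], n_cdr12=1),
            _record(1, events=[MutationEvent("33", "insertion", "-", "G")], n_cdr12=1),
            _record(2, events=[MutationEvent("33", "insertion", "-", "A")], n_cdr12=1),
        ]
        comp = repstats.mutated_residue_composition(recs, "insertion")
        assert comp["33"]["G"] == pytest.approx(2 / 3)
        assert comp["33"]["A"] == pytest.approx(1 / 3)

    def test_single_substitution(self):
        recs = [_record(0, events=[MutationEvent("59", "substitution", "S", "D")])]
        comp = repstats.mutated_residue_composition(recs, "substitution")
        assert comp == {"59": {"D": 1.0}}

    def test_zero_events_empty_table(self):
        assert repstats.mutated_residue_composition([_record(0)], "insertion") == {}


def _random_table(py_rng: random.Random, n: int):
    aa = "ACDEFG"
    recs = []
    for i in range(n):
        seq = "".join(py_rng.choice("ACGT") for _ in range(py_rng.randint(1, 4)))
        numbered = {
            str(p): py_rng.choice(aa)
            for p in (27, 31, 42, 59, 105)
            if py_rng.random() < 0.8
        }
        events = []
        if "59" in numbered and py_rng.random() < 0.4:
            obs = numbered["59"]
            germ = py_rng.choice([a for a in aa if a != obs])
            events.append(MutationEvent("59", "substitution", germ, obs))
        if py_rng.random() < 0.3:
            events.append(
                MutationEvent("33", "insertion", "-", py_rng.choice(aa))
            )
        recs.append(
            _record(
                i,
                sequence=seq,
                v_call=py_rng.choice(["V1", "V2", "V3"]),
                v_family=py_rng.choice(["IGHV1", "IGHV3"]),
                j_family=py_rng.choice(["IGHJ4", "IGHJ6"]),
                cdr3_aa="A" * py_rng.randint(1, 6),
                numbered=numbered,
                events=events,
                n_cdr12=sum(1 for e in events if imgt.in_cdr12(e.position)),
            )
        )
    return recs


@pytest.mark.parametrize("seed", range(10))
def test_statistics_match_single_pass_oracles(seed):
    """Every repstats operation equals a brute-force counting oracle on a
    random record table."""
    py_rng = random.Random(seed)
    recs = _random_table(py_rng, py_rng.randint(1, 200))

    hist = repstats.redundancy_histogram(recs)
    expect = oracles.redundancy_counts([r.sequence for r in recs])
    for bin_, pct in expect.items():
        assert hist[bin_] == pytest.approx(pct)
    assert sum(hist.values()) == pytest.approx(100.0)

    df, dropped = repstats.vj_pairing_matrix(recs, "gene")
    expect_pairs = oracles.pairing_fractions([(r.v_call, r.j_family) for r in recs])
    for (v_lab, j_lab), frac in expect_pairs.items():
        assert df.loc[v_lab, j_lab] == pytest.approx(frac)
    assert df.values.sum() == pytest.approx(1.0)

    dist = repstats.cdr_length_distribution(recs, "cdr3")
    from collections import Counter

    lengths = Counter(len(r.cdr3_aa) for r in recs)
    for length, cnt in lengths.items():
        assert dist[length] == pytest.approx(100.0 * cnt / len(recs))

    cols = {}
    for r in recs:
        for lab, aa in r.numbered_residues.items():
            cols.setdefault(lab, []).append(aa)
    comp = repstats.positional_composition(recs, (27, 31, 42, 59, 105))
    for lab, expect_freqs in oracles.column_compositions(cols).items():
        freqs, cov = comp[lab]
        assert freqs == pytest.approx(expect_freqs)
        assert cov == pytest.approx(len(cols[lab]) / len(recs))
        assert sum(freqs.values()) == pytest.approx(1.0)

    prof = repstats.wu_kabat_profile({k: v for k, v in cols.items() if v})
    for lab, residues in cols.items():
        if residues:
            assert prof.positions[lab] == pytest.approx(oracles.wu_kabat(residues))

    mfreq = repstats.mutation_frequency_profile(recs)
    n59 = sum(1 for r in recs if "59" in r.numbered_residues)
    subs59 = sum(
        1 for r in recs for e in r.mutation_events
        if e.kind == "substitution" and e.position == "59"
    )
    ins33 = sum(
        1 for r in recs for e in r.mutation_events
        if e.kind == "insertion" and e.position == "33"
    )
    if n59:
        assert mfreq["59"]["substitution"] == pytest.approx(subs59 / n59)
    if ins33:
        assert mfreq["33"]["insertion"] == pytest.approx(ins33 / len(recs))

    ng = repstats.nongermline_count_distribution(recs)
    assert ng["pct_zero"] + ng["pct_1_10"] + ng["pct_gt10"] == pytest.approx(100.0)
    assert ng["mean"] == pytest.approx(
        sum(r.n_nongermline_cdr12 for r in recs) / len(recs)
    )
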