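"""Decomposition, .st parsing/serialization, and ste round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsc.energy_model import ComponentEnergy, structure_energy
from lsc.structure_io import (
    StructureParseError,
    StructureValidationError,
    annotate_from_dotbracket,
    parse_st,
    pairing_from_dotbracket,
    read_ste,
    write_st,
    write_ste,
)
from lsc.synthetic_data import random_structure

TOY_ST = """\
#Name: toy
#Length: 9
#PageNumber: 1
GGGAAACCC
(((...)))
SSSHHHSSS
S1 1..3 "GGG" 7..9 "CCC"
H1 4..6 "AAA" (3,7) G:C
"""


class TestDecomposition:
    def test_minimal_hairpin(self):
        s = annotate_from_dotbracket("GGGAAACCC", "(((...)))")
        stem = s.record("S1")
        assert stem.strand_ranges == ((1, 3), (7, 9))
        assert [(i, s.pairing[i - 1]) for i in (1, 2, 3)] == [(1, 9), (2, 8), (3, 7)]
        hp = s.record("H1")
        assert hp.strand_ranges == ((4, 6),)
        assert hp.closing_pairs == ((3, 7),)

    def test_four_pair_stem(self):
        s = annotate_from_dotbracket("GGGGAAACCCC", "((((...))))")
        assert s.record("S1").length_summary == (4,)
        assert s.record("H1").length_summary == (3,)
        assert len(s.substructures) == 2

    def test_bulge_on_five_prime_strand(self):
        s = annotate_from_dotbracket("GGAAGGAAACCCC", "((..((...))))")
        kinds = {r.label: r.kind for r in s.substructures}
        assert kinds == {"S1": "stem", "B1": "bulge", "S2": "stem", "H1": "hairpin"}
        b = s.record("B1")
        assert b.strand_ranges == ((3, 4),)
        assert b.length_summary == (2,)

    def test_symmetric_internal_loop(self):
        s = annotate_from_dotbracket("GGAAGGAAACCAACC", "((..((...))..))")
        i1 = s.record("I1")
        assert i1.kind == "internal"
        assert i1.length_summary == (2, 2)
        assert i1.strand_ranges == ((3, 4), (12, 13))

    def test_multiloop_and_exterior(self):
        db = ".((.((...)).((...)).))."
        seq = "A" * len(db)
        s = annotate_from_dotbracket(seq, db)
        kinds = [r.kind for r in s.substructures]
        assert kinds.count("multiloop") == 1
        assert kinds.count("exterior") == 2
        m = s.record("M1")
        assert len(m.closing_pairs) == 3  # closing pair + two branches

    def test_pseudoknot_pairs_flagged_not_decomposed(self):
        s = annotate_from_dotbracket("GGGAAACCCAAAUUU", "(((..[[.)))..]]")
        assert s.pk_pairs == ((6, 15), (7, 14))
        # pk positions are loop members on the nested page
        hp = s.record("H1")
        assert hp.pseudoknot
        assert s.pairing[5] == 15

    def test_positions_tile_exactly_once(self, rng):
        for _ in range(25):
            seq, db = random_structure(rng, int(rng.integers(10, 120)))
            s = annotate_from_dotbracket(seq, db)
            seen = sorted(p for r in s.substructures for p in r.positions())
            assert seen == list(range(1, s.length + 1))

    def test_errors(self):
        with pytest.raises(StructureParseError):
            annotate_from_dotbracket("AAAA", "(((.")
        with pytest.raises(StructureParseError):
            annotate_from_dotbracket("AAAA", "(..)(")
        with pytest.raises(StructureParseError):
            annotate_from_dotbracket("AAAAA", "(..)")


class TestStFormat:
    def test_parse_minimal(self):
        s = parse_st(TOY_ST)
        assert s.identifier == "toy"
        assert s.record("S1").strand_ranges == ((1, 3), (7, 9))
        assert s.record("H1").strand_ranges == ((4, 6),)

    def test_parse_agrees_with_annotate(self):
        s1 = parse_st(TOY_ST)
        s2 = annotate_from_dotbracket("GGGAAACCC", "(((...)))", "toy")
        assert s1 == s2

    def test_inconsistent_annotation_rejected(self):
        bad = TOY_ST.replace('H1 4..6 "AAA" (3,7) G:C', 'H1 4..5 "AA" (3,7) G:C')
        with pytest.raises(StructureValidationError, match="H1"):
            parse_st(bad)

    def test_annotation_vs_paired_position(self):
        # dot-bracket pairs position 5, annotation still claims H1 at 4..6
        bad = TOY_ST.replace("(((...)))", "((((.))))").replace(
            "SSSHHHSSS", "SSSSHSSSS"
        ).replace('S1 1..3 "GGG" 7..9 "CCC"', 'S1 1..4 "GGGA" 6..9 "ACCC"')
        with pytest.raises(StructureValidationError):
            parse_st(bad)

    def test_malformed_line_names_line(self):
        bad = TOY_ST + "H2 oops\n"
        with pytest.raises(StructureParseError, match="line 9"):
            parse_st(bad)

    def test_length_mismatch(self):
        bad = TOY_ST.replace("#Length: 9", "#Length: 11")
        with pytest.raises(StructureValidationError):
            parse_st(bad)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(12, 120))
    def test_round_trip_identity(self, seed, length):
        rng = np.random.default_rng(seed)
        seq, db = random_structure(rng, length)
        s = annotate_from_dotbracket(seq, db)
        assert parse_st(write_st(s)) == s


class TestSteFormat:
    def test_values_written_to_two_decimals(self):
        s = annotate_from_dotbracket("GGGAAACCC", "(((...)))")
        text = write_ste(s, {"S1": -5.4, "H1": 4.5})
        assert '-5.40' in text and '4.50' in text

    def test_round_trip_preserves_energies(self, params, rng):
        for _ in range(15):
            seq, db = random_structure(rng, int(rng.integers(15, 100)))
            s = annotate_from_dotbracket(seq, db)
            res = structure_energy(s, params)
            s2, energies = read_ste(write_ste(s, res.components))
            assert s2 == s
            for label, comp in res.components.items():
                if label in energies and comp.computable:
                    assert energies[label] == round(comp.value, 2)

    def test_non_computable_written_as_sentinel(self):
        # A:G closing pair cannot be evaluated -> sentinel with flag
        s = annotate_from_dotbracket("AAGAAACGC", "(((...)))")
        comp = ComponentEnergy(
            value=float("nan"), component_label="S1", computable=False,
            reason="non-canonical pair",
        )
        text = write_ste(s, {"S1": comp, "H1": 4.5})
        assert "NA" in text
        _, energies = read_ste(text)
        assert energies["S1"] is None

    def test_missing_label_listed(self):
        s = annotate_from_dotbracket("GGGAAACCC", "(((...)))")
        with pytest.raises(StructureValidationError, match="H1"):
            write_ste(s, {"S1": -5.4})


def test_pairing_from_dotbracket_pages():
    pairing, pk = pairing_from_dotbracket("([)]")
    assert pairing == (3, 4, 1, 2)
    assert pk == ((2, 4),)
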