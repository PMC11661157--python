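"""Parameter loading and nearest-neighbor component energies.

The independent oracle throughout is ViennaRNA's structure evaluation with
dangling ends disabled; our evaluator must reproduce it as the exact sum of
per-substructure components.
"""

import math
import re

import numpy as np
import pytest

from lsc.energy_model import (
    EnergyConfig,
    LoopGeometryError,
    ParameterFileError,
    PAIR_INDEX,
    T37,
    bulge_energy,
    default_parameter_path,
    hairpin_energy,
    internal_loop_energy,
    load_params,
    stem_energy,
    structure_energy,
)
from lsc.structure_io import annotate_from_dotbracket
from lsc.synthetic_data import random_structure


class TestLoadParams:
    def test_stack_entry_matches_file_value(self, params):
        # first stack row of the Turner 2004 file: CG over CG is -240 dacal
        assert params.stack_table[PAIR_INDEX["CG"], PAIR_INDEX["CG"]] == -240
        assert params.stack_table[PAIR_INDEX["GC"], PAIR_INDEX["GC"]] == -340

    def test_default_temperature_is_37C(self, params):
        assert params.temperature == pytest.approx(310.15)

    def test_missing_table_named_in_error(self):
        text = default_parameter_path().read_text()
        start = text.index("# hairpin\n")
        end = text.index("# hairpin_enthalpies")
        broken = text[:start] + text[end:]
        with pytest.raises(ParameterFileError, match="hairpin_init"):
            load_params(broken)

    def test_non_numeric_entry_rejected(self):
        text = default_parameter_path().read_text()
        broken = text.replace("  -240  ", "  oops  ", 1)
        with pytest.raises(ParameterFileError, match="oops"):
            load_params(broken)

    def test_initiation_monotone_beyond_nine(self, params):
        for arr in (params.hairpin_init, params.bulge_init, params.internal_init):
            tail = arr[9:31]
            assert np.all(np.diff(tail) >= 0)

    def test_temperature_rescaling_direction(self):
        hot = load_params(temperature=330.15)
        cold = load_params(temperature=310.15)
        # loop initiation is entropic (less favorable when hot); stacking is
        # enthalpy-driven (weaker when hot)
        assert hot.hairpin_init[4] > cold.hairpin_init[4]
        assert hot.stack_table[0, 0] > cold.stack_table[0, 0]
        assert hot.lxc == pytest.approx(cold.lxc * 330.15 / 310.15)


class TestStemEnergy:
    def test_single_pair_stem_has_no_stacking(self, params, vienna_eval):
        seq, db = "AAAAAAUAA", "..(...).."
        s = annotate_from_dotbracket(seq, db)
        comp = stem_energy(s, s.record("S1"), params)
        # lonely A:U pair: no stacking, exterior-branch and triloop-side
        # terminal AU penalties only
        assert comp.terms == {"end_penalty": 1.0}
        assert comp.value == pytest.approx(1.0)
        res = structure_energy(s, params)
        assert res.total == pytest.approx(vienna_eval(seq, db), abs=0.01)

    def test_two_pair_gc_helix_is_the_stack_entry(self, params):
        s = annotate_from_dotbracket("GGAAACC", "((...))")
        comp = stem_energy(s, s.record("S1"), params)
        step = params.stack_table[
            PAIR_INDEX["GC"], PAIR_INDEX[s.sequence[5] + s.sequence[1]]
        ]
        assert comp.value == pytest.approx(step / 100.0)

    def test_non_canonical_pair_flagged(self, params):
        s = annotate_from_dotbracket("AAGAAACGC", "(((...)))")
        comp = stem_energy(s, s.record("S1"), params)
        assert not comp.computable
        assert "non-canonical" in comp.reason

    def test_helix_in_context_matches_reference(self, params, vienna_eval, rng):
        for _ in range(100):
            h = int(rng.integers(1, 9))
            loop = int(rng.integers(3, 8))
            db = "(" * h + "." * loop + ")" * h
            seq, db = _canonical_for(db, rng)
            st = annotate_from_dotbracket(seq, db)
            res = structure_energy(st, params)
            assert res.computable
            assert res.total == pytest.approx(vienna_eval(seq, db), abs=0.01)


def _canonical_for(db, rng):
    from lsc.structure_io import pairing_from_dotbracket

    pairing, _ = pairing_from_dotbracket(db)
    choices = ("CG", "GC", "AU", "UA", "GU", "UG")
    seq = [""] * len(db)
    for i in range(1, len(db) + 1):
        j = pairing[i - 1]
        if j == 0:
            seq[i - 1] = "ACGU"[rng.integers(4)]
        elif j > i:
            p = choices[rng.integers(6)]
            seq[i - 1], seq[j - 1] = p[0], p[1]
    return "".join(seq), db


class TestHairpinEnergy:
    def test_size_two_loop_is_an_error(self, params):
        s = annotate_from_dotbracket("GGAACC", "((..))")
        with pytest.raises(LoopGeometryError):
            hairpin_energy(s, s.record("H1"), params)

    def test_size_four_cg_closed_matches_reference(self, params, vienna_eval):
        seq, db = "GGGCAAAAGCCC", "((((....))))"
        st = annotate_from_dotbracket(seq, db)
        assert st.sequence[3] + st.sequence[8] == "CG"
        res = structure_energy(st, params)
        assert res.total == pytest.approx(vienna_eval(seq, db), abs=0.01)

    def test_large_loop_extrapolation_closed_form(self, params, vienna_eval):
        size = 40
        seq = "GGG" + "A" * size + "CCC"
        db = "(((" + "." * size + ")))"
        st = annotate_from_dotbracket(seq, db)
        comp = hairpin_energy(st, st.record("H1"), params)
        mm = params.mismatch_hairpin[PAIR_INDEX["GC"], 1, 1]  # A/A mismatch
        expected = (params.hairpin_init[30]
                    + int(params.lxc * math.log(size / 30.0)) + mm) / 100.0
        assert comp.value == pytest.approx(expected, abs=1e-9)
        res = structure_energy(st, params)
        assert res.total == pytest.approx(vienna_eval(seq, db), abs=0.01)

    def test_special_tetraloop_value_used(self, params):
        # CAACGG is in the tetraloop table
        st = annotate_from_dotbracket("GGCAACGGCC", "(((....)))")
        comp = hairpin_energy(st, st.record("H1"), params)
        assert comp.terms == {"special": params.special_hairpins["CAACGG"] / 100.0}


class TestBulgeEnergy:
    @pytest.mark.parametrize("size", [1, 2, 5])
    def test_matches_reference(self, params, vienna_eval, size):
        seq = "GGG" + "A" * size + "GGAAAACCCCC"
        db = "(((" + "." * size + "((....)))))"
        st = annotate_from_dotbracket(seq, db)
        assert st.record("B1").length_summary == (size,)
        res = structure_energy(st, params)
        assert res.total == pytest.approx(vienna_eval(seq, db), abs=0.01)

    def test_size_one_keeps_cross_stack(self, params):
        seq, db = "GGGAGGAAAACCCCC", "(((.((....)))))"
        st = annotate_from_dotbracket(seq, db)
        comp = bulge_energy(st, st.record("B1"), params)
        assert "stacking" in comp.terms
        assert comp.terms["initiation"] == params.bulge_init[1] / 100.0

    def test_size_31_extrapolation(self, params):
        size = 31
        seq = "GGG" + "A" * size + "GGAAAACCCCC"
        db = "(((" + "." * size + "((....)))))"
        st = annotate_from_dotbracket(seq, db)
        comp = bulge_energy(st, st.record("B1"), params)
        expected = (params.bulge_init[30]
                    + int(params.lxc * math.log(31 / 30.0))) / 100.0
        assert comp.terms["initiation"] == pytest.approx(expected, abs=1e-9)


class TestInternalLoopEnergy:
    def _loop(self, n1, n2):
        seq = "GGG" + "A" * n1 + "GGAAAACC" + "C" * n2 + "CCC"
        db = "(((" + "." * n1 + "((....))" + "." * n2 + ")))"
        return seq, db

    @pytest.mark.parametrize("n1,n2", [(1, 1), (1, 2), (2, 1), (2, 2),
                                       (2, 3), (1, 5), (3, 3), (4, 7)])
    def test_matches_reference(self, params, vienna_eval, n1, n2):
        seq, db = self._loop(n1, n2)
        st = annotate_from_dotbracket(seq, db)
        assert st.record("I1").length_summary == (n1, n2)
        res = structure_energy(st, params)
        assert res.total == pytest.approx(vienna_eval(seq, db), abs=0.01)

    def test_symmetric_loop_has_no_asymmetry_term(self, params):
        seq, db = self._loop(3, 3)
        st = annotate_from_dotbracket(seq, db)
        comp = internal_loop_energy(st, st.record("I1"), params)
        assert "asymmetry" not in comp.terms

    def test_2x3_uses_one_asymmetry_unit(self, params):
        seq, db = self._loop(2, 3)
        st = annotate_from_dotbracket(seq, db)
        comp = internal_loop_energy(st, st.record("I1"), params)
        assert comp.terms["asymmetry"] == params.asymmetry_penalty / 100.0
        assert comp.terms["initiation"] == params.internal_init[5] / 100.0


class TestStructureEnergy:
    def test_empty_structure_is_zero(self, params):
        st = annotate_from_dotbracket("AAAAA", ".....")
        res = structure_energy(st, params)
        assert res.total == 0.0
        assert all(c.value == 0.0 for c in res.components.values())

    def test_component_sum_is_total_exactly(self, params, rng):
        for _ in range(30):
            seq, db = random_structure(rng, int(rng.integers(20, 100)))
            st = annotate_from_dotbracket(seq, db)
            res = structure_energy(st, params)
            total = sum(c.value for c in res.components.values() if c.computable)
            assert res.total == pytest.approx(total, abs=1e-12)

    def test_decomposition_matches_reference_broadly(self, params, vienna_eval, rng):
        n_ml = 0
        for _ in range(100):
            seq, db = random_structure(rng, int(rng.integers(20, 81)))
            st = annotate_from_dotbracket(seq, db)
            res = structure_energy(st, params)
            ref = vienna_eval(seq, db)
            tol = 0.05 if any(r.kind == "multiloop" for r in st.substructures) else 0.01
            n_ml += tol == 0.05
            assert res.total == pytest.approx(ref, abs=tol)
        assert n_ml >= 10  # multiloops must actually be exercised

    def test_end_penalty_attribution_conserves_total(self, params, rng):
        stem_cfg = EnergyConfig(end_penalty_on="stem")
        loop_cfg = EnergyConfig(end_penalty_on="loop")
        for _ in range(20):
            seq, db = random_structure(rng, int(rng.integers(20, 90)))
            st = annotate_from_dotbracket(seq, db)
            a = structure_energy(st, params, stem_cfg)
            b = structure_energy(st, params, loop_cfg)
            assert a.total == pytest.approx(b.total, abs=1e-9)

    def test_n_containing_components_flagged_not_dropped(self, params):
        st = annotate_from_dotbracket("GGGANACCC", "(((...)))")
        res = structure_energy(st, params)
        assert not res.computable
        assert not res.components["H1"].computable
        assert res.components["H1"].reason == "contains N"
        assert res.components["S1"].computable
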