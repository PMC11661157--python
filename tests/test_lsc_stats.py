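"""Net-dG statistics: binned regressions, rotation control, group tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsc.energy_model import default_params
from lsc.lsc_stats import (
    bin_loop_vs_stem,
    compare_to_control,
    make_record,
    net_energy,
    net_energy_records,
    read_records_tsv,
    rotation_control,
    summarize_groups,
    write_records_tsv,
)
from lsc.structure_io import annotate_from_dotbracket
from lsc.synthetic_data import SimulationConfig, simulate_net_energy_records


class TestNetEnergy:
    def test_single_stem(self):
        assert net_energy(3.0, [-5.0]) == pytest.approx(-2.0)

    def test_two_way_junction_averages_stems(self):
        assert net_energy(2.0, [-4.0, -6.0]) == pytest.approx(-3.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-20, 20), st.floats(-20, 20))
    def test_duplicate_stem_equals_single(self, x, s):
        assert net_energy(x, [s, s]) == pytest.approx(net_energy(x, [s]))

    @pytest.mark.parametrize("stems", [[], [1.0, 2.0, 3.0]])
    def test_wrong_stem_count(self, stems):
        with pytest.raises(ValueError):
            net_energy(1.0, stems)

    def test_linear_in_each_argument(self):
        a = net_energy(1.0, [-2.0, -4.0])
        b = net_energy(2.0, [-2.0, -4.0])
        c = net_energy(1.0, [-4.0, -2.0])
        assert b - a == pytest.approx(1.0)
        assert c == pytest.approx(a)  # stem permutation invariance

    def test_records_from_structure(self, params):
        # stem-loop with a bulge: hairpin gets one stem, bulge gets two
        seq, db = "GGGAGGAAAACCCCC", "(((.((....)))))"
        stct = annotate_from_dotbracket(seq, db, "x")
        recs = net_energy_records(stct, params)
        by_kind = {r.loop_kind: r for r in recs}
        assert set(by_kind) == {"hairpin", "bulge"}
        assert len(by_kind["hairpin"].stem_dgs) == 1
        assert len(by_kind["bulge"].stem_dgs) == 2
        for r in recs:
            assert r.net_dg == pytest.approx(net_energy(r.loop_dg, r.stem_dgs))


class TestBinLoopVsStem:
    def test_single_bin_is_degenerate(self):
        recs = [make_record("s", f"H{i}", "hairpin", 1.1, [-3.0]) for i in range(50)]
        with pytest.raises(ValueError):
            bin_loop_vs_stem(recs)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(0)
        loop = rng.uniform(1.0, 6.0, size=5000)
        stem = -2.0 * loop + rng.normal(0, 0.1, size=5000)
        recs = [make_record("s", f"H{i}", "hairpin", l, [s])
                for i, (l, s) in enumerate(zip(loop, stem))]
        fit = bin_loop_vs_stem(recs)
        assert -2.1 <= fit.median_fit.slope <= -1.9
        assert fit.median_fit.r2 > 0.99

    def test_constant_bin_quantiles_collapse(self):
        recs = (
            [make_record("s", f"H{i}", "hairpin", 0.1, [-3.0]) for i in range(100)]
            + [make_record("s", f"G{i}", "hairpin", 0.6, [-4.0]) for i in range(100)]
        )
        fit = bin_loop_vs_stem(recs)
        b = fit.bins[0]
        assert b.q05 == b.median == -3.0

    def test_sparse_bins_excluded(self):
        recs = (
            [make_record("s", f"H{i}", "hairpin", 0.1, [-3.0 + 0.01 * i]) for i in range(30)]
            + [make_record("s", f"G{i}", "hairpin", 0.6, [-4.0 + 0.01 * i]) for i in range(30)]
            + [make_record("s", "L", "hairpin", 5.0, [-9.0])]
        )
        fit = bin_loop_vs_stem(recs)
        assert len(fit.bins) == 2
        assert fit.excluded_bins == 1


class TestRotationControl:
    def _structure(self, sid, n_loops, rng):
        return [
            make_record(sid, f"H{k}", "hairpin",
                        float(rng.uniform(1, 5)), [float(rng.normal(-5, 1))])
            for k in range(n_loops)
        ]

    def test_three_loops_ineligible(self, rng):
        recs = self._structure("a", 3, rng)
        assert rotation_control(recs) == []

    def test_four_loops_get_disjoint_stems(self, rng):
        recs = self._structure("a", 4, rng)
        ctrl = rotation_control(recs)
        assert len(ctrl) == 4
        own = {r.loop_label + "_ctrl": set(r.stem_dgs) for r in recs}
        for c in ctrl:
            assert not (set(c.stem_dgs) & own[c.loop_label])

    def test_loop_and_stem_multisets_preserved(self, rng):
        recs = self._structure("a", 6, rng)
        ctrl = rotation_control(recs)
        assert sorted(r.loop_dg for r in ctrl) == sorted(r.loop_dg for r in recs)
        assert sorted(r.stem_summary for r in ctrl) == pytest.approx(
            sorted(r.stem_summary for r in recs)
        )

    def test_kinds_do_not_mix(self, rng):
        recs = self._structure("a", 4, rng) + [
            make_record("a", f"B{k}", "bulge", 2.0, [-4.0 - k, -5.0 - k])
            for k in range(2)
        ]
        ctrl = rotation_control(recs)
        assert all(c.loop_kind == "hairpin" for c in ctrl)

    def test_independence_preserves_variance(self):
        config = SimulationConfig(
            n_structures=1000, loops_per_structure=("fixed", 6),
            compensation_slope=0.0, noise_sd=0.5, rng_seed=42,
        )
        recs = simulate_net_energy_records(config)
        ctrl = rotation_control(recs)
        v0 = np.var([r.net_dg for r in recs])
        v1 = np.var([r.net_dg for r in ctrl])
        assert abs(v1 - v0) / v0 < 0.05


class TestCompareToControl:
    def test_identity_comparison(self):
        rng = np.random.default_rng(1)
        recs = [make_record("s", f"H{i}", "hairpin", float(l), [-3.0])
                for i, l in enumerate(rng.uniform(1, 4, size=200))]
        cmp = compare_to_control(recs, recs)
        assert cmp.f_statistic == pytest.approx(1.0)
        assert all(abs(d) < 1e-15 for d in cmp.frequency_difference)

    def test_planted_compensation_beats_control(self):
        config = SimulationConfig(
            n_structures=1000, loops_per_structure=("fixed", 6),
            compensation_slope=1.0, noise_sd=0.3, rng_seed=5,
        )
        recs = simulate_net_energy_records(config)
        ctrl = rotation_control(recs)
        cmp = compare_to_control(recs, ctrl)
        assert cmp.var_original < cmp.var_control
        assert cmp.p_value < 0.01

    def test_frequency_difference_sums_to_zero(self):
        rng = np.random.default_rng(2)
        a = [make_record("s", f"H{i}", "hairpin", float(l), [-3.0])
             for i, l in enumerate(rng.uniform(0, 4, 300))]
        b = [make_record("s", f"G{i}", "hairpin", float(l), [-5.0])
             for i, l in enumerate(rng.uniform(1, 6, 200))]
        cmp = compare_to_control(a, b)
        assert abs(sum(cmp.frequency_difference)) < 1e-12

    def test_empty_input_rejected(self):
        recs = [make_record("s", "H1", "hairpin", 1.0, [-3.0])]
        with pytest.raises(ValueError):
            compare_to_control(recs, [])


class TestSummarizeGroups:
    def _records(self, rng, group, n, offset=0.0):
        return [
            make_record("s", f"{group}{i}", "hairpin",
                        float(rng.uniform(1, 4)),
                        [float(rng.normal(-5 + offset, 1))], rna_type=group)
            for i in range(n)
        ]

    def test_single_group_summary_only(self, rng):
        summaries, tests = summarize_groups(self._records(rng, "tRNA", 50))
        assert set(summaries) == {"tRNA"}
        assert tests == {}
        assert summaries["tRNA"].count == 50

    def test_unknown_group_key(self, rng):
        with pytest.raises(ValueError):
            summarize_groups(self._records(rng, "x", 30), group_key="organ")

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            recs = self._records(rng, "a", 500) + self._records(rng, "b", 500)
            _, tests = summarize_groups(recs)
            if tests[("a", "b")] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_offset_groups_strongly_separated(self):
        rng = np.random.default_rng(8)
        recs = self._records(rng, "meso", 500) + self._records(rng, "thermo", 500, offset=-1.0)
        _, tests = summarize_groups(recs)
        assert tests[("meso", "thermo")] < 1e-6

    def test_taxon_grouping_uses_tags(self, rng):
        recs = [
            make_record("s", f"H{i}", "hairpin", 1.0, [-3.0],
                        taxon_tags=("plant",)) for i in range(30)
        ] + [
            make_record("s", f"G{i}", "hairpin", 1.0, [-4.0],
                        taxon_tags=("metazoan",)) for i in range(30)
        ]
        summaries, _ = summarize_groups(recs, group_key="taxon")
        assert set(summaries) == {"metazoan", "plant"}


def test_records_tsv_round_trip(tmp_path, rng):
    recs = [
        make_record("s1", "H1", "hairpin", 1.5, [-3.25], rna_type="tRNA",
                    taxon_tags=("thermophile",)),
        make_record("s1", "B1", "bulge", 2.0, [-4.0, -6.5], rna_type="rRNA"),
    ]
    path = tmp_path / "records.tsv"
    write_records_tsv(recs, path)
    back = read_records_tsv(path)
    assert back == recs
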