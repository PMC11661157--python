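"""AUROC, region reactivities, per-position profiles, Hill fits."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from lsc.reactivity_analysis import (
    FidelityResult,
    ReactivityProfile,
    analyze_profile,
    bin_auroc_fit_hill,
    compute_auroc,
    net_dg_reactivity_regression,
    per_position_profile,
    region_reactivities,
)
from lsc.validation import brute_force_auroc, random_pairing_dotbracket


def make_profile(sequence, db, reactivity, mask=None, net_dg=None, name="p"):
    n = len(sequence)
    return ReactivityProfile(
        name=name, sequence=sequence, designed_dotbracket=db,
        reactivity=tuple(reactivity),
        region_mask=tuple(mask or ["local"] * n),
        net_dg=net_dg,
    )


class TestComputeAuroc:
    def test_perfect_separation(self):
        p = make_profile("AAAA", "(..)", [0.1, 0.8, 0.9, 0.2])
        assert compute_auroc(p).value == pytest.approx(1.0)

    def test_all_tied_scores(self):
        p = make_profile("AAAA", "(..)", [0.5, 0.5, 0.5, 0.5])
        assert compute_auroc(p).value == pytest.approx(0.5)

    def test_three_of_four_concordant(self):
        # positives {0.5, 0.2}, negatives {0.3, 0.1}: 3 concordant pairs
        p = make_profile("AAAA", "(..)", [0.3, 0.5, 0.2, 0.1])
        assert compute_auroc(p).value == pytest.approx(0.75)

    def test_only_ac_residues_scored(self):
        # G positions carry no signal even with extreme reactivity
        p = make_profile("AGAG", "(..)", [0.1, 0.0, 0.9, 0.9])
        res = compute_auroc(p)
        assert res.n_pos == 1 and res.n_neg == 1
        assert res.value == pytest.approx(1.0)

    def test_empty_class_gives_reason(self):
        p = make_profile("AAAA", "....", [0.1, 0.2, 0.3, 0.4])
        res = compute_auroc(p)
        assert res.value is None
        assert "negatives" in res.reason

    def test_scope_masks(self):
        mask = ["local"] * 3 + ["distal"] * 3
        p = make_profile("AAAAAA", "(.)(.)", [0.1, 0.9, 0.1, 0.5, 0.5, 0.5],
                         mask=mask)
        assert compute_auroc(p, "local").value == pytest.approx(1.0)
        assert compute_auroc(p, "distal").value == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        r = [0.3, 0.5, 0.2, 0.1, 0.7, 0.05]
        p1 = make_profile("AAAAAA", "((..))", r)
        p2 = make_profile("AAAAAA", "((..))", [x ** 3 + 1 for x in r])
        assert compute_auroc(p1).value == compute_auroc(p2).value

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_equals_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, n))
        db = random_pairing_dotbracket(rng, n)
        react = np.round(rng.random(n), 1)
        react[rng.random(n) < 0.15] = math.nan
        p = make_profile(seq, db, react)
        keep = p.informative()
        oracle = brute_force_auroc(react[keep], ~p.paired()[keep])
        est = compute_auroc(p).value
        if oracle is None:
            assert est is None
        else:
            assert est == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(6, 40))
            seq = "".join("AC"[i] for i in rng.integers(0, 2, n))
            db = random_pairing_dotbracket(rng, n)
            react = np.round(rng.random(n), 2)
            p = make_profile(seq, db, react)
            y = ~p.paired()
            if y.all() or not y.any():
                continue
            assert compute_auroc(p).value == pytest.approx(
                roc_auc_score(y, react), abs=1e-12
            )


class TestRegionReactivities:
    def test_g_residues_excluded_from_stem_mean(self):
        # designed-paired A/C: A(0.1), C(0.3); the paired G(0.9) and the
        # G/U-only closing strand carry no signal -> mean 0.2
        p = make_profile("ACGAAAUGU", "(((...)))",
                         [0.1, 0.3, 0.9, 0.5, 0.5, 0.5, 0.7, 0.7, 0.7])
        out = region_reactivities(p)
        assert out["mean_local_stem_reactivity"] == pytest.approx(0.2)

    def test_all_zero_region_log_is_pseudocount(self):
        p = make_profile("AAAAAA", "((..))", [0.0] * 6)
        out = region_reactivities(p, pseudocount=1e-4)
        assert out["log_mean_local_stem_reactivity"] == pytest.approx(math.log10(1e-4))

    def test_empty_region_is_missing(self):
        p = make_profile("AAAA", "(..)", [0.1, 0.5, 0.5, 0.1])
        out = region_reactivities(p)
        assert out["mean_distal_stem_reactivity"] is None


class TestPerPositionProfile:
    def _bulge_profile(self, name="b", net_dg=-7.0):
        # S1 = (1,12),(2,11); bulge at 3; S2 = (4,10),(5,9); loop 6-8
        seq = "A" * 12
        db = "((.((...))))"
        react = [0.1, 0.3, 0.5, 0.3, 0.3, 0.5, 0.5, 0.5, 0.3, 0.3, 0.3, 0.1]
        return make_profile(seq, db, react, mask=["local"] * 12,
                            net_dg=net_dg, name=name)

    def test_two_stem_positions_averaged_per_molecule(self):
        p = self._bulge_profile()
        out = per_position_profile([p], min_nucleotides=1)
        by_pos = {s.position: s for s in out}
        # position 1: S1 inner pair (2,11) = 0.3; S2 outer pair (4,10) = 0.3
        assert by_pos[1].mean == pytest.approx(0.3)
        # position 2: S1 (1,12) = 0.1; S2 (5,9) = 0.3 -> 0.2
        assert by_pos[2].mean == pytest.approx(0.2)

    def test_positions_beyond_six_never_reported(self, rng):
        h = 9
        seq = "A" * (2 * h + 3)
        db = "(" * h + "..." + ")" * h
        react = list(rng.random(2 * h + 3))
        mask = ["local"] * len(seq)
        profiles = [make_profile(seq, db, react, mask=mask, net_dg=-7.0,
                                 name=f"p{i}") for i in range(40)]
        out = per_position_profile(profiles, min_nucleotides=1)
        assert max(s.position for s in out) == 6

    def test_sample_size_rule_at_seventy(self):
        # one informative nucleotide per profile per position
        seq, db = "GGAAACC", "((...))"
        def prof(i):
            return make_profile(seq, db, [0.0, 0.0, 0.5, 0.5, 0.5, 0.1, 0.1],
                                mask=["local"] * 7, net_dg=-7.0, name=f"p{i}")
        with pytest.raises(ValueError):
            per_position_profile([prof(i) for i in range(69)])
        out = per_position_profile([prof(i) for i in range(70)])
        assert {s.n_nucleotides for s in out} == {70}


def _hill(s, floor, ceiling, k, n):
    return floor + (ceiling - floor) * s ** n / (k ** n + s ** n)


def _fidelity(net, auroc, **kw):
    base = dict(
        auroc_global=None, auroc_distal=None,
        mean_local_stem_reactivity=None, mean_distal_stem_reactivity=None,
        mean_local_loop_reactivity=None, mean_distal_loop_reactivity=None,
        log_mean_local_stem_reactivity=None, log_mean_distal_stem_reactivity=None,
        log_mean_local_loop_reactivity=None, log_mean_distal_loop_reactivity=None,
    )
    base.update(kw)
    return FidelityResult(name=f"v{net:.3f}", net_dg=net, auroc_local=auroc, **base)


class TestHillFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        true = dict(floor=0.5, ceiling=1.0, k=5.0, n=3.0)
        offset = 5.0
        nets = rng.uniform(-15.0, 4.999, size=4000)
        results = [
            _fidelity(x, _hill(offset - x, **true) + rng.normal(0, 0.01))
            for x in nets
        ]
        fit = bin_auroc_fit_hill(results, bin_width=0.2)
        assert not fit.degenerate
        assert fit.offset == pytest.approx(offset)
        assert fit.floor == pytest.approx(true["floor"], rel=0.05)
        assert fit.ceiling == pytest.approx(true["ceiling"], rel=0.05)
        assert fit.midpoint == pytest.approx(true["k"], rel=0.05)
        assert fit.hill_n == pytest.approx(true["n"], rel=0.05)

    def test_crossing_matches_numeric_root(self):
        results = [
            _fidelity(x, _hill(6.0 - x, 0.5, 1.0, 4.0, 2.5))
            for x in np.arange(-12.0, 5.8, 0.2)
        ]
        fit = bin_auroc_fit_hill(results)
        crossing = fit.crossing_at(0.9)
        root = optimize.brentq(lambda x: fit.predict(x) - 0.9, -12.0, fit.offset - 1e-9)
        assert crossing == pytest.approx(root, abs=1e-6)

    def test_crossing_monotone_in_threshold(self):
        results = [
            _fidelity(x, _hill(6.0 - x, 0.5, 1.0, 4.0, 2.5))
            for x in np.arange(-12.0, 5.8, 0.2)
        ]
        fit = bin_auroc_fit_hill(results)
        crossings = [fit.crossing_at(t) for t in (0.7, 0.8, 0.9, 0.95)]
        assert all(a > b for a, b in zip(crossings, crossings[1:]))

    def test_flat_data_degenerate(self):
        results = [_fidelity(x, 0.8) for x in np.arange(-6.0, 0.0, 0.2)]
        fit = bin_auroc_fit_hill(results)
        assert fit.degenerate
        assert fit.crossing_at(0.9) is None

    def test_threshold_outside_range_has_no_crossing(self):
        results = [
            _fidelity(x, _hill(6.0 - x, 0.5, 0.85, 4.0, 2.5))
            for x in np.arange(-12.0, 5.8, 0.2)
        ]
        fit = bin_auroc_fit_hill(results)
        assert fit.crossing_at(0.9) is None

    def test_too_few_bins_rejected(self):
        results = [_fidelity(x, 0.9) for x in (0.1, 0.5, 0.9)]
        with pytest.raises(ValueError):
            bin_auroc_fit_hill(results)


class TestRegression:
    def test_noiseless_recovery(self):
        results = [
            _fidelity(x, 0.9, log_mean_local_stem_reactivity=-2.0 + 0.12 * x)
            for x in np.linspace(-10, 2, 40)
        ]
        fit = net_dg_reactivity_regression(results, "log_mean_local_stem")
        assert fit.slope == pytest.approx(0.12)
        assert fit.r2 == pytest.approx(1.0)

    def test_shuffled_response_uncorrelated(self):
        rng = np.random.default_rng(3)
        nets = rng.uniform(-10, 2, size=500)
        ys = -2.0 + 0.12 * nets
        low_r2 = 0
        reps = 100
        for _ in range(reps):
            perm = rng.permutation(len(ys))
            results = [
                _fidelity(x, 0.9, log_mean_local_stem_reactivity=float(ys[j]))
                for x, j in zip(nets, perm)
            ]
            if net_dg_reactivity_regression(results, "log_mean_local_stem").r2 < 0.02:
                low_r2 += 1
        assert low_r2 >= 95

    def test_insufficient_data_rejected(self):
        results = [_fidelity(0.0, 0.9, log_mean_local_stem_reactivity=-2.0)]
        with pytest.raises(ValueError):
            net_dg_reactivity_regression(results, "log_mean_local_stem")

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            net_dg_reactivity_regression([], "banana")
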