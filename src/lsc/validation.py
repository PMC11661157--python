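"""End-to-end validation runs for the analysis pipeline.

Each function here sets up a self-contained study — synthetic structures or
libraries at the documented conditions — runs the relevant pipeline stage,
and reports summary numbers: oracle agreement of the energy decomposition
and the AUROC estimator, recovery of planted loop-stem compensation, the
behavior of the rotation control, and the fidelity of the Hill-curve
threshold crossing.  The test suite asserts on these numbers and the
reproduction script reports them.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .energy_model import default_params, structure_energy
from .library_design import (
    c_repeat_filter,
    generate_library,
    hairpin_template,
    length_filter,
    LibraryVariant,
)
from .lsc_stats import (
    bin_loop_vs_stem,
    compare_to_control,
    rotation_control,
)
from .reactivity_analysis import (
    ReactivityProfile,
    bin_auroc_fit_hill,
    compute_auroc,
    fidelity_table,
    net_dg_reactivity_regression,
)
from .structure_io import annotate_from_dotbracket
from .synthetic_data import (
    SimulationConfig,
    analytic_crossing,
    random_structure,
    simulate_net_energy_records,
    simulate_reactivity_profiles,
)

__all__ = [
    "check_energy_decomposition",
    "brute_force_auroc",
    "check_auroc_oracle",
    "check_lsc_recovery",
    "check_null_slope_coverage",
    "check_rotation_control",
    "check_hill_recovery",
    "check_filters",
]


def _vienna_reference(sequence: str, dotbracket: str) -> float:
    """Independent nearest-neighbor evaluation (ViennaRNA, no dangles)."""
    import RNA

    md = RNA.md()
    md.dangles = 0
    return float(RNA.fold_compound(sequence, md).eval_structure(dotbracket))


def check_energy_decomposition(
    n_structures: int = 120,
    min_len: int = 20,
    max_len: int = 80,
    seed: int = 1,
) -> dict:
    """Compare component-energy sums against the reference evaluator on
    random nested structures; returns worst absolute errors (kcal/mol)."""
    params = default_params()
    rng = np.random.default_rng(seed)
    worst, worst_ml, n_ml = 0.0, 0.0, 0
    for _ in range(n_structures):
        seq, db = random_structure(rng, int(rng.integers(min_len, max_len + 1)))
        st = annotate_from_dotbracket(seq, db)
        res = structure_energy(st, params)
        if not res.computable:  # pragma: no cover - generator is canonical
            raise AssertionError("random structure produced non-computable energy")
        err = abs(res.total - _vienna_reference(seq, db))
        if any(r.kind == "multiloop" for r in st.substructures):
            n_ml += 1
            worst_ml = max(worst_ml, err)
        else:
            worst = max(worst, err)
    return {
        "n": n_structures,
        "n_multiloop": n_ml,
        "max_abs_error": worst,
        "max_abs_error_multiloop": worst_ml,
    }


def brute_force_auroc(scores: np.ndarray, positives: np.ndarray) -> float | None:
    """Concordant-pair counting oracle: ties credited one half."""
    pos = scores[positives]
    neg = scores[~positives]
    if len(pos) == 0 or len(neg) == 0:
        return None
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def check_auroc_oracle(
    n_profiles: int = 1000, max_len: int = 50, seed: int = 1
) -> dict:
    """Rank-based AUROC vs brute-force counting on random profiles with
    ties, missing values, and uninformative residues."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    compared = 0
    for k in range(n_profiles):
        n = int(rng.integers(4, max_len + 1))
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))
        db = random_pairing_dotbracket(rng, n)
        # quantized scores force ties; some missing
        react = np.round(rng.random(n), 1)
        react[rng.random(n) < 0.1] = math.nan
        profile = ReactivityProfile(
            name=f"r{k}", sequence=seq, designed_dotbracket=db,
            reactivity=tuple(react), region_mask=tuple(["local"] * n),
        )
        keep = profile.informative()
        scores = react[keep]
        positives = ~profile.paired()[keep]
        oracle = brute_force_auroc(scores, positives)
        est = compute_auroc(profile, "local").value
        if oracle is None:
            if est is not None:
                raise AssertionError("estimator returned a value for empty class")
            continue
        compared += 1
        worst = max(worst, abs(est - oracle))
    return {"n": n_profiles, "n_compared": compared, "max_abs_diff": worst}


def random_pairing_dotbracket(rng: np.random.Generator, n: int) -> str:
    """Nested dot-bracket realizing a random set of paired positions
    (outermost-in pairing of the chosen positions)."""
    idx = np.flatnonzero(rng.random(n) < 0.5)
    chars = ["."] * n
    m = len(idx) - (len(idx) % 2)
    for k in range(m // 2):
        chars[idx[k]] = "("
        chars[idx[m - 1 - k]] = ")"
    return "".join(chars)


def check_lsc_recovery(seed: int = 1, n_records: int = 5000) -> dict:
    """Planted compensation (beta = 1, noise 0.5) slope recovery."""
    loops_per = 5
    config = SimulationConfig(
        n_structures=n_records // loops_per,
        loops_per_structure=("fixed", loops_per),
        compensation_slope=1.0,
        noise_sd=0.5,
        rng_seed=seed,
    )
    records = simulate_net_energy_records(config)
    fit = bin_loop_vs_stem(records)
    return {
        "n": len(records),
        "median_slope": fit.median_fit.slope,
        "median_r2": fit.median_fit.r2,
        "q05_slope": fit.q05_fit.slope,
    }


def check_null_slope_coverage(
    seed: int = 1, n_replicates: int = 100, n_records: int = 1000
) -> dict:
    """With beta = 0 the slope CI should cover 0 in >= 90% of replicates."""
    loops_per = 5
    covered = 0
    for rep in range(n_replicates):
        config = SimulationConfig(
            n_structures=n_records // loops_per,
            loops_per_structure=("fixed", loops_per),
            compensation_slope=0.0,
            noise_sd=0.5,
            rng_seed=seed * 100_003 + rep,
        )
        fit = bin_loop_vs_stem(simulate_net_energy_records(config))
        lo, hi = fit.median_fit.slope_ci95
        if lo <= 0.0 <= hi:
            covered += 1
    return {"n_replicates": n_replicates, "coverage": covered / n_replicates}


def check_rotation_control(
    seed: int = 1, n_structures: int = 1000, n_independent_reps: int = 20
) -> dict:
    """Planted compensation should show original variance far below the
    rotation control (small F, p < 0.01); under independence F ~ 1."""
    planted = SimulationConfig(
        n_structures=n_structures, loops_per_structure=("fixed", 6),
        compensation_slope=1.0, noise_sd=0.5, rng_seed=seed,
    )
    records = simulate_net_energy_records(planted)
    control = rotation_control(records)
    cmp_planted = compare_to_control(records, control)

    fs = []
    for rep in range(n_independent_reps):
        cfg = replace(planted, compensation_slope=0.0,
                      rng_seed=seed * 99_991 + rep)
        recs = simulate_net_energy_records(cfg)
        ctrl = rotation_control(recs)
        fs.append(compare_to_control(recs, ctrl).f_statistic)
    return {
        "n_structures": n_structures,
        "f_planted": cmp_planted.f_statistic,
        "p_planted": cmp_planted.p_value,
        "var_original": cmp_planted.var_original,
        "var_control": cmp_planted.var_control,
        "f_independent_mean": float(np.mean(fs)),
        "n_independent_reps": n_independent_reps,
    }


def check_hill_recovery(seed: int = 1, n_variants: int = 2000) -> dict:
    """End-to-end two-state recovery on a designed hairpin library.

    Generates the library, simulates reactivities, runs the fidelity
    pipeline, fits the Hill curve to binned local AUROC, and compares the
    fitted AUROC = 0.9 crossing with the model's analytic crossing; also
    regresses local and distal log stem reactivity on net dG.
    """
    config = SimulationConfig(rng_seed=seed)
    library = generate_library(hairpin_template(), n_variants, rng_seed=seed)
    profiles = simulate_reactivity_profiles(library, config)
    results, excluded = fidelity_table(profiles)
    fit = bin_auroc_fit_hill(results, bin_width=0.2, threshold=0.9)
    crossing = fit.crossing_at(0.9)
    target = analytic_crossing(0.9, config)
    local = net_dg_reactivity_regression(results, "log_mean_local_stem")
    distal = net_dg_reactivity_regression(results, "log_mean_distal_stem")
    nets = [v.net_dg for v in library]
    return {
        "n_variants": n_variants,
        "n_analyzed": len(results),
        "n_c_repeat_excluded": len(excluded),
        "net_dg_min": float(min(nets)),
        "net_dg_max": float(max(nets)),
        "fitted_crossing": crossing,
        "analytic_crossing": target,
        "crossing_error": None if crossing is None else abs(crossing - target),
        "hill_n": fit.hill_n,
        "hill_floor": fit.floor,
        "hill_ceiling": fit.ceiling,
        "degenerate": fit.degenerate,
        "local_slope": local.slope,
        "local_slope_ci": local.slope_ci95,
        "local_r2": local.r2,
        "distal_slope": distal.slope,
        "distal_slope_ci": distal.slope_ci95,
        "distal_ci_contains_zero": distal.slope_ci95[0] <= 0.0 <= distal.slope_ci95[1],
    }


def _toy_variant(name: str, length: int) -> LibraryVariant:
    return LibraryVariant(
        name=name, sequence="A" * length, designed_dotbracket="." * length,
        region_mask=tuple(["excluded"] * length), design_params={}, net_dg=0.0,
    )


def check_filters() -> dict:
    """Exact filter arithmetic on constructed toy sets."""
    lengths = [100] * 10 + [131]
    variants = [_toy_variant(f"v{i}", n) for i, n in enumerate(lengths)]
    kept, removed = length_filter(variants)
    base = _toy_variant("x", 9)
    with_repeat = replace(base, name="c5", sequence="AACCCCCAA")
    without = replace(base, name="c4", sequence="AACCCCAA",
                      designed_dotbracket="." * 8, region_mask=tuple(["excluded"] * 8))
    kept_c, removed_c = c_repeat_filter([with_repeat, without])
    return {
        "length_filter_kept": len(kept),
        "length_filter_removed": removed,
        "c_repeat_removed": len(removed_c),
        "c_repeat_kept": len(kept_c),
    }
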