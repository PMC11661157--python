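"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators stand in for the two data sources of the study:

* :func:`simulate_net_energy_records` emulates a structure database's
  substructure energies with a *planted* loop-stem compensation: loop dG is
  drawn from a positive distribution and the adjacent stem summary is
  ``-beta * loop - c + noise`` (plus family offsets), so ``beta = 1``
  reproduces compensation (net dG concentrated near ``-c``) and ``beta = 0``
  the independent null.

* :func:`simulate_reactivity_profiles` emulates DMS probing of designed
  variants under a two-state model: a variant folds as designed with
  Boltzmann probability ``p = 1 / (1 + exp(net_dG / RT))`` and is otherwise
  divergent.  Designed-paired A/C residues in the local region draw from the
  paired reactivity distribution with probability ``p`` and from the
  unpaired distribution otherwise; the distal region is always folded;
  designed-unpaired residues always draw unpaired; G/U residues are
  uninformative (missing).

:func:`random_structure` additionally samples random nested secondary
structures with canonical pairs (hairpin loops of three or more
nucleotides), used for decomposition and energy-evaluation testing.

All generators are reproducible from their seed; the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .lsc_stats import NetEnergyRecord, make_record
from .library_design import LibraryVariant
from .reactivity_analysis import ReactivityProfile

__all__ = [
    "SimulationConfig",
    "simulate_net_energy_records",
    "simulate_reactivity_profiles",
    "analytic_auroc_ceiling",
    "analytic_auroc",
    "analytic_crossing",
    "random_structure",
]

RT_37C = 0.6163  # kcal/mol at 310.15 K


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic database and reactivity model.

    Distribution specs are ``(name, *params)`` tuples: loops-per-structure
    accepts ``("fixed", n)``, ``("uniform", lo, hi)`` or ``("poisson", lam)``;
    the loop-dG spec accepts ``("lognormal", mu, sigma)`` or
    ``("uniform", lo, hi)`` (kcal/mol, positive support expected).
    """

    n_structures: int = 1000
    loops_per_structure: tuple = ("fixed", 6)
    loop_dg_distribution: tuple = ("lognormal", 1.25, 0.35)
    compensation_slope: float = 1.0       # beta
    compensation_offset: float = 3.0      # c: stem = -beta*loop - c + noise
    noise_sd: float = 0.5                 # kcal/mol
    stem_split_sd: float = 0.5            # spread of the two stems of a junction
    loop_kind_probs: Mapping[str, float] = field(
        default_factory=lambda: {"hairpin": 1.0}
    )
    family_offsets: Mapping[str, float] = field(default_factory=dict)
    rng_seed: int = 0
    # two-state reactivity model
    rt: float = RT_37C                    # kcal/mol
    paired_mean: float = 0.01             # exponential mean
    unpaired_mean: float = 0.10           # gamma mean
    unpaired_shape: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.rt <= 0:
            raise ValueError("RT must be positive")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if not math.isclose(sum(self.loop_kind_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("loop_kind_probs must sum to 1")
        _validate_spec(self.loops_per_structure, ("fixed", "uniform", "poisson"))
        _validate_spec(self.loop_dg_distribution, ("lognormal", "uniform"))


def _validate_spec(spec: tuple, allowed: tuple[str, ...]) -> None:
    if not spec or spec[0] not in allowed:
        raise ValueError(f"invalid distribution spec {spec!r}; expected one of {allowed}")


def _draw_counts(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    kind = spec[0]
    if kind == "fixed":
        return np.full(n, int(spec[1]))
    if kind == "uniform":
        return rng.integers(int(spec[1]), int(spec[2]) + 1, size=n)
    return np.maximum(rng.poisson(float(spec[1]), size=n), 1)


def _draw_loop_dg(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    if spec[0] == "lognormal":
        return rng.lognormal(float(spec[1]), float(spec[2]), size=n)
    return rng.uniform(float(spec[1]), float(spec[2]), size=n)


def simulate_net_energy_records(config: SimulationConfig) -> list[NetEnergyRecord]:
    """Synthetic per-loop records with planted compensation.

    For each loop, ``stem_summary = -beta * loop_dg - c + N(0, noise_sd)``
    plus the structure's family offset; two-way junctions split the summary
    symmetrically into two stems.  Net dG follows by definition.
    """
    rng = np.random.default_rng(config.rng_seed)
    families = sorted(config.family_offsets) or [""]
    kinds = sorted(config.loop_kind_probs)
    kind_p = np.array([config.loop_kind_probs[k] for k in kinds])
    counts = _draw_counts(rng, config.loops_per_structure, config.n_structures)
    records: list[NetEnergyRecord] = []
    label_char = {"hairpin": "H", "bulge": "B", "internal": "I"}
    for s in range(config.n_structures):
        fam = families[rng.integers(len(families))]
        offset = config.family_offsets.get(fam, 0.0)
        m = int(counts[s])
        loop_dg = _draw_loop_dg(rng, config.loop_dg_distribution, m)
        noise = rng.normal(0.0, config.noise_sd, size=m) if config.noise_sd else np.zeros(m)
        summary = (-config.compensation_slope * loop_dg
                   - config.compensation_offset + noise + offset)
        loop_kinds = rng.choice(kinds, size=m, p=kind_p)
        per_kind_counter: dict[str, int] = {}
        for k in range(m):
            kind = str(loop_kinds[k])
            per_kind_counter[kind] = per_kind_counter.get(kind, 0) + 1
            label = f"{label_char[kind]}{per_kind_counter[kind]}"
            if kind == "hairpin":
                stems: list[float] = [float(summary[k])]
            else:
                d = float(rng.normal(0.0, config.stem_split_sd))
                stems = [float(summary[k]) + d, float(summary[k]) - d]
            records.append(make_record(
                f"SYN{s:06d}", label, kind, float(loop_dg[k]), stems,
                rna_type=fam, taxon_tags=(),
            ))
    return records


# ---------------------------------------------------------------------------
# two-state reactivity model
# ---------------------------------------------------------------------------

def folded_fraction(net_dg: float, rt: float = RT_37C) -> float:
    """Two-state Boltzmann folded fraction p = 1/(1 + exp(net_dG / RT))."""
    return 1.0 / (1.0 + math.exp(net_dg / rt))


def _draw_paired(rng: np.random.Generator, config: SimulationConfig, size: int) -> np.ndarray:
    return rng.exponential(config.paired_mean, size=size)


def _draw_unpaired(rng: np.random.Generator, config: SimulationConfig, size: int) -> np.ndarray:
    return rng.gamma(config.unpaired_shape,
                     config.unpaired_mean / config.unpaired_shape, size=size)


def simulate_reactivity_profiles(
    variants: Sequence[LibraryVariant],
    config: SimulationConfig,
) -> list[ReactivityProfile]:
    """DMS-like reactivity profiles for designed variants.

    Per A/C residue: designed-unpaired residues draw from the unpaired
    distribution; designed-paired residues in the local region draw paired
    with probability ``p = folded_fraction(net_dg)`` and unpaired otherwise
    (per-residue Bernoulli, emulating an ensemble of molecules); the distal
    region is always folded.  G/U residues are missing (uninformative).
    """
    rng = np.random.default_rng(config.rng_seed)
    out: list[ReactivityProfile] = []
    for v in variants:
        if v.net_dg is None:
            raise ValueError(f"{v.name}: variant lacks net_dg")
        p = folded_fraction(v.net_dg, config.rt)
        n = len(v.sequence)
        react = np.full(n, math.nan)
        from .structure_io import pairing_from_dotbracket

        pairing, _ = pairing_from_dotbracket(v.designed_dotbracket)
        mask = ["excluded" if m == "primer" else m for m in v.region_mask]
        for i in range(n):
            if v.sequence[i] not in ("A", "C"):
                continue
            paired = pairing[i] > 0
            if not paired:
                react[i] = _draw_unpaired(rng, config, 1)[0]
            elif mask[i] == "local" and rng.random() >= p:
                react[i] = _draw_unpaired(rng, config, 1)[0]
            else:
                react[i] = _draw_paired(rng, config, 1)[0]
        out.append(ReactivityProfile(
            name=v.name,
            sequence=v.sequence,
            designed_dotbracket=v.designed_dotbracket,
            reactivity=tuple(react),
            region_mask=tuple(mask),
            net_dg=v.net_dg,
        ))
    return out


def analytic_auroc_ceiling(config: SimulationConfig, n_grid: int = 20001) -> float:
    """P(unpaired draw > paired draw) for the configured distributions,
    by numerical integration: the AUROC of a fully folded variant."""
    from scipy import stats as sps

    lam = 1.0 / config.paired_mean
    shape = config.unpaired_shape
    scale = config.unpaired_mean / shape
    # integrate P(U > x) f_P(x) dx on a log-dense grid
    x = np.linspace(0.0, config.paired_mean * 40.0, n_grid)
    f_p = lam * np.exp(-lam * x)
    sf_u = sps.gamma.sf(x, a=shape, scale=scale)
    return float(np.trapezoid(f_p * sf_u, x))


def analytic_auroc(net_dg: float, config: SimulationConfig) -> float:
    """Expected local AUROC under the two-state model.

    Positives are always unpaired draws; negatives are a p / (1-p) mixture
    of paired and unpaired draws, so AUROC = p * A_max + (1 - p) * 0.5 with
    A_max the fully-folded separation."""
    p = folded_fraction(net_dg, config.rt)
    a_max = analytic_auroc_ceiling(config)
    return p * a_max + (1.0 - p) * 0.5


def analytic_crossing(threshold: float, config: SimulationConfig) -> float:
    """Net dG at which the expected local AUROC equals ``threshold``."""
    a_max = analytic_auroc_ceiling(config)
    p_star = (threshold - 0.5) / (a_max - 0.5)
    if not 0.0 < p_star < 1.0:
        raise ValueError(f"threshold {threshold} unreachable (A_max={a_max:.4f})")
    return float(config.rt * math.log(1.0 / p_star - 1.0))


# ---------------------------------------------------------------------------
# random nested structures (testing support)
# ---------------------------------------------------------------------------

_PAIR_CHOICES = ("CG", "GC", "AU", "UA", "GU", "UG")
_PAIR_WEIGHTS = (0.30, 0.30, 0.16, 0.16, 0.04, 0.04)


def random_structure(
    rng: np.random.Generator,
    length: int,
    branch_prob: float = 0.55,
) -> tuple[str, str]:
    """Random nested secondary structure with canonical pairs.

    Hairpin loops are always at least 3 nt; helices may stack into bulges,
    internal loops, and multiloops.  Returns (sequence, dot-bracket).
    """

    def region(n: int) -> str:
        out: list[str] = []
        i = 0
        while i < n:
            rem = n - i
            if rem >= 7 and rng.random() < branch_prob:
                span = int(rng.integers(7, rem + 1))
                out.append(branch(span))
                i += span
            else:
                out.append(".")
                i += 1
        return "".join(out)

    def branch(span: int) -> str:
        hmax = min(8, (span - 3) // 2)
        h = int(rng.integers(1, hmax + 1))
        inner = span - 2 * h
        return "(" * h + region(inner) + ")" * h

    db = region(length)
    from .structure_io import pairing_from_dotbracket

    pairing, _ = pairing_from_dotbracket(db)
    seq = [""] * length
    bases = "ACGU"
    for i in range(1, length + 1):
        j = pairing[i - 1]
        if j == 0:
            seq[i - 1] = bases[rng.integers(4)]
        elif j > i:
            pair = _PAIR_CHOICES[rng.choice(len(_PAIR_CHOICES), p=_PAIR_WEIGHTS)]
            seq[i - 1], seq[j - 1] = pair[0], pair[1]
    return "".join(seq), db
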