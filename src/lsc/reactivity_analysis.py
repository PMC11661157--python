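"""Folding-fidelity statistics from per-nucleotide DMS reactivities.

DMS methylates accessible (unpaired) adenines and cytosines, read out as
per-position mutation fractions; G and U carry no signal.  Agreement of a
reactivity profile with its designed structure is quantified as the AUROC
over informative (A/C) residues, treating designed-unpaired residues as
positive predictions and the reactivity as the score: 1.0 means perfect
separation of loop from stem reactivities, 0.5 no discrimination.

Scopes: *global* (all residues), *local* (the randomized/variable region of
a designed variant), and *distal* (the constant control region).  Binned
local AUROC versus net dG follows a saturating sigmoid and is fit with the
Hill equation on a shifted stability scale; the fitted curve's crossing of a
chosen AUROC threshold gives the minimum net stability needed for
consistent folding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lsc_stats import LinearFit, _ols
from .structure_io import pairing_from_dotbracket

__all__ = [
    "ReactivityProfile",
    "AurocResult",
    "FidelityResult",
    "HillFit",
    "compute_auroc",
    "region_reactivities",
    "analyze_profile",
    "fidelity_table",
    "per_position_profile",
    "bin_auroc_fit_hill",
    "net_dg_reactivity_regression",
    "read_reactivity_table",
    "write_fidelity_tsv",
]

INFORMATIVE = ("A", "C")
DEFAULT_PSEUDOCOUNT = 1e-4
#: net-dG bin edges for the per-position profiles (kcal/mol)
DEFAULT_POSITION_BINS = (-20.0, -15.0, -10.0, -5.0, 0.0, 10.0)


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-nucleotide mutation fractions aligned to a designed structure.

    ``reactivity`` holds one value per position (NaN = missing/no
    coverage); ``region_mask`` holds one of ``local`` / ``distal`` /
    ``excluded`` per position.  ``net_dg`` is the designed net free energy
    of the variable substructure, carried along for binning.
    """

    name: str
    sequence: str
    designed_dotbracket: str
    reactivity: tuple[float, ...]
    region_mask: tuple[str, ...]
    net_dg: float | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (len(self.designed_dotbracket) == len(self.reactivity)
                == len(self.region_mask) == n):
            raise ValueError(f"{self.name}: field lengths differ")
        bad = [x for x in self.reactivity if not math.isnan(x) and x < 0]
        if bad:
            raise ValueError(f"{self.name}: negative reactivities")

    def paired(self) -> np.ndarray:
        pairing, _ = pairing_from_dotbracket(self.designed_dotbracket)
        return np.array([p > 0 for p in pairing])

    def informative(self) -> np.ndarray:
        seq = np.array(list(self.sequence))
        react = np.asarray(self.reactivity)
        return np.isin(seq, INFORMATIVE) & ~np.isnan(react)

    def scope_mask(self, scope: str) -> np.ndarray:
        mask = np.asarray(self.region_mask)
        if scope == "global":
            return np.ones(len(self.sequence), dtype=bool)
        if scope in ("local", "distal"):
            return mask == scope
        raise ValueError(f"unknown scope {scope!r}")


@dataclass(frozen=True)
class AurocResult:
    value: float | None
    n_pos: int
    n_neg: int
    reason: str = ""


def compute_auroc(profile: ReactivityProfile, scope: str = "global") -> AurocResult:
    """Rank-based AUROC over informative residues in the given scope.

    Designed-unpaired residues are the positives, reactivity is the score;
    ties are credited 0.5 (Mann-Whitney convention), so the value equals
    brute-force concordant-pair counting.  Returns a missing value with a
    reason when a class is empty.
    """
    keep = profile.informative() & profile.scope_mask(scope)
    paired = profile.paired()
    scores = np.asarray(profile.reactivity)[keep]
    positives = ~paired[keep]
    n_pos = int(positives.sum())
    n_neg = int(len(positives) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return AurocResult(None, n_pos, n_neg,
                           f"no {'positives' if n_pos == 0 else 'negatives'} in scope {scope}")
    ranks = stats.rankdata(scores)  # average ranks: ties get 0.5 credit
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0
    return AurocResult(float(u / (n_pos * n_neg)), n_pos, n_neg)


@dataclass(frozen=True)
class FidelityResult:
    name: str
    net_dg: float | None
    auroc_global: float | None
    auroc_local: float | None
    auroc_distal: float | None
    mean_local_stem_reactivity: float | None
    mean_distal_stem_reactivity: float | None
    mean_local_loop_reactivity: float | None
    mean_distal_loop_reactivity: float | None
    log_mean_local_stem_reactivity: float | None
    log_mean_distal_stem_reactivity: float | None
    log_mean_local_loop_reactivity: float | None
    log_mean_distal_loop_reactivity: float | None


def _region_mean(profile: ReactivityProfile, region: str, want_paired: bool) -> float | None:
    keep = (profile.informative() & profile.scope_mask(region)
            & (profile.paired() == want_paired))
    if not keep.any():
        return None
    return float(np.asarray(profile.reactivity)[keep].mean())


def region_reactivities(
    profile: ReactivityProfile,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, float | None]:
    """Mean reactivity of informative residues per (region x stem/loop),
    with log10(mean + pseudocount) transforms alongside."""
    out: dict[str, float | None] = {}
    for region in ("local", "distal"):
        for part, want_paired in (("stem", True), ("loop", False)):
            m = _region_mean(profile, region, want_paired)
            out[f"mean_{region}_{part}_reactivity"] = m
            out[f"log_mean_{region}_{part}_reactivity"] = (
                None if m is None else math.log10(m + pseudocount)
            )
    return out


def analyze_profile(
    profile: ReactivityProfile,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FidelityResult:
    """AUROC in all three scopes plus region reactivity means."""
    means = region_reactivities(profile, pseudocount)
    return FidelityResult(
        name=profile.name,
        net_dg=profile.net_dg,
        auroc_global=compute_auroc(profile, "global").value,
        auroc_local=compute_auroc(profile, "local").value,
        auroc_distal=compute_auroc(profile, "distal").value,
        **means,  # type: ignore[arg-type]
    )


def fidelity_table(
    profiles: Sequence[ReactivityProfile],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[list[FidelityResult], list[str]]:
    """Analyze profiles after the C-repeat exclusion.

    Sequences with more than four consecutive C are removed first (DMS
    reactivities in long C runs are unreliable) and reported by name, never
    silently dropped.
    """
    from .library_design import has_c_repeat

    excluded = [p.name for p in profiles if has_c_repeat(p.sequence)]
    kept = [p for p in profiles if p.name not in set(excluded)]
    return [analyze_profile(p, pseudocount) for p in kept], excluded


# ---------------------------------------------------------------------------
# per-position stem reactivity profiles
# ---------------------------------------------------------------------------

def _local_stem_positions(profile: ReactivityProfile) -> list[list[tuple[int, ...]]]:
    """Per local stem: positions (0-based) of pairs indexed from the loop.

    Element ``[s][k]`` holds the two sequence positions of stem ``s``'s pair
    at distance ``k+1`` from the variable loop (pair 1 = closing pair).
    """
    from .structure_io import annotate_from_dotbracket

    st = annotate_from_dotbracket(profile.sequence, profile.designed_dotbracket,
                                  profile.name)
    mask = np.asarray(profile.region_mask)
    loops = [
        r for r in st.substructures
        if r.kind in ("hairpin", "bulge", "internal")
        and all(mask[p - 1] == "local" for p in r.positions())
        and r.positions()
    ]
    if not loops:
        return []
    loop = loops[0]
    by_inner = {s.closing_pairs[1]: s for s in st.records("stem")}
    by_outer = {s.closing_pairs[0]: s for s in st.records("stem")}
    out: list[list[tuple[int, ...]]] = []
    # enclosing stem: count from its inner pair outward
    stem = by_inner[loop.closing_pairs[0]]
    (i0, j0), (ii, jj) = stem.closing_pairs
    out.append([(ii - k, jj + k) for k in range(stem.length_summary[0])])
    if loop.kind in ("bulge", "internal"):
        # nested stem: count from its outer pair inward
        stem2 = by_outer[loop.closing_pairs[1]]
        (p0, q0), _ = stem2.closing_pairs
        out.append([(p0 + k, q0 - k) for k in range(stem2.length_summary[0])])
    return out


@dataclass(frozen=True)
class PositionBinStat:
    bin_label: str
    position: int
    mean: float
    ci95_halfwidth: float
    n_molecules: int
    n_nucleotides: int


def per_position_profile(
    profiles: Sequence[ReactivityProfile],
    bins: Sequence[float] = DEFAULT_POSITION_BINS,
    max_position: int = 6,
    min_nucleotides: int = 70,
) -> list[PositionBinStat]:
    """Mean reactivity (+/- 95% CI) of stem pairs 1..6 counted from the
    variable loop, per net-dG bin.

    Per molecule, a pair's value is the mean of its informative residues;
    for two-way junctions the two stems' same-index values are averaged
    before pooling.  (bin, position) cells with fewer than
    ``min_nucleotides`` contributing informative nucleotides are omitted.
    """
    edges = np.asarray(bins, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least one bin")
    values: dict[tuple[int, int], list[float]] = {}
    ncounts: dict[tuple[int, int], int] = {}
    for profile in profiles:
        if profile.net_dg is None:
            raise ValueError(f"{profile.name}: profile lacks net_dg")
        b = int(np.digitize(profile.net_dg, edges)) - 1
        if b < 0 or b >= len(edges) - 1:
            continue
        stems = _local_stem_positions(profile)
        if not stems:
            continue
        react = np.asarray(profile.reactivity)
        info = profile.informative()
        for k in range(max_position):
            per_stem: list[float] = []
            n_nt = 0
            for stem in stems:
                if k >= len(stem):
                    continue
                vals = [react[p - 1] for p in stem[k] if info[p - 1]]
                if vals:
                    per_stem.append(float(np.mean(vals)))
                    n_nt += len(vals)
            if per_stem:
                key = (b, k + 1)
                values.setdefault(key, []).append(float(np.mean(per_stem)))
                ncounts[key] = ncounts.get(key, 0) + n_nt
    out: list[PositionBinStat] = []
    for (b, pos), vals in sorted(values.items()):
        if ncounts[(b, pos)] < min_nucleotides:
            continue
        arr = np.asarray(vals)
        sem = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
        out.append(PositionBinStat(
            bin_label=f"[{edges[b]:g},{edges[b+1]:g})",
            position=pos,
            mean=float(arr.mean()),
            ci95_halfwidth=float(1.96 * sem),
            n_molecules=len(arr),
            n_nucleotides=ncounts[(b, pos)],
        ))
    if not out:
        raise ValueError("no (bin, position) cell met the sample-size rule")
    return out


# ---------------------------------------------------------------------------
# Hill fit of binned AUROC vs net dG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillFit:
    """Hill curve A(s) = floor + (ceiling - floor) s^n / (K^n + s^n) on the
    stability scale s = offset - net_dg (kcal/mol, s >= 0 on fitted bins)."""

    floor: float
    ceiling: float
    midpoint: float  # K, stability scale
    hill_n: float
    offset: float
    bin_centers: tuple[float, ...] = ()
    bin_means: tuple[float, ...] = ()
    bin_counts: tuple[int, ...] = ()
    degenerate: bool = False
    message: str = ""

    def predict_stability(self, s: np.ndarray | float) -> np.ndarray | float:
        s = np.maximum(np.asarray(s, dtype=float), 0.0)
        return self.floor + (self.ceiling - self.floor) * s ** self.hill_n / (
            self.midpoint ** self.hill_n + s ** self.hill_n
        )

    def predict(self, net_dg: np.ndarray | float) -> np.ndarray | float:
        return self.predict_stability(self.offset - np.asarray(net_dg, dtype=float))

    def crossing_at(self, threshold: float) -> float | None:
        """net dG at which the fitted curve crosses ``threshold``
        (closed form; None when the threshold is outside (floor, ceiling))."""
        if self.degenerate or not (self.floor < threshold < self.ceiling):
            return None
        s = self.midpoint * ((threshold - self.floor) /
                             (self.ceiling - threshold)) ** (1.0 / self.hill_n)
        return float(self.offset - s)


def _hill(s, floor, ceiling, k, n):
    return floor + (ceiling - floor) * s ** n / (k ** n + s ** n)


def bin_auroc_fit_hill(
    results: Sequence[FidelityResult],
    bin_width: float = 0.2,
    threshold: float = 0.9,
    min_bin_count: int = 1,
) -> HillFit:
    """Average local AUROC in net-dG bins and fit the Hill equation.

    The stability scale is s = offset - net dG with the offset at the
    largest populated bin edge, so every fitted bin has s >= 0.  Flat or
    non-convergent data yield a degenerate fit flagged with diagnostics;
    ``crossing_at(threshold)`` reports the net dG of the threshold crossing.
    """
    pts = [(r.net_dg, r.auroc_local) for r in results
           if r.net_dg is not None and r.auroc_local is not None]
    if not pts:
        raise ValueError("no results with net_dg and local AUROC")
    net = np.array([p[0] for p in pts])
    auc = np.array([p[1] for p in pts])
    idx = np.floor(net / bin_width).astype(int)
    centers, means, counts = [], [], []
    for b in np.unique(idx):
        sel = idx == b
        if sel.sum() < min_bin_count:
            continue
        centers.append((b + 0.5) * bin_width)
        means.append(float(auc[sel].mean()))
        counts.append(int(sel.sum()))
    centers = np.array(centers)
    means = np.array(means)
    if len(centers) < 5:
        raise ValueError(f"need >= 5 populated bins, got {len(centers)}")
    offset = float((np.floor(net.max() / bin_width) + 1) * bin_width)
    s = offset - centers

    base = dict(
        offset=offset, bin_centers=tuple(centers), bin_means=tuple(means),
        bin_counts=tuple(counts),
    )
    if float(means.max() - means.min()) < 0.02:
        return HillFit(
            floor=float(means.mean()), ceiling=float(means.mean()),
            midpoint=math.nan, hill_n=math.nan, degenerate=True,
            message="flat AUROC data: no transition to fit", **base,
        )
    try:
        p0 = (max(means.min(), 0.01), min(means.max(), 1.0),
              max(float(np.median(s)), 0.5), 2.0)
        popt, _ = optimize.curve_fit(
            _hill, s, means, p0=p0,
            bounds=((0.0, 0.0, 1e-6, 0.05), (1.5, 1.5, 100.0, 50.0)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return HillFit(
            floor=math.nan, ceiling=math.nan, midpoint=math.nan,
            hill_n=math.nan, degenerate=True,
            message=f"Hill fit did not converge: {exc}", **base,
        )
    floor, ceiling, k, n = (float(v) for v in popt)
    if not floor < ceiling:
        return HillFit(
            floor=floor, ceiling=ceiling, midpoint=k, hill_n=n,
            degenerate=True, message="inverted fit (floor >= ceiling)", **base,
        )
    return HillFit(floor=floor, ceiling=ceiling, midpoint=k, hill_n=n, **base)


# ---------------------------------------------------------------------------
# regressions of reactivity on net dG
# ---------------------------------------------------------------------------

_RESPONSES = {
    "log_mean_local_stem": "log_mean_local_stem_reactivity",
    "log_mean_distal_stem": "log_mean_distal_stem_reactivity",
    "log_mean_local_loop": "log_mean_local_loop_reactivity",
    "log_mean_distal_loop": "log_mean_distal_loop_reactivity",
}


def net_dg_reactivity_regression(
    results: Sequence[FidelityResult],
    response: str = "log_mean_local_stem",
    min_results: int = 10,
) -> LinearFit:
    """OLS of a reactivity response on net dG (slope CI and R^2)."""
    if response in _RESPONSES:
        attr = _RESPONSES[response]
    elif response in FidelityResult.__dataclass_fields__:
        attr = response
    else:
        raise ValueError(f"unknown response {response!r}")
    xs, ys = [], []
    for r in results:
        y = getattr(r, attr)
        if r.net_dg is not None and y is not None:
            xs.append(r.net_dg)
            ys.append(y)
    if len(xs) < min_results:
        raise ValueError(f"need >= {min_results} results with {response}, got {len(xs)}")
    return _ols(np.asarray(xs), np.asarray(ys))


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def read_reactivity_table(
    table_path,
    designs: Mapping[str, str],
    masks: Mapping[str, Sequence[str]],
    net_dgs: Mapping[str, float] | None = None,
) -> list[ReactivityProfile]:
    """Assemble profiles from a long-format reactivity table.

    The table (CSV/TSV by extension) needs columns ``name``, ``position``
    (1-based), ``base`` and ``mutation_fraction``; ``designs`` maps name to
    designed dot-bracket, ``masks`` to per-position region labels.
    Positions absent from the table are missing (NaN).
    """
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(table_path, sep=sep)
    need = {"name", "position", "base", "mutation_fraction"}
    if not need <= set(df.columns):
        raise ValueError(f"reactivity table missing columns {need - set(df.columns)}")
    out = []
    for name, grp in df.groupby("name", sort=True):
        if name not in designs:
            raise KeyError(f"no designed structure for {name}")
        db = designs[name]
        n = len(db)
        seq = ["N"] * n
        react = [math.nan] * n
        for row in grp.itertuples(index=False):
            p = int(row.position)
            if not 1 <= p <= n:
                raise ValueError(f"{name}: position {p} outside 1..{n}")
            seq[p - 1] = str(row.base).upper().replace("T", "U")
            react[p - 1] = float(row.mutation_fraction)
        out.append(ReactivityProfile(
            name=str(name),
            sequence="".join(seq),
            designed_dotbracket=db,
            reactivity=tuple(react),
            region_mask=tuple(masks[name]),
            net_dg=None if net_dgs is None else net_dgs.get(name),
        ))
    return out


def write_fidelity_tsv(results: Sequence[FidelityResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
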