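"""Net free-energy records and database-level local-stability statistics.

The unit of analysis is one loop (hairpin, bulge, or internal loop) together
with its adjacent stem(s).  Its *net dG* is the sum of the destabilizing
loop free energy and the stabilizing stem free energy — the single adjacent
stem for hairpins, the arithmetic mean of the two flanking stems for two-way
junctions.  Local stability compensation (LSC) predicts that more
destabilizing loops sit next to more stabilizing stems, so that net dG stays
in a consistent, mostly negative band.

This module provides the record container, binned loop-vs-stem regressions
(median and 5% weakest-stem quantile per loop-dG bin), an in-structure
rotation control that pairs each loop with a distal loop's stems, the
frequency/variance comparison against that control, and per-group summaries
with pairwise tests.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure_io import AnnotatedStructure, SubstructureRecord
from .energy_model import (
    DEFAULT_CONFIG,
    EnergyConfig,
    NearestNeighborParams,
    structure_energy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NetEnergyRecord",
    "BinSummary",
    "LinearFit",
    "BinRegressionResult",
    "ControlComparison",
    "GroupSummary",
    "net_energy",
    "make_record",
    "net_energy_records",
    "bin_loop_vs_stem",
    "rotation_control",
    "compare_to_control",
    "summarize_groups",
    "records_to_frame",
    "write_records_tsv",
    "read_records_tsv",
]

LOOP_KINDS = ("hairpin", "bulge", "internal")


def net_energy(loop_dg: float, stem_dgs: Sequence[float]) -> float:
    """loop dG plus the stem summary (single stem, or mean of the two
    flanking stems for two-way junctions)."""
    if not 1 <= len(stem_dgs) <= 2:
        raise ValueError(f"expected 1 or 2 stem energies, got {len(stem_dgs)}")
    return float(loop_dg) + float(np.mean(stem_dgs))


@dataclass(frozen=True)
class NetEnergyRecord:
    """One loop with its adjacent stem energies and net dG (kcal/mol)."""

    structure_id: str
    loop_label: str
    loop_kind: str
    loop_dg: float
    stem_dgs: tuple[float, ...]
    stem_summary: float
    net_dg: float
    rna_type: str = ""
    taxon_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.loop_kind not in LOOP_KINDS:
            raise ValueError(f"unknown loop kind {self.loop_kind!r}")


def make_record(
    structure_id: str,
    loop_label: str,
    loop_kind: str,
    loop_dg: float,
    stem_dgs: Sequence[float],
    rna_type: str = "",
    taxon_tags: Iterable[str] = (),
) -> NetEnergyRecord:
    """Build a record with stem summary and net dG derived by definition."""
    summary = float(np.mean(stem_dgs))
    return NetEnergyRecord(
        structure_id=structure_id,
        loop_label=loop_label,
        loop_kind=loop_kind,
        loop_dg=float(loop_dg),
        stem_dgs=tuple(float(s) for s in stem_dgs),
        stem_summary=summary,
        net_dg=net_energy(loop_dg, stem_dgs),
        rna_type=rna_type,
        taxon_tags=frozenset(taxon_tags),
    )


def net_energy_records(
    structure: AnnotatedStructure,
    params: NearestNeighborParams,
    config: EnergyConfig = DEFAULT_CONFIG,
    rna_type: str = "",
    taxon_tags: Iterable[str] = (),
) -> list[NetEnergyRecord]:
    """Per-loop net-dG records for every computable hairpin, bulge, and
    internal loop of an annotated structure.

    The adjacent stems are found through the loop's closing pairs: the outer
    closing pair is the inner pair of the enclosing stem, the inner closing
    pair (two-way junctions) is the outer pair of the nested stem.  Loops
    with a non-computable loop or stem energy are skipped with a debug log.
    """
    result = structure_energy(structure, params, config)
    by_inner = {s.closing_pairs[1]: s for s in structure.records("stem")}
    by_outer = {s.closing_pairs[0]: s for s in structure.records("stem")}
    out: list[NetEnergyRecord] = []
    tags = frozenset(taxon_tags)
    for rec in structure.substructures:
        if rec.kind not in LOOP_KINDS:
            continue
        loop_e = result.components[rec.label]
        if not loop_e.computable:
            logger.debug("skipping %s/%s: %s", structure.identifier, rec.label, loop_e.reason)
            continue
        stems = [by_inner[rec.closing_pairs[0]]]
        if rec.kind in ("bulge", "internal"):
            stems.append(by_outer[rec.closing_pairs[1]])
        stem_es = [result.components[s.label] for s in stems]
        if not all(e.computable for e in stem_es):
            logger.debug("skipping %s/%s: stem non-computable", structure.identifier, rec.label)
            continue
        out.append(make_record(
            structure.identifier, rec.label, rec.kind,
            loop_e.value, [e.value for e in stem_es],
            rna_type=rna_type, taxon_tags=tags,
        ))
    return out


# ---------------------------------------------------------------------------
# binned loop-vs-stem regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinSummary:
    bin_center: float
    count: int
    median: float
    q05: float
    values: tuple[float, ...]


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r2: float
    stderr: float
    slope_ci95: tuple[float, float]
    n: int

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def _ols(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> LinearFit:
    """(Weighted) least-squares line with a t-based 95% CI on the slope.

    Weights handle heteroscedastic responses such as per-bin medians, whose
    sampling variance scales inversely with the bin count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    if n > 2:
        sigma2 = (w * resid ** 2).sum() / (n - 2)
        stderr = math.sqrt(sigma2 / sxx)
        tcrit = stats.t.ppf(0.975, n - 2)
        ci = (slope - tcrit * stderr, slope + tcrit * stderr)
    else:
        stderr = math.nan
        ci = (-math.inf, math.inf)
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 - (w * resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        stderr=float(stderr),
        slope_ci95=(float(ci[0]), float(ci[1])),
        n=n,
    )


@dataclass(frozen=True)
class BinRegressionResult:
    bins: tuple[BinSummary, ...]
    median_fit: LinearFit
    q05_fit: LinearFit
    excluded_bins: int  # populated below the per-bin minimum


def _bin_edges(values: np.ndarray, width: float) -> np.ndarray:
    """Bin index per value, with edges anchored at 0 kcal/mol."""
    return np.floor(values / width).astype(int)


def bin_loop_vs_stem(
    records: Sequence[NetEnergyRecord],
    bin_width: float = 0.25,
    min_bin_count: int = 20,
    n_boot: int = 500,
    boot_seed: int = 0,
) -> BinRegressionResult:
    """Bin loop dG (edges anchored at 0) and regress the per-bin median and
    5% quantile of the stem summary on the bin centers.

    The fits weight bins by their record counts (the sampling variance of a
    bin summary scales as 1/n).  Slope confidence intervals come from a
    stratified within-bin bootstrap (percentile, ``n_boot`` resamples,
    seeded), which stays calibrated for the heteroscedastic, non-Gaussian
    bin medians; set ``n_boot=0`` for the parametric t-interval.  Bins with
    fewer than ``min_bin_count`` records are excluded from the fits (their
    count is reported).  Raises if fewer than two bins remain.
    """
    if not records:
        raise ValueError("no records")
    loop = np.array([r.loop_dg for r in records])
    stem = np.array([r.stem_summary for r in records])
    idx = _bin_edges(loop, bin_width)
    summaries: list[BinSummary] = []
    excluded = 0
    for b in np.unique(idx):
        vals = stem[idx == b]
        if len(vals) < min_bin_count:
            excluded += 1
            continue
        summaries.append(BinSummary(
            bin_center=(b + 0.5) * bin_width,
            count=len(vals),
            median=float(np.median(vals)),
            q05=float(np.quantile(vals, 0.05)),  # linear interpolation
            values=tuple(vals),
        ))
    if len(summaries) < 2:
        raise ValueError(
            f"need >= 2 populated bins (min {min_bin_count} records each), "
            f"got {len(summaries)}"
        )
    centers = np.array([s.bin_center for s in summaries])
    counts = np.array([s.count for s in summaries], dtype=float)
    median_fit = _ols(centers, np.array([s.median for s in summaries]), counts)
    q05_fit = _ols(centers, np.array([s.q05 for s in summaries]), counts)
    if n_boot:
        rng = np.random.default_rng(boot_seed)
        med_b, q05_b = [], []
        for s in summaries:
            vals = np.asarray(s.values)
            res = vals[rng.integers(0, len(vals), size=(n_boot, len(vals)))]
            med_b.append(np.median(res, axis=1))
            q05_b.append(np.quantile(res, 0.05, axis=1))
        median_fit = _with_boot_ci(median_fit, centers, counts, np.vstack(med_b))
        q05_fit = _with_boot_ci(q05_fit, centers, counts, np.vstack(q05_b))
    return BinRegressionResult(
        bins=tuple(summaries),
        median_fit=median_fit,
        q05_fit=q05_fit,
        excluded_bins=excluded,
    )


def _with_boot_ci(
    fit: LinearFit, x: np.ndarray, w: np.ndarray, y_boot: np.ndarray
) -> LinearFit:
    """Replace a fit's slope CI/stderr with stratified-bootstrap values
    (``y_boot``: bins x resamples)."""
    sw = w.sum()
    xbar = (w * x).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    ybar = (w[:, None] * y_boot).sum(axis=0) / sw
    slopes = ((w * (x - xbar))[:, None] * (y_boot - ybar)).sum(axis=0) / sxx
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return replace(
        fit,
        stderr=float(slopes.std(ddof=1)),
        slope_ci95=(float(lo), float(hi)),
    )


# ---------------------------------------------------------------------------
# rotation control
# ---------------------------------------------------------------------------

def rotation_control(records: Sequence[NetEnergyRecord]) -> list[NetEnergyRecord]:
    """In-structure null: replace each loop's stems with those of a distal
    loop of the same kind in the same structure (cyclic shift by 2 in
    annotation order).

    Only (structure, kind) groups with more than three loops participate, so
    no loop can receive one of its own stems; records where the shifted stem
    set still intersects the loop's own stems (stems shared with a
    neighboring loop) are dropped.  Ineligible groups are silently excluded
    (counts logged).
    """
    groups: dict[tuple[str, str], list[NetEnergyRecord]] = defaultdict(list)
    for r in records:
        groups[(r.structure_id, r.loop_kind)].append(r)
    out: list[NetEnergyRecord] = []
    ineligible = 0
    dropped_shared = 0
    for key, grp in groups.items():
        m = len(grp)
        if m <= 3:
            ineligible += 1
            continue
        for i, r in enumerate(grp):
            donor = grp[(i + 2) % m]
            if set(donor.stem_dgs) & set(r.stem_dgs):
                dropped_shared += 1
                continue
            out.append(make_record(
                r.structure_id, r.loop_label + "_ctrl", r.loop_kind,
                r.loop_dg, donor.stem_dgs,
                rna_type=r.rna_type, taxon_tags=r.taxon_tags,
            ))
    logger.info(
        "rotation_control: %d control records, %d ineligible groups, "
        "%d dropped for shared stems", len(out), ineligible, dropped_shared,
    )
    return out


@dataclass(frozen=True)
class ControlComparison:
    bin_centers: tuple[float, ...]
    frequency_difference: tuple[float, ...]  # original minus control, sums to 0
    f_statistic: float
    p_value: float
    var_original: float
    var_control: float
    n_original: int
    n_control: int


def compare_to_control(
    records: Sequence[NetEnergyRecord],
    control: Sequence[NetEnergyRecord],
    bin_width: float = 0.25,
    alternative: str = "two-sided",
) -> ControlComparison:
    """Per-bin net-dG frequency difference (original - control, both
    normalized) plus an F test on the two variances."""
    if not records or not control:
        raise ValueError("both record sets must be non-empty")
    x = np.array([r.net_dg for r in records])
    y = np.array([r.net_dg for r in control])
    bx = _bin_edges(x, bin_width)
    by = _bin_edges(y, bin_width)
    lo = min(bx.min(), by.min())
    hi = max(bx.max(), by.max())
    all_bins = np.arange(lo, hi + 1)
    fx = np.array([(bx == b).sum() for b in all_bins], dtype=float) / len(x)
    fy = np.array([(by == b).sum() for b in all_bins], dtype=float) / len(y)
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    cdf = stats.f.cdf(f, dfx, dfy)
    if alternative == "two-sided":
        p = 2.0 * min(cdf, 1.0 - cdf)
    elif alternative == "less":  # original variance smaller than control
        p = cdf
    elif alternative == "greater":
        p = 1.0 - cdf
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return ControlComparison(
        bin_centers=tuple((all_bins + 0.5) * bin_width),
        frequency_difference=tuple(fx - fy),
        f_statistic=f,
        p_value=float(min(p, 1.0)),
        var_original=vx,
        var_control=vy,
        n_original=len(x),
        n_control=len(y),
    )


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    group: str
    count: int
    median: float
    sd: float
    kde_x: tuple[float, ...]
    kde_y: tuple[float, ...]
    kde_bandwidth: float


def summarize_groups(
    records: Sequence[NetEnergyRecord],
    group_key: str = "rna_type",
    min_group: int = 20,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[dict[str, GroupSummary], dict[tuple[str, str], float]]:
    """Per-group net-dG summaries (median, SD, Gaussian KDE with Scott's
    rule) and pairwise Mann-Whitney U p-values.

    ``group_key`` is ``"rna_type"`` or ``"taxon"`` (a record with several
    taxon tags contributes to each).  Groups below ``min_group`` are
    dropped.  ``pairs`` restricts the tests; by default all group pairs are
    tested (none if a single group remains).
    """
    groups: dict[str, list[float]] = defaultdict(list)
    if group_key == "rna_type":
        for r in records:
            groups[r.rna_type].append(r.net_dg)
    elif group_key == "taxon":
        for r in records:
            for t in r.taxon_tags:
                groups[t].append(r.net_dg)
    else:
        raise ValueError(f"unknown group key {group_key!r}")
    groups = {g: v for g, v in groups.items() if len(v) >= min_group}

    summaries: dict[str, GroupSummary] = {}
    for g, vals in sorted(groups.items()):
        arr = np.asarray(vals)
        if len(arr) > 1 and np.ptp(arr) > 0:
            kde = stats.gaussian_kde(arr)  # Scott's rule bandwidth
            xs = np.linspace(arr.min() - 1.0, arr.max() + 1.0, 200)
            ys = kde(xs)
            bw = float(kde.factor * arr.std(ddof=1))
        else:
            xs = np.asarray([float(arr[0])]) if len(arr) else np.asarray([])
            ys = np.ones_like(xs)
            bw = 0.0
        summaries[g] = GroupSummary(
            group=g, count=len(arr), median=float(np.median(arr)),
            sd=float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0,
            kde_x=tuple(xs), kde_y=tuple(ys), kde_bandwidth=bw,
        )

    tests: dict[tuple[str, str], float] = {}
    names = sorted(summaries)
    if pairs is None:
        pairs = [(a, b) for k, a in enumerate(names) for b in names[k + 1:]]
    for a, b in pairs:
        if a in groups and b in groups:
            stat = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            tests[(a, b)] = float(stat.pvalue)
    return summaries, tests


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

_COLUMNS = [
    "structure_id", "loop_label", "kind", "loop_dg",
    "stem_dg_1", "stem_dg_2", "rna_type", "taxa",
]


def records_to_frame(records: Sequence[NetEnergyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "structure_id": r.structure_id,
            "loop_label": r.loop_label,
            "kind": r.loop_kind,
            "loop_dg": r.loop_dg,
            "stem_dg_1": r.stem_dgs[0],
            "stem_dg_2": r.stem_dgs[1] if len(r.stem_dgs) > 1 else np.nan,
            "rna_type": r.rna_type,
            "taxa": ";".join(sorted(r.taxon_tags)),
            "stem_summary": r.stem_summary,
            "net_dg": r.net_dg,
        })
    return pd.DataFrame(rows)


def write_records_tsv(records: Sequence[NetEnergyRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> list[NetEnergyRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        stems = [row.stem_dg_1]
        if not pd.isna(row.stem_dg_2):
            stems.append(row.stem_dg_2)
        taxa = [] if pd.isna(row.taxa) or not row.taxa else str(row.taxa).split(";")
        out.append(make_record(
            str(row.structure_id), str(row.loop_label), str(row.kind),
            float(row.loop_dg), stems,
            rna_type="" if pd.isna(row.rna_type) else str(row.rna_type),
            taxon_tags=taxa,
        ))
    return out
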