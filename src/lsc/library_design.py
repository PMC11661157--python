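"""Randomized RNA variant libraries on a triply-bulged hairpin template.

Each library probes one loop type (hairpin, bulge, or internal loop) with a
variable region — the studied loop and its adjacent stem(s) — embedded in a
constant scaffold that serves as the distal control.  The scaffold, from the
outside in, is: a short 5' flank, constant stems S1/S2 separated by constant
two-nucleotide bulges, the variable substructure, and a 3' flank.  The
hairpin library varies the terminal stem and its loop; the bulge and
internal-loop libraries vary the studied loop and both flanking stems (the
apical hairpin loop is then constant).

Sequence constraints follow the library-synthesis rules: loop residues are
A/C only (DMS-informative), variable stems vary in length, GC content, and
G:U pairs; constant stems keep a fixed GC content, G:C/C:G closing pairs,
no G:U pairs, and are accepted only within a narrow band around the modal
stacking energy so their free energy is near-constant while their sequence
varies.  Variants must be mutually distinct: pairwise distance of at least
20 under positional mismatches over the shared prefix plus the absolute
length difference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .energy_model import (
    DEFAULT_CONFIG,
    EnergyConfig,
    NearestNeighborParams,
    default_params,
    pair_type,
    structure_energy,
)
from .lsc_stats import net_energy
from .structure_io import AnnotatedStructure, annotate_from_dotbracket

__all__ = [
    "DesignTemplate",
    "LibraryVariant",
    "hairpin_template",
    "bulge_template",
    "internal_template",
    "generate_library",
    "length_filter",
    "c_repeat_filter",
    "has_c_repeat",
    "sequence_distance",
    "studied_loop_net_dg",
    "write_fasta",
    "write_design_csv",
    "write_masks_json",
]

_PAIRS_NO_GU = ("GC", "CG", "AU", "UA")
_PAIRS_GU = ("GU", "UG")


@dataclass(frozen=True)
class DesignTemplate:
    """Design rules for one library type.

    Bounds are inclusive; stem lengths in base pairs, loop lengths in
    nucleotides (per strand for internal loops).
    """

    kind: str  # hairpin | bulge | internal
    stem_bounds: tuple[int, int] = (4, 12)
    hairpin_bounds: tuple[int, int] = (3, 11)
    bulge_bounds: tuple[int, int] = (1, 9)
    internal_bounds: tuple[int, int] = (1, 9)
    const_stem_len: int = 7
    const_gc: float = 0.5  # fixed GC content of constant stems
    const_bulge_len: int = 2
    const_hairpin_len: int = 4
    const_energy_tol: float = 0.25  # kcal/mol band around the modal energy
    p5: str = "GG"
    p3: str = "AACAACAAAC"
    gc_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    gu_grid: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.kind not in ("hairpin", "bulge", "internal"):
            raise ValueError(f"unknown library kind {self.kind!r}")

    def median_lengths(self) -> dict[str, int]:
        mid = lambda b: (b[0] + b[1]) // 2
        d = {"s4": mid(self.stem_bounds)}
        if self.kind == "hairpin":
            d.update(s3=self.const_stem_len, b3=self.const_bulge_len,
                     loop1=mid(self.hairpin_bounds), loop2=0)
        elif self.kind == "bulge":
            d.update(s3=mid(self.stem_bounds), b3=mid(self.bulge_bounds),
                     loop1=self.const_hairpin_len, loop2=0)
        else:
            d.update(s3=mid(self.stem_bounds), b3=0,
                     loop1=self.const_hairpin_len, loop2=mid(self.internal_bounds))
        return d

    @property
    def scaffold_dotbracket(self) -> str:
        db, _, _ = _scaffold(self, **self.median_lengths())
        return db

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        """Labeled 1-based inclusive spans on the median-length scaffold."""
        _, _, spans = _scaffold(self, **self.median_lengths())
        return spans


def hairpin_template(**kw) -> DesignTemplate:
    return DesignTemplate(kind="hairpin", **kw)


def bulge_template(**kw) -> DesignTemplate:
    return DesignTemplate(kind="bulge", **kw)


def internal_template(**kw) -> DesignTemplate:
    return DesignTemplate(kind="internal", **kw)


def _scaffold(
    t: DesignTemplate, s4: int, s3: int, b3: int, loop1: int, loop2: int
) -> tuple[str, list[str], dict[str, tuple[int, int]]]:
    """Dot-bracket, per-position region mask, and labeled spans for given
    variable lengths.

    ``loop1`` is the hairpin loop; for the internal library ``b3``/``loop2``
    are the 5'/3' strand lengths of the studied internal loop (``b3`` named
    for the slot it occupies in the bulge libraries).
    """
    h1 = h2 = t.const_stem_len
    b1 = b2 = t.const_bulge_len
    if t.kind == "internal":
        n1, n2 = b3, loop2
    else:
        n1, n2 = b3, 0
    local = {"hairpin": ("S4", "H"), "bulge": ("S3", "B3", "S4"),
             "internal": ("S3", "I", "S4")}[t.kind]

    parts: list[tuple[str, str, str]] = []  # (label, db chars, mask)

    def add(label: str, db: str, mask: str) -> None:
        parts.append((label, db, mask))

    add("P5", "." * len(t.p5), "primer")
    add("S1f", "(" * h1, "distal")
    add("B1", "." * b1, "distal")
    add("S2f", "(" * h2, "distal")
    add("B2", "." * b2, "distal" if t.kind == "hairpin" else "excluded")
    add("S3f", "(" * s3, "local" if "S3" in local else "distal")
    add("B3", "." * n1, "local" if t.kind != "hairpin" else "excluded")
    add("S4f", "(" * s4, "local")
    add("H", "." * loop1, "local" if t.kind == "hairpin" else "excluded")
    add("S4r", ")" * s4, "local")
    add("I2", "." * n2, "local" if t.kind == "internal" else "")
    add("S3r", ")" * s3, "local" if "S3" in local else "distal")
    add("S2r", ")" * h2, "distal")
    add("S1r", ")" * h1, "distal")
    add("P3", "." * len(t.p3), "primer")

    db = "".join(p[1] for p in parts)
    mask: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 1
    for label, chars, m in parts:
        if chars:
            spans[label] = (pos, pos + len(chars) - 1)
            mask.extend([m] * len(chars))
            pos += len(chars)
    return db, mask, spans


@dataclass(frozen=True)
class LibraryVariant:
    name: str
    sequence: str
    designed_dotbracket: str
    region_mask: tuple[str, ...]
    design_params: Mapping[str, float]
    net_dg: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.designed_dotbracket):
            raise ValueError(f"{self.name}: sequence/structure length mismatch")


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _stack_sum(pairs: Sequence[str], params: NearestNeighborParams) -> float:
    """Stacking energy (kcal/mol) of a helix given 5'->3' pair strings."""
    total = 0.0
    for a, b in zip(pairs, pairs[1:]):
        total += params.stack_table[pair_type(a[0], a[1]), pair_type(b[1], b[0])]
    return total / 100.0


def _random_stem(
    rng: np.random.Generator, length: int, gc: float, gu: int,
    gc_closing: bool = False,
) -> list[str]:
    """Random pair list: ``gu`` G:U pairs, GC fraction ``gc`` of the rest."""
    gu = min(gu, length - (2 if gc_closing else 0))
    n_gc = int(round(gc * (length - gu)))
    n_gc = min(n_gc, length - gu)
    kinds = ["gu"] * gu + ["gc"] * n_gc + ["au"] * (length - gu - n_gc)
    if gc_closing:
        if n_gc < 2:
            raise ValueError("constant stems need GC closing pairs at both ends")
        inner = kinds.copy()
        inner.remove("gc")
        inner.remove("gc")
        rng.shuffle(inner)
        kinds = ["gc"] + inner + ["gc"]
    else:
        rng.shuffle(kinds)
    out = []
    for k in kinds:
        if k == "gc":
            out.append(("GC", "CG")[rng.integers(2)])
        elif k == "au":
            out.append(("AU", "UA")[rng.integers(2)])
        else:
            out.append(("GU", "UG")[rng.integers(2)])
    return out


def _constant_stem_pool(
    t: DesignTemplate,
    rng: np.random.Generator,
    params: NearestNeighborParams,
    n_candidates: int = 2000,
) -> list[list[str]]:
    """Constant-energy stem candidates: fixed GC content, no G:U, G:C/C:G
    closing pairs, stacking energy within ``const_energy_tol`` of the
    candidate median."""
    cands = [
        _random_stem(rng, t.const_stem_len, t.const_gc, 0, gc_closing=True)
        for _ in range(n_candidates)
    ]
    energies = np.array([_stack_sum(c, params) for c in cands])
    target = float(np.median(energies))
    pool = [c for c, e in zip(cands, energies)
            if abs(e - target) <= t.const_energy_tol]
    if len(pool) < 20:
        raise RuntimeError("constant-stem pool too small; widen const_energy_tol")
    return pool


def _ac_loop(rng: np.random.Generator, n: int) -> str:
    return "".join("AC"[k] for k in rng.integers(0, 2, size=n))


def _realize(
    t: DesignTemplate,
    rng: np.random.Generator,
    pools: Mapping[str, list[list[str]]],
    params: NearestNeighborParams,
) -> tuple[str, str, list[str], dict[str, float]]:
    """One candidate variant: sequence, dot-bracket, mask, design params."""
    lo, hi = t.stem_bounds
    s4 = int(rng.integers(lo, hi + 1))
    gc = float(rng.choice(t.gc_grid))
    gu = int(rng.choice(t.gu_grid))
    if t.kind == "hairpin":
        s3 = t.const_stem_len
        b3 = t.const_bulge_len
        loop1 = int(rng.integers(t.hairpin_bounds[0], t.hairpin_bounds[1] + 1))
        loop2 = 0
        loop_len = loop1
    elif t.kind == "bulge":
        s3 = int(rng.integers(lo, hi + 1))
        b3 = int(rng.integers(t.bulge_bounds[0], t.bulge_bounds[1] + 1))
        loop1 = t.const_hairpin_len
        loop2 = 0
        loop_len = b3
    else:
        s3 = int(rng.integers(lo, hi + 1))
        b3 = int(rng.integers(t.internal_bounds[0], t.internal_bounds[1] + 1))
        loop1 = t.const_hairpin_len
        loop2 = int(rng.integers(t.internal_bounds[0], t.internal_bounds[1] + 1))
        loop_len = b3 + loop2
    db, mask, _ = _scaffold(t, s4=s4, s3=s3, b3=b3, loop1=loop1, loop2=loop2)

    def pick(pool):
        return pool[rng.integers(len(pool))]

    stems = {
        "S1": pick(pools["const"]),
        "S2": pick(pools["const"]),
        "S4": _random_stem(rng, s4, gc, gu),
    }
    if t.kind == "hairpin":
        stems["S3"] = pick(pools["const"])
    else:
        stems["S3"] = _random_stem(rng, s3, gc, gu)

    f = {k: "".join(p[0] for p in v) for k, v in stems.items()}
    r = {k: "".join(p[1] for p in reversed(v)) for k, v in stems.items()}
    seq = (
        t.p5 + f["S1"] + _ac_loop(rng, t.const_bulge_len) + f["S2"]
        + _ac_loop(rng, t.const_bulge_len) + f["S3"]
        + _ac_loop(rng, b3 if t.kind != "internal" else b3)
        + f["S4"] + _ac_loop(rng, loop1) + r["S4"]
        + (_ac_loop(rng, loop2) if t.kind == "internal" else "")
        + r["S3"] + r["S2"] + r["S1"] + t.p3
    )
    design = {
        "loop_len": loop_len,
        "stem_len": s4 if t.kind == "hairpin" else (s3 + s4) / 2.0,
        "gc_content": gc,
        "gu_count": gu,
    }
    return seq, db, mask, design


def studied_loop_net_dg(
    structure: AnnotatedStructure,
    region_mask: Sequence[str],
    kind: str,
    params: NearestNeighborParams,
    config: EnergyConfig = DEFAULT_CONFIG,
) -> float:
    """Net dG of the variable-region loop of a designed structure."""
    mask = list(region_mask)
    loops = [
        rec for rec in structure.substructures
        if rec.kind == kind and rec.positions()
        and all(mask[p - 1] == "local" for p in rec.positions())
    ]
    if len(loops) != 1:
        raise ValueError(
            f"{structure.identifier}: expected exactly one local {kind} loop, "
            f"found {len(loops)}"
        )
    loop = loops[0]
    result = structure_energy(structure, params, config)
    by_inner = {s.closing_pairs[1]: s for s in structure.records("stem")}
    by_outer = {s.closing_pairs[0]: s for s in structure.records("stem")}
    stems = [by_inner[loop.closing_pairs[0]]]
    if kind in ("bulge", "internal"):
        stems.append(by_outer[loop.closing_pairs[1]])
    comps = [result.components[loop.label]] + [result.components[s.label] for s in stems]
    if not all(c.computable for c in comps):
        raise ValueError(f"{structure.identifier}: non-computable substructure energy")
    return net_energy(comps[0].value, [c.value for c in comps[1:]])


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def sequence_distance(a: str, b: str) -> int:
    """Positional mismatches over the shared prefix plus |length difference|."""
    shared = min(len(a), len(b))
    mism = sum(x != y for x, y in zip(a[:shared], b[:shared]))
    return mism + abs(len(a) - len(b))


_BASE_CODE = {"A": 1, "C": 2, "G": 3, "U": 4}


def _encode(seq: str, width: int) -> np.ndarray:
    out = np.zeros(width, dtype=np.uint8)
    out[:len(seq)] = [_BASE_CODE[c] for c in seq]
    return out


def generate_library(
    template: DesignTemplate,
    n: int,
    rng_seed: int,
    min_distance: int = 20,
    max_attempts: int = 10_000,
    params: NearestNeighborParams | None = None,
    config: EnergyConfig = DEFAULT_CONFIG,
) -> list[LibraryVariant]:
    """Generate ``n`` variants satisfying the design constraints.

    Rejection sampling against the pairwise distance constraint with
    ``max_attempts`` draws per variant; raises with the achieved count if a
    slot cannot be filled.  Reproducible from ``rng_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or default_params()
    rng = np.random.default_rng(rng_seed)
    pools = {"const": _constant_stem_pool(template, rng, params)}

    # worst-case length bound for the padded distance matrix
    t = template
    max_len = (len(t.p5) + len(t.p3) + 4 * t.stem_bounds[1]
               + 2 * (2 * t.const_stem_len + 2 * t.const_bulge_len)
               + t.hairpin_bounds[1] + t.bulge_bounds[1]
               + 2 * t.internal_bounds[1] + t.const_hairpin_len + 8)
    enc = np.zeros((n, max_len), dtype=np.uint8)
    lengths = np.zeros(n, dtype=np.int64)

    variants: list[LibraryVariant] = []
    for k in range(n):
        placed = False
        for _ in range(max_attempts):
            seq, db, mask, design = _realize(template, rng, pools, params)
            if len(seq) > max_len:  # pragma: no cover - bound is generous
                raise RuntimeError("scaffold longer than the length bound")
            if variants:
                c = _encode(seq, max_len)
                prev = enc[:k]
                mism = ((prev != c) & (prev != 0) & (c != 0)).sum(axis=1)
                dist = mism + np.abs(lengths[:k] - len(seq))
                if int(dist.min()) < min_distance:
                    continue
            st = annotate_from_dotbracket(seq, db, f"{template.kind}_{k:05d}")
            net = studied_loop_net_dg(st, mask, template.kind, params, config)
            enc[k] = _encode(seq, max_len)
            lengths[k] = len(seq)
            variants.append(LibraryVariant(
                name=st.identifier,
                sequence=seq,
                designed_dotbracket=db,
                region_mask=tuple(mask),
                design_params=design,
                net_dg=net,
            ))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"distance constraint unsatisfiable after {max_attempts} "
                f"attempts; achieved {len(variants)} of {n} variants"
            )
    return variants


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def length_filter(variants: Sequence[LibraryVariant]) -> tuple[list[LibraryVariant], int]:
    """Keep variants within 20% of the input set's mean sequence length."""
    if not variants:
        raise ValueError("empty variant set")
    lengths = np.array([len(v.sequence) for v in variants], dtype=float)
    mean = lengths.mean()
    keep = (lengths >= 0.8 * mean) & (lengths <= 1.2 * mean)
    survivors = [v for v, k in zip(variants, keep) if k]
    return survivors, int((~keep).sum())


def has_c_repeat(sequence: str, max_run: int = 4) -> bool:
    """True if the sequence contains a C run longer than ``max_run``."""
    return "C" * (max_run + 1) in sequence.upper().replace("T", "U")


def c_repeat_filter(
    variants: Sequence[LibraryVariant], max_run: int = 4
) -> tuple[list[LibraryVariant], list[str]]:
    """Remove sequences with C repeats longer than ``max_run`` (unreliable
    DMS reactivities); returns survivors and the removed names."""
    removed = [v.name for v in variants if has_c_repeat(v.sequence, max_run)]
    survivors = [v for v in variants if not has_c_repeat(v.sequence, max_run)]
    return survivors, removed


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

def write_fasta(variants: Sequence[LibraryVariant], path) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f">{v.name}\n{v.sequence}\n")


def write_design_csv(variants: Sequence[LibraryVariant], path) -> None:
    """name,dot-bracket CSV (the format consumed by the reactivity stage)."""
    with open(path, "w") as fh:
        fh.write("name,structure\n")
        for v in variants:
            fh.write(f"{v.name},{v.designed_dotbracket}\n")


def read_library(fasta_path, design_csv_path, masks_json_path) -> list[LibraryVariant]:
    """Rebuild a variant list from the three written formats."""
    seqs: dict[str, str] = {}
    name = None
    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:]
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line
    designs: dict[str, str] = {}
    with open(design_csv_path) as fh:
        header = fh.readline()
        for line in fh:
            n, db = line.strip().split(",", 1)
            designs[n] = db
    with open(masks_json_path) as fh:
        meta = json.load(fh)
    out = []
    for n, seq in seqs.items():
        m = meta[n]
        out.append(LibraryVariant(
            name=n, sequence=seq, designed_dotbracket=designs[n],
            region_mask=tuple(m["region_mask"]),
            design_params=m["design_params"], net_dg=m["net_dg"],
        ))
    return out


def write_masks_json(variants: Sequence[LibraryVariant], path) -> None:
    payload = {
        v.name: {
            "region_mask": list(v.region_mask),
            "design_params": dict(v.design_params),
            "net_dg": v.net_dg,
        }
        for v in variants
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
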