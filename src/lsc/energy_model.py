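"""Turner 2004 nearest-neighbor free energies for individual substructures.

The evaluator computes the free energy of each substructure of an
:class:`~lsc.structure_io.AnnotatedStructure` separately — stem stacking
sums, hairpin/bulge/internal loop terms, and the linear multiloop model —
so that a whole structure's energy decomposes exactly into per-component
contributions.  Parameters are read from a Turner-2004-style plain-text
parameter file (the widely distributed ``.par`` dialect); by default the
``rna_turner2004.par`` set distributed with the installed ViennaRNA package
is located and parsed.

Units and conventions
---------------------
Parameter tables are stored in the file's printed units (dacal/mol = 0.01
kcal/mol); :class:`ComponentEnergy` values are kcal/mol.  Loop-size
extrapolation beyond 30 nt uses ``lxc * ln(size/30)`` with C-style integer
truncation so that totals agree exactly with reference evaluators working in
integer dacal.  Dangling ends and coaxial stacking are excluded throughout,
which keeps the loop/stem attribution unambiguous.

AU/GU helix-end penalties: the Turner rules charge an explicit terminal-AU
term in some loop contexts (hairpin triloops, bulges of two or more
nucleotides, multiloop and exterior branches) and fold it into the terminal
mismatch tables elsewhere.  By default the explicit terms are charged to the
**stem** component so that "stem dG" is the self-contained stabilizing term
of the local-stability analysis; setting ``EnergyConfig.end_penalty_on =
"loop"`` moves them to the adjacent loop component (exterior branches stay
on the stem since exterior segments are not energy-bearing).  Mismatch-table
contributions always remain with the loop.  Either way the component sum is
unchanged.
"""

from __future__ import annotations

import math
import re
import sys
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np

from .structure_io import AnnotatedStructure, SubstructureRecord

__all__ = [
    "NearestNeighborParams",
    "ComponentEnergy",
    "EnergyConfig",
    "StructureEnergyResult",
    "ParameterFileError",
    "LoopGeometryError",
    "load_params",
    "stem_energy",
    "hairpin_energy",
    "bulge_energy",
    "internal_loop_energy",
    "multiloop_energy",
    "structure_energy",
]

T37 = 310.15  # kelvin
INF = 10_000_000  # "INF" sentinel used by the .par dialect (dacal/mol)
MAXLOOP = 30
LXC37 = 107.856  # dacal/mol, loop-size extrapolation coefficient at 37 C

# pair-type order used by the .par tables
PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")
PAIR_INDEX = {p: k for k, p in enumerate(PAIR_ORDER)}
NT5 = {"N": 0, "A": 1, "C": 2, "G": 3, "U": 4}  # 5-wide nucleotide axes


class ParameterFileError(ValueError):
    """Malformed or incomplete nearest-neighbor parameter file."""


class LoopGeometryError(ValueError):
    """Sterically impossible or malformed loop geometry."""


def pair_type(a: str, b: str) -> int | None:
    """Canonical pair type index (0..5) or None for non-canonical pairs."""
    return PAIR_INDEX.get(a + b)


@dataclass
class NearestNeighborParams:
    """Turner 2004 tables, in the file's printed units (dacal/mol).

    Mismatch and internal-loop tables are indexed by pair type
    (CG, GC, GU, UG, AU, UA, NN) and nucleotide (N, A, C, G, U); the 2x2
    internal-loop table omits the N rows (canonical pairs and ACGU only).
    """

    stack_table: np.ndarray            # (7, 7)
    hairpin_init: np.ndarray           # (31,)
    bulge_init: np.ndarray             # (31,)
    internal_init: np.ndarray          # (31,)
    mismatch_hairpin: np.ndarray       # (7, 5, 5)
    mismatch_internal: np.ndarray      # (7, 5, 5)
    mismatch_internal_1n: np.ndarray   # (7, 5, 5)
    mismatch_internal_23: np.ndarray   # (7, 5, 5)
    int11: np.ndarray                  # (7, 7, 5, 5)
    int21: np.ndarray                  # (7, 7, 5, 5, 5)
    int22: np.ndarray                  # (6, 6, 4, 4, 4, 4)
    special_hairpins: dict[str, float] # pair-inclusive sequence -> dacal/mol
    asymmetry_penalty: float           # per unit asymmetry (NINIO slope)
    asymmetry_cap: float               # MAX_NINIO
    end_penalty: float                 # terminal AU/GU
    ml_base: float                     # multiloop: per unpaired nucleotide
    ml_closing: float                  # multiloop: offset
    ml_intern: float                   # multiloop: per branch (incl. closing)
    lxc: float                         # extrapolation coefficient
    temperature: float = T37           # kelvin
    source: str = ""

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterFileError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class ComponentEnergy:
    """Free energy of one substructure, kcal/mol, with a term breakdown."""

    value: float
    component_label: str
    terms: Mapping[str, float] = field(default_factory=dict)
    computable: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.computable and self.terms:
            total = sum(self.terms.values())
            if abs(total - self.value) > 1e-9:
                raise ValueError(
                    f"{self.component_label}: terms sum {total} != value {self.value}"
                )


@dataclass(frozen=True)
class EnergyConfig:
    """Attribution switches for the component decomposition."""

    end_penalty_on: str = "stem"  # "stem" | "loop"

    def __post_init__(self) -> None:
        if self.end_penalty_on not in ("stem", "loop"):
            raise ValueError("end_penalty_on must be 'stem' or 'loop'")


DEFAULT_CONFIG = EnergyConfig()


# ---------------------------------------------------------------------------
# parameter-file parsing
# ---------------------------------------------------------------------------

_SECTION_SHAPES = {
    "stack": (7, 7),
    "mismatch_hairpin": (7, 5, 5),
    "mismatch_internal": (7, 5, 5),
    "mismatch_internal_1n": (7, 5, 5),
    "mismatch_internal_23": (7, 5, 5),
    "mismatch_multi": (7, 5, 5),
    "mismatch_exterior": (7, 5, 5),
    "dangle5": (7, 5),
    "dangle3": (7, 5),
    "int11": (7, 7, 5, 5),
    "int21": (7, 7, 5, 5, 5),
    "int22": (6, 6, 4, 4, 4, 4),
    "hairpin": (31,),
    "bulge": (31,),
    "internal": (31,),
    "ML_params": (6,),
    "NINIO": (3,),
    "Misc": (4,),
}

_REQUIRED = {
    "stack": "stack",
    "hairpin": "hairpin_init",
    "bulge": "bulge_init",
    "internal": "internal_init",
    "mismatch_hairpin": "mismatch_hairpin",
    "mismatch_internal": "mismatch_internal",
    "mismatch_internal_1n": "mismatch_internal_1n",
    "mismatch_internal_23": "mismatch_internal_23",
    "int11": "int11",
    "int21": "int21",
    "int22": "int22",
    "ML_params": "ml_params",
    "NINIO": "ninio",
    "Misc": "misc",
}

_SPECIAL_SECTIONS = {"Triloops": 5, "Tetraloops": 6, "Hexaloops": 8}


def _split_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for raw in text.splitlines():
        line = re.sub(r"/\*.*?\*/", " ", raw).strip()
        if raw.startswith("##"):
            continue
        if raw.startswith("#"):
            name = raw[1:].strip()
            if name == "END":
                break
            current = sections.setdefault(name, [])
            continue
        if current is not None and line:
            current.append(line)
    return sections


def _parse_numbers(name: str, lines: list[str], shape: tuple[int, ...]) -> np.ndarray:
    tokens: list[float] = []
    for line in lines:
        for tok in line.split():
            if tok == "INF":
                tokens.append(INF)
            else:
                try:
                    tokens.append(float(tok))
                except ValueError as exc:
                    raise ParameterFileError(
                        f"table {name}: non-numeric entry '{tok}'"
                    ) from exc
    expected = int(np.prod(shape))
    if len(tokens) != expected:
        raise ParameterFileError(
            f"table {name}: expected {expected} entries, found {len(tokens)}"
        )
    return np.asarray(tokens, dtype=float).reshape(shape)


def _parse_special(name: str, lines: list[str], seq_len: int) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for line in lines:
        parts = line.split()
        if len(parts) != 3 or len(parts[0]) != seq_len:
            raise ParameterFileError(f"table {name}: malformed line '{line}'")
        try:
            out[parts[0]] = (float(parts[1]), float(parts[2]))
        except ValueError as exc:
            raise ParameterFileError(
                f"table {name}: non-numeric entry in '{line}'"
            ) from exc
    return out


def default_parameter_path() -> Path:
    """Locate the Turner 2004 parameter file of the installed ViennaRNA."""
    candidates = [
        Path(sys.prefix) / "share" / "ViennaRNA" / "rna_turner2004.par",
        Path(sys.exec_prefix) / "share" / "ViennaRNA" / "rna_turner2004.par",
    ]
    for c in candidates:
        if c.is_file():
            return c
    raise ParameterFileError(
        "could not locate rna_turner2004.par; pass parameter-file content to "
        "load_params() instead"
    )


def _rescale(dg: np.ndarray | float, dh: np.ndarray | float | None, temperature: float):
    """dG(T) = dH - (dH - dG37) * T/310.15, leaving INF entries untouched."""
    if temperature == T37:
        return dg
    if dh is None:
        raise ParameterFileError(
            "temperature rescaling requested but the parameter file provides "
            "no enthalpies"
        )
    tt = temperature / T37
    out = np.where(
        (np.asarray(dg) >= INF) | (np.asarray(dh) >= INF),
        np.asarray(dg, dtype=float),
        np.asarray(dh, dtype=float) - (np.asarray(dh, dtype=float) - np.asarray(dg, dtype=float)) * tt,
    )
    return out if isinstance(dg, np.ndarray) else float(out)


def load_params(source: str | Path = "turner2004", temperature: float = T37) -> NearestNeighborParams:
    """Load a Turner-2004-style parameter file.

    ``source`` may be the named built-in set ``"turner2004"`` (resolved to the
    parameter file distributed with the installed ViennaRNA), a filesystem
    path, or the file content itself (recognized by embedded newlines).
    ``temperature`` is in kelvin; values other than 310.15 K rescale every
    free energy from the file's enthalpies.
    """
    if isinstance(source, Path):
        label, text = str(source), source.read_text()
    elif "\n" in source:
        label, text = "<content>", source
    elif source == "turner2004":
        path = default_parameter_path()
        label, text = str(path), path.read_text()
    else:
        path = Path(source)
        if not path.is_file():
            raise ParameterFileError(f"no such parameter source: {source!r}")
        label, text = str(path), path.read_text()

    sections = _split_sections(text)
    for sec, friendly in _REQUIRED.items():
        if sec not in sections:
            raise ParameterFileError(f"required table missing: {friendly} ({sec})")

    tables: dict[str, np.ndarray] = {}
    for sec, shape in _SECTION_SHAPES.items():
        if sec in sections:
            tables[sec] = _parse_numbers(sec, sections[sec], shape)

    def table(sec: str) -> np.ndarray:
        dh = tables.get(sec + "_enthalpies")
        if sec + "_enthalpies" in sections and dh is None:
            dh = _parse_numbers(
                sec + "_enthalpies", sections[sec + "_enthalpies"], _SECTION_SHAPES[sec]
            )
        return _rescale(tables[sec], dh, temperature)

    for sec in list(sections):
        base = sec.removesuffix("_enthalpies")
        if base != sec and base in _SECTION_SHAPES:
            tables[sec] = _parse_numbers(sec, sections[sec], _SECTION_SHAPES[base])

    specials: dict[str, float] = {}
    for sec, seq_len in _SPECIAL_SECTIONS.items():
        if sec in sections:
            for seq, (dg, dh) in _parse_special(sec, sections[sec], seq_len).items():
                specials[seq] = float(_rescale(dg, dh, temperature))

    ml = tables["ML_params"].ravel()
    ninio = tables["NINIO"].ravel()
    misc = tables["Misc"].ravel()
    tt = temperature / T37

    return NearestNeighborParams(
        stack_table=table("stack"),
        hairpin_init=table("hairpin"),
        bulge_init=table("bulge"),
        internal_init=table("internal"),
        mismatch_hairpin=table("mismatch_hairpin"),
        mismatch_internal=table("mismatch_internal"),
        mismatch_internal_1n=table("mismatch_internal_1n"),
        mismatch_internal_23=table("mismatch_internal_23"),
        int11=table("int11"),
        int21=table("int21"),
        int22=table("int22"),
        special_hairpins=specials,
        asymmetry_penalty=float(_rescale(ninio[0], ninio[1], temperature)),
        asymmetry_cap=float(ninio[2]),
        end_penalty=float(_rescale(misc[2], misc[3], temperature)),
        ml_base=float(_rescale(ml[0], ml[1], temperature)),
        ml_closing=float(_rescale(ml[2], ml[3], temperature)),
        ml_intern=float(_rescale(ml[4], ml[5], temperature)),
        lxc=LXC37 * tt,
        temperature=temperature,
        source=label,
    )


@lru_cache(maxsize=4)
def default_params(temperature: float = T37) -> NearestNeighborParams:
    """Cached Turner 2004 parameter set."""
    return load_params("turner2004", temperature=temperature)


# ---------------------------------------------------------------------------
# component evaluation (internally in dacal/mol, exported in kcal/mol)
# ---------------------------------------------------------------------------

def _pt(structure: AnnotatedStructure, i: int, j: int) -> int | None:
    return pair_type(structure.sequence[i - 1], structure.sequence[j - 1])


def _nt(structure: AnnotatedStructure, i: int) -> int:
    return NT5[structure.sequence[i - 1]]


def _extrapolated_init(init: np.ndarray, size: int, lxc: float) -> float:
    if size <= MAXLOOP:
        return float(init[size])
    # C-style truncation keeps integer-dacal totals exact
    return float(init[MAXLOOP]) + int(lxc * math.log(size / 30.0))


def _not_computable(label: str, reason: str) -> ComponentEnergy:
    return ComponentEnergy(
        value=math.nan, component_label=label, terms={}, computable=False, reason=reason
    )


def _component(label: str, terms: dict[str, float]) -> ComponentEnergy:
    terms_kcal = {k: v / 100.0 for k, v in terms.items() if v != 0.0}
    value = sum(terms.values()) / 100.0
    return ComponentEnergy(value=value, component_label=label, terms=terms_kcal)


def _exterior_branches(structure: AnnotatedStructure) -> set[tuple[int, int]]:
    """Outermost nested pairs (branches of the exterior loop)."""
    nested = list(structure.pairing)
    for i, j in structure.pk_pairs:
        nested[i - 1] = 0
        nested[j - 1] = 0
    out: set[tuple[int, int]] = set()
    k = 1
    n = structure.length
    while k <= n:
        if nested[k - 1] > k:
            out.add((k, nested[k - 1]))
            k = nested[k - 1] + 1
        else:
            k += 1
    return out


def _is_special_hairpin(structure: AnnotatedStructure, rec: SubstructureRecord,
                        params: NearestNeighborParams) -> float | None:
    i, j = rec.closing_pairs[0]
    size = rec.length_summary[0]
    if size in (3, 4, 6):
        key = structure.sequence[i - 1:j]
        if key in params.special_hairpins:
            return params.special_hairpins[key]
    return None


def _stem_end_penalty_contexts(
    structure: AnnotatedStructure,
    stem: SubstructureRecord,
    params: NearestNeighborParams,
) -> list[tuple[str, tuple[int, int]]]:
    """(context, pair) for each stem end whose context charges an explicit
    terminal AU/GU penalty under the Turner rules."""
    outer, inner = stem.closing_pairs
    contexts: list[tuple[str, tuple[int, int]]] = []
    ext = _exterior_branches(structure)
    if outer in ext:
        contexts.append(("exterior", outer))
    for rec in structure.substructures:
        if rec.kind == "multiloop":
            for p in rec.closing_pairs:
                if p == outer or (p == inner and rec.closing_pairs[0] == inner):
                    contexts.append(("multiloop", p))
        elif rec.kind == "bulge" and rec.length_summary[0] >= 2:
            if rec.closing_pairs[0] == inner:
                contexts.append(("bulge", inner))
            if rec.closing_pairs[1] == outer:
                contexts.append(("bulge", outer))
        elif rec.kind == "hairpin" and rec.closing_pairs[0] == inner:
            if rec.length_summary[0] == 3 and _is_special_hairpin(structure, rec, params) is None:
                contexts.append(("hairpin", inner))
    return contexts


def _end_penalty_total(
    structure: AnnotatedStructure,
    stem: SubstructureRecord,
    params: NearestNeighborParams,
    config: EnergyConfig,
) -> float:
    total = 0.0
    for context, (i, j) in _stem_end_penalty_contexts(structure, stem, params):
        if config.end_penalty_on == "loop" and context != "exterior":
            continue  # charged to the adjacent loop component instead
        pt = _pt(structure, i, j)
        if pt is not None and pt > 1:  # GU, UG, AU, UA
            total += params.end_penalty
    return total


def stem_energy(
    structure: AnnotatedStructure,
    stem: SubstructureRecord,
    params: NearestNeighborParams,
    config: EnergyConfig = DEFAULT_CONFIG,
) -> ComponentEnergy:
    """Stacking free energy of a stem (+ end penalties per configuration).

    A one-pair stem has no stacking steps; its value is the configured end
    terms only.  Any non-canonical pair makes the stem non-computable.
    """
    if stem.kind != "stem":
        raise ValueError(f"{stem.label} is not a stem")
    if stem.contains_n:
        return _not_computable(stem.label, "contains N")
    (i0, j0), _ = stem.closing_pairs
    h = stem.length_summary[0]
    stacking = 0.0
    for k in range(h):
        i, j = i0 + k, j0 - k
        pt = _pt(structure, i, j)
        if pt is None:
            return _not_computable(
                stem.label,
                f"non-canonical pair {structure.sequence[i-1]}:{structure.sequence[j-1]} at ({i},{j})",
            )
        if k < h - 1:
            pt2 = _pt(structure, j - 1, i + 1)  # next pair, reversed orientation
            if pt2 is None:
                return _not_computable(stem.label, f"non-canonical pair at ({i+1},{j-1})")
            stacking += params.stack_table[pt, pt2]
    terms = {"stacking": stacking}
    ends = _end_penalty_total(structure, stem, params, config)
    if ends:
        terms["end_penalty"] = ends
    return _component(stem.label, terms)


def hairpin_energy(
    structure: AnnotatedStructure,
    loop: SubstructureRecord,
    params: NearestNeighborParams,
    config: EnergyConfig = DEFAULT_CONFIG,
) -> ComponentEnergy:
    """Hairpin loop free energy: length initiation, terminal mismatch for
    loops over 3 nt, special tri/tetra/hexaloop energies, and lxc
    extrapolation beyond 30 nt."""
    if loop.kind != "hairpin":
        raise ValueError(f"{loop.label} is not a hairpin")
    size = loop.length_summary[0]
    if size < 3:
        raise LoopGeometryError(
            f"{loop.label}: hairpin loop of {size} nt is sterically impossible"
        )
    if loop.contains_n:
        return _not_computable(loop.label, "contains N")
    i, j = loop.closing_pairs[0]
    pt = _pt(structure, i, j)
    if pt is None:
        return _not_computable(loop.label, f"non-canonical closing pair ({i},{j})")

    special = _is_special_hairpin(structure, loop, params)
    if special is not None:
        return _component(loop.label, {"special": special})

    terms = {"initiation": _extrapolated_init(params.hairpin_init, size, params.lxc)}
    if size == 3:
        if config.end_penalty_on == "loop" and pt > 1:
            terms["end_penalty"] = params.end_penalty
    else:
        terms["mismatch"] = float(
            params.mismatch_hairpin[pt, _nt(structure, i + 1), _nt(structure, j - 1)]
        )
    return _component(loop.label, terms)


def bulge_energy(
    structure: AnnotatedStructure,
    loop: SubstructureRecord,
    params: NearestNeighborParams,
    config: EnergyConfig = DEFAULT_CONFIG,
) -> ComponentEnergy:
    """Bulge loop free energy: single-nucleotide bulges keep the cross-bulge
    stack (quasi-continuous helix); larger bulges take initiation plus end
    penalties per the configured attribution."""
    if loop.kind != "bulge":
        raise ValueError(f"{loop.label} is not a bulge")
    size = loop.length_summary[0]
    if size < 1:
        raise LoopGeometryError(f"{loop.label}: zero-size bulge")
    if loop.contains_n:
        return _not_computable(loop.label, "contains N")
    (i, j), (p, q) = loop.closing_pairs
    pt = _pt(structure, i, j)
    pt2 = _pt(structure, q, p)  # inner pair, reversed orientation
    if pt is None or pt2 is None:
        return _not_computable(loop.label, "non-canonical closing pair")
    terms = {"initiation": _extrapolated_init(params.bulge_init, size, params.lxc)}
    if size == 1:
        terms["stacking"] = float(params.stack_table[pt, pt2])
    elif config.end_penalty_on == "loop":
        ends = 0.0
        if pt > 1:
            ends += params.end_penalty
        if pt2 > 1:
            ends += params.end_penalty
        if ends:
            terms["end_penalty"] = ends
    return _component(loop.label, terms)


def internal_loop_energy(
    structure: AnnotatedStructure,
    loop: SubstructureRecord,
    params: NearestNeighborParams,
    config: EnergyConfig = DEFAULT_CONFIG,
) -> ComponentEnergy:
    """Internal loop free energy: dedicated 1x1 / 2x1 / 2x2 tables, the 2x3
    and 1xn mismatch variants, and the generic initiation + capped asymmetry
    + terminal mismatch rule otherwise."""
    if loop.kind != "internal":
        raise ValueError(f"{loop.label} is not an internal loop")
    if loop.contains_n:
        return _not_computable(loop.label, "contains N")
    n1, n2 = loop.length_summary
    (i, j), (p, q) = loop.closing_pairs
    pt = _pt(structure, i, j)
    pt2 = _pt(structure, q, p)
    if pt is None or pt2 is None:
        return _not_computable(loop.label, "non-canonical closing pair")
    si1 = _nt(structure, i + 1)
    sj1 = _nt(structure, j - 1)
    sp1 = _nt(structure, p - 1)
    sq1 = _nt(structure, q + 1)
    ns, nl = min(n1, n2), max(n1, n2)

    if ns == 1 and nl == 1:
        return _component(loop.label, {"int11": float(params.int11[pt, pt2, si1, sj1])})
    if ns == 1 and nl == 2:
        if n1 == 1:
            v = params.int21[pt, pt2, si1, sq1, sj1]
        else:
            v = params.int21[pt2, pt, sq1, si1, sp1]
        return _component(loop.label, {"int21": float(v)})
    if ns == 2 and nl == 2:
        v = params.int22[pt, pt2, si1 - 1, sp1 - 1, sq1 - 1, sj1 - 1]
        return _component(loop.label, {"int22": float(v)})

    terms: dict[str, float] = {}
    if ns == 2 and nl == 3:
        terms["initiation"] = float(params.internal_init[5])
        terms["asymmetry"] = params.asymmetry_penalty
        terms["mismatch"] = float(
            params.mismatch_internal_23[pt, si1, sj1]
            + params.mismatch_internal_23[pt2, sq1, sp1]
        )
    elif ns == 1:  # 1xn, n >= 3
        terms["initiation"] = _extrapolated_init(params.internal_init, nl + 1, params.lxc)
        terms["asymmetry"] = min(params.asymmetry_cap, (nl - ns) * params.asymmetry_penalty)
        terms["mismatch"] = float(
            params.mismatch_internal_1n[pt, si1, sj1]
            + params.mismatch_internal_1n[pt2, sq1, sp1]
        )
    else:
        terms["initiation"] = _extrapolated_init(params.internal_init, n1 + n2, params.lxc)
        asym = min(params.asymmetry_cap, (nl - ns) * params.asymmetry_penalty)
        if asym:
            terms["asymmetry"] = asym
        terms["mismatch"] = float(
            params.mismatch_internal[pt, si1, sj1]
            + params.mismatch_internal[pt2, sq1, sp1]
        )
    return _component(loop.label, terms)


def multiloop_energy(
    structure: AnnotatedStructure,
    loop: SubstructureRecord,
    params: NearestNeighborParams,
    config: EnergyConfig = DEFAULT_CONFIG,
) -> ComponentEnergy:
    """Linear multiloop model: offset + per-branch + per-unpaired terms."""
    if loop.kind != "multiloop":
        raise ValueError(f"{loop.label} is not a multiloop")
    if loop.contains_n:
        return _not_computable(loop.label, "contains N")
    unpaired = sum(loop.length_summary)
    n_branch = len(loop.closing_pairs)  # closing pair + branches
    terms = {
        "ml_closing": params.ml_closing,
        "ml_branches": params.ml_intern * n_branch,
    }
    if params.ml_base and unpaired:
        terms["ml_unpaired"] = params.ml_base * unpaired
    if config.end_penalty_on == "loop":
        ends = 0.0
        for i, j in loop.closing_pairs:
            pt = _pt(structure, i, j)
            if pt is None:
                return _not_computable(loop.label, "non-canonical pair")
            if pt > 1:
                ends += params.end_penalty
        if ends:
            terms["end_penalty"] = ends
    return _component(loop.label, terms)


@dataclass(frozen=True)
class StructureEnergyResult:
    total: float
    components: Mapping[str, ComponentEnergy]
    computable: bool

    def term(self, label: str) -> float:
        return self.components[label].value


def structure_energy(
    structure: AnnotatedStructure,
    params: NearestNeighborParams,
    config: EnergyConfig = DEFAULT_CONFIG,
) -> StructureEnergyResult:
    """Evaluate every substructure; the total is the exact component sum.

    Exterior segments carry zero energy (their branch AU/GU penalties are
    charged to the stems).  If any component is non-computable the total is
    the sum of computable components and the result is flagged.
    """
    dispatch = {
        "stem": stem_energy,
        "hairpin": hairpin_energy,
        "bulge": bulge_energy,
        "internal": internal_loop_energy,
        "multiloop": multiloop_energy,
    }
    components: dict[str, ComponentEnergy] = {}
    total = 0.0
    ok = True
    for rec in structure.substructures:
        if rec.kind == "exterior":
            components[rec.label] = ComponentEnergy(0.0, rec.label, {})
            continue
        try:
            comp = dispatch[rec.kind](structure, rec, params, config)
        except LoopGeometryError as exc:
            comp = _not_computable(rec.label, str(exc))
        components[rec.label] = comp
        if comp.computable:
            total += comp.value
        else:
            ok = False
    return StructureEnergyResult(total=total, components=components, computable=ok)
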