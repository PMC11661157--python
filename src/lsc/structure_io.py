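"""Secondary-structure containers, decomposition, and .st/.ste serialization.

The central container is :class:`AnnotatedStructure`: a sequence, its
base-pairing map, the dot-bracket string, and an ordered list of labeled
substructures (stems, hairpin loops, bulges, internal loops, multiloops,
exterior segments) following bpRNA conventions: maximal helices are stems,
and every loop is classified by the helices that flank it.

Coordinates are 1-based inclusive throughout.  Pseudoknotted pairs (bracket
pages beyond ``()``) are retained in the pairing map but excluded from the
stem/loop decomposition, which is defined on the nested page only; records
whose span contains a pseudoknotted position carry ``pseudoknot=True``.

The ``.st`` dialect read and written here mirrors the bpRNA "structure type"
layout: header lines, sequence, dot-bracket, a per-position type string, then
one annotation line per substructure strand.  ``.ste`` ("structure type
energy") files are the same with one appended free-energy field per line,
kcal/mol to two decimals, or a sentinel (default ``NA``) for substructures
whose energy is not computable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotatedStructure",
    "SubstructureRecord",
    "StructureParseError",
    "StructureValidationError",
    "pairing_from_dotbracket",
    "annotate_from_dotbracket",
    "parse_st",
    "read_ste",
    "write_st",
    "write_ste",
    "decomposition_to_json",
]

VALID_BASES = set("ACGUN")

# bracket pages in priority order; page 0 is the nested page
_OPENERS = "([{<" + "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_CLOSERS = ")]}>" + "abcdefghijklmnopqrstuvwxyz"
_PAGE_OF_OPENER = {c: i for i, c in enumerate(_OPENERS)}
_PAGE_OF_CLOSER = {c: i for i, c in enumerate(_CLOSERS)}

_KIND_CHAR = {
    "stem": "S",
    "hairpin": "H",
    "bulge": "B",
    "internal": "I",
    "multiloop": "M",
    "exterior": "X",
}


class StructureParseError(ValueError):
    """Malformed .st/.ste or dot-bracket input."""


class StructureValidationError(ValueError):
    """Internally inconsistent structure (annotation vs dot-bracket, pairing)."""


@dataclass(frozen=True)
class SubstructureRecord:
    """One labeled substructure.

    ``strand_ranges`` holds 1-based inclusive (start, end) ranges: two equal
    ranges for a stem (5' and 3' strand), one for hairpins/bulges/exterior
    segments, two for internal loops, and one per unpaired segment for
    multiloops (empty segments appear as ``(s, s-1)`` placeholders so segment
    order is preserved).  ``closing_pairs`` are the flanking base pair(s):
    (outer, inner) pair for stems, the single closing pair for hairpins, the
    outer and inner closing pairs for bulges and internal loops, and the
    closing pair followed by each branch pair for multiloops.
    ``length_summary`` is the number of base pairs (stems, one entry) or the
    unpaired count per strand/segment (loops).
    """

    kind: str
    label: str
    strand_ranges: tuple[tuple[int, int], ...]
    closing_pairs: tuple[tuple[int, int], ...] = ()
    length_summary: tuple[int, ...] = ()
    pseudoknot: bool = False
    contains_n: bool = False

    def positions(self) -> list[int]:
        out: list[int] = []
        for s, e in self.strand_ranges:
            out.extend(range(s, e + 1))
        return out


@dataclass(frozen=True)
class AnnotatedStructure:
    identifier: str
    sequence: str
    pairing: tuple[int, ...]  # 1-based partner index per position, 0 = unpaired
    dotbracket: str
    substructures: tuple[SubstructureRecord, ...]
    pk_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.dotbracket) != n or len(self.pairing) != n:
            raise StructureValidationError(
                f"{self.identifier}: sequence ({n}), dot-bracket "
                f"({len(self.dotbracket)}) and pairing ({len(self.pairing)}) "
                "lengths differ"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise StructureValidationError(
                f"{self.identifier}: invalid bases {sorted(bad)}"
            )
        for i, j in enumerate(self.pairing, start=1):
            if j:
                if j == i:
                    raise StructureValidationError(
                        f"{self.identifier}: position {i} paired with itself"
                    )
                if self.pairing[j - 1] != i:
                    raise StructureValidationError(
                        f"{self.identifier}: pairing not symmetric at {i}<->{j}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def record(self, label: str) -> SubstructureRecord:
        for rec in self.substructures:
            if rec.label == label:
                return rec
        raise KeyError(label)

    def records(self, kind: str) -> list[SubstructureRecord]:
        return [r for r in self.substructures if r.kind == kind]

    def type_string(self) -> str:
        chars = ["X"] * self.length
        for rec in self.substructures:
            c = _KIND_CHAR[rec.kind]
            for p in rec.positions():
                chars[p - 1] = c
        return "".join(chars)


# ---------------------------------------------------------------------------
# dot-bracket parsing / decomposition
# ---------------------------------------------------------------------------

def pairing_from_dotbracket(dotbracket: str) -> tuple[tuple[int, ...], tuple[tuple[int, int], ...]]:
    """Return (pairing, pk_pairs) for a possibly multi-page dot-bracket.

    ``pairing`` covers all pages; ``pk_pairs`` lists the pairs on pages
    beyond the first.  Raises :class:`StructureParseError` on unbalanced
    brackets or unknown characters.
    """
    n = len(dotbracket)
    pairing = [0] * n
    pk: list[tuple[int, int]] = []
    stacks: dict[int, list[int]] = {}
    for idx, ch in enumerate(dotbracket, start=1):
        if ch == ".":
            continue
        if ch in _PAGE_OF_OPENER:
            stacks.setdefault(_PAGE_OF_OPENER[ch], []).append(idx)
        elif ch in _PAGE_OF_CLOSER:
            page = _PAGE_OF_CLOSER[ch]
            stack = stacks.get(page)
            if not stack:
                raise StructureParseError(
                    f"unbalanced '{ch}' at position {idx}"
                )
            i = stack.pop()
            pairing[i - 1] = idx
            pairing[idx - 1] = i
            if page > 0:
                pk.append((i, idx))
        else:
            raise StructureParseError(
                f"invalid dot-bracket character '{ch}' at position {idx}"
            )
    for page, stack in stacks.items():
        if stack:
            raise StructureParseError(
                f"unbalanced '{_OPENERS[page]}' at position {stack[-1]}"
            )
    # nested page must be non-crossing
    nested = sorted(
        (i, j) for i, j in enumerate(pairing, start=1)
        if j > i and (i, j) not in pk
    )
    open_spans: list[tuple[int, int]] = []
    for i, j in nested:
        while open_spans and open_spans[-1][1] < i:
            open_spans.pop()
        if open_spans and not (open_spans[-1][0] < i and j < open_spans[-1][1]):
            raise StructureParseError(
                f"crossing pairs on the primary page near ({i},{j})"
            )
        open_spans.append((i, j))
    return tuple(pairing), tuple(sorted(pk))


def _nested_pairing(pairing: Sequence[int], pk_pairs: Iterable[tuple[int, int]]) -> list[int]:
    nested = list(pairing)
    for i, j in pk_pairs:
        nested[i - 1] = 0
        nested[j - 1] = 0
    return nested


def _decompose(sequence: str, pairing: Sequence[int], pk_pairs: tuple[tuple[int, int], ...]) -> tuple[SubstructureRecord, ...]:
    """bpRNA-convention decomposition of the nested page."""
    n = len(sequence)
    nested = _nested_pairing(pairing, pk_pairs)
    pk_positions = {p for ij in pk_pairs for p in ij}

    def has_n(positions: Iterable[int]) -> bool:
        return any(sequence[p - 1] == "N" for p in positions)

    def has_pk(positions: Iterable[int]) -> bool:
        return any(p in pk_positions for p in positions)

    # --- stems: maximal runs of stacked nested pairs
    pairs = [(i, nested[i - 1]) for i in range(1, n + 1) if nested[i - 1] > i]
    pair_set = set(pairs)
    stems: list[tuple[int, int, int]] = []  # (i, j, n_bp) with outer pair (i, j)
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pair_set:
            continue  # not the outer pair of its helix
        k = 0
        while (i + k + 1, j - k - 1) in pair_set:
            k += 1
        stems.append((i, j, k + 1))
    stems.sort()
    outer_of = {}
    inner_of = {}
    for i, j, h in stems:
        outer_of[(i, j)] = (i, j, h)
        inner_of[(i, j)] = (i + h - 1, j - h + 1)

    def children(lo: int, hi: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """Branch outer pairs and unpaired segments (incl. empty) in [lo, hi]."""
        branches: list[tuple[int, int]] = []
        segments: list[tuple[int, int]] = []
        k = lo
        seg_start = lo
        while k <= hi:
            if nested[k - 1] > k:
                segments.append((seg_start, k - 1))
                branches.append((k, nested[k - 1]))
                k = nested[k - 1] + 1
                seg_start = k
            else:
                k += 1
        segments.append((seg_start, hi))
        return branches, segments

    records: list[tuple[int, str, SubstructureRecord]] = []  # (sort pos, kind, rec)
    counters = {k: 0 for k in _KIND_CHAR}

    def make(kind: str, first_pos: int, **kw) -> None:
        counters[kind] += 1
        label = f"{_KIND_CHAR[kind]}{counters[kind]}"
        records.append((first_pos, kind, SubstructureRecord(kind=kind, label=label, **kw)))

    # stems, in 5'->3' order of the 5' strand (defines S numbering)
    for i, j, h in stems:
        positions = list(range(i, i + h)) + list(range(j - h + 1, j + 1))
        make(
            "stem", i,
            strand_ranges=((i, i + h - 1), (j - h + 1, j)),
            closing_pairs=((i, j), (i + h - 1, j - h + 1)),
            length_summary=(h,),
            pseudoknot=has_pk(positions),
            contains_n=has_n(positions),
        )

    # loops: walk each stem's inner closing pair, in order of appearance of
    # the loop's first position (bpRNA numbers loops 5'->3')
    loop_specs: list[tuple[int, str, dict]] = []
    for i, j, h in stems:
        ii, jj = i + h - 1, j - h + 1
        branches, segments = children(ii + 1, jj - 1)
        if not branches:
            size = jj - ii - 1
            loop_specs.append((ii + 1, "hairpin", dict(
                strand_ranges=((ii + 1, jj - 1),),
                closing_pairs=((ii, jj),),
                length_summary=(size,),
            )))
        elif len(branches) == 1:
            (p, q) = branches[0]
            left = segments[0]
            right = segments[1]
            n1 = left[1] - left[0] + 1
            n2 = right[1] - right[0] + 1
            if n1 > 0 and n2 > 0:
                loop_specs.append((left[0], "internal", dict(
                    strand_ranges=(left, right),
                    closing_pairs=((ii, jj), (p, q)),
                    length_summary=(n1, n2),
                )))
            else:
                seg = left if n1 > 0 else right
                loop_specs.append((seg[0], "bulge", dict(
                    strand_ranges=(seg,),
                    closing_pairs=((ii, jj), (p, q)),
                    length_summary=(seg[1] - seg[0] + 1,),
                )))
        else:
            first = min(s[0] for s in segments) if segments else ii + 1
            loop_specs.append((first, "multiloop", dict(
                strand_ranges=tuple(segments),
                closing_pairs=tuple([(ii, jj)] + branches),
                length_summary=tuple(s[1] - s[0] + 1 for s in segments),
            )))

    # exterior: top-level unpaired segments (one record per non-empty segment)
    top_branches, top_segments = children(1, n)
    for seg in top_segments:
        if seg[1] >= seg[0]:
            loop_specs.append((seg[0], "exterior", dict(
                strand_ranges=(seg,),
                closing_pairs=tuple(top_branches),
                length_summary=(seg[1] - seg[0] + 1,),
            )))

    for first, kind, kw in sorted(loop_specs, key=lambda t: t[0]):
        positions = [p for s, e in kw["strand_ranges"] for p in range(s, e + 1)]
        closing_positions = [p for ij in kw["closing_pairs"] for p in ij]
        make(
            kind, first,
            pseudoknot=has_pk(positions),
            contains_n=has_n(positions + closing_positions),
            **kw,
        )

    records.sort(key=lambda t: (t[0], t[1] != "stem"))
    return tuple(rec for _, _, rec in records)


def annotate_from_dotbracket(
    sequence: str, dotbracket: str, identifier: str = "structure"
) -> AnnotatedStructure:
    """Build an :class:`AnnotatedStructure` from sequence + dot-bracket."""
    sequence = sequence.upper().replace("T", "U")
    if len(sequence) != len(dotbracket):
        raise StructureParseError(
            f"{identifier}: sequence length {len(sequence)} != "
            f"dot-bracket length {len(dotbracket)}"
        )
    pairing, pk = pairing_from_dotbracket(dotbracket)
    subs = _decompose(sequence, pairing, pk)
    return AnnotatedStructure(
        identifier=identifier,
        sequence=sequence,
        pairing=pairing,
        dotbracket=dotbracket,
        substructures=subs,
        pk_pairs=pk,
    )


# ---------------------------------------------------------------------------
# .st / .ste serialization
# ---------------------------------------------------------------------------

_ENERGY_RE = r"(?:\s+(?P<energy>-?\d+\.\d+|NA))?"
_RANGE = r"(\d+)\.\.(\d+)"
_SEQ = r'"([ACGUN]*)"'
_PAIR = r"\((\d+),(\d+)\)\s+([ACGUN]):([ACGUN])"

_LINE_RES = {
    "stem": re.compile(rf"^(S\d+)\s+{_RANGE}\s+{_SEQ}\s+{_RANGE}\s+{_SEQ}{_ENERGY_RE}$"),
    "hairpin": re.compile(rf"^(H\d+)\s+{_RANGE}\s+{_SEQ}\s+{_PAIR}{_ENERGY_RE}$"),
    "bulge": re.compile(rf"^(B\d+)\s+{_RANGE}\s+{_SEQ}\s+{_PAIR}\s+{_PAIR}{_ENERGY_RE}$"),
    "internal": re.compile(rf"^(I\d+)\.([12])\s+{_RANGE}\s+{_SEQ}\s+{_PAIR}{_ENERGY_RE}$"),
    "multiloop": re.compile(rf"^(M\d+)\.(\d+)\s+{_RANGE}\s+{_SEQ}\s+{_PAIR}{_ENERGY_RE}$"),
    "exterior": re.compile(rf"^(X\d+)\s+{_RANGE}\s+{_SEQ}{_ENERGY_RE}$"),
    "pk": re.compile(r"^PK\d+\s+\((\d+),(\d+)\)$"),
}


def _pair_text(structure: AnnotatedStructure, pair: tuple[int, int]) -> str:
    i, j = pair
    return f"({i},{j}) {structure.sequence[i-1]}:{structure.sequence[j-1]}"


def _seq_slice(structure: AnnotatedStructure, rng: tuple[int, int]) -> str:
    s, e = rng
    return structure.sequence[s - 1:e]


def _format_energy(value: float | None, sentinel: str) -> str:
    return sentinel if value is None else f"{value:.2f}"


def _record_lines(
    structure: AnnotatedStructure,
    rec: SubstructureRecord,
    energy: str | None,
) -> list[str]:
    tail = f" {energy}" if energy is not None else ""
    q = lambda rng: f'{rng[0]}..{rng[1]} "{_seq_slice(structure, rng)}"'
    if rec.kind == "stem":
        return [f"{rec.label} {q(rec.strand_ranges[0])} {q(rec.strand_ranges[1])}{tail}"]
    if rec.kind == "hairpin":
        return [f"{rec.label} {q(rec.strand_ranges[0])} "
                f"{_pair_text(structure, rec.closing_pairs[0])}{tail}"]
    if rec.kind == "bulge":
        return [f"{rec.label} {q(rec.strand_ranges[0])} "
                f"{_pair_text(structure, rec.closing_pairs[0])} "
                f"{_pair_text(structure, rec.closing_pairs[1])}{tail}"]
    if rec.kind == "internal":
        return [
            f"{rec.label}.1 {q(rec.strand_ranges[0])} "
            f"{_pair_text(structure, rec.closing_pairs[0])}{tail}",
            f"{rec.label}.2 {q(rec.strand_ranges[1])} "
            f"{_pair_text(structure, rec.closing_pairs[1])}{tail}",
        ]
    if rec.kind == "multiloop":
        lines = []
        k = 0
        for rng in rec.strand_ranges:
            if rng[1] < rng[0]:
                continue  # empty segment: re-derived from the dot-bracket
            k += 1
            lines.append(
                f"{rec.label}.{k} {q(rng)} "
                f"{_pair_text(structure, rec.closing_pairs[0])}{tail}"
            )
        if not lines:  # fully paired multiloop: placeholder keeps the energy
            lines.append(
                f"{rec.label}.0 {q(rec.strand_ranges[0])} "
                f"{_pair_text(structure, rec.closing_pairs[0])}{tail}"
            )
        return lines
    if rec.kind == "exterior":
        return [f"{rec.label} {q(rec.strand_ranges[0])}{tail}"]
    raise ValueError(rec.kind)


def write_st(structure: AnnotatedStructure) -> str:
    """Serialize to the .st dialect (no energies)."""
    return _write(structure, energies=None, sentinel="NA")


def write_ste(
    structure: AnnotatedStructure,
    energies: Mapping[str, object],
    sentinel: str = "NA",
) -> str:
    """Serialize to a .ste file: .st content with per-substructure energies.

    ``energies`` maps every substructure label to a kcal/mol float, ``None``
    (non-computable, written as ``sentinel``), or an object with ``value`` and
    ``computable`` attributes (a ``ComponentEnergy``).
    """
    missing = [r.label for r in structure.substructures if r.label not in energies]
    if missing:
        raise StructureValidationError(
            f"missing energies for labels: {', '.join(missing)}"
        )
    return _write(structure, energies=energies, sentinel=sentinel)


def _energy_value(entry: object) -> float | None:
    if entry is None:
        return None
    if hasattr(entry, "value") and hasattr(entry, "computable"):
        return entry.value if entry.computable else None  # type: ignore[attr-defined]
    return float(entry)  # type: ignore[arg-type]


def _write(
    structure: AnnotatedStructure,
    energies: Mapping[str, object] | None,
    sentinel: str,
) -> str:
    npages = 1 + (1 if structure.pk_pairs else 0)
    lines = [
        f"#Name: {structure.identifier}",
        f"#Length: {structure.length}",
        f"#PageNumber: {npages}",
        structure.sequence,
        structure.dotbracket,
        structure.type_string(),
    ]
    for rec in structure.substructures:
        e = None
        if energies is not None:
            e = _format_energy(_energy_value(energies[rec.label]), sentinel)
        lines.extend(_record_lines(structure, rec, e))
    for k, (i, j) in enumerate(structure.pk_pairs, start=1):
        lines.append(f"PK{k} ({i},{j})")
    return "\n".join(lines) + "\n"


def parse_st(text: str) -> AnnotatedStructure:
    """Parse .st (or .ste) content; annotation lines are cross-checked
    against the decomposition re-derived from the dot-bracket."""
    structure, _ = _parse(text)
    return structure


def read_ste(text: str, sentinel: str = "NA") -> tuple[AnnotatedStructure, dict[str, float | None]]:
    """Parse a .ste file, returning the structure and its label->energy map
    (``None`` where the sentinel was written)."""
    structure, energies = _parse(text, sentinel=sentinel)
    return structure, energies


def _parse(text: str, sentinel: str = "NA") -> tuple[AnnotatedStructure, dict[str, float | None]]:
    raw_lines = [ln.rstrip("\n") for ln in text.splitlines()]
    body: list[tuple[int, str]] = [
        (no, ln) for no, ln in enumerate(raw_lines, start=1) if ln.strip()
    ]
    identifier = "structure"
    declared_length = None
    i = 0
    while i < len(body) and body[i][1].startswith("#"):
        no, ln = body[i]
        m = re.match(r"#(\w+):\s*(.*)$", ln)
        if not m:
            raise StructureParseError(f"line {no}: malformed header '{ln}'")
        key, val = m.group(1), m.group(2).strip()
        if key == "Name":
            identifier = val
        elif key == "Length":
            declared_length = int(val)
        i += 1
    if len(body) - i < 3:
        raise StructureParseError("missing sequence / dot-bracket / type lines")
    (no_seq, sequence), (no_db, dotbracket), (no_ts, typestr) = body[i:i + 3]
    i += 3
    sequence = sequence.strip().upper().replace("T", "U")
    dotbracket = dotbracket.strip()
    typestr = typestr.strip()
    if set(sequence) - VALID_BASES:
        raise StructureParseError(f"line {no_seq}: invalid sequence characters")
    if declared_length is not None and declared_length != len(sequence):
        raise StructureValidationError(
            f"declared length {declared_length} != sequence length {len(sequence)}"
        )
    if len(dotbracket) != len(sequence):
        raise StructureValidationError(
            f"line {no_db}: dot-bracket length {len(dotbracket)} != "
            f"sequence length {len(sequence)}"
        )
    structure = annotate_from_dotbracket(sequence, dotbracket, identifier)
    if len(typestr) != len(sequence):
        raise StructureValidationError(
            f"line {no_ts}: type string length mismatch"
        )
    if typestr != structure.type_string():
        diff = next(
            k for k, (a, b) in enumerate(zip(typestr, structure.type_string()), 1)
            if a != b
        )
        raise StructureValidationError(
            f"line {no_ts}: type string disagrees with dot-bracket at "
            f"position {diff}"
        )

    derived = {rec.label: rec for rec in structure.substructures}
    energies: dict[str, float | None] = {}
    seen: set[str] = set()
    for no, ln in body[i:]:
        ln = ln.strip()
        parsed = None
        for kind, regex in _LINE_RES.items():
            m = regex.match(ln)
            if m:
                parsed = (kind, m)
                break
        if parsed is None:
            raise StructureParseError(f"line {no}: malformed annotation '{ln}'")
        kind, m = parsed
        if kind == "pk":
            i0, j0 = int(m.group(1)), int(m.group(2))
            if (i0, j0) not in structure.pk_pairs:
                raise StructureValidationError(
                    f"line {no}: pseudoknot pair ({i0},{j0}) not in dot-bracket"
                )
            continue
        label = m.group(1)
        if label not in derived:
            raise StructureValidationError(
                f"line {no}: label {label} not derivable from the dot-bracket"
            )
        rec = derived[label]
        if rec.kind != kind:
            raise StructureValidationError(
                f"line {no}: label {label} is a {rec.kind}, annotated as {kind}"
            )
        _check_line(no, kind, m, rec, structure)
        energy_txt = m.groupdict().get("energy")
        if energy_txt is not None:
            value = None if energy_txt == sentinel else float(energy_txt)
            if label in energies and energies[label] != value:
                raise StructureValidationError(
                    f"line {no}: conflicting energies for {label}"
                )
            energies[label] = value
        seen.add(label)
    missing = [
        r.label for r in structure.substructures
        if r.label not in seen and any(e >= s for s, e in r.strand_ranges)
    ]
    if missing:
        raise StructureValidationError(
            f"annotation lines missing for: {', '.join(missing)}"
        )
    return structure, energies


def _check_line(
    no: int,
    kind: str,
    m: re.Match,
    rec: SubstructureRecord,
    structure: AnnotatedStructure,
) -> None:
    g = m.groups()
    if kind == "stem":
        r1 = (int(g[1]), int(g[2]))
        r2 = (int(g[4]), int(g[5]))
        ok = rec.strand_ranges == (r1, r2)
        seqs_ok = (g[3] == _seq_slice(structure, r1)) and (g[6] == _seq_slice(structure, r2))
    elif kind in ("hairpin", "bulge"):
        r1 = (int(g[1]), int(g[2]))
        ok = rec.strand_ranges[0] == r1
        pair = (int(g[4]), int(g[5]))
        ok = ok and rec.closing_pairs[0] == pair
        if kind == "bulge":
            pair2 = (int(g[8]), int(g[9]))
            ok = ok and rec.closing_pairs[1] == pair2
        seqs_ok = g[3] == _seq_slice(structure, r1)
    elif kind == "internal":
        part = int(g[1]) - 1
        r1 = (int(g[2]), int(g[3]))
        ok = rec.strand_ranges[part] == r1
        ok = ok and rec.closing_pairs[part] == (int(g[5]), int(g[6]))
        seqs_ok = g[4] == _seq_slice(structure, r1)
    elif kind == "multiloop":
        r1 = (int(g[2]), int(g[3]))
        ok = r1 in rec.strand_ranges
        seqs_ok = g[4] == _seq_slice(structure, r1)
    else:  # exterior
        r1 = (int(g[1]), int(g[2]))
        ok = rec.strand_ranges[0] == r1
        seqs_ok = g[3] == _seq_slice(structure, r1)
    if not ok:
        raise StructureValidationError(
            f"line {no}: {rec.label} annotation disagrees with the dot-bracket "
            f"decomposition"
        )
    if not seqs_ok:
        raise StructureValidationError(
            f"line {no}: {rec.label} quoted sequence disagrees with the "
            f"sequence line"
        )


def decomposition_to_json(structure: AnnotatedStructure) -> str:
    """JSON dump of the decomposition (for downstream tooling)."""
    payload = {
        "identifier": structure.identifier,
        "length": structure.length,
        "sequence": structure.sequence,
        "dotbracket": structure.dotbracket,
        "pk_pairs": [list(p) for p in structure.pk_pairs],
        "substructures": [
            {
                "kind": r.kind,
                "label": r.label,
                "strand_ranges": [list(x) for x in r.strand_ranges],
                "closing_pairs": [list(x) for x in r.closing_pairs],
                "length_summary": list(r.length_summary),
                "pseudoknot": r.pseudoknot,
                "contains_n": r.contains_n,
            }
            for r in structure.substructures
        ],
    }
    return json.dumps(payload, indent=2)
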