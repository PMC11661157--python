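"""Constrained refolding of under-folded database structures.

Consensus-derived secondary structures can leave long stretches unpaired
where sequence does not align to the consensus; such "under-folded"
structures distort loop free energies.  The remedy is to refold the
sequence with the trusted (consensus) base pairs enforced as hard
constraints and let a thermodynamic folding engine arrange the rest.

The folding engine is pluggable behind a two-method contract
(:class:`FoldingBackend`): ``fold(sequence, constraint) -> dot-bracket`` and
``version()``.  A ViennaRNA-backed implementation and a deterministic mock
(for tests and adversarial contract checks) are provided.  ``refold``
verifies the hard guarantee that no forced pair is lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

from .structure_io import AnnotatedStructure, annotate_from_dotbracket

__all__ = [
    "ConstraintSpec",
    "FoldingBackend",
    "ViennaBackend",
    "MockBackend",
    "BackendContractError",
    "build_constraints",
    "refold",
    "flag_underfolded",
]


class BackendContractError(RuntimeError):
    """The folding backend violated its contract (lost a forced pair)."""


@dataclass(frozen=True)
class ConstraintSpec:
    """Hard pairing constraints: forced pairs in the standard dialect
    ('(' / ')' at forced partners, '.' = unconstrained/free)."""

    length: int
    forced_pairs: frozenset[tuple[int, int]]
    constraint_string: str

    def __post_init__(self) -> None:
        if len(self.constraint_string) != self.length:
            raise ValueError("constraint string length mismatch")


def build_constraints(
    forced_pairs: Iterable[tuple[int, int]], length: int
) -> ConstraintSpec:
    """Constraint string with '(' at i and ')' at j for each forced pair.

    Pairs must be 1-based, within range, non-overlapping, and nested
    (crossing/pseudoknotted constraints are unsupported).
    """
    pairs = sorted((min(i, j), max(i, j)) for i, j in forced_pairs)
    used: set[int] = set()
    for i, j in pairs:
        if i == j:
            raise ValueError(f"pair ({i},{j}) is self-pairing")
        if not (1 <= i < j <= length):
            raise ValueError(f"pair ({i},{j}) outside 1..{length}")
        if i in used or j in used:
            raise ValueError(f"position reused in pair ({i},{j})")
        used.update((i, j))
    open_spans: list[tuple[int, int]] = []
    for i, j in pairs:
        while open_spans and open_spans[-1][1] < i:
            open_spans.pop()
        if open_spans and not (open_spans[-1][0] < i and j < open_spans[-1][1]):
            raise ValueError(f"crossing constraint pairs near ({i},{j})")
        open_spans.append((i, j))
    chars = ["."] * length
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return ConstraintSpec(
        length=length,
        forced_pairs=frozenset(pairs),
        constraint_string="".join(chars),
    )


@runtime_checkable
class FoldingBackend(Protocol):
    def fold(self, sequence: str, constraint: str | None = None) -> str:
        """Return a dot-bracket honoring every constrained pair."""

    def version(self) -> str: ...


class ViennaBackend:
    """MFE folding through the installed ViennaRNA python bindings."""

    def __init__(self, dangles: int = 2):
        import RNA  # deferred: optional at import time

        self._rna = RNA
        self._dangles = dangles

    def fold(self, sequence: str, constraint: str | None = None) -> str:
        RNA = self._rna
        md = RNA.md()
        md.dangles = self._dangles
        fc = RNA.fold_compound(sequence, md)
        if constraint is not None:
            fc.hc_add_from_db(
                constraint,
                RNA.CONSTRAINT_DB_DEFAULT | RNA.CONSTRAINT_DB_ENFORCE_BP,
            )
        db, _ = fc.mfe()
        return db

    def version(self) -> str:
        return f"ViennaRNA {self._rna.__version__}"


class MockBackend:
    """Deterministic backend for tests: echoes preset structures."""

    def __init__(self, outputs: dict[str, str] | None = None, default: str | None = None):
        self._outputs = outputs or {}
        self._default = default

    def fold(self, sequence: str, constraint: str | None = None) -> str:
        if sequence in self._outputs:
            return self._outputs[sequence]
        if self._default is not None:
            return self._default
        raise RuntimeError(f"mock backend has no output for {sequence!r}")

    def version(self) -> str:
        return "mock-1"


def refold(
    sequence: str,
    constraints: ConstraintSpec,
    backend: FoldingBackend,
    identifier: str = "refolded",
) -> AnnotatedStructure:
    """Fold with hard constraints and re-derive the decomposition.

    Raises :class:`BackendContractError` if the backend's structure misses
    any forced pair; backend failures propagate with context.
    """
    if len(sequence) != constraints.length:
        raise ValueError("sequence length differs from constraint length")
    try:
        db = backend.fold(sequence, constraints.constraint_string)
    except BackendContractError:
        raise
    except Exception as exc:
        raise RuntimeError(
            f"folding backend {backend.version()} failed on {identifier}: {exc}"
        ) from exc
    structure = annotate_from_dotbracket(sequence, db, identifier)
    missing = [
        (i, j) for i, j in sorted(constraints.forced_pairs)
        if structure.pairing[i - 1] != j
    ]
    if missing:
        raise BackendContractError(
            f"{backend.version()} violated {len(missing)} forced pair(s) on "
            f"{identifier}: {missing[:5]}"
        )
    return structure


def flag_underfolded(
    structure: AnnotatedStructure, max_unpaired_run: int = 20
) -> tuple[bool, list[tuple[int, int]]]:
    """Flag structures with long unpaired stretches.

    Returns (flag, runs): flag is true iff any maximal unpaired run is at
    least ``max_unpaired_run`` nucleotides; offending runs are returned as
    1-based inclusive ranges.
    """
    runs: list[tuple[int, int]] = []
    start = None
    for idx, partner in enumerate(list(structure.pairing) + [1], start=1):
        if partner == 0:
            if start is None:
                start = idx
        else:
            if start is not None and idx - start >= max_unpaired_run:
                runs.append((start, idx - 1))
            start = None
    return bool(runs), runs
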