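"""Shared domain types: basis labels, subspace superpositions, candidates, traces.

Conventions used everywhere in the package:

* A *basis label* is a big-endian text bitstring: the leftmost pair of bits
  belongs to the first interaction site, and within a pair the left bit is
  the hydrophobic one.  The statevector index of a label is simply
  ``int(label, 2)``.
* All amplitudes in this package are real and non-negative except for the
  phase flips the search introduces internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .errors import SizeError

_BITS = frozenset("01")


def validate_label(bits: str, *, expect_len: Optional[int] = None) -> str:
    """Validate a basis-label bitstring and return it.

    Raises :class:`SizeError` on a length mismatch, ``ValueError`` on
    non-binary characters.
    """
    if not isinstance(bits, str) or not bits or not set(bits) <= _BITS:
        raise ValueError(f"not a non-empty 0/1 bitstring: {bits!r}")
    if expect_len is not None and len(bits) != expect_len:
        raise SizeError(f"label {bits!r} has {len(bits)} bits, expected {expect_len}")
    return bits


def label_index(bits: str) -> int:
    """Statevector index of a big-endian basis label."""
    return int(validate_label(bits), 2)


def index_label(index: int, n_qubits: int) -> str:
    """Big-endian basis label of a statevector index."""
    return format(index, f"0{n_qubits}b")


@dataclass(frozen=True)
class SuperpositionState:
    """The search subspace |s> = (1/sqrt(N)) * sum over distinct basis labels.

    Amplitudes are uniform and real; ``basis`` preserves the caller's order
    (last-occurrence order of the window scan).
    """

    basis: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.basis:
            raise ValueError("superposition needs at least one basis label")
        width = len(self.basis[0])
        for b in self.basis:
            validate_label(b, expect_len=width)
        if len(set(self.basis)) != len(self.basis):
            raise ValueError("superposition basis labels must be distinct")

    @property
    def n_states(self) -> int:
        return len(self.basis)

    @property
    def n_qubits(self) -> int:
        return len(self.basis[0])

    @property
    def amplitude(self) -> float:
        """Uniform amplitude 1/sqrt(N)."""
        return 1.0 / math.sqrt(self.n_states)

    def statevector(self) -> np.ndarray:
        """Dense real statevector over the full 2**n_qubits basis."""
        vec = np.zeros(2 ** self.n_qubits)
        amp = self.amplitude
        for b in self.basis:
            vec[int(b, 2)] = amp
        return vec


@dataclass
class DockingCandidate:
    """A located (and optionally evaluated) docking site.

    ``start_offset`` is a 0-based site index into the original, unshifted
    protein chain.  ``distance`` and ``rank`` are filled by the evaluation
    stage; ``clamped`` flags a sampled distance whose radicand dipped below
    zero from shot noise and was clamped to 0.
    """

    start_offset: int
    label: str
    probability: Optional[float] = None
    threshold: Optional[float] = None
    distance: Optional[float] = None
    rank: Optional[int] = None
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "start_offset": self.start_offset,
            "label": self.label,
            "probability": self.probability,
            "threshold": self.threshold,
            "distance": self.distance,
            "rank": self.rank,
            "clamped": self.clamped,
        }


@dataclass(frozen=True)
class NodeRecord:
    """One presence decision in the search tree."""

    shift: int
    start_offsets: tuple[int, ...]
    n_unique: int
    path: str  # "deterministic" | "grover"
    iterations: int
    p_target: float
    threshold: float
    present: bool

    def to_dict(self) -> dict:
        return {
            "kind": "node",
            "shift": self.shift,
            "start_offsets": list(self.start_offsets),
            "n_unique": self.n_unique,
            "path": self.path,
            "iterations": self.iterations,
            "p_target": self.p_target,
            "threshold": self.threshold,
            "present": self.present,
        }


@dataclass(frozen=True)
class TruncationRecord:
    """Trailing sites of a shift pass that did not fill a whole window."""

    shift: int
    dropped_offsets: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "kind": "truncation",
            "shift": self.shift,
            "dropped_offsets": list(self.dropped_offsets),
        }


@dataclass(frozen=True)
class ShiftSkipRecord:
    """A shift pass skipped because the remaining protein is shorter than one window."""

    shift: int
    reason: str

    def to_dict(self) -> dict:
        return {"kind": "shift_skip", "shift": self.shift, "reason": self.reason}


@dataclass
class SearchTrace:
    """Audit trail of the segmentation/shift/bisection controller.

    Every presence decision the controller takes is recorded together with
    the probability and threshold it was derived from.
    """

    records: list = field(default_factory=list)

    def add(self, record) -> None:
        self.records.append(record)

    def nodes(self) -> list[NodeRecord]:
        return [r for r in self.records if isinstance(r, NodeRecord)]

    def truncations(self) -> list[TruncationRecord]:
        return [r for r in self.records if isinstance(r, TruncationRecord)]

    def to_dict(self) -> dict:
        return {"records": [r.to_dict() for r in self.records]}


@dataclass
class SearchResult:
    """Candidates (positions only) plus the full trace that produced them."""

    candidates: list[DockingCandidate]
    trace: SearchTrace

    def offsets(self) -> list[int]:
        return [c.start_offset for c in self.candidates]


def dedupe_preserve_order(items: Iterable[str]) -> list[str]:
    seen = set()
    out = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out
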