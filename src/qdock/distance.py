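"""Quantum Euclidean distance via amplitude embedding and the SWAP test.

Two real vectors A and B (here: the amplitude-encoded ligand and a candidate
docking slice) are compared by preparing

    |psi> = (|A> (x) |0> + |B> (x) |1>) / sqrt(2)
    |phi> = (|A| |0> - |B| |1>) / sqrt(Z),      Z = |A|^2 + |B|^2

and running a SWAP test between |phi> and the ancilla qubit of |psi>.  The
probability of reading 0 on the control qubit is

    p0 = 1/2 + 1/2 * || <phi|psi> ||^2

where the bra contracts only the ancilla, leaving the register vector
(A - B)/sqrt(2Z); hence

    D = sqrt(4 Z (p0 - 1/2)) = |A - B|

recovers the ordinary Euclidean distance exactly on the statevector backend.
Candidates are ranked ascending by D: the slice most similar to the ligand
(in the continuous interaction values, not just the thresholded bits) ranks
first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .encoding import (
    DEFAULT_QUBIT_BUDGET,
    MoleculeChain,
    SiteRanges,
    encode_chain_amplitude,
)
from .errors import CapacityError, DegenerateInputError, SizeError
from .model import DockingCandidate
from .segmentation import encode_chain_binary

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class EmbeddedVector:
    """A real vector amplitude-embedded as a unit quantum state plus its norm."""

    raw: np.ndarray
    norm: float
    unit_state: np.ndarray

    @classmethod
    def from_raw(cls, raw: Sequence[float]) -> "EmbeddedVector":
        arr = np.asarray(raw, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("embedding needs a non-empty 1-D real vector")
        n = float(np.linalg.norm(arr))
        unit = arr / n if n > 0 else np.zeros_like(arr)
        return cls(raw=arr, norm=n, unit_state=unit)


@dataclass(frozen=True)
class SwapTestResult:
    """One SWAP-test distance estimate."""

    p0: float
    Z: float
    distance: float
    shots: Union[int, str]
    clamped: bool = False


def classical_euclidean(x: Sequence[float], y: Sequence[float]) -> float:
    """Plain Euclidean distance; the classical validation oracle."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise SizeError(f"length mismatch {xa.shape} vs {ya.shape}")
    return float(np.linalg.norm(xa - ya))


def build_phi(A: EmbeddedVector, B: EmbeddedVector) -> tuple[np.ndarray, float]:
    """Norm qubit |phi> = (|A||0> - |B||1>)/sqrt(Z) and Z = |A|^2 + |B|^2."""
    Z = A.norm**2 + B.norm**2
    if Z <= 0:
        raise DegenerateInputError("both vectors have zero norm")
    phi = np.array([A.norm, -B.norm]) / math.sqrt(Z)
    return phi, Z


def build_psi(A: EmbeddedVector, B: EmbeddedVector) -> np.ndarray:
    """Entangled data state (|A>|0> + |B>|1>)/sqrt(2).

    The ancilla qubit is the LEAST significant bit of the returned vector:
    amplitude index 2*x + anc, so even indices carry |A> and odd carry |B>.
    """
    a, b = A.unit_state, B.unit_state
    if a.size != b.size:
        raise SizeError(f"dimension mismatch {a.size} vs {b.size}")
    psi = np.empty(2 * a.size)
    psi[0::2] = a / _SQRT2
    psi[1::2] = b / _SQRT2
    return psi


def swap_test_p0(
    psi: np.ndarray,
    phi: np.ndarray,
    *,
    backend: str = "exact",
    shots: Optional[int] = None,
    seed=None,
    qubit_budget: int = DEFAULT_QUBIT_BUDGET,
) -> float:
    """Probability of measuring 0 on the SWAP-test control qubit.

    The circuit is simulated literally: control in |0>, Hadamard, a SWAP of
    phi's qubit with psi's ancilla qubit controlled on the control, Hadamard,
    measure.  ``sampling`` draws a seeded binomial estimate of p0.
    """
    psi = np.asarray(psi, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if phi.size != 2:
        raise SizeError("phi must be a single-qubit state (length 2)")
    if psi.ndim != 1 or psi.size % 2 or psi.size < 2:
        raise SizeError("psi must be a register-plus-ancilla state of even length")
    n_total = int(math.log2(psi.size)) + 2  # psi qubits + phi + control
    if n_total > qubit_budget:
        raise CapacityError(f"SWAP test needs {n_total} qubits, budget {qubit_budget}")

    d = psi.size // 2
    # after the first Hadamard both control branches hold |psi>|phi> / sqrt(2)
    joint = np.kron(psi, phi) / _SQRT2            # control-0 branch
    swapped = (
        np.kron(psi, phi).reshape(d, 2, 2).transpose(0, 2, 1).reshape(-1) / _SQRT2
    )                                             # control-1 branch after cSWAP
    # second Hadamard recombines; measure the control
    branch0 = (joint + swapped) / _SQRT2
    p0 = float(branch0 @ branch0)
    p0 = min(max(p0, 0.0), 1.0)
    if backend == "exact":
        return p0
    if backend == "sampling":
        if not shots or shots < 1:
            raise ValueError("sampling backend needs shots >= 1")
        rng = np.random.default_rng(seed)
        return float(rng.binomial(shots, p0)) / shots
    raise ValueError(f"unknown backend {backend!r}")


def distance_from_p0(p0: float, Z: float) -> SwapTestResult:
    """Distance D = sqrt(4 Z (p0 - 1/2)); shot noise below 1/2 clamps to 0."""
    if Z <= 0:
        raise DegenerateInputError("Z must be positive")
    radicand = 4.0 * Z * (p0 - 0.5)
    clamped = radicand < 0
    d = 0.0 if clamped else math.sqrt(radicand)
    return SwapTestResult(p0=p0, Z=Z, distance=d, shots="exact", clamped=clamped)


def quantum_distance(
    a_raw: Sequence[float],
    b_raw: Sequence[float],
    *,
    backend: str = "exact",
    shots: Optional[int] = None,
    seed=None,
    qubit_budget: int = DEFAULT_QUBIT_BUDGET,
) -> SwapTestResult:
    """End-to-end SWAP-test Euclidean distance between two real vectors."""
    A = EmbeddedVector.from_raw(a_raw)
    B = EmbeddedVector.from_raw(b_raw)
    phi, Z = build_phi(A, B)
    if A.norm == 0 or B.norm == 0:
        # a zero-norm side has no amplitude state; the distance reduces to
        # the other vector's norm, which phi/Z already carry
        other = A if A.norm > 0 else B
        return SwapTestResult(p0=1.0, Z=Z, distance=other.norm, shots=shots or "exact")
    psi = build_psi(A, B)
    p0 = swap_test_p0(
        psi, phi, backend=backend, shots=shots, seed=seed, qubit_budget=qubit_budget
    )
    res = distance_from_p0(p0, Z)
    return SwapTestResult(
        p0=res.p0, Z=Z, distance=res.distance,
        shots=shots if backend == "sampling" else "exact",
        clamped=res.clamped,
    )


def rank_candidates(
    ligand: MoleculeChain,
    candidates: Sequence,
    protein: MoleculeChain,
    ranges: SiteRanges,
    config=None,
) -> list[DockingCandidate]:
    """Evaluate located positions by amplitude-state distance and rank them.

    ``candidates`` may be start offsets (ints) or positioned
    :class:`DockingCandidate` objects.  Each candidate slice and the ligand
    are amplitude-encoded (unit states, so Z = 2) and compared by the
    SWAP-test distance; the result is sorted ascending by distance with ties
    broken by start offset, ranks 1..m.
    """
    from .io import RunConfig

    cfg = config if config is not None else RunConfig(ranges=ranges)
    L = len(ligand)
    lig_state = encode_chain_amplitude(ligand, ranges, qubit_budget=cfg.qubit_budget)
    out: list[DockingCandidate] = []
    for i, cand in enumerate(candidates):
        if isinstance(cand, DockingCandidate):
            off, prob, thr = cand.start_offset, cand.probability, cand.threshold
        else:
            off, prob, thr = int(cand), None, None
        chunk = protein.slice(off, L)
        chunk_state = encode_chain_amplitude(chunk, ranges, qubit_budget=cfg.qubit_budget)
        res = quantum_distance(
            lig_state,
            chunk_state,
            backend=cfg.backend,
            shots=cfg.shots if cfg.backend == "sampling" else None,
            seed=None if cfg.seed is None else [cfg.seed, 1_000_000 + i],
            qubit_budget=cfg.qubit_budget,
        )
        out.append(
            DockingCandidate(
                start_offset=off,
                label=encode_chain_binary(chunk, ranges),
                probability=prob,
                threshold=thr,
                distance=res.distance,
                clamped=res.clamped,
            )
        )
    out.sort(key=lambda c: (c.distance, c.start_offset))
    for r, cand in enumerate(out, start=1):
        cand.rank = r
    return out
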