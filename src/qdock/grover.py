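"""Grover search over a non-uniform subspace superposition.

Classic Grover assumes a uniform superposition over the whole register; here
the initial state |s> spans only the distinct window labels of the protein
(a Hilbert subspace), so the search converges in fewer than sqrt(N)
iterations, N being the number of basis states actually in |s>.  One
iteration is the usual pair of reflections

    oracle     O = I - 2|t><t|        (phase-flip the ligand label |t>)
    diffusion  G = 2|s><s| - I        (reflect about the initial state)

and for a present target the exact probability after k iterations is the
textbook sin^2((2k+1) * arcsin(1/sqrt(N))).  For an absent target the state
never moves (O acts as identity on span(s), G fixes |s>) and the target
probability stays exactly zero — which is what makes the 1/N presence
threshold work.

Two interchangeable diffusion implementations are provided:

* ``matrix`` — G built as an explicit dense unitary and applied directly;
* ``ancilla`` — the amplitude-amplification construction: un-prepare |s>,
  reflect about |0...0> via phase kickback on an extra ancilla qubit held in
  |->, re-prepare.  Its marginal distribution over the search register is
  identical to the matrix path (up to a global phase per iteration).

Backends: ``exact`` returns squared amplitudes; ``sampling`` draws a seeded
multinomial of ``shots`` measurement outcomes from them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

from .encoding import DEFAULT_QUBIT_BUDGET
from .errors import CapacityError, SizeError
from .model import SuperpositionState, index_label, validate_label

#: Absolute tolerance on the 1/N presence boundary; absorbs float roundoff in
#: the simulated probability (the two-state present case sits exactly at 1/N).
PRESENCE_TOL = 1e-9


@dataclass(frozen=True)
class MeasurementDistribution:
    """Outcome of measuring the search register.

    ``shots`` is the literal string ``"exact"`` for the statevector backend,
    in which case ``probabilities`` are exact squared amplitudes and
    ``counts`` is None; for the sampling backend ``counts`` holds seeded
    multinomial draws and ``probabilities`` the empirical frequencies.
    """

    n_qubits: int
    shots: Union[int, str]
    seed: Optional[int]
    probabilities: Mapping[str, float]
    counts: Optional[Mapping[str, int]] = None

    def probability(self, label: str) -> float:
        validate_label(label, expect_len=self.n_qubits)
        return float(self.probabilities.get(label, 0.0))

    def count(self, label: str) -> int:
        if self.counts is None:
            raise ValueError("exact backend has no counts")
        return int(self.counts.get(label, 0))


@dataclass(frozen=True)
class PresenceDecision:
    """The 1/N presence test for one target label."""

    target: str
    p_target: float
    threshold: float
    present: bool
    iterations_used: int

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "p_target": self.p_target,
            "threshold": self.threshold,
            "present": self.present,
            "iterations_used": self.iterations_used,
        }


def oracle_reflection(target: str, n_qubits: int) -> np.ndarray:
    """Dense unitary O = I - 2|t><t|: phase-flips the target basis state.

    Hermitian and self-inverse.
    """
    validate_label(target, expect_len=n_qubits)
    op = np.eye(2**n_qubits)
    t = int(target, 2)
    op[t, t] = -1.0
    return op


def diffusion_reflection(s: SuperpositionState) -> np.ndarray:
    """Dense unitary G = 2|s><s| - I: reflects about the initial superposition.

    Hermitian and self-inverse.
    """
    vec = s.statevector()
    return 2.0 * np.outer(vec, vec) - np.eye(vec.size)


def choose_iterations(n_states: int) -> int:
    """Iteration count k = max(1, floor(pi/4 * sqrt(N))) for a single marked item.

    Always fewer than sqrt(N) for N >= 2 (floor(0.785*sqrt(N)) < sqrt(N)),
    and the standard optimum for one marked state among N.  N = 1 has no
    quantum path — the caller compares the single label deterministically.
    """
    if n_states < 2:
        raise ValueError("quantum search needs at least 2 basis states; N=1 is deterministic")
    return max(1, math.floor(math.pi / 4.0 * math.sqrt(n_states)))


def _distribution_from_probs(
    probs: np.ndarray,
    n_qubits: int,
    target: str,
    backend: str,
    shots: Optional[int],
    seed,
) -> MeasurementDistribution:
    if backend == "exact":
        nz = {index_label(i, n_qubits): float(p) for i, p in enumerate(probs) if p > 1e-15}
        nz.setdefault(target, 0.0)
        return MeasurementDistribution(n_qubits, "exact", None, nz)
    if backend == "sampling":
        if not shots or shots < 1:
            raise ValueError("sampling backend needs shots >= 1")
        rng = np.random.default_rng(seed)
        draw = rng.multinomial(shots, probs / probs.sum())
        counts = {index_label(i, n_qubits): int(c) for i, c in enumerate(draw) if c > 0}
        counts.setdefault(target, 0)
        freqs = {lab: c / shots for lab, c in counts.items()}
        seed_val = seed if seed is None or isinstance(seed, int) else None
        return MeasurementDistribution(n_qubits, shots, seed_val, freqs, counts)
    raise ValueError(f"unknown backend {backend!r}")


def run_grover(
    s: SuperpositionState,
    target: str,
    k: Optional[int] = None,
    *,
    backend: str = "exact",
    shots: Optional[int] = None,
    seed=None,
    diffusion: str = "matrix",
    qubit_budget: int = DEFAULT_QUBIT_BUDGET,
) -> MeasurementDistribution:
    """Prepare |s>, apply k Grover iterations, measure the register.

    ``k=None`` uses :func:`choose_iterations`.  ``diffusion`` selects the
    explicit-unitary path (``"matrix"``) or the ancilla amplitude-
    amplification path (``"ancilla"``); both yield the same register
    distribution.
    """
    n = s.n_qubits
    validate_label(target, expect_len=n)
    if n > qubit_budget:
        raise CapacityError(f"search register of {n} qubits exceeds budget {qubit_budget}")
    if k is None:
        k = choose_iterations(s.n_states)
    if k < 1:
        raise ValueError("iteration count must be >= 1")
    if diffusion == "ancilla":
        return run_grover_ancilla(
            s, target, k, backend=backend, shots=shots, seed=seed, qubit_budget=qubit_budget
        )
    if diffusion != "matrix":
        raise ValueError(f"unknown diffusion implementation {diffusion!r}")

    vec = s.statevector()
    gate = diffusion_reflection(s)
    t = int(target, 2)
    for _ in range(k):
        vec[t] = -vec[t]  # oracle: phase flip
        vec = gate @ vec
    probs = vec**2
    return _distribution_from_probs(probs, n, target, backend, shots, seed)


def _preparation_unitary(s_vec: np.ndarray) -> np.ndarray:
    """Real unitary A with A|0...0> = |s> (a Householder reflection)."""
    dim = s_vec.size
    e0 = np.zeros(dim)
    e0[0] = 1.0
    v = e0 - s_vec
    vv = v @ v
    if vv < 1e-28:
        return np.eye(dim)
    return np.eye(dim) - 2.0 * np.outer(v, v) / vv


def run_grover_ancilla(
    s: SuperpositionState,
    target: str,
    k: Optional[int] = None,
    *,
    backend: str = "exact",
    shots: Optional[int] = None,
    seed=None,
    qubit_budget: int = DEFAULT_QUBIT_BUDGET,
) -> MeasurementDistribution:
    """Grover via amplitude amplification with one extra ancilla qubit.

    The diffusion is compiled as A * R0 * A^dagger where A prepares |s> and
    R0 reflects about |0...0> by phase kickback: the ancilla sits in
    |-> = (|0> - |1>)/sqrt(2) and an X on it, controlled on the register
    being all-zero, deposits the -1 phase.  The register marginal equals the
    explicit-matrix path exactly.
    """
    n = s.n_qubits
    validate_label(target, expect_len=n)
    if n + 1 > qubit_budget:
        raise CapacityError(f"ancilla search needs {n + 1} qubits, budget {qubit_budget}")
    if k is None:
        k = choose_iterations(s.n_states)
    if k < 1:
        raise ValueError("iteration count must be >= 1")

    dim = 2**n
    s_vec = s.statevector()
    prep = _preparation_unitary(s_vec)
    minus = np.array([1.0, -1.0]) / math.sqrt(2.0)
    # ancilla is the least-significant bit: amplitude index = 2*register + anc
    state = np.kron(s_vec, minus)
    t = int(target, 2)
    for _ in range(k):
        state[2 * t] = -state[2 * t]
        state[2 * t + 1] = -state[2 * t + 1]
        block = state.reshape(dim, 2)
        block = prep.T @ block  # A^dagger on the register (A is real)
        # X on the ancilla controlled on register == |0...0>; with the
        # ancilla in |-> this is a -1 phase on the register-zero component
        block[0, 0], block[0, 1] = block[0, 1], block[0, 0]
        block = prep @ block
        state = block.reshape(-1)
    probs = (state.reshape(dim, 2) ** 2).sum(axis=1)
    return _distribution_from_probs(probs, n, target, backend, shots, seed)


def decide_presence(
    dist: MeasurementDistribution, target: str, n_states: int, *, iterations_used: int = 1
) -> PresenceDecision:
    """Presence test: the target is present iff p_target reaches 1/N.

    The threshold comes from the two-state extreme: with N = 2 a present
    ligand label measures at exactly 1/2 after amplification while an absent
    one measures at 0, so the boundary is inclusive (within PRESENCE_TOL for
    float roundoff).  With more basis states a present target lands well
    above 1/N and an absent one stays at exactly 0 on the exact backend.
    """
    if n_states < 2:
        raise ValueError("presence threshold 1/N needs N >= 2")
    threshold = 1.0 / n_states
    p = dist.probability(target)
    return PresenceDecision(
        target=target,
        p_target=p,
        threshold=threshold,
        present=bool(p >= threshold - PRESENCE_TOL),
        iterations_used=iterations_used,
    )
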