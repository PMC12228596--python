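"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: the
substring scan is plain string slicing, the Grover closed form is the
textbook trigonometric identity, and brute-force Grover builds the two
reflection matrices from their definitions with raw numpy.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from qdock import DEFAULT_RANGES, PropertyRange, SiteRanges


@pytest.fixture
def unit_ranges() -> SiteRanges:
    return DEFAULT_RANGES


@pytest.fixture
def skew_ranges() -> SiteRanges:
    return SiteRanges(h=PropertyRange(0.2, 0.8), hb=PropertyRange(-1.0, 3.0))


def substring_scan(protein_label: str, ligand_label: str) -> list[int]:
    """Independent oracle: site offsets of every aligned slice equal to the ligand."""
    L = len(ligand_label) // 2
    P = len(protein_label) // 2
    return [
        off
        for off in range(P - L + 1)
        if protein_label[2 * off : 2 * off + 2 * L] == ligand_label
    ]


def grover_closed_form(n_states: int, k: int) -> float:
    """Exact in-set target probability sin^2((2k+1) arcsin(1/sqrt(N)))."""
    theta = math.asin(1.0 / math.sqrt(n_states))
    return math.sin((2 * k + 1) * theta) ** 2


def brute_force_grover(basis: list[str], target: str, k: int) -> np.ndarray:
    """Matrix-level Grover from first principles, independent of qdock.grover."""
    n = len(basis[0])
    dim = 2**n
    s = np.zeros(dim)
    for b in basis:
        s[int(b, 2)] = 1.0 / math.sqrt(len(basis))
    oracle = np.eye(dim)
    t = int(target, 2)
    oracle[t, t] = -1.0
    diffusion = 2.0 * np.outer(s, s) - np.eye(dim)
    vec = s.copy()
    for _ in range(k):
        vec = diffusion @ (oracle @ vec)
    return vec**2


def random_distinct_labels(n_states: int, n_qubits: int, rng) -> list[str]:
    """N distinct random basis labels of the given width."""
    idx = rng.choice(2**n_qubits, size=n_states, replace=False)
    return [format(int(i), f"0{n_qubits}b") for i in idx]
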