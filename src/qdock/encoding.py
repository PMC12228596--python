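"""Quantum-state encodings of lattice interaction sites.

Each interaction site of a protein or ligand carries two continuous
properties — a hydrophobic interaction strength ``h`` and a hydrogen-bonding
strength ``hb`` — each bounded by a user-supplied range.  Two encodings map
these values onto qubits:

* **Binary (search) encoding** — each property is thresholded at the
  midpoint of its range: values in ``[min, mid)`` become ``|0>``, values in
  ``[mid, max]`` (midpoint included) become ``|1>``.  One site therefore
  yields two bits, hydrophobic bit first, and a whole chain is the
  concatenation of its per-site pairs.  These labels are what the Grover
  stage searches over.

* **Amplitude (evaluation) encoding** — each property becomes a one-qubit
  superposition ``alpha|0> + beta|1>`` whose amplitudes interpolate between
  the range endpoints:

      alpha = (max - v) / sqrt((max - v)^2 + (v - min)^2)
      beta  = (v - min) / sqrt((max - v)^2 + (v - min)^2)

  A site is the tensor product of its two property qubits and a chain the
  tensor product of its sites.  These states feed the SWAP-test distance.

Out-of-range values raise :class:`~qdock.errors.RangeViolationError` rather
than being clamped: a silently clamped value would corrupt the binary label
and make the search lie.  All amplitudes are real and non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import CapacityError, EmptyChainError, RangeViolationError

#: Default ceiling on register width for amplitude states (2 qubits per site).
DEFAULT_QUBIT_BUDGET = 20


@dataclass(frozen=True)
class PropertyRange:
    """Closed range of one continuous interaction property."""

    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise ValueError(
                f"property range needs minimum < maximum, got [{self.minimum}, {self.maximum}]"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.minimum + self.maximum)

    def contains(self, value: float) -> bool:
        return self.minimum <= value <= self.maximum

    def check(self, value: float, *, what: str = "value", site: Optional[int] = None) -> float:
        if not self.contains(value):
            where = f" at site {site}" if site is not None else ""
            raise RangeViolationError(
                f"{what}={value!r}{where} outside range [{self.minimum}, {self.maximum}]"
            )
        return value


@dataclass(frozen=True)
class SiteRanges:
    """The pair of ranges shared by every site of a problem instance."""

    h: PropertyRange
    hb: PropertyRange


@dataclass(frozen=True)
class InteractionSite:
    """One lattice interaction site: hydrophobic and hydrogen-bonding values."""

    h: float
    hb: float


@dataclass(frozen=True)
class MoleculeChain:
    """Ordered sequence of interaction sites representing a protein or ligand."""

    sites: Tuple[InteractionSite, ...]
    role: str = "protein"  # "protein" | "ligand"

    def __post_init__(self) -> None:
        if len(self.sites) == 0:
            raise EmptyChainError(f"{self.role} chain has no interaction sites")
        if self.role not in ("protein", "ligand"):
            raise ValueError(f"role must be 'protein' or 'ligand', got {self.role!r}")
        object.__setattr__(self, "sites", tuple(self.sites))

    def __len__(self) -> int:
        return len(self.sites)

    def slice(self, start: int, n_sites: int) -> "MoleculeChain":
        """Contiguous sub-chain of ``n_sites`` sites starting at ``start``."""
        if start < 0 or start + n_sites > len(self.sites):
            raise IndexError(f"slice [{start}, {start + n_sites}) outside chain of {len(self)}")
        return MoleculeChain(self.sites[start : start + n_sites], role=self.role)


def map_value_to_bit(value: float, rng: PropertyRange, *, site: Optional[int] = None) -> int:
    """Threshold one property value at its range midpoint.

    The midpoint belongs to the upper, closed interval: ``[min, mid) -> 0``
    and ``[mid, max] -> 1``.
    """
    rng.check(value, site=site)
    return 1 if value >= rng.midpoint else 0


def encode_site_binary(
    site: InteractionSite, ranges: SiteRanges, *, index: Optional[int] = None
) -> str:
    """Two-bit label of one site: hydrophobic bit then hydrogen-bonding bit."""
    ranges.h.check(site.h, what="h", site=index)
    ranges.hb.check(site.hb, what="hb", site=index)
    return f"{map_value_to_bit(site.h, ranges.h)}{map_value_to_bit(site.hb, ranges.hb)}"


def encode_chain_binary(chain: MoleculeChain, ranges: SiteRanges) -> str:
    """Concatenated per-site labels, first site leftmost; length = 2 x sites."""
    return "".join(
        encode_site_binary(site, ranges, index=i) for i, site in enumerate(chain.sites)
    )


def amplitude_pair(value: float, rng: PropertyRange, *, site: Optional[int] = None) -> Tuple[float, float]:
    """Amplitudes (alpha, beta) of one property qubit alpha|0> + beta|1>.

    Endpoint-interpolating: value at ``min`` gives (1, 0), at ``max`` gives
    (0, 1), and beta grows strictly monotonically in between.  Always unit
    norm; both amplitudes non-negative.
    """
    rng.check(value, site=site)
    up = rng.maximum - value
    down = value - rng.minimum
    denom = math.hypot(up, down)
    # denom = 0 would need value == min == max, excluded by min < max
    return up / denom, down / denom


def encode_site_amplitude(
    site: InteractionSite, ranges: SiteRanges, *, index: Optional[int] = None
) -> np.ndarray:
    """Four real amplitudes (ac, ad, bc, bd) over basis order 00, 01, 10, 11."""
    a, b = amplitude_pair(site.h, ranges.h, site=index)
    c, d = amplitude_pair(site.hb, ranges.hb, site=index)
    return np.array([a * c, a * d, b * c, b * d])


def encode_chain_amplitude(
    chain: MoleculeChain,
    ranges: SiteRanges,
    *,
    qubit_budget: int = DEFAULT_QUBIT_BUDGET,
) -> np.ndarray:
    """Tensor product of per-site amplitude states; 2 qubits per site, big-endian.

    The first site occupies the leftmost (most significant) bits of the basis
    index.  Raises :class:`CapacityError` when the chain would need more than
    ``qubit_budget`` qubits.
    """
    n_qubits = 2 * len(chain)
    if n_qubits > qubit_budget:
        raise CapacityError(
            f"{len(chain)}-site chain needs {n_qubits} qubits, budget is {qubit_budget}"
        )
    state = np.ones(1)
    for i, site in enumerate(chain.sites):
        state = np.kron(state, encode_site_amplitude(site, ranges, index=i))
    return state


def chain_values(chain: MoleculeChain) -> np.ndarray:
    """Raw (h, hb) values as a flat vector, site-major order."""
    return np.array([v for s in chain.sites for v in (s.h, s.hb)])
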