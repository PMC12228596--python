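"""Seeded synthetic interaction chains with planted docking sites.

Everything the pipeline consumes can be generated here, reproducibly: random
chains whose (h, hb) values are uniform within their ranges, proteins with a
ligand copy planted at a chosen offset (exactly, or only at the binary-label
level), proteins guaranteed to contain no match, and continuous realizations
of printed bitstring instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .encoding import (
    InteractionSite,
    MoleculeChain,
    PropertyRange,
    SiteRanges,
    encode_chain_binary,
    map_value_to_bit,
)
from .errors import FixtureError, SizeError

#: Default ranges for generated instances.  The lattice model treats the two
#: interaction strengths as abstract bounded reals; the unit interval is the
#: canonical choice when no physical scale is given.
DEFAULT_RANGES = SiteRanges(h=PropertyRange(0.0, 1.0), hb=PropertyRange(0.0, 1.0))


@dataclass(frozen=True)
class PlantSpec:
    """Where and how to plant a ligand copy into a protein.

    ``exact-continuous`` copies the ligand's continuous values verbatim
    (distance 0 to the ligand).  ``exact-binary`` draws values that land in
    the same midpoint half-intervals as the ligand's — identical binary
    label, different continuous values; ``jitter`` > 0 bounds how far each
    drawn value may sit from the ligand's (it must stay inside the label's
    half-interval), while ``jitter`` = 0 draws freely within the
    half-interval.
    """

    offset: int
    mode: str = "exact-binary"  # "exact-binary" | "exact-continuous"
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("plant offset must be >= 0")
        if self.mode not in ("exact-binary", "exact-continuous"):
            raise ValueError(f"unknown plant mode {self.mode!r}")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def random_chain(
    n_sites: int,
    ranges: SiteRanges = DEFAULT_RANGES,
    seed=None,
    *,
    role: str = "protein",
) -> MoleculeChain:
    """Chain of ``n_sites`` sites with values uniform within their ranges."""
    if n_sites < 1:
        raise SizeError("chain needs at least one site")
    rng = np.random.default_rng(seed)
    hs = rng.uniform(ranges.h.minimum, ranges.h.maximum, n_sites)
    hbs = rng.uniform(ranges.hb.minimum, ranges.hb.maximum, n_sites)
    return MoleculeChain(
        tuple(InteractionSite(float(h), float(hb)) for h, hb in zip(hs, hbs)), role=role
    )


def _half_interval(value: float, rng: PropertyRange) -> tuple[float, float]:
    """The half-interval of ``value`` under the midpoint binary rule."""
    mid = rng.midpoint
    if value >= mid:
        return mid, rng.maximum
    return rng.minimum, mid


def _draw_same_bit(value: float, prop: PropertyRange, jitter: float, rng) -> float:
    lo, hi = _half_interval(value, prop)
    if jitter == 0.0:
        return float(rng.uniform(lo, hi))
    new = value + float(rng.uniform(-jitter, jitter))
    if not (lo <= new <= hi) or map_value_to_bit(new, prop) != map_value_to_bit(value, prop):
        raise FixtureError(
            f"jitter {jitter} pushed value {value} to {new}, across the "
            f"half-interval [{lo}, {hi}]"
        )
    return new


def plant_site(
    protein: MoleculeChain,
    ligand: MoleculeChain,
    spec: PlantSpec,
    ranges: SiteRanges = DEFAULT_RANGES,
    seed=None,
) -> MoleculeChain:
    """Return a copy of ``protein`` with the ligand planted at ``spec.offset``."""
    L = len(ligand)
    if spec.offset + L > len(protein):
        raise SizeError(
            f"plant at offset {spec.offset} of a {L}-site ligand overruns a "
            f"{len(protein)}-site protein"
        )
    rng = np.random.default_rng(seed)
    sites = list(protein.sites)
    for i, lig_site in enumerate(ligand.sites):
        if spec.mode == "exact-continuous":
            new = InteractionSite(lig_site.h, lig_site.hb)
        else:
            new = InteractionSite(
                _draw_same_bit(lig_site.h, ranges.h, spec.jitter, rng),
                _draw_same_bit(lig_site.hb, ranges.hb, spec.jitter, rng),
            )
        sites[spec.offset + i] = new
    return MoleculeChain(tuple(sites), role=protein.role)


def chain_from_label(
    bits: str,
    ranges: SiteRanges = DEFAULT_RANGES,
    seed=None,
    *,
    role: str = "protein",
) -> MoleculeChain:
    """A continuous chain whose binary encoding equals a printed bitstring.

    Per bit, a value is drawn uniformly in the matching midpoint
    half-interval, so the chain realizes the label while carrying generic
    continuous values.
    """
    if len(bits) % 2:
        raise SizeError("label length must be even (2 bits per site)")
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(0, len(bits), 2):
        vals = []
        for bit, prop in ((bits[i], ranges.h), (bits[i + 1], ranges.hb)):
            lo, hi = (
                (prop.midpoint, prop.maximum) if bit == "1" else (prop.minimum, prop.midpoint)
            )
            vals.append(float(rng.uniform(lo, hi)))
        sites.append(InteractionSite(vals[0], vals[1]))
    chain = MoleculeChain(tuple(sites), role=role)
    assert encode_chain_binary(chain, ranges) == bits
    return chain


def scan_label_matches(protein_label: str, ligand_label: str) -> list[int]:
    """Classical scan: site offsets where a ligand-sized slice equals the label."""
    L = len(ligand_label) // 2
    P = len(protein_label) // 2
    return [
        off
        for off in range(P - L + 1)
        if protein_label[2 * off : 2 * off + 2 * L] == ligand_label
    ]


def random_negative_protein(
    n_sites: int,
    ligand: MoleculeChain,
    ranges: SiteRanges = DEFAULT_RANGES,
    seed=None,
    *,
    max_tries: int = 10_000,
) -> MoleculeChain:
    """Rejection-sample a protein with NO slice matching the ligand's label."""
    lig_label = encode_chain_binary(ligand, ranges)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        cand = random_chain(n_sites, ranges, rng)
        if not scan_label_matches(encode_chain_binary(cand, ranges), lig_label):
            return cand
    raise FixtureError(
        f"no {n_sites}-site protein avoiding label {lig_label} in {max_tries} tries"
    )


# Reference worked-instance bitstrings realized as continuous chains.
EXAMPLE_SEARCH_PROTEIN = "1111110110001111"   # 8 sites, ligand 1111
EXAMPLE_SEARCH_LIGAND = "1111"
EXAMPLE_DEVICE_PROTEIN = "010011001111000110100011"  # 12 sites, ligand 1100
EXAMPLE_DEVICE_LIGAND = "1100"


def fixture_suite(
    outdir, ranges: SiteRanges = DEFAULT_RANGES, seed: int = 0
) -> dict[str, Path]:
    """Write the worked-example and randomized fixtures as chain CSVs.

    Includes the two reference bitstring instances realized as continuous
    chains, the three benchmark problem shapes (4/1, 10/2 and 27/3 sites,
    random values), a planted-site instance and a guaranteed-negative
    instance.  Returns a name -> path mapping.
    """
    from .io import write_chain_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.spawn(16))
    paths: dict[str, Path] = {}

    def _write(name: str, chain: MoleculeChain) -> None:
        path = outdir / f"{name}.csv"
        write_chain_csv(chain, path)
        paths[name] = path

    _write(
        "search_example_protein",
        chain_from_label(EXAMPLE_SEARCH_PROTEIN, ranges, next(seeds)),
    )
    _write(
        "search_example_ligand",
        chain_from_label(EXAMPLE_SEARCH_LIGAND, ranges, next(seeds), role="ligand"),
    )
    _write(
        "device_example_protein",
        chain_from_label(EXAMPLE_DEVICE_PROTEIN, ranges, next(seeds)),
    )
    _write(
        "device_example_ligand",
        chain_from_label(EXAMPLE_DEVICE_LIGAND, ranges, next(seeds), role="ligand"),
    )
    for name, n_p, n_l in (
        ("shape_small", 4, 1),
        ("shape_medium", 10, 2),
        ("shape_large", 27, 3),
    ):
        _write(f"{name}_protein", random_chain(n_p, ranges, next(seeds)))
        _write(f"{name}_ligand", random_chain(n_l, ranges, next(seeds), role="ligand"))
    lig = random_chain(2, ranges, next(seeds), role="ligand")
    prot = random_chain(10, ranges, next(seeds))
    planted = plant_site(prot, lig, PlantSpec(offset=4, mode="exact-continuous"), ranges)
    _write("planted_ligand", lig)
    _write("planted_protein", planted)
    _write("negative_protein", random_negative_protein(10, lig, ranges, next(seeds)))
    _write("negative_ligand", lig)
    return paths
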