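"""Protein segmentation, shift and the bisection search controller.

The protein's binary label is chopped into consecutive ligand-sized windows;
the distinct window labels (keeping each label's *last* occurrence) form the
search superposition |s>.  A presence test on |s> says whether the ligand
label occurs anywhere in the windowed range; if it does, the range is
bisected and both halves are searched recursively until single windows
localize the hits.  Because windows are aligned to the ligand size, the
whole procedure is repeated for shift offsets 0 .. L-1 (L = ligand sites),
each shift dropping the leading sites so that every contiguous run of L
sites eventually lines up with a window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from . import grover
from .encoding import MoleculeChain, SiteRanges, encode_chain_binary
from .errors import SizeError
from .model import (
    DockingCandidate,
    NodeRecord,
    SearchResult,
    SearchTrace,
    ShiftSkipRecord,
    SuperpositionState,
    TruncationRecord,
    validate_label,
)


@dataclass(frozen=True)
class WindowSet:
    """Consecutive, non-overlapping ligand-sized windows of a protein label.

    ``windows`` holds ``(start_site_offset, label)`` pairs; offsets are site
    indices relative to the (possibly shifted) chain the label came from.
    ``dropped_bits`` is the trailing remainder too short to fill a window.
    """

    window_bits: int
    windows: Tuple[Tuple[int, str], ...]
    dropped_bits: int = 0

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(lab for _, lab in self.windows)

    def __len__(self) -> int:
        return len(self.windows)


def segment_windows(protein_label: str, ligand_sites: int) -> WindowSet:
    """Chop a protein label left-to-right into 2*ligand_sites-bit windows.

    A trailing remainder shorter than one window is dropped (the lattice
    model has no partial sites) and reported via ``dropped_bits``.
    """
    validate_label(protein_label)
    if ligand_sites < 1:
        raise SizeError("ligand must have at least one site")
    wbits = 2 * ligand_sites
    if len(protein_label) < wbits:
        raise SizeError(
            f"protein label of {len(protein_label)} bits shorter than one "
            f"{wbits}-bit window"
        )
    n_windows = len(protein_label) // wbits
    windows = tuple(
        (w * ligand_sites, protein_label[w * wbits : (w + 1) * wbits])
        for w in range(n_windows)
    )
    return WindowSet(wbits, windows, dropped_bits=len(protein_label) - n_windows * wbits)


def unique_latest(labels: Sequence[str]) -> list[str]:
    """Distinct labels ordered by their LAST occurrence.

    A repeated window label adds nothing to a presence question, so only the
    latest occurrence of each label enters the superposition.
    """
    if not labels:
        raise ValueError("no window labels to deduplicate")
    last = {}
    for pos, lab in enumerate(labels):
        last[lab] = pos  # later occurrence overwrites
    return [lab for lab, _ in sorted(last.items(), key=lambda kv: kv[1])]


def build_superposition(basis: Sequence[str]) -> SuperpositionState:
    """Uniform superposition (amplitude 1/sqrt(N)) over distinct labels."""
    return SuperpositionState(tuple(basis))


def shift_chain(protein: MoleculeChain, offset: int) -> MoleculeChain:
    """Drop the first ``offset`` sites, realigning windows to a new origin.

    Downstream results must add ``offset`` back so candidate positions refer
    to the original protein.
    """
    if offset < 0:
        raise SizeError("shift offset must be non-negative")
    if offset >= len(protein):
        raise SizeError(f"shift {offset} >= protein length {len(protein)}")
    if offset == 0:
        return protein
    return MoleculeChain(protein.sites[offset:], role=protein.role)


def bisect_windows(n_windows: int) -> Tuple[int, int]:
    """Split a window range into (ceil(w/2), floor(w/2)) on a window boundary."""
    if n_windows < 2:
        raise SizeError("cannot bisect a single-window range")
    left = math.ceil(n_windows / 2)
    return left, n_windows - left


def locate_docking_sites(
    protein: MoleculeChain,
    ligand: MoleculeChain,
    ranges: SiteRanges,
    config=None,
) -> SearchResult:
    """Run the full shift + segmentation + bisection search.

    For every shift offset 0 .. L-1 the shifted protein is binary-encoded,
    windowed, and searched recursively: each node builds the unique-latest
    superposition over its window range and asks whether the ligand label is
    present (deterministically when only one distinct label remains, via the
    Grover presence test otherwise).  Present multi-window ranges are
    bisected and BOTH halves explored — a present parent does not say which
    half holds the match, and there may be several.  Absent ranges are
    pruned.  Candidates are deduplicated by start offset and sorted; every
    decision lands in the trace.
    """
    from .io import RunConfig  # local import to avoid a cycle

    cfg = config if config is not None else RunConfig(ranges=ranges)
    L = len(ligand)
    if L > len(protein):
        raise SizeError(f"ligand of {L} sites longer than protein of {len(protein)}")
    ligand_label = encode_chain_binary(ligand, ranges)
    trace = SearchTrace()
    found: dict[int, DockingCandidate] = {}
    # one independent, reproducible seed stream per run for the sampler
    seed_counter = [0]

    def _next_seed():
        if cfg.backend != "sampling":
            return None
        seed_counter[0] += 1
        return [0 if cfg.seed is None else cfg.seed, seed_counter[0]]

    def _search(shift: int, windows: Sequence[Tuple[int, str]]) -> None:
        labels = [lab for _, lab in windows]
        basis = unique_latest(labels)
        n_unique = len(basis)
        offsets = tuple(off for off, _ in windows)
        if n_unique == 1:
            p = 1.0 if basis[0] == ligand_label else 0.0
            present = basis[0] == ligand_label
            trace.add(
                NodeRecord(shift, offsets, 1, "deterministic", 0, p, 1.0, present)
            )
        else:
            s = build_superposition(basis)
            k = cfg.iterations if isinstance(cfg.iterations, int) else grover.choose_iterations(n_unique)
            dist = grover.run_grover(
                s,
                ligand_label,
                k,
                backend=cfg.backend,
                shots=cfg.shots,
                seed=_next_seed(),
                diffusion=cfg.diffusion,
                qubit_budget=cfg.qubit_budget,
            )
            decision = grover.decide_presence(dist, ligand_label, n_unique, iterations_used=k)
            present = decision.present
            trace.add(
                NodeRecord(
                    shift,
                    offsets,
                    n_unique,
                    "grover",
                    k,
                    decision.p_target,
                    decision.threshold,
                    present,
                )
            )
        if not present:
            return
        if len(windows) == 1:
            off, lab = windows[0]
            rec = trace.nodes()[-1]
            found.setdefault(
                off,
                DockingCandidate(
                    start_offset=off,
                    label=lab,
                    probability=rec.p_target,
                    threshold=rec.threshold,
                ),
            )
            return
        left, _right = bisect_windows(len(windows))
        _search(shift, windows[:left])
        _search(shift, windows[left:])

    for shift in range(L):
        if len(protein) - shift < L:
            trace.add(ShiftSkipRecord(shift, "remaining protein shorter than one window"))
            continue
        shifted = shift_chain(protein, shift)
        label = encode_chain_binary(shifted, ranges)
        ws = segment_windows(label, L)
        if ws.dropped_bits:
            first_dropped = shift + len(ws) * L
            trace.add(
                TruncationRecord(shift, tuple(range(first_dropped, len(protein))))
            )
        # report offsets relative to the ORIGINAL protein
        windows = tuple((shift + off, lab) for off, lab in ws.windows)
        _search(shift, windows)

    candidates = [found[off] for off in sorted(found)]
    return SearchResult(candidates=candidates, trace=trace)
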