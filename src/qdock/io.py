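"""File formats and run configuration: chain CSV, YAML/JSON config, JSON report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .encoding import (
    DEFAULT_QUBIT_BUDGET,
    InteractionSite,
    MoleculeChain,
    PropertyRange,
    SiteRanges,
)
from .errors import ChainFormatError, ConfigError
from .model import SearchResult

_CHAIN_COLUMNS = ["index", "h", "hb"]


def read_chain_csv(path, *, role: str = "protein") -> MoleculeChain:
    """Read a chain CSV with header ``index,h,hb`` and contiguous 0-based indices.

    Malformed files raise :class:`ChainFormatError` naming the offending
    line (line 1 is the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ChainFormatError(f"{path}: unreadable CSV ({exc})") from exc
    if list(df.columns) != _CHAIN_COLUMNS:
        raise ChainFormatError(
            f"{path}:1: header must be exactly 'index,h,hb', got {','.join(df.columns)}"
        )
    if len(df) == 0:
        raise ChainFormatError(f"{path}: no interaction sites")
    sites = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            idx = int(row["index"])
        except (TypeError, ValueError):
            raise ChainFormatError(f"{path}:{row_no}: non-integer index {row['index']!r}")
        expected = row_no - 2
        if idx != expected:
            raise ChainFormatError(
                f"{path}:{row_no}: index {idx} breaks contiguity, expected {expected}"
            )
        try:
            h = float(row["h"])
            hb = float(row["hb"])
        except (TypeError, ValueError):
            raise ChainFormatError(
                f"{path}:{row_no}: non-numeric cell (h={row['h']!r}, hb={row['hb']!r})"
            )
        sites.append(InteractionSite(h, hb))
    return MoleculeChain(tuple(sites), role=role)


def write_chain_csv(chain: MoleculeChain, path) -> Path:
    """Write a chain CSV; floats use shortest round-trip repr (lossless)."""
    path = Path(path)
    lines = ["index,h,hb"]
    lines += [f"{i},{s.h!r},{s.hb!r}" for i, s in enumerate(chain.sites)]
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs besides the two chains.

    ``iterations`` is ``"auto"`` (optimal for one marked state) or a fixed
    positive integer override; ``diffusion`` selects the explicit-unitary or
    the ancilla amplitude-amplification implementation.
    """

    ranges: SiteRanges = field(
        default_factory=lambda: SiteRanges(PropertyRange(0.0, 1.0), PropertyRange(0.0, 1.0))
    )
    backend: str = "exact"
    shots: int = 8192
    seed: Optional[int] = None
    iterations: Union[str, int] = "auto"
    diffusion: str = "matrix"
    qubit_budget: int = DEFAULT_QUBIT_BUDGET

    def __post_init__(self) -> None:
        if self.backend not in ("exact", "sampling"):
            raise ConfigError(f"backend must be 'exact' or 'sampling', got {self.backend!r}")
        if self.backend == "sampling" and (not isinstance(self.shots, int) or self.shots < 1):
            raise ConfigError("sampling backend needs shots >= 1")
        if self.iterations != "auto" and (
            not isinstance(self.iterations, int) or self.iterations < 1
        ):
            raise ConfigError("iterations must be 'auto' or a positive integer")
        if self.diffusion not in ("matrix", "ancilla"):
            raise ConfigError(f"diffusion must be 'matrix' or 'ancilla', got {self.diffusion!r}")
        if self.qubit_budget < 2:
            raise ConfigError("qubit budget must be at least 2")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        rng_block = data.pop("ranges", None)
        if rng_block is not None:
            try:
                ranges = SiteRanges(
                    h=PropertyRange(float(rng_block["h"]["min"]), float(rng_block["h"]["max"])),
                    hb=PropertyRange(
                        float(rng_block["hb"]["min"]), float(rng_block["hb"]["max"])
                    ),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"malformed ranges block: {rng_block!r}") from exc
        else:
            ranges = SiteRanges(PropertyRange(0.0, 1.0), PropertyRange(0.0, 1.0))
        known = {"backend", "shots", "seed", "iterations", "diffusion", "qubit_budget"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(ranges=ranges, **data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "ranges": {
                "h": {"min": self.ranges.h.minimum, "max": self.ranges.h.maximum},
                "hb": {"min": self.ranges.hb.minimum, "max": self.ranges.hb.maximum},
            },
            "backend": self.backend,
            "shots": self.shots,
            "seed": self.seed,
            "iterations": self.iterations,
            "diffusion": self.diffusion,
            "qubit_budget": self.qubit_budget,
        }


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_report(
    result: SearchResult,
    *,
    config: RunConfig,
    protein_path=None,
    ligand_path=None,
    ranked=None,
) -> dict:
    """Machine-readable docking report; byte-stable for a fixed exact-backend run."""
    nodes = result.trace.nodes()
    warnings = []
    truncated = result.trace.truncations()
    if truncated:
        warnings.append(
            {
                "kind": "truncated_windows",
                "detail": [t.to_dict() for t in truncated],
            }
        )
    cands = ranked if ranked is not None else result.candidates
    for c in cands:
        if c.clamped:
            warnings.append(
                {"kind": "clamped_distance", "start_offset": c.start_offset}
            )
    return {
        "inputs": {
            "protein_sha256": _sha256(protein_path) if protein_path else None,
            "ligand_sha256": _sha256(ligand_path) if ligand_path else None,
            "config": config.to_dict(),
        },
        "trace_summary": {
            "decisions": len(nodes),
            "grover_calls": sum(1 for n in nodes if n.path == "grover"),
            "deterministic_checks": sum(1 for n in nodes if n.path == "deterministic"),
        },
        "trace": result.trace.to_dict(),
        "candidates": [c.to_dict() for c in cands],
        "warnings": warnings,
    }


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
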