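"""Fluorescence-fraction to copy-number conversions (formulas 5-6).

Bound fractions become absolute complexes per replication fork through the
HeLa proteome copy numbers (~2.6 million PCNA molecules in ~865,300
homotrimers; 926,424 RPA1 molecules, one per RPA heterotrimer) and the
~4000 forks simultaneously active in mid S-phase.  Each RPA heterotrimer
covers ~30 nt of ssDNA, converting RPA complexes per fork into an ssDNA
length per fork.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StoichiometryConstants",
    "HELA",
    "complexes_per_fork",
    "ssdna_per_fork",
    "residual_complexes",
    "unwinding_rate",
]


@dataclass(frozen=True)
class StoichiometryConstants:
    """Proteome copy numbers and fork count for one cell line."""

    pcna_molecules: int = 2_600_000
    pcna_homotrimers: int = 865_300
    rpa_heterotrimers: int = 926_424
    active_forks: int = 4_000
    rpa_footprint_nt: float = 30.0
    cell_line: str = "HeLa"

    def __post_init__(self) -> None:
        for name in ("pcna_molecules", "pcna_homotrimers", "rpa_heterotrimers", "active_forks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rpa_footprint_nt <= 0:
            raise ValueError("rpa_footprint_nt must be positive")
        if abs(self.pcna_homotrimers - self.pcna_molecules / 3) > 0.01 * self.pcna_homotrimers:
            raise ValueError("homotrimer count should be ~1/3 of PCNA molecules")

    def complexes(self, species: str) -> int:
        """Number of complexes in the nucleus for ``species`` (pcna | rpa)."""
        key = species.lower()
        if key in ("pcna", "pcna_homotrimer"):
            return self.pcna_homotrimers
        if key in ("rpa", "rpa1", "rpa_heterotrimer"):
            return self.rpa_heterotrimers
        raise ValueError(f"unknown species {species!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StoichiometryConstants":
        return cls(**json.loads(Path(path).read_text()))


HELA = StoichiometryConstants()


def complexes_per_fork(fraction, constants: StoichiometryConstants = HELA, species: str = "rpa"):
    """Formula (5): G_t = F_t x N_complexes / N_forks, elementwise.

    ``fraction`` is the formula-(4) bound fraction (scalar or array);
    slightly negative noise values (> -0.05) are tolerated and propagate.
    An SD trace scales by the same constant (first-order propagation).
    """
    f = np.asarray(fraction, dtype=float)
    if np.any(f < -0.05) or np.any(f > 1.0 + 1e-9):
        raise ValueError("bound fraction outside [-0.05, 1]")
    g = f * constants.complexes(species) / constants.active_forks
    return g if np.ndim(fraction) else float(g)


def ssdna_per_fork(g_t, constants: StoichiometryConstants = HELA):
    """Formula (6): H_t = G_t x footprint (nt of ssDNA per fork)."""
    h = np.asarray(g_t, dtype=float) * constants.rpa_footprint_nt
    return h if np.ndim(g_t) else float(h)


def residual_complexes(pre_level: float, residual_fraction: float) -> float:
    """Complexes remaining after treatment, reported at one decimal."""
    if not 0.0 <= residual_fraction <= 1.0:
        raise ValueError("residual_fraction must be in [0, 1]")
    return round(pre_level * residual_fraction, 1)


def unwinding_rate(ssdna_rate_nt_per_min: float, strands: int = 2) -> float:
    """Convert an ssDNA generation rate (nt/min) to an unwinding rate (per s).

    With ssDNA accumulating on both strands (``strands=2``) the duplex is
    unwound at half the per-nucleotide rate, in bp/s; ``strands=1`` simply
    converts nt/min to nt/s.
    """
    if strands not in (1, 2):
        raise ValueError("strands must be 1 or 2")
    return ssdna_rate_nt_per_min / 60.0 / strands
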