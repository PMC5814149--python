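"""Explicit microtubule populations in radial coordinates.

Positions are distances from the structure center (effective 1D geometry);
every filament points outward, so its minus end is at ``minus_pos`` and its
plus end at ``minus_pos + length``.  2D embedding (assigning an angle to each
filament) happens only at rendering time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FilamentSet", "count_severed_minus_ends"]


@dataclass
class FilamentSet:
    """Microtubules as radial segments.

    ``minus_pos`` (µm), ``length`` (µm) and ``birth_time`` (s) are parallel
    arrays; polarity is fixed outward.
    """

    minus_pos: np.ndarray
    length: np.ndarray
    birth_time: np.ndarray | None = None
    angles: np.ndarray | None = field(default=None)  # rad, set when embedded in 2D

    def __post_init__(self) -> None:
        self.minus_pos = np.asarray(self.minus_pos, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        if self.birth_time is None:
            self.birth_time = np.zeros_like(self.minus_pos)
        else:
            self.birth_time = np.asarray(self.birth_time, dtype=float)
        if self.angles is not None:
            self.angles = np.asarray(self.angles, dtype=float)
        if not (self.minus_pos.shape == self.length.shape == self.birth_time.shape):
            raise ValueError("minus_pos, length and birth_time must have equal length")
        if np.any(self.length < 0):
            raise ValueError("filament lengths must be non-negative")
        if np.any(self.minus_pos < 0):
            raise ValueError("minus-end positions must be non-negative")

    def __len__(self) -> int:
        return len(self.minus_pos)

    @property
    def plus_pos(self) -> np.ndarray:
        return self.minus_pos + self.length

    @property
    def total_length(self) -> float:
        return float(self.length.sum())

    def spanning(self, r: float) -> np.ndarray:
        """Boolean mask of filaments whose lattice crosses radius r."""
        return (self.minus_pos < r) & (self.plus_pos > r)

    def coverage(self, bin_edges: np.ndarray) -> np.ndarray:
        """Polymer length per unit length (dimensionless coverage) per bin."""
        bin_edges = np.asarray(bin_edges, dtype=float)
        lo = np.clip(self.minus_pos[:, None], bin_edges[:-1], bin_edges[1:])
        hi = np.clip(self.plus_pos[:, None], bin_edges[:-1], bin_edges[1:])
        return (hi - lo).sum(axis=0) / np.diff(bin_edges)

    def subset(self, mask: np.ndarray) -> "FilamentSet":
        return FilamentSet(
            minus_pos=self.minus_pos[mask],
            length=self.length[mask],
            birth_time=self.birth_time[mask],
            angles=None if self.angles is None else self.angles[mask],
        )


def count_severed_minus_ends(
    filaments: FilamentSet, r: float, bin_edges: np.ndarray
) -> np.ndarray:
    """Ground-truth minus-end counts for a cut at radius r.

    Counts, per radial bin below the cut, the minus ends of filaments that
    span r (the filaments a circular cut at r actually severs).  This is the
    direct-bookkeeping quantity the ablation pipeline estimates from the
    depolymerization-wave areas.
    """
    sel = filaments.spanning(r)
    counts, _ = np.histogram(filaments.minus_pos[sel], bins=np.asarray(bin_edges, float))
    return counts.astype(float)
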