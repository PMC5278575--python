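"""Shared domain types for bead-chain genome models.

Coordinates at genome scale are in micrometres (the model nucleus has a
radius of a few μm, so positions stay O(1)); locus-scale models use
nanometres throughout.  Genomic intervals are 0-based half-open, following
the BED convention.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "ContactRecord",
    "Bead",
    "NucleusGeometry",
    "ConstraintKind",
    "Constraint",
    "AnnealSchedule",
    "StructureEnsemble",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class ContactRecord:
    """One sparse Hi-C bin pair; bins are identified by their start coordinate.

    Records are kept in canonical order: ``(chromA, binA) <= (chromB, binB)``
    lexicographically.
    """

    chromA: str
    binA: int
    chromB: str
    binB: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative contact count {self.count}")

    @classmethod
    def make(cls, chromA: str, binA: int, chromB: str, binB: int, count: int) -> "ContactRecord":
        """Build a record with endpoints put in canonical order."""
        if (chromA, binA) > (chromB, binB):
            chromA, binA, chromB, binB = chromB, binB, chromA, binA
        return cls(chromA, binA, chromB, binB, count)

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.chromA, self.binA, self.chromB, self.binB)

    @property
    def is_intra(self) -> bool:
        return self.chromA == self.chromB


@dataclass
class Bead:
    """One modeled chromatin domain: a genomic interval with a radius,
    homolog tag and lamin-association flag."""

    bead_id: int
    interval: GenomicInterval
    homolog: str = "A"
    radius: float = 1.0
    lamin: bool = False

    def __post_init__(self) -> None:
        if self.homolog not in ("A", "B"):
            raise ValueError(f"homolog must be 'A' or 'B', got {self.homolog!r}")
        if self.radius <= 0:
            raise ValueError(f"bead radius must be positive, got {self.radius}")

    def with_radius(self, radius: float) -> "Bead":
        return replace(self, radius=radius)


@dataclass(frozen=True)
class NucleusGeometry:
    """Spherical model nucleus: radius (μm) and the fraction of its volume
    occupied by beads."""

    radius: float = 5.0
    occupancy: float = 0.15

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("nucleus radius must be positive")
        if not 0 < self.occupancy < 1:
            raise ValueError("occupancy must lie strictly between 0 and 1")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


class ConstraintKind(enum.Enum):
    PAIR_ATTRACT = "pair_attract"
    PAIR_LOWER_BOUND = "pair_lower_bound"
    PERIPHERY = "periphery"
    CENTER = "center"


@dataclass(frozen=True)
class Constraint:
    """A typed harmonic restraint contributing k·f(‖Δ‖ − d)² to the loss.

    Radial kinds (periphery, center) measure the distance of bead ``i`` to a
    zero-radius dummy bead at the nucleus center; ``j`` is −1 for those.
    """

    kind: ConstraintKind
    i: int
    j: int
    target: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.target < 0:
            raise ValueError("target distance must be non-negative")
        if self.weight < 0:
            raise ValueError("constraint weight must be non-negative")


#: move kinds in the order used by AnnealSchedule.move_weights
MOVE_KINDS = (
    "chain_translate",
    "chain_rotate",
    "crankshaft",
    "arm_pivot",
    "bead_hinge",
)


@dataclass
class AnnealSchedule:
    """Simulated-annealing run parameters.

    ``t0=None`` auto-selects the initial temperature as the initial loss
    divided by the bead count.  Cooling is geometric:
    ``T <- T * (1 - cooling_rate)`` each iteration.  ``move_weights`` orders
    the five move kinds as in :data:`MOVE_KINDS`; equal weights by default.
    """

    iterations: int = 2_000_000
    t0: float | None = None
    cooling_rate: float = 1e-5
    seed: int = 0
    move_weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    trace_stride: int = 1000
    max_step: float = 0.5
    max_angle: float = np.pi / 2
    max_segment: int = 20

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.cooling_rate < 1:
            raise ValueError("cooling_rate must be in (0, 1)")
        w = np.asarray(self.move_weights, dtype=float)
        if w.shape != (5,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("move_weights must be 5 non-negative reals with positive sum")


@dataclass
class StructureEnsemble:
    """N independently optimized coordinate sets over one shared bead list."""

    beads: list[Bead]
    members: list[np.ndarray] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    geometry: NucleusGeometry | None = None

    def __post_init__(self) -> None:
        n = len(self.beads)
        for m in self.members:
            if m.shape != (n, 3):
                raise ValueError(f"member shape {m.shape} does not match {n} beads")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads])

    def stacked(self) -> np.ndarray:
        """Coordinates as one (n_members, n_beads, 3) array."""
        return np.stack(self.members)
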