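"""Size-class binning, size distributions and prey-spectrum composition.

All distributions in the pipeline share one binning scheme: 4-mm shell
length classes from 17–21 up to 57–61 mm, eleven classes in total. Classes
are half-open ``[lo, lo + w)`` so every size maps to exactly one class; the
shared-edge convention is lower-inclusive and the grid is configurable so
the alternative can be examined.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import SizeRangeError
from .events import EventTable, PREY_GROUPS


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the reported tables).

    Python's built-in round is banker's rounding; percentage tables here
    round 0.05 up, e.g. 165/327 -> 50.5.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class SizeClassGrid:
    """Contiguous half-open 4-mm size classes, default 17–21 ... 57–61 mm."""

    lower: float = 17.0
    width: float = 4.0
    n_classes: int = 11

    def __post_init__(self) -> None:
        if self.width <= 0 or self.n_classes < 1:
            raise ValueError("grid needs positive width and at least one class")

    @property
    def upper(self) -> float:
        return self.lower + self.width * self.n_classes

    def edges(self) -> np.ndarray:
        return self.lower + self.width * np.arange(self.n_classes + 1)

    def labels(self) -> list[str]:
        e = self.edges()
        return [f"{e[i]:g}-{e[i + 1]:g}" for i in range(self.n_classes)]

    def index(self, length_mm: float) -> int:
        if not (self.lower <= length_mm < self.upper):
            raise SizeRangeError(
                f"size {length_mm} mm outside grid span [{self.lower}, {self.upper})"
            )
        return int((length_mm - self.lower) // self.width)

    def indices(self, lengths_mm: np.ndarray) -> np.ndarray:
        lengths_mm = np.asarray(lengths_mm, dtype=float)
        bad = (lengths_mm < self.lower) | (lengths_mm >= self.upper)
        if bad.any():
            raise SizeRangeError(
                f"size {lengths_mm[bad][0]} mm outside grid span "
                f"[{self.lower}, {self.upper})"
            )
        return ((lengths_mm - self.lower) // self.width).astype(int)


def size_class(length_mm: float, grid: SizeClassGrid) -> int:
    """Class index of a shell length on the grid (half-open classes)."""
    return grid.index(length_mm)


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class counts aligned to a grid."""

    counts: tuple[int, ...]
    grid: SizeClassGrid

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def class_distribution(
    table: EventTable, grid: SizeClassGrid | None = None, which: str = "predator"
) -> ClassDistribution:
    """Histogram of predator (or prey) sizes on the class grid."""
    grid = grid or SizeClassGrid()
    if which == "predator":
        sizes = table.predator_lengths
    elif which == "prey":
        sizes = table.prey_lengths
    else:
        raise ValueError(f"which must be 'predator' or 'prey', got {which!r}")
    counts = np.zeros(grid.n_classes, dtype=int)
    if len(sizes):
        np.add.at(counts, grid.indices(sizes), 1)
    return ClassDistribution(counts=tuple(int(c) for c in counts), grid=grid)


@dataclass(frozen=True)
class PreySpectrum:
    """Prey composition by group (with per-taxon breakdown) of one table."""

    group_counts: dict[str, int]
    taxon_counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.group_counts.values())

    def percentages(self) -> dict[str, float]:
        """Group percentages, 1 decimal, half away from zero.

        Always recomputed from counts; stored percentages are never the
        source of truth.
        """
        total = self.total
        if total == 0:
            return {g: 0.0 for g in self.group_counts}
        return {
            g: round_half_away(100.0 * c / total, 1)
            for g, c in self.group_counts.items()
        }

    def taxon_percentages(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {}
        return {
            t: round_half_away(100.0 * c / total, 1)
            for t, c in self.taxon_counts.items()
        }


def prey_spectrum(table: EventTable) -> PreySpectrum:
    """Composition of the prey spectrum by group and taxon."""
    groups = Counter(table.prey_groups.tolist())
    taxa = Counter(table._frame["prey_taxon"].tolist())
    return PreySpectrum(
        group_counts={g: int(groups.get(g, 0)) for g in PREY_GROUPS},
        taxon_counts={t: int(c) for t, c in sorted(taxa.items())},
    )


def spectrum_by_class(
    table: EventTable, grid: SizeClassGrid | None = None
) -> list[PreySpectrum]:
    """One prey spectrum per predator size class.

    Classes with no events get an explicit empty spectrum (total 0) rather
    than being dropped; presentation layers may omit singletons, the
    computation never does. Per-class totals always sum to the whole-table
    spectrum (conservation).
    """
    grid = grid or SizeClassGrid()
    idx = grid.indices(table.predator_lengths) if len(table) else np.array([], dtype=int)
    out: list[PreySpectrum] = []
    for c in range(grid.n_classes):
        out.append(prey_spectrum(table.subset(idx == c)))
    return out


def recovery_rate(released: int, recovered: int) -> int:
    """Percentage of released prey that resumed normal activity.

    Integer percentage, rounded half away from zero — e.g. 19 of 21
    gastropods -> 90, 11 of 14 bivalves -> 79.
    """
    if released <= 0:
        raise ValueError("released must be positive")
    if not 0 <= recovered <= released:
        raise ValueError("recovered must lie in [0, released]")
    return int(round_half_away(100.0 * recovered / released, 0))
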