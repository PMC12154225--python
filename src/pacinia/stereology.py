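"""Stereological densities and whole-structure extrapolation.

Junction counts made in a sampled extent (a length of axon, an area of
membrane, or a volume of inner core) are converted to densities and
extrapolated linearly to the whole structure, then divided among cells.
Intermediate arithmetic is kept at full precision; only the reported totals
are rounded (half away from zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class ExtentKind(str, Enum):
    """The dimensionality of a sampled extent."""

    LENGTH_UM = "length_um"
    AREA_UM2 = "area_um2"
    VOLUME_UM3 = "volume_um3"


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class DensityEstimate:
    """A count per unit of sampled extent.

    ``count`` is normally the integer number of structures identified in the
    sampled extent, but fractional counts are accepted so that a published
    density (e.g. per 1000 um^3) can be re-expressed exactly.
    """

    count: float
    sampled_extent: float
    kind: ExtentKind
    density: float

    @classmethod
    def from_count(cls, count: float, extent: float, kind: ExtentKind | str) -> "DensityEstimate":
        kind = ExtentKind(kind)
        if extent <= 0:
            raise ValueError("sampled extent must be positive")
        if count < 0:
            raise ValueError("count must be non-negative")
        return cls(count=float(count), sampled_extent=float(extent), kind=kind,
                   density=count / extent)


def density_estimate(count: float, extent: float, kind: ExtentKind | str) -> DensityEstimate:
    """Exact ratio ``count / extent`` with its extent kind carried through."""
    return DensityEstimate.from_count(count, extent, kind)


@dataclass(frozen=True)
class ExtrapolatedTotals:
    """Density scaled to a whole structure and shared among cells."""

    density: DensityEstimate
    total_extent: float
    estimated_total: float
    estimated_total_rounded: int
    n_cells: int
    per_cell: float
    per_cell_rounded: int


def extrapolate_totals(
    d: DensityEstimate,
    total_extent: float,
    kind: ExtentKind | str,
    n_cells: int = 60,
) -> ExtrapolatedTotals:
    """Scale a sampled density to the full extent and divide among cells.

    The kind of ``total_extent`` must match the density's (an areal density
    cannot be multiplied by a volume). ``n_cells`` defaults to 60, the
    conventional lamellar-cell count of one inner core.
    """
    kind = ExtentKind(kind)
    if kind is not d.kind:
        raise ValueError(f"extent kind mismatch: density is per {d.kind.value}, "
                         f"total extent is {kind.value}")
    if total_extent <= 0:
        raise ValueError("total extent must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    total = d.density * total_extent
    per_cell = total / n_cells
    return ExtrapolatedTotals(
        density=d,
        total_extent=float(total_extent),
        estimated_total=total,
        estimated_total_rounded=_round_half_away(total),
        n_cells=int(n_cells),
        per_cell=per_cell,
        per_cell_rounded=_round_half_away(per_cell),
    )
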