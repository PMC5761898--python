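"""Cell counting and percent-positive quantification within polygonal regions.

CD8 positivity in a region is expressed as ``100 * n_positive / n_total``,
where the denominator is every nucleated cell whose point location falls in
the region.  Cells are treated as dimensionless points; membership is
boundary-inclusive (a cell exactly on the region edge counts as inside).
When a region contains no cells the percent is *undefined* and returned as
``nan`` — callers decide whether to exclude such regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry


@dataclass(frozen=True)
class RegionStats:
    """Cell counts and percent positive for one region.

    ``percent_positive`` is ``nan`` when ``n_total == 0``.
    """

    n_total: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_positive < 0:
            raise ValueError("counts must be non-negative")
        if self.n_positive > self.n_total:
            raise ValueError(
                f"n_positive ({self.n_positive}) exceeds n_total ({self.n_total})"
            )

    @property
    def percent_positive(self) -> float:
        return percent_positive(self.n_total, self.n_positive)


def percent_positive(n_total: int, n_positive: int) -> float:
    """Percent of positive cells; ``nan`` for an empty region.

    Raises ``ValueError`` if counts are negative or inconsistent.
    """
    if n_total < 0 or n_positive < 0:
        raise ValueError("counts must be non-negative")
    if n_positive > n_total:
        raise ValueError(f"n_positive ({n_positive}) exceeds n_total ({n_total})")
    if n_total == 0:
        return math.nan
    return 100.0 * n_positive / n_total


def cells_in_region(
    x: np.ndarray, y: np.ndarray, region: BaseGeometry
) -> np.ndarray:
    """Boolean mask of cells inside ``region``, boundary-inclusive."""
    if region.is_empty:
        return np.zeros(np.shape(x), dtype=bool)
    if not region.is_valid:
        raise ValueError("invalid region polygon")
    # For points, intersects == closure membership, i.e. boundary-inclusive.
    return shapely.intersects_xy(region, np.asarray(x, float), np.asarray(y, float))


def count_cells(cells, region: BaseGeometry) -> tuple[int, int]:
    """Count (n_total, n_positive) cells whose location lies in ``region``.

    ``cells`` is any object with ``x_um``, ``y_um`` and ``positive`` columns
    (a :class:`~tilsampling.synthetic.CellTable` or a DataFrame in the cell
    CSV dialect).
    """
    x = np.asarray(cells["x_um"], dtype=float)
    y = np.asarray(cells["y_um"], dtype=float)
    pos = np.asarray(cells["positive"], dtype=bool)
    inside = cells_in_region(x, y, region)
    return int(inside.sum()), int((inside & pos).sum())


def region_stats(cells, region: BaseGeometry) -> RegionStats:
    """Convenience wrapper returning :class:`RegionStats` for a region."""
    n_total, n_positive = count_cells(cells, region)
    return RegionStats(n_total=n_total, n_positive=n_positive)
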