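"""Virtual core biopsies: grid tessellation of a slide ROI and core scoring.

A slide is tiled by non-overlapping axis-aligned rectangles of fixed area
(default 2 mm², square) anchored at the ROI bounding-box min corner.  Each
tile is a candidate "core".  A core is retained when its exact polygon
intersection with the ROI covers at least ``min_overlap`` mm² (default 0.7)
and at least ``min_tumor_fraction`` of the core area (default 33%).  With
the defaults the overlap filter is the operative one: 0.7 / 2.0 = 35% > 33%.

Scoring counts cells inside rect ∩ ROI.  A cell exactly on the shared edge
of two tiles is assigned to the tile with the smaller row-major index, so a
partition of the slide conserves total counts.  Retained cores that contain
no cells get an undefined percent and are dropped from downstream
resampling with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from shapely.geometry import box

from .quantify import percent_positive
from .synthetic import UM2_PER_MM2, UM_PER_MM, SlideGeometry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoreGridConfig:
    """Tiling and retention parameters for simulated core biopsies."""

    core_area: float = 2.0  # mm^2
    min_overlap: float = 0.7  # mm^2
    min_tumor_fraction: float = 0.33
    aspect: float = 1.0  # width : height
    anchor_offset: tuple[float, float] = (0.0, 0.0)  # um; robustness knob

    def __post_init__(self) -> None:
        if not (0.0 < self.min_overlap <= self.core_area):
            raise ValueError("require 0 < min_overlap <= core_area")
        if not (0.0 <= self.min_tumor_fraction <= 1.0):
            raise ValueError("min_tumor_fraction must lie in [0, 1]")
        if self.aspect <= 0:
            raise ValueError("aspect must be positive")

    @property
    def tile_width_um(self) -> float:
        return math.sqrt(self.core_area * self.aspect) * UM_PER_MM

    @property
    def tile_height_um(self) -> float:
        return math.sqrt(self.core_area / self.aspect) * UM_PER_MM


@dataclass(frozen=True)
class Core:
    """One simulated biopsy rectangle; counts filled in by scoring."""

    core_id: tuple[int, int]  # (row, col), row-major grid index
    rect: tuple[float, float, float, float]  # (x0, y0, x1, y1) um
    overlap_area: float  # mm^2 of rect ∩ ROI
    core_area: float  # mm^2
    n_cells: int | None = None
    n_positive: int | None = None

    @property
    def tumor_fraction(self) -> float:
        return self.overlap_area / self.core_area

    @property
    def percent_cd8(self) -> float:
        if self.n_cells is None:
            raise ValueError("core not yet scored")
        return percent_positive(self.n_cells, self.n_positive)


@dataclass(frozen=True)
class CoreGrid:
    """A tiling of one slide plus the retained cores."""

    geometry: SlideGeometry
    config: CoreGridConfig
    origin: tuple[float, float]  # um, grid anchor
    n_rows: int
    n_cols: int
    cores: tuple[Core, ...]


def generate_core_grid(
    geometry: SlideGeometry, config: CoreGridConfig | None = None
) -> CoreGrid:
    """Tile the ROI bounding box and keep tiles passing both area filters."""
    config = config or CoreGridConfig()
    roi = geometry.roi_union
    if not geometry.roi_polygons or roi.area <= 0:
        xmin, ymin = geometry.bounding_box[:2] if geometry.bounding_box else (0.0, 0.0)
        return CoreGrid(geometry, config, (xmin, ymin), 0, 0, ())

    xmin, ymin, xmax, ymax = geometry.bounding_box
    w, h = config.tile_width_um, config.tile_height_um
    x0 = xmin + config.anchor_offset[0]
    y0 = ymin + config.anchor_offset[1]
    if x0 > xmin or y0 > ymin:
        # shift anchor back a full tile so the grid still covers the box
        x0 -= w * math.ceil(max(0.0, x0 - xmin) / w)
        y0 -= h * math.ceil(max(0.0, y0 - ymin) / h)
    n_cols = max(1, math.ceil((xmax - x0) / w - 1e-12))
    n_rows = max(1, math.ceil((ymax - y0) / h - 1e-12))

    cores: list[Core] = []
    for r in range(n_rows):
        for c in range(n_cols):
            rect = box(x0 + c * w, y0 + r * h, x0 + (c + 1) * w, y0 + (r + 1) * h)
            overlap_mm2 = rect.intersection(roi).area / UM2_PER_MM2
            core = Core(
                core_id=(r, c),
                rect=rect.bounds,
                overlap_area=overlap_mm2,
                core_area=config.core_area,
            )
            if (
                core.overlap_area >= config.min_overlap - 1e-12
                and core.tumor_fraction >= config.min_tumor_fraction - 1e-12
            ):
                cores.append(core)
    return CoreGrid(geometry, config, (x0, y0), n_rows, n_cols, tuple(cores))


def assign_tiles(
    x: np.ndarray, y: np.ndarray, grid: CoreGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Map cell coordinates to (row, col) tile indices.

    Half-open tie rule: a cell exactly on a shared edge belongs to the tile
    with the smaller row-major index (the tile above/left); cells on the
    grid's min edge belong to row/col 0.
    """
    w = grid.config.tile_width_um
    h = grid.config.tile_height_um
    x0, y0 = grid.origin
    col = np.ceil((np.asarray(x, float) - x0) / w).astype(int) - 1
    row = np.ceil((np.asarray(y, float) - y0) / h).astype(int) - 1
    return np.clip(row, 0, None), np.clip(col, 0, None)


def score_cores(
    grid: CoreGrid, cells: pd.DataFrame, drop_empty: bool = True
) -> list[Core]:
    """Count cells per retained core over rect ∩ ROI.

    Cells outside the ROI never count, even when inside the rectangle.
    Cores left with zero cells are dropped (``drop_empty``) with a warning,
    since their percent is undefined.
    """
    from .quantify import cells_in_region

    x = np.asarray(cells["x_um"], float)
    y = np.asarray(cells["y_um"], float)
    pos = np.asarray(cells["positive"], bool)
    in_roi = cells_in_region(x, y, grid.geometry.roi_union)
    row, col = assign_tiles(x, y, grid)

    n_cols = max(grid.n_cols, 1)
    n_tiles = max(grid.n_rows, 1) * n_cols
    key = (row * n_cols + col)[in_roi]
    totals = np.bincount(key, minlength=n_tiles)
    positives = np.bincount(key[pos[in_roi]], minlength=n_tiles)

    scored: list[Core] = []
    n_empty = 0
    for core in grid.cores:
        k = core.core_id[0] * n_cols + core.core_id[1]
        n_tot = int(totals[k])
        n_pos = int(positives[k])
        if n_tot == 0 and drop_empty:
            n_empty += 1
            continue
        scored.append(replace(core, n_cells=n_tot, n_positive=n_pos))
    if n_empty:
        logger.warning("dropped %d retained core(s) containing zero cells", n_empty)
    return scored


def cores_to_frame(slide_id: str, cores: list[Core]) -> pd.DataFrame:
    """Tidy per-core table in the documented CSV dialect."""
    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "row": [c.core_id[0] for c in cores],
            "col": [c.core_id[1] for c in cores],
            "x0_um": [c.rect[0] for c in cores],
            "y0_um": [c.rect[1] for c in cores],
            "x1_um": [c.rect[2] for c in cores],
            "y1_um": [c.rect[3] for c in cores],
            "overlap_mm2": [c.overlap_area for c in cores],
            "n_cells": [c.n_cells for c in cores],
            "n_positive": [c.n_positive for c in cores],
            "percent_cd8": [c.percent_cd8 for c in cores],
        }
    )
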