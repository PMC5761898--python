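"""Synthetic cohorts of CD8 IHC measurements: section tables and spatial slides.

Two generators emulate the structure of a step-sectioned FFPE study:

* :func:`generate_section_measurements` draws, for each patient, a latent
  true percent-CD8 from a between-patient normal distribution, then adds
  independent section-level noise — the hierarchy that variance-component
  and section-resampling analyses assume.  Values are clipped to [0, 100]
  on the raw percent scale (the scale the analyses model); clip events are
  counted in the table's ``attrs``.
* :func:`generate_slide` realises one slide as a marked spatial point
  pattern: a Poisson number of cells placed uniformly over a tumor ROI
  polygon, each marked CD8+ with a location-dependent probability that is
  either constant or enriched within a band along the ROI margin (some
  tumors concentrate cytotoxic T cells at the invasive margin).  The
  marking field is rescaled so its area-weighted mean equals the requested
  slide-level percent for both patterns.

Coordinates are in micrometres, origin at the bounding-box min corner,
x rightward and y downward; areas are reported in mm² (1 mm² = 1e6 μm²).
All randomness flows through ``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

UM_PER_MM = 1000.0
UM2_PER_MM2 = 1e6

@dataclass(frozen=True)
class GroupSpec:
    """Parameters of one histology group in the synthetic cohort."""

    group_label: str
    n_patients: int
    mean_percent: float
    between_patient_sd: float
    within_patient_sd: float
    n_sections: int = 8
    tissue_loss_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_sections < 1:
            raise ValueError("n_patients and n_sections must be >= 1")
        if not (0.0 <= self.mean_percent <= 100.0):
            raise ValueError("mean_percent must lie in [0, 100]")
        if self.between_patient_sd < 0 or self.within_patient_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0.0 <= self.tissue_loss_rate <= 1.0):
            raise ValueError("tissue_loss_rate must lie in [0, 1]")
        for name in ("mean_percent", "between_patient_sd", "within_patient_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def default_groups(tissue_loss_rate: float = 0.02) -> list[GroupSpec]:
    """The default cohort: 6 ductal and 6 medullary breast carcinomas plus
    13 colorectal carcinomas, 8 step sections per block.

    Group means and within-patient (section-to-section) SDs follow the
    published group summaries for this kind of cohort; between-patient SDs
    are calibrated once from the published medians and ranges, since only
    pooled intrapatient SDs are reported at the group level.
    """
    return [
        GroupSpec("ductal", 6, 8.8, 7.0, 1.2, tissue_loss_rate=tissue_loss_rate),
        GroupSpec("medullary", 6, 24.0, 13.0, 1.7, tissue_loss_rate=tissue_loss_rate),
        GroupSpec("crc", 13, 3.8, 3.0, 0.4, tissue_loss_rate=tissue_loss_rate),
    ]


#: Factor by which tissue loss reduces a section's expected cell count
#: (a lost level retains roughly 30% of the original tissue area).
TISSUE_LOSS_CELL_FACTOR = 0.3

#: Expected nucleated cells per full (no-loss) section.
DEFAULT_SECTION_CELLS = 20_000


def generate_section_measurements(
    groups: list[GroupSpec],
    seed: int,
    mean_section_cells: int = DEFAULT_SECTION_CELLS,
) -> pd.DataFrame:
    """Simulate section-level percent-CD8 measurements for a cohort.

    Returns a DataFrame with columns ``patient_id, group, section,
    percent_cd8, n_cells, tissue_loss``; one row per stained level.  The
    number of values clipped into [0, 100] is stored in
    ``df.attrs["n_clipped"]`` and the seed in ``df.attrs["seed"]``.
    """
    if not groups:
        raise ValueError("at least one GroupSpec required")
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    n_clipped = 0
    patient_counter = 0
    for g in groups:
        n_p, n_s = g.n_patients, g.n_sections
        pids = [f"{g.group_label}-{patient_counter + i + 1:03d}" for i in range(n_p)]
        patient_counter += n_p
        latent = rng.normal(g.mean_percent, g.between_patient_sd, size=n_p)
        values = latent[:, None] + rng.normal(0.0, g.within_patient_sd, size=(n_p, n_s))
        clipped = np.clip(values, 0.0, 100.0)
        n_clipped += int(np.sum(clipped != values))
        loss = rng.random((n_p, n_s)) < g.tissue_loss_rate
        lam = np.where(
            loss, mean_section_cells * TISSUE_LOSS_CELL_FACTOR, mean_section_cells
        )
        n_cells = rng.poisson(lam)
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(pids, n_s),
                    "group": g.group_label,
                    "section": np.tile(np.arange(1, n_s + 1), n_p),
                    "percent_cd8": clipped.ravel(),
                    "n_cells": n_cells.ravel(),
                    "tissue_loss": loss.ravel(),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["n_clipped"] = n_clipped
    out.attrs["seed"] = seed
    if n_clipped:
        logger.info("clipped %d section values into [0, 100]", n_clipped)
    return out


# ---------------------------------------------------------------------------
# Spatial slides
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one simulated slide (ROI + marked point pattern)."""

    roi_polygon: Polygon
    cell_density: float  # cells per mm^2
    target_percent: float
    pattern: str = "uniform"  # or "margin_enriched"
    margin_width: float = 200.0  # um
    margin_enrichment: float = 3.0

    def __post_init__(self) -> None:
        if self.cell_density <= 0:
            raise ValueError("cell_density must be positive")
        if not (0.0 <= self.target_percent <= 100.0):
            raise ValueError("target_percent must lie in [0, 100]")
        if self.pattern not in ("uniform", "margin_enriched"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.margin_enrichment < 1.0:
            raise ValueError("margin_enrichment must be >= 1")
        poly = self.roi_polygon
        if poly.is_empty or not poly.is_valid or poly.area <= 0:
            raise ValueError("roi_polygon must be a simple polygon with area > 0")


@dataclass(frozen=True)
class SlideGeometry:
    """Tumor-ROI polygons of one slide, μm coordinates."""

    roi_polygons: tuple[Polygon, ...]
    bounding_box: tuple[float, float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bounding_box is None:
            if not self.roi_polygons:
                raise ValueError("empty geometry needs an explicit bounding box")
            object.__setattr__(
                self, "bounding_box", unary_union(self.roi_polygons).bounds
            )
        for p in self.roi_polygons:
            if not p.is_valid:
                raise ValueError("invalid ROI polygon")

    @property
    def roi_union(self):
        if not self.roi_polygons:
            return Polygon()
        return unary_union(self.roi_polygons)

    @property
    def roi_area_mm2(self) -> float:
        return self.roi_union.area / UM2_PER_MM2


def rectangle_roi(width_mm: float, height_mm: float) -> Polygon:
    """Axis-aligned rectangular ROI preset, anchored at the origin (μm)."""
    return box(0.0, 0.0, width_mm * UM_PER_MM, height_mm * UM_PER_MM)


def _margin_regions(roi: Polygon, margin_width: float):
    """Split the ROI into (interior, margin-area-fraction).

    The margin is the band within ``margin_width`` μm of the ROI boundary;
    an erosion wider than the inradius empties the interior, in which case
    the whole ROI is margin and marking degenerates to uniform.
    """
    interior = roi.buffer(-margin_width)
    if interior.is_empty or interior.area <= 0:
        return None, 1.0
    return interior, 1.0 - interior.area / roi.area


def positivity_field(spec: SlideSpec):
    """Return ``(p_interior, p_margin, interior_geom)`` for a slide spec.

    The area-weighted mean of the field equals ``target_percent / 100``
    exactly: with margin fraction ``f``, the base rate is
    ``target / (f * e + (1 - f))`` and the margin rate is ``e`` times base.
    For heavily stained slides the requested enrichment can push the margin
    rate past 1; it then saturates at 1 and the interior rate is raised to
    ``(target - f) / (1 - f)`` so the mean-preservation contract still
    holds (the effective enrichment is simply smaller than requested).
    """
    target = spec.target_percent / 100.0
    if spec.pattern == "uniform":
        return target, target, None
    interior, f = _margin_regions(spec.roi_polygon, spec.margin_width)
    if interior is None:  # whole ROI is margin -> uniform
        return target, target, None
    base = target / (f * spec.margin_enrichment + (1.0 - f))
    p_margin = base * spec.margin_enrichment
    if p_margin > 1.0:
        p_margin = 1.0
        base = (target - f) / (1.0 - f)  # >= 0 whenever saturation occurs
        logger.info(
            "margin positivity saturated at 1; effective enrichment reduced"
        )
    return base, p_margin, interior


def generate_slide(spec: SlideSpec, seed: int) -> tuple[SlideGeometry, pd.DataFrame]:
    """Simulate one slide: geometry plus a cell table.

    The cell table has columns ``x_um, y_um, positive`` with one row per
    nucleated cell; the total count is Poisson(density × ROI area) and
    positions are uniform on the ROI.
    """
    rng = np.random.default_rng(seed)
    roi = spec.roi_polygon
    area_mm2 = roi.area / UM2_PER_MM2
    n_cells = int(rng.poisson(spec.cell_density * area_mm2))
    xs, ys = _uniform_points_in_polygon(roi, n_cells, rng)

    p_interior, p_margin, interior = positivity_field(spec)
    if interior is None:
        p = np.full(n_cells, p_interior)
    else:
        inside = shapely.intersects_xy(interior, xs, ys)
        p = np.where(inside, p_interior, p_margin)
    positive = rng.random(n_cells) < p

    geometry = SlideGeometry(roi_polygons=(roi,), bounding_box=roi.bounds)
    cells = pd.DataFrame({"x_um": xs, "y_um": ys, "positive": positive})
    cells.attrs["seed"] = seed
    return geometry, cells


def _uniform_points_in_polygon(poly: Polygon, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample ``n`` uniform points from ``poly``."""
    xmin, ymin, xmax, ymax = poly.bounds
    accept_rate = poly.area / ((xmax - xmin) * (ymax - ymin))
    xs = np.empty(0)
    ys = np.empty(0)
    while xs.size < n:
        m = max(1024, int(1.2 * (n - xs.size) / max(accept_rate, 1e-6)))
        cx = rng.uniform(xmin, xmax, m)
        cy = rng.uniform(ymin, ymax, m)
        keep = shapely.intersects_xy(poly, cx, cy)
        xs = np.concatenate([xs, cx[keep]])
        ys = np.concatenate([ys, cy[keep]])
    return xs[:n], ys[:n]
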