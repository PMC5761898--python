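"""Tessellate a slide into virtual 2 mm^2 core biopsies and score them.

Simulates one margin-enriched slide (CD8+ cells concentrated near the
tumor boundary), overlays the core grid, filters cores by ROI overlap
(>= 0.7 mm^2) and tumor fraction (>= 33%), and prints per-core statistics.
"""

import numpy as np

import tilsampling as ts

spec = ts.SlideSpec(
    roi_polygon=ts.rectangle_roi(9.0, 9.0),
    cell_density=600.0,
    target_percent=8.0,
    pattern="margin_enriched",
    margin_width=300.0,
    margin_enrichment=3.0,
)
geometry, cells = ts.generate_slide(spec, seed=3)
print(f"slide: {len(cells)} cells over {geometry.roi_area_mm2:.1f} mm^2 of ROI, "
      f"{100 * cells['positive'].mean():.2f}% CD8+ overall")

grid = ts.generate_core_grid(geometry, ts.CoreGridConfig())
scored = ts.score_cores(grid, cells)
percents = np.array([c.percent_cd8 for c in scored])
print(f"grid: {grid.n_rows} x {grid.n_cols} tiles, {len(scored)} cores retained")
print(f"core percent CD8+: mean {percents.mean():.2f}, SD {percents.std(ddof=1):.2f}, "
      f"range {percents.min():.2f}-{percents.max():.2f}")

print(
    "\nThe spread across cores is what a needle biopsy samples from: the "
    "margin-enriched pattern makes boundary cores run hotter than the "
    "slide average, so single-core estimates inherit that spatial "
    "heterogeneity."
)
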