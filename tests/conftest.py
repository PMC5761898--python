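import numpy as np
import pandas as pd
import pytest

import tilsampling as ts


@pytest.fixture
def toy_measurements() -> pd.DataFrame:
    """Two patients, two sections each, constant within patient."""
    return pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P2", "P2"],
            "group": "g",
            "section": [1, 2, 1, 2],
            "percent_cd8": [1.0, 1.0, 3.0, 3.0],
            "n_cells": 100,
            "tissue_loss": False,
        }
    )


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return ts.generate_section_measurements(ts.default_groups(), seed=11)


@pytest.fixture(scope="session")
def demo_slide():
    """One uniform 8%-positive slide with its scored core grid."""
    spec = ts.SlideSpec(
        roi_polygon=ts.rectangle_roi(11.0, 11.0),
        cell_density=600.0,
        target_percent=8.0,
    )
    geometry, cells = ts.generate_slide(spec, seed=21)
    grid = ts.generate_core_grid(geometry, ts.CoreGridConfig())
    scored = ts.score_cores(grid, cells)
    return geometry, cells, grid, scored


def make_measurements(values_by_patient: dict[str, list[float]]) -> pd.DataFrame:
    """Build a measurement table from {patient_id: [section values]}."""
    rows = []
    for pid, vals in values_by_patient.items():
        for i, v in enumerate(vals, start=1):
            rows.append((pid, "g", i, float(v), 100, False))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "group", "section", "percent_cd8", "n_cells", "tissue_loss"],
    )


def ray_cast_inside(px: float, py: float, vertices: np.ndarray) -> bool:
    """Brute-force point-in-polygon: ray casting plus on-edge detection."""
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-segment check (boundary counts as inside)
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-9:
            if min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 and (
                min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9
            ):
                return True
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside
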