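"""Shared fixtures: one mid-size plan/measurement chain reused across tests.

The 5 cm target case on the 2 mm phantom grid is the workhorse — building
it once per session keeps the suite fast while exercising the full
geometry (five beams, helical diode lattice, all three ROIs).
"""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from virtualqa import (
    DoseGrid,
    PHANTOM_EXTENT_MM,
    build_geometry,
    compose_plan,
    make_grid,
    roi_set,
    sample_plan_at_diodes,
)


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def phantom_grid2():
    return make_grid(PHANTOM_EXTENT_MM, (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def case50(phantom_grid2, geometry):
    """ROIs, plan (600 cGy) and planned diode reading for the 5 cm target."""
    rois = roi_set(phantom_grid2, 50.0)
    plan = compose_plan(rois["target"], 600.0, target_diameter_mm=50.0)
    planned = sample_plan_at_diodes(plan, geometry)
    return {"rois": rois, "plan": plan, "planned": planned}


@pytest.fixture(scope="session")
def smooth_fields():
    """A pair of smooth positive random 3D dose fields on a 12 cm cube."""
    rng = np.random.default_rng(42)
    grid = make_grid((120.0, 120.0, 120.0), (2.0, 2.0, 2.0))

    def build():
        v = gaussian_filter(rng.random(grid.shape), sigma=5)
        return 100.0 * (v - v.min()) / (v.max() - v.min()) + 20.0

    ref = DoseGrid(grid, build())
    evl = DoseGrid(grid, 0.97 * ref.values + 0.05 * build())
    return ref, evl
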