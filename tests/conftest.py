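import numpy as np
import pytest

from adaptrt.grid import DoseGrid, GridSpec, StructureSet
from adaptrt.pipeline import StudyConfig, run_study


@pytest.fixture
def grid2mm():
    return GridSpec(shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0), origin=(-40.0, -40.0, -40.0))


@pytest.fixture
def sphere_mask(grid2mm):
    """Sphere of radius 10 mm centred at the origin (voxel-centre rule)."""
    gx, gy, gz = grid2mm.coordinate_grids()
    return (gx**2 + gy**2 + gz**2) <= 10.0**2


def make_uniform_dose(grid: GridSpec, value: float) -> DoseGrid:
    return DoseGrid(grid, np.full(grid.shape, float(value)))


@pytest.fixture
def uniform_dose(grid2mm):
    return make_uniform_dose(grid2mm, 10.0)


@pytest.fixture(scope="session")
def default_study():
    """The full default synthetic study (32 patients x 5 fractions).

    Session-scoped: this is the expensive end-to-end run shared by the
    cohort-property and acceptance tests (~2 min). Returns (result, seconds).
    """
    import time

    config = StudyConfig()
    t0 = time.perf_counter()
    result = run_study(config, collect_dvh=True)
    return result, time.perf_counter() - t0


@pytest.fixture(scope="session")
def tiny_study():
    """A 2-patient x 2-fraction study for schema and determinism tests."""
    config = StudyConfig(master_seed=123, n_patients=2, n_fractions=2)
    return run_study(config, collect_dvh=False)


def make_structures(grid: GridSpec, **masks) -> StructureSet:
    return StructureSet(grid=grid, masks=dict(masks))
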