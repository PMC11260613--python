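import numpy as np
import pytest

from accudose import (
    DoseGrid,
    GridGeometry,
    PhantomSpec,
    StructureSet,
    generate_phantom,
)


@pytest.fixture
def geom() -> GridGeometry:
    """Small anisotropic grid used across unit tests."""
    return GridGeometry(shape=(8, 8, 4), spacing=(4.0, 4.0, 5.0), origin=(0.0, 0.0, 0.0),
                        frame_id="test")


@pytest.fixture
def uniform_dose(geom):
    def make(value: float, geometry: GridGeometry | None = None) -> DoseGrid:
        g = geometry or geom
        return DoseGrid(values=np.full(g.shape, float(value)), geometry=g)

    return make


@pytest.fixture
def ramp_dose():
    """Linear dose ramp along x: value equals the x coordinate in mm."""

    def make(shape=(16, 4, 4), spacing=(1.0, 1.0, 1.0), scale=1.0) -> DoseGrid:
        g = GridGeometry(shape=shape, spacing=spacing)
        x = g.voxel_centers_mm()[0]
        vals = np.broadcast_to(x[:, None, None] * scale, shape).copy()
        return DoseGrid(values=vals, geometry=g)

    return make


@pytest.fixture
def small_structures(geom) -> StructureSet:
    """Body filling the grid, a central PTV block, one flanking OAR."""
    body = np.ones(geom.shape, dtype=bool)
    ptv = np.zeros(geom.shape, dtype=bool)
    ptv[3:5, 3:5, 1:3] = True
    oar = np.zeros(geom.shape, dtype=bool)
    oar[5:7, 3:5, 1:3] = True
    return StructureSet(geometry=geom, masks={"body": body, "ptv": ptv, "bladder": oar})


@pytest.fixture(scope="session")
def phantom_case():
    """One default phantom, shared across tests (generation is deterministic)."""
    return generate_phantom(PhantomSpec(), seed=20240001)


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec()
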