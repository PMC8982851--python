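import numpy as np
import pytest

import corridors as c


@pytest.fixture(scope="session")
def small_stack():
    """A 50x50 standardized synthetic predictor stack (2 smooth + 2 distance)."""
    return c.make_predictor_stack((50, 50), 1000.0, 2, 2, seed=1)


@pytest.fixture(scope="session")
def planted():
    """The planted-channel fixture: width-3 L-channel, contrast 10, on a
    landscape large enough that the channel covers well under 10% of cells."""
    return c.plant_corridor_landscape((100, 100), channel_width=3, contrast=10.0)


def suitability_map(values, label="test", **kw):
    return c.SuitabilityMap(grid=c.RasterGrid(np.asarray(values, dtype=float), **kw),
                            species_label=label)


def chain_resistance(values, nodata=None):
    """1-D (or 2-D) resistance surface with optional nodata, 1-km cells."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    grid = c.RasterGrid(values, nodata_mask=nodata)
    return c.ResistanceSurface(grid=grid, scaling="linear")
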