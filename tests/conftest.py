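import numpy as np
import pytest

from invasionrisk import GridHeader, Raster, RasterStack


@pytest.fixture
def header_3x3():
    return GridHeader(ncols=3, nrows=3, xllcorner=0.0, yllcorner=0.0, cellsize=1.0)


@pytest.fixture
def small_stack(header_3x3):
    """Two hand-set 3x3 layers with one nodata cell in layer 'b'."""
    a = Raster(values=np.arange(9, dtype=float).reshape(3, 3),
               header=header_3x3, name="a")
    b_vals = (np.arange(9, dtype=float).reshape(3, 3) * 10.0)
    b_vals[1, 1] = np.nan
    b = Raster(values=b_vals, header=header_3x3, name="b")
    return RasterStack({"a": a, "b": b})


@pytest.fixture
def landscape():
    from invasionrisk import make_landscape
    return make_landscape(seed=11, rows=30, cols=30, n_predictors=4,
                          autocorrelation_range=5, organic_band=True)
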