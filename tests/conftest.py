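import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from drypheno import SyntheticSeasonSpec, VISeries, simulate_raster
from drypheno.raster import run_raster

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def noiseless_spec():
    return SyntheticSeasonSpec(noise_sd=0.0, gap_fraction=0.0)


@pytest.fixture
def flat_series():
    dates = pd.date_range("2009-01-01", "2011-12-31", freq="D")
    return VISeries(dates=dates, values=np.full(len(dates), 0.3))


@pytest.fixture(scope="session")
def raster_run(tmp_path_factory):
    """One shared 50x50, 2-year raster simulation + retrieval + export.

    10% of pixels are bare soil by construction, so the expected retrieval
    ratio is exactly 90%.
    """
    out_dir = tmp_path_factory.mktemp("gdpd")
    sim = simulate_raster(
        nx=50, ny=50, years=(2009, 2010), target_year=2010, seed=42,
        bare_fraction=0.1,
    )
    result = run_raster(
        sim.stack, sim.dates, sim.grid, years=[2010], out_dir=out_dir
    )
    return sim, result, out_dir
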