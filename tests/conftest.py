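import pandas as pd
import pytest

from litmix import DesignSpec, LitterParams, ObservationSeries, packaged_params


@pytest.fixture(scope="session")
def table2():
    """Calibrated peatland litter pair (wet bryophyte, dry gramineae)."""
    return packaged_params("table2_calibrated")


@pytest.fixture(scope="session")
def sphagnum(table2):
    return table2["sphagnum_rubellum"]


@pytest.fixture(scope="session")
def molinia(table2):
    return table2["molinia_caerulea"]


@pytest.fixture
def bunnell_params():
    """Simple bunnell litter used in hand-checked examples."""
    return LitterParams(name="demo", lwc_max=10, k_max=0.01, e=0.1,
                        model_kind="bunnell", c=5, d=5)


@pytest.fixture
def moyano_params():
    return LitterParams(name="demo-moyano", lwc_max=10, k_max=0.01, e=0.1,
                        model_kind="moyano", a=5, b=0.5)


@pytest.fixture
def noiseless_design():
    return DesignSpec(noise_sd_lwc=0.0, noise_sd_mass=0.0, seed=0)


def make_series(records, litter="test"):
    """ObservationSeries from (day, replicate, variable, value) tuples."""
    data = pd.DataFrame(records,
                        columns=["day", "replicate", "variable", "value"])
    return ObservationSeries(litter=litter, data=data)


def lwc_series(days, values, replicate=1, litter="test"):
    """A water-content-only series."""
    records = [(d, replicate, "lwc", v) for d, v in zip(days, values)]
    return make_series(records, litter=litter)
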