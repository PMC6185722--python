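import numpy as np
import pytest

import bgrsom as b


@pytest.fixture(scope="session")
def reference_tables():
    """Bundled composition / properties / parameters tables."""
    return b.load_fixtures()


@pytest.fixture(scope="session")
def reference_properties():
    return b.fixture_properties()


@pytest.fixture()
def soil():
    return b.SoilContext("silty", bat_factor=1.0)


@pytest.fixture()
def example_params():
    return b.TurnoverParams(k=0.4, eta=0.85)


@pytest.fixture()
def noisefree_curve(soil, example_params):
    """Exact model curve on the standard daily window, tiny known variance."""
    days = np.arange(1.0, 21.0)
    values = b.cumulative_mineralization(example_params, days, soil)
    return b.IncubationCurve(days, values, np.full(days.shape, 1e-6))
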