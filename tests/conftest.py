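import numpy as np
import pandas as pd
import pytest

from sgdco2.io import SurfaceTimeSeries


def make_series(n=48, step_min=30, start="2024-03-01 00:00", **channels):
    """Build a SurfaceTimeSeries with given channel arrays (others constant)."""
    idx = pd.date_range(start, periods=n, freq=f"{step_min}min")
    defaults = {
        "pco2": 500.0,
        "rn": 2.0,
        "do_sat": 95.0,
        "salinity": 30.0,
        "temperature": 25.0,
        "depth": 1.5,
        "wind": 3.0,
    }
    data = {}
    for col, default in defaults.items():
        val = channels.get(col, default)
        data[col] = np.broadcast_to(np.asarray(val, dtype=float), (n,)).copy()
    return SurfaceTimeSeries(pd.DataFrame(data, index=idx))


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def tidal_sim():
    """Tidal-dominated preset simulation, shared across tests."""
    from sgdco2.synthetic import preset, simulate_box_model

    return simulate_box_model(preset("tidal_dominated", seed=11))


@pytest.fixture(scope="session")
def diel_sim():
    from sgdco2.synthetic import preset, simulate_box_model

    return simulate_box_model(preset("diel_dominated", seed=11))


@pytest.fixture(scope="session")
def conservative_sim():
    from sgdco2.synthetic import preset, simulate_box_model

    return simulate_box_model(preset("conservative_mixing", seed=11))
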