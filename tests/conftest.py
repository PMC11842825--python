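import numpy as np
import pytest

import varslope as vs


@pytest.fixture(scope="session")
def scheme():
    return vs.make_window_scheme()


def make_leg(
    leg_id=0,
    along_track_km=100.0,
    coverage=1.0,
    elapsed_hours=8.3,
    centroid_lat=0.0,
    centroid_lon=-30.0,
    variable="chl_mg_m3",
    values=None,
):
    """Construct a Leg with explicit metadata for QC and table tests."""
    n = vs.LEG_SIZE
    if values is None:
        values = np.random.default_rng(leg_id).standard_normal(n)
    return vs.Leg(
        leg_id=leg_id,
        timestamps=None,
        lat=np.full(n, centroid_lat),
        lon=np.full(n, centroid_lon),
        values={variable: values},
        coverage={variable: coverage},
        along_track_km=along_track_km,
        elapsed_hours=elapsed_hours,
        centroid_lat=centroid_lat,
        centroid_lon=centroid_lon,
    )


@pytest.fixture
def leg_factory():
    return make_leg
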