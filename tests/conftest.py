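import logging

import numpy as np
import pandas as pd
import pytest

from mtrack.core_data import ErrorModel, ObservationSet
from mtrack.ctcrw import RegularTrack

# recovery-experiment warnings (degenerate mixture fits on tiny fixtures)
# are expected noise in the test logs
logging.getLogger("mtrack").setLevel(logging.ERROR)


@pytest.fixture
def error_model():
    return ErrorModel()


@pytest.fixture
def tiny_error_model():
    """Near-exact measurements (sub-metre) for projection-style checks."""
    return ErrorModel(base_sd_lon_km=1e-4, base_sd_lat_km=1e-4,
                      gl_sd_lon_km=1e-4, gl_sd_lat_km=1e-4)


def make_obs(t, lon, lat, loc_class="3", animal_id="A"):
    n = len(t)
    cls = [loc_class] * n if isinstance(loc_class, str) else list(loc_class)
    df = pd.DataFrame({
        "animal_id": animal_id, "t": np.asarray(t, float),
        "lon": np.asarray(lon, float), "lat": np.asarray(lat, float),
        "loc_class": cls,
    })
    return ObservationSet(df)


def make_track(t, lon, lat, animal_id="A", low_confidence=None):
    n = len(t)
    df = pd.DataFrame({
        "animal_id": animal_id, "t": np.asarray(t, float),
        "lon": np.asarray(lon, float), "lat": np.asarray(lat, float),
        "low_confidence": np.zeros(n, bool) if low_confidence is None else low_confidence,
    })
    return RegularTrack(df=df)
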