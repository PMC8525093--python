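import numpy as np
import pandas as pd
import pytest

from tealmig.synthetic import SimConfig, simulate_cohort
from tealmig.tracks import Track


@pytest.fixture(scope="session")
def small_cohort():
    """Six-bird cohort used by several module tests (fixed seed)."""
    return simulate_cohort(SimConfig(seed=42, n_birds=6))


@pytest.fixture(scope="session")
def acceptance_cohort():
    """The 20-bird parameter-recovery cohort (fixed seed)."""
    return simulate_cohort(SimConfig(seed=7, n_birds=20))


def make_track(bird_id, hours, lons, lats, start="2018-08-01T00:00:00Z"):
    t0 = pd.Timestamp(start)
    t = pd.DatetimeIndex([t0 + pd.Timedelta(hours=float(h)) for h in hours])
    return Track(bird_id, t, np.asarray(lons, float), np.asarray(lats, float))
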