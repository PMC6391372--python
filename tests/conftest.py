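"""Shared fixtures: the full synthetic dataset and one complete pipeline run.

The heavy end-to-end objects are session-scoped so the recovery and
count-based checks share a single generation + analysis pass.
"""

import numpy as np
import pandas as pd
import pytest

from sowshift import pipeline, synthetic_data as sd
from sowshift.io_formats import RunConfig

SEED = 0


@pytest.fixture(scope="session")
def dataset():
    """Full synthetic data bundle (27 states × 10 years × 5 locations)."""
    return sd.generate_all(seed=SEED)


@pytest.fixture(scope="session")
def full_run(dataset):
    """One complete pipeline run on the session dataset."""
    return pipeline.run_pipeline(dataset, RunConfig(seed=SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture()
def one_state_weather():
    """Noise-free single-location daily weather for a mid-latitude state."""
    return sd.climatology_frame(sd.STATE_PARAMS["IL"], year=2010, location_id="IL_clim")


@pytest.fixture()
def random_daily_frame():
    """Factory for random (but valid) daily series covering a whole year."""

    def _make(seed, n_days=365):
        r = np.random.default_rng(seed)
        doy = np.arange(1, n_days + 1)
        tmin = r.normal(10, 6, n_days)
        tmax = tmin + r.uniform(2, 15, n_days)
        return pd.DataFrame({
            "doy": doy,
            "tmin": tmin,
            "tmax": tmax,
            "precip": np.where(r.random(n_days) < 0.4,
                               r.gamma(0.7, 8, n_days), 0.0),
            "srad": r.uniform(5, 30, n_days),
            "vp": r.uniform(0.2, 2.5, n_days),
            "dayl": r.uniform(3e4, 6e4, n_days),
        })

    return _make
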