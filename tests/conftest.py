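import numpy as np
import pandas as pd
import pytest

from homestay import features, preprocess, simulate
from homestay.config import PipelineConfig, SimConfig

TZ = "America/New_York"


def make_gps(times_s, lats, lons, pid="p001", origin="2017-02-06T00:00:00-05:00"):
    """Build a GPS frame from offsets in seconds relative to an origin."""
    t0 = pd.Timestamp(origin)
    times = [t0 + pd.Timedelta(seconds=float(s)) for s in times_s]
    return pd.DataFrame({
        "participant": pid,
        "time": pd.to_datetime(times, utc=True),
        "lat": np.asarray(lats, dtype=float),
        "lon": np.asarray(lons, dtype=float),
    })


def indicator(codes):
    codes = np.asarray(codes)
    cats, inv = np.unique(codes, return_inverse=True)
    Z = np.zeros((len(codes), len(cats)))
    Z[np.arange(len(codes)), inv] = 1.0
    return Z


@pytest.fixture(scope="session")
def small_sim_cfg():
    return SimConfig(n_participants=12, n_days=7, gps_interval=600,
                     compliance_rate=0.9, seed=42)


@pytest.fixture(scope="session")
def small_pipe_cfg():
    return PipelineConfig(gps_interval=600)


@pytest.fixture(scope="session")
def small_cohort(small_sim_cfg):
    return simulate.simulate_cohort(small_sim_cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort, small_pipe_cfg):
    stays, home, timeline, comp = preprocess.preprocess_cohort(
        small_cohort.gps, small_pipe_cfg)
    return {"stays": stays, "home": home, "timeline": timeline, "completeness": comp}


@pytest.fixture(scope="session")
def small_features(small_cohort, small_preprocessed, small_pipe_cfg):
    table, diag = features.build_features(
        small_cohort.ema, small_preprocessed["timeline"],
        small_preprocessed["home"], small_pipe_cfg)
    return table, diag
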