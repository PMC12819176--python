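import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cpforage as cf

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def habitat_map():
    return cf.default_habitat_map()


@pytest.fixture(scope="session")
def oracle_population():
    """Noise-free, outlier-free 90-day population with exact ground truth."""
    cfg = cf.oracle_config(end="2023-03-03T00:00:00Z")
    tracks, truth, table = cf.simulate_population(cfg)
    return cfg, tracks, truth, table


@pytest.fixture(scope="session")
def oracle_trips(oracle_population):
    """Segmented trips for every bird of the oracle population."""
    cfg, tracks, truth, _ = oracle_population
    out = {}
    for tr in tracks:
        colony = cfg.colony_urban if tr.status == "urban" else cfg.colony_wild
        clean, _ = cf.filter_speed_outliers(tr)
        sites = cf.detect_resting_sites(clean, colony)
        timeline = cf.build_central_timeline(clean, colony, sites)
        out[tr.bird_id] = cf.segment_trips(clean, timeline)
    return out


def make_track(bird_id, times, lats, lons, status=None):
    """Build a Track from plain lists (times as UTC-parseable strings)."""
    fixes = pd.DataFrame({
        "timestamp": pd.to_datetime(list(times), utc=True),
        "lat": np.asarray(lats, dtype=float),
        "lon": np.asarray(lons, dtype=float),
        "battery_pct": np.nan,
        "flag": "ok",
    })
    return cf.Track(bird_id, status, fixes)


@pytest.fixture
def track_factory():
    return make_track
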