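import numpy as np
import pandas as pd
import pytest

import reefskill as rs
from reefskill.series import PairedDataset, SEASON_OF_MONTH


def make_site(site_id="S0", lat=21.3, lon=-157.8, depth=7.0, **kw):
    defaults = dict(
        site_id=site_id, lat=lat, lon=lon, depth_m=depth,
        start="2011-01-01", end="2011-07-01",
        island="Oahu", distance_to_shore_m=300.0,
    )
    defaults.update(kw)
    return rs.SyntheticSiteConfig(**defaults)


def pairs_from_arrays(obs, model, times=None, **meta):
    """Minimal paired dataset from raw arrays, for statistics tests."""
    obs = np.asarray(obs, dtype=float)
    n = len(obs)
    if times is None:
        times = pd.date_range("2012-01-01", periods=n, freq="3h", tz="UTC")
    times = pd.DatetimeIndex(times)
    frame = pd.DataFrame({
        "site_id": meta.get("site_id", "S0"),
        "island": meta.get("island", "Oahu"),
        "lat": meta.get("lat", 21.3),
        "lon": meta.get("lon", -157.8),
        "depth_m": meta.get("depth_m", 7.0),
        "distance_to_shore_m": meta.get("distance_to_shore_m", 300.0),
        "time": times,
        "obs": obs,
        "model": np.asarray(model, dtype=float),
        "n_obs_in_window": 5,
        "year": times.year,
        "day_of_year": times.dayofyear,
        "season": [SEASON_OF_MONTH[m] for m in times.month],
    })
    return PairedDataset(frame)


@pytest.fixture(scope="session")
def small_archive():
    """Three sites, six months, mild noise, known constant bias of 0.15 °C."""
    sites = [
        make_site("S0", depth=5.0),
        make_site("S1", lat=20.8, lon=-156.4, depth=15.0, island="Maui",
                  distance_to_shore_m=600.0),
        make_site("S2", lat=21.9, lon=-159.5, depth=25.0, island="Kauai",
                  distance_to_shore_m=900.0),
    ]
    err = rs.ModelErrorConfig(constant_bias=0.15, extra_noise_sd=0.1)
    obs, model = rs.make_paired_dataset(sites, err, seed=7)
    ds = rs.build_paired_dataset(obs, model)
    return sites, err, obs, model, ds
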