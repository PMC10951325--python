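"""Matchup construction: logger CSV ingest, model extraction, temporal pairing.

The pairing rule follows standard snapshot-archive matchup practice: the
model stores instantaneous 3-hourly snapshots, so logger values are averaged
in a window centered on each snapshot — ±10 min for 5-min loggers and ±1 h
for 30-min loggers, both windows containing five logger samples when the
record is gap-free.  Window endpoints are inclusive on both sides.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .series import PairedDataset, SiteMeta, TemperatureSeries, season_of

logger = logging.getLogger("reefskill")

#: Default spin-up cutoff: matchups before this instant belong to the model's
#: assimilation spin-up and are excluded from the Taylor and bias-GAM stages.
SPINUP_CUTOFF = pd.Timestamp("2011-01-01T00:00:00Z")

#: Half-window length (minutes) keyed by logger cadence (minutes).
WINDOW_HALF_MIN = {5: 10, 30: 60}

EARTH_RADIUS_M = 6_371_000.0

REQUIRED_OBS_COLUMNS = ["site_id", "latitude", "longitude", "depth", "time", "temperature"]


def great_circle_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance in meters (inputs in decimal degrees)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def read_obs_csv(path) -> list[TemperatureSeries]:
    """Read a tabledap-style logger CSV into one series per (site, depth).

    Expects columns site_id, latitude, longitude, depth, time (ISO-8601),
    temperature.  A units row under the header (as tabledap emits) is
    detected and skipped.  Rows with missing temperature are dropped and
    counted in the log; non-monotone timestamps are sorted with a warning.
    """
    raw = pd.read_csv(path, dtype={"site_id": str})
    missing = [c for c in REQUIRED_OBS_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"observation CSV missing required column(s): {missing}")
    # tabledap puts a units row (e.g. "UTC, degrees_north, ...") under the header
    if len(raw):
        first = str(raw["latitude"].iloc[0]).strip()
        if pd.isna(pd.to_numeric(pd.Series([first]), errors="coerce").iloc[0]):
            raw = raw.iloc[1:].reset_index(drop=True)
    raw["temperature"] = pd.to_numeric(raw["temperature"], errors="coerce")
    n_missing = int(raw["temperature"].isna().sum())
    if n_missing:
        logger.info("read_obs_csv: dropped %d rows with missing temperature", n_missing)
        raw = raw.dropna(subset=["temperature"])
    raw["time"] = pd.to_datetime(raw["time"], utc=True, format="ISO8601")
    for c in ("latitude", "longitude", "depth"):
        raw[c] = pd.to_numeric(raw[c])

    out: list[TemperatureSeries] = []
    for (site_id, depth), grp in raw.groupby(["site_id", "depth"], sort=True):
        if not grp["time"].is_monotonic_increasing:
            logger.warning("read_obs_csv: %s @ %s m: timestamps not sorted; sorting",
                           site_id, depth)
            grp = grp.sort_values("time")
        dist_col = grp["distance_to_shore_m"] if "distance_to_shore_m" in grp else None
        meta = SiteMeta(
            site_id=str(site_id),
            lat=float(grp["latitude"].iloc[0]),
            lon=float(grp["longitude"].iloc[0]),
            depth_m=float(depth),
            island=str(grp["island"].iloc[0]) if "island" in grp else "",
            distance_to_shore_m=float(dist_col.iloc[0]) if dist_col is not None else float("nan"),
        )
        diffs = grp["time"].diff().dropna().dt.total_seconds() / 60.0
        cadence = float(np.median(diffs)) if len(diffs) else float("nan")
        out.append(TemperatureSeries(
            meta=meta, source="observed",
            data=pd.Series(grp["temperature"].to_numpy(), index=pd.DatetimeIndex(grp["time"])),
            cadence_min=cadence,
        ))
    return out


def _nearest_cell(lats: np.ndarray, lons: np.ndarray, lat: float, lon: float) -> tuple[int, int]:
    """Nearest grid cell by great-circle distance; ties go to the lower index
    (lat-major scan order)."""
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    d = great_circle_m(glat.ravel(), glon.ravel(), lat, lon)
    flat = int(np.argmin(np.round(d, 6)))  # round so exact ties resolve by index
    return flat // len(lons), flat % len(lons)


def read_model_series(path, lat: float, lon: float, stratum_m: float) -> TemperatureSeries:
    """Extract the model temperature series nearest (lat, lon) at one stratum.

    Accepts CF-style NetCDF (dims time/depth/lat/lon, variable
    ``temperature`` in °C) or an equivalent long-format griddap CSV with
    columns time, depth, latitude, longitude, temperature.
    """
    path = str(path)
    if path.endswith(".nc"):
        import xarray as xr
        with xr.open_dataset(path) as nc:
            var = "temperature" if "temperature" in nc else "temp"
            lat_name = "latitude" if "latitude" in nc.coords else "lat"
            lon_name = "longitude" if "longitude" in nc.coords else "lon"
            lats = nc[lat_name].to_numpy().astype(float)
            lons = nc[lon_name].to_numpy().astype(float)
            strata = nc["depth"].to_numpy().astype(float)
            times = pd.DatetimeIndex(nc["time"].to_numpy())
            cube = nc[var].transpose("time", "depth", lat_name, lon_name).to_numpy()
    else:
        tab = pd.read_csv(path, parse_dates=["time"])
        lats = np.sort(tab["latitude"].unique().astype(float))
        lons = np.sort(tab["longitude"].unique().astype(float))
        strata = np.sort(tab["depth"].unique().astype(float))
        times = pd.DatetimeIndex(np.sort(tab["time"].unique()))
        cube = np.full((len(times), len(strata), len(lats), len(lons)), np.nan)
        ti = times.get_indexer(pd.DatetimeIndex(tab["time"]))
        di = np.searchsorted(strata, tab["depth"].to_numpy(dtype=float))
        yi = np.searchsorted(lats, tab["latitude"].to_numpy(dtype=float))
        xi = np.searchsorted(lons, tab["longitude"].to_numpy(dtype=float))
        cube[ti, di, yi, xi] = tab["temperature"].to_numpy(dtype=float)

    if not (lats.min() <= lat <= lats.max()) or not (lons.min() <= lon <= lons.max()):
        raise ValueError(
            f"point ({lat}, {lon}) outside grid domain "
            f"[{lats.min()}, {lats.max()}] x [{lons.min()}, {lons.max()}]")
    k = np.flatnonzero(np.isclose(strata, stratum_m))
    if len(k) == 0:
        raise ValueError(f"stratum {stratum_m} m absent; available strata: {list(strata)}")
    iy, ix = _nearest_cell(lats, lons, lat, lon)
    values = cube[:, int(k[0]), iy, ix]
    diffs = np.diff(times.asi8) / 60e9
    cadence = float(np.median(diffs)) if len(diffs) else 180.0
    meta = SiteMeta(site_id=f"cell_{iy}_{ix}", lat=float(lats[iy]), lon=float(lons[ix]),
                    depth_m=float(strata[int(k[0])]))
    return TemperatureSeries(meta=meta, source="model",
                             data=pd.Series(values, index=times), cadence_min=cadence)


def match_depth(obs_depth_m: float, strata: Sequence[float]) -> float:
    """Nearest model stratum to a deployment depth; exact ties go shallower."""
    if len(strata) == 0:
        raise ValueError("empty strata list")
    s = np.asarray(sorted(strata), dtype=float)
    d = np.abs(s - obs_depth_m)
    return float(s[int(np.argmin(d))])  # argmin returns first (shallower) on ties


def pair_series(obs: TemperatureSeries, model: TemperatureSeries,
                min_window_n: int = 1) -> pd.DataFrame:
    """Build matchup rows for one site: windowed obs mean vs. model snapshot.

    The half-window is ±10 min for 5-min loggers and ±1 h for 30-min loggers
    (five samples when gap-free), endpoints inclusive.  A matchup is emitted
    only when the snapshot lies within both series' time ranges and at least
    ``min_window_n`` logger samples fall in the window.
    """
    cadence = int(round(obs.cadence_min))
    if cadence not in WINDOW_HALF_MIN:
        raise ValueError(f"unsupported observation cadence {obs.cadence_min} min "
                         f"(supported: {sorted(WINDOW_HALF_MIN)})")
    if not np.isclose(model.cadence_min, 180.0):
        raise ValueError(f"model cadence must be 3-hourly, got {model.cadence_min} min")
    if obs.meta.site_id != model.meta.site_id:
        raise ValueError("pair_series requires series from the same site")
    half_ns = WINDOW_HALF_MIN[cadence] * 60 * 10**9

    obs_ns = obs.timestamps.asi8
    snap_ns = model.timestamps.asi8
    in_overlap = (snap_ns >= obs_ns[0]) & (snap_ns <= obs_ns[-1])
    lo = np.searchsorted(obs_ns, snap_ns - half_ns, side="left")
    hi = np.searchsorted(obs_ns, snap_ns + half_ns, side="right")
    count = hi - lo
    keep = in_overlap & (count >= max(1, min_window_n))
    csum = np.concatenate([[0.0], np.cumsum(obs.values)])
    means = (csum[hi[keep]] - csum[lo[keep]]) / count[keep]

    times = model.timestamps[keep]
    meta = obs.meta
    return pd.DataFrame({
        "site_id": meta.site_id,
        "island": meta.island,
        "lat": meta.lat,
        "lon": meta.lon,
        "depth_m": meta.depth_m,
        "distance_to_shore_m": meta.distance_to_shore_m,
        "time": times,
        "obs": means,
        "model": model.values[keep],
        "n_obs_in_window": count[keep],
        "year": times.year,
        "day_of_year": times.dayofyear,
        "season": season_of(times.month) if len(times) else np.array([], dtype=object),
    })


def build_paired_dataset(obs_list: Sequence[TemperatureSeries],
                         model_list: Sequence[TemperatureSeries],
                         min_window_n: int = 3) -> PairedDataset:
    """Pair each observation series with its same-site model series."""
    models = {m.meta.site_id: m for m in model_list}
    frames = []
    for obs in obs_list:
        if obs.meta.site_id not in models:
            raise ValueError(f"no model series for site {obs.meta.site_id}")
        frames.append(pair_series(obs, models[obs.meta.site_id], min_window_n=min_window_n))
    return PairedDataset(pd.concat(frames, ignore_index=True))


def exclude_spinup(ds: PairedDataset, cutoff=SPINUP_CUTOFF) -> PairedDataset:
    """Drop matchups before the spin-up cutoff (default 2011-01-01T00:00Z).

    Raw-comparison statistics use the full series; the Taylor and bias-GAM
    stages apply this exclusion.
    """
    cutoff = pd.Timestamp(cutoff)
    if cutoff.tz is None:
        cutoff = cutoff.tz_localize("UTC")
    return PairedDataset(ds.frame.loc[ds.frame["time"] >= cutoff])


def distance_to_shore(lat: float, lon: float,
                      coastline: np.ndarray) -> float:
    """Great-circle distance (m) from a site to the nearest vertex of a
    coastline polyline given as an (n, 2) array of (lat, lon) degrees."""
    coastline = np.asarray(coastline, dtype=float)
    d = great_circle_m(coastline[:, 0], coastline[:, 1], lat, lon)
    return float(np.min(d))
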