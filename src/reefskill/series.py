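"""Core containers: site metadata, temperature series, paired matchup datasets.

Temperatures are degrees Celsius throughout; all timestamps are UTC.
A :class:`TemperatureSeries` holds one logger or one model grid-cell/stratum
record.  A :class:`PairedDataset` holds the 3-hourly matchups (windowed
observation mean vs. model snapshot) that every downstream statistic consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("reefskill")

#: Calendar-quarter season labels keyed by month number.
SEASON_OF_MONTH = {
    1: "JFM", 2: "JFM", 3: "JFM",
    4: "AMJ", 5: "AMJ", 6: "AMJ",
    7: "JAS", 8: "JAS", 9: "JAS",
    10: "OND", 11: "OND", 12: "OND",
}

#: Plausible open-ocean/reef temperature range used for flagging, °C.
PLAUSIBLE_RANGE = (0.0, 40.0)

#: Columns of the tabular form of a paired dataset.
PAIR_COLUMNS = [
    "site_id", "island", "lat", "lon", "depth_m", "distance_to_shore_m",
    "time", "obs", "model", "n_obs_in_window", "year", "day_of_year", "season",
]


@dataclass
class SiteMeta:
    """Location and deployment metadata for one logger site."""

    site_id: str
    lat: float
    lon: float
    depth_m: float
    island: str = ""
    distance_to_shore_m: float = float("nan")

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be a non-empty token")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if self.depth_m <= 0:
            raise ValueError(f"depth_m must be positive, got {self.depth_m}")


def _as_utc_index(timestamps) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(timestamps)
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    else:
        idx = idx.tz_convert("UTC")
    return idx


@dataclass
class TemperatureSeries:
    """A timestamped temperature record for one site and depth.

    Parameters
    ----------
    meta : SiteMeta
    source : {"observed", "model"}
    data : pandas.Series
        Temperature in °C indexed by strictly increasing UTC timestamps.
    cadence_min : float
        Nominal sampling interval in minutes (5 or 30 for loggers, 180 for
        3-hourly model snapshots).
    provenance : object, optional
        For synthetic series, the generating configuration and realized
        noise; lets the degradation step rescale individual harmonics.
    """

    meta: SiteMeta
    source: str
    data: pd.Series
    cadence_min: float
    provenance: object = None

    def __post_init__(self) -> None:
        if self.source not in ("observed", "model"):
            raise ValueError(f"source must be 'observed' or 'model', got {self.source!r}")
        idx = _as_utc_index(self.data.index)
        values = np.asarray(self.data, dtype=float)
        if len(idx) != len(values):
            raise ValueError("timestamps and values differ in length")
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if len(idx) > 1 and idx.has_duplicates:
            raise ValueError("duplicate timestamps in series")
        finite = values[np.isfinite(values)]
        lo, hi = PLAUSIBLE_RANGE
        n_bad = int(np.sum((finite < lo) | (finite > hi)))
        if n_bad:
            logger.warning(
                "%s/%s: %d of %d values outside plausible range %s °C",
                self.meta.site_id, self.source, n_bad, len(values), PLAUSIBLE_RANGE,
            )
        self.data = pd.Series(values, index=idx, name="temperature")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def time_range(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.data.index[0], self.data.index[-1]


class PairedDataset:
    """The 3-hourly matchup table: one row per (site, snapshot time).

    ``obs`` is the windowed logger mean, ``model`` the co-located snapshot.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in PAIR_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"paired frame missing columns: {missing}")
        frame = frame.reset_index(drop=True).copy()
        frame["time"] = _as_utc_index(frame["time"])
        if frame.duplicated(subset=["site_id", "time"]).any():
            raise ValueError("duplicate (site_id, time) keys in paired dataset")
        self.frame = frame

    @property
    def n(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def obs(self) -> np.ndarray:
        return self.frame["obs"].to_numpy(dtype=float)

    @property
    def model(self) -> np.ndarray:
        return self.frame["model"].to_numpy(dtype=float)

    def subset(self, mask) -> "PairedDataset":
        return PairedDataset(self.frame.loc[np.asarray(mask)])

    @classmethod
    def concat(cls, parts: Iterable["PairedDataset"]) -> "PairedDataset":
        frames = [p.frame for p in parts]
        if not frames:
            raise ValueError("no paired datasets to concatenate")
        return cls(pd.concat(frames, ignore_index=True))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PairedDataset":
        frame = pd.read_csv(path, parse_dates=["time"])
        frame["island"] = frame["island"].fillna("").astype(str)
        return cls(frame)

    def __repr__(self) -> str:  # pragma: no cover
        sites = self.frame["site_id"].nunique()
        return f"PairedDataset(n={self.n}, sites={sites})"


def season_of(months: np.ndarray) -> np.ndarray:
    """Map month numbers to calendar-quarter season labels."""
    return np.array([SEASON_OF_MONTH[int(m)] for m in np.asarray(months)])
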