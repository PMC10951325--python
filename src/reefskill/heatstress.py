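"""Coral heat-stress metrics: climatological anomalies, detrended daily
temperatures, and biweekly mean/CV variability indices.

Each source (observed, model) is always referenced to its *own* climatology
and its own seasonal fit, so the comparison asks whether the model
reproduces the observed departures, not the observed absolute values.
The 14-day coefficient of variation (sd/mean over consecutive two-week
blocks, on °C) is the short-timescale variability index used as a bleaching
predictor at marginal heat stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pspline import fit_cyclic_smooth
from .series import PairedDataset, TemperatureSeries

#: Months of the peak bleaching window (July–October).
PEAK_BLEACHING_MONTHS = (7, 8, 9, 10)


@dataclass
class ClimatologyTable:
    """Long-term monthly means for one source over a baseline period."""

    source: str                    # "observed" | "model"
    baseline: tuple[int, int]      # (start_year, end_year), inclusive
    values: pd.Series              # index month 1..12, °C


@dataclass
class MetricComparison:
    """OLS comparison of a model-derived metric against the observed one."""

    metric: str
    slope: float
    intercept: float
    r_squared: float
    n: int


def _series_of(obj) -> tuple[pd.Series, str]:
    if isinstance(obj, TemperatureSeries):
        return obj.data, obj.source
    if isinstance(obj, pd.Series):
        return obj, str(obj.attrs.get("source", "observed"))
    raise TypeError("expected TemperatureSeries or pandas Series")


def monthly_climatology(series, baseline_years: tuple[int, int] = (2010, 2017),
                        source: str | None = None) -> ClimatologyTable:
    """Mean temperature per calendar month over the baseline years.

    Every calendar month must be represented at least once within the
    baseline, otherwise the climatology is undefined and an error lists the
    missing months.
    """
    data, src = _series_of(series)
    if source is not None:
        src = source
    y0, y1 = baseline_years
    in_base = (data.index.year >= y0) & (data.index.year <= y1)
    sub = data[in_base]
    clim = sub.groupby(sub.index.month).mean()
    missing = sorted(set(range(1, 13)) - set(clim.index))
    if missing:
        raise ValueError(f"no data in month(s) {missing} within baseline "
                         f"{baseline_years}; climatology undefined")
    clim = clim.reindex(range(1, 13))
    clim.index.name = "month"
    return ClimatologyTable(source=src, baseline=(y0, y1), values=clim)


def monthly_anomalies(series, clim: ClimatologyTable) -> pd.DataFrame:
    """Monthly mean minus the same-source climatology, one row per
    (year, month) present in the series."""
    data, src = _series_of(series)
    if src != clim.source:
        raise ValueError(f"source mismatch: series is {src!r} but "
                         f"climatology is {clim.source!r}")
    grp = data.groupby([data.index.year, data.index.month]).mean()
    years = grp.index.get_level_values(0).to_numpy()
    months = grp.index.get_level_values(1).to_numpy()
    anom = grp.to_numpy() - clim.values.loc[months].to_numpy()
    return pd.DataFrame({"source": src, "year": years, "month": months,
                         "anomaly": anom})


def daily_means(ds: PairedDataset, source: str, per_site: bool = False) -> pd.Series:
    """Daily mean temperature from the matchup table for one source.

    Default pools all matchups falling on a UTC day; ``per_site=True``
    averages site-day means so sites with denser records do not dominate.
    """
    col = {"observed": "obs", "model": "model"}[source]
    frame = ds.frame
    day = frame["time"].dt.normalize()
    if per_site:
        site_day = frame.groupby([frame["site_id"], day])[col].mean()
        out = site_day.groupby(level=1).mean()
    else:
        out = frame.groupby(day)[col].mean()
    out = out.sort_index()
    out.attrs["source"] = source
    return out


def seasonal_detrend(daily: pd.Series, k: int = 10) -> pd.Series:
    """Residuals of daily temperature about a cyclic day-of-year spline fit.

    The seasonal curve is a penalized cyclic cubic spline of temperature on
    day of year (continuous across the year boundary, REML-selected
    smoothness); residuals are observed − fitted.  Requires at least 180
    distinct days of year, else the cycle is unidentifiable.
    """
    daily = daily.dropna().sort_index()
    doy = daily.index.dayofyear.to_numpy(dtype=float)
    if len(np.unique(doy)) < 180:
        raise ValueError("fewer than 180 distinct days of year; "
                         "seasonal cycle unidentifiable")
    y = daily.to_numpy(dtype=float)
    _, predict = fit_cyclic_smooth(doy, y, k=k)
    fitted = predict(doy)
    resid = pd.Series(y - fitted, index=daily.index, name="detrended")
    tss = float(np.sum((y - y.mean()) ** 2))
    resid.attrs["r_squared"] = 1.0 - float(np.sum((y - fitted) ** 2)) / tss if tss else 0.0
    resid.attrs["source"] = daily.attrs.get("source", "observed")
    return resid


def biweekly_metrics(series, site_id: str | None = None) -> pd.DataFrame:
    """Mean and CV (sd/mean, on °C) over consecutive 14-day blocks.

    Blocks are non-overlapping and anchored at the series' first timestamp's
    date; a trailing block covering fewer than 7 distinct days of data is
    dropped.  Returns columns site_id, window_start, mean, cv, n_samples.
    """
    data, _ = _series_of(series)
    if site_id is None:
        site_id = series.meta.site_id if isinstance(series, TemperatureSeries) else ""
    data = data.dropna().sort_index()
    if len(data) == 0:
        return pd.DataFrame(columns=["site_id", "window_start", "mean", "cv",
                                     "n_samples"])
    anchor = data.index[0].normalize()
    block = ((data.index - anchor).days // 14).to_numpy()
    days = data.index.normalize()
    rows = []
    for b in np.unique(block):
        sel = block == b
        vals = data.to_numpy()[sel]
        rows.append({
            "site_id": site_id,
            "window_start": anchor + pd.Timedelta(days=14 * int(b)),
            "mean": float(vals.mean()),
            "cv": float(vals.std(ddof=1) / vals.mean()) if len(vals) > 1 else 0.0,
            "n_samples": int(len(vals)),
            "n_days": int(len(np.unique(days[sel]))),
        })
    out = pd.DataFrame(rows)
    if len(out) and out["n_days"].iloc[-1] < 7:
        out = out.iloc[:-1]
    return out.drop(columns=["n_days"]).reset_index(drop=True)


def biweekly_from_pairs(ds: PairedDataset, source: str,
                        months: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Biweekly windows for every site in a paired dataset.

    ``months`` restricts to a month subset (e.g. the July–October peak
    bleaching window) before windowing.
    """
    col = {"observed": "obs", "model": "model"}[source]
    frames = []
    for site, grp in ds.frame.groupby("site_id"):
        sub = grp
        if months is not None:
            sub = grp.loc[grp["time"].dt.month.isin(months)]
        if len(sub) == 0:
            continue
        s = pd.Series(sub[col].to_numpy(), index=pd.DatetimeIndex(sub["time"]))
        frames.append(biweekly_metrics(s, site_id=str(site)))
    if not frames:
        return pd.DataFrame(columns=["site_id", "window_start", "mean", "cv",
                                     "n_samples"])
    return pd.concat(frames, ignore_index=True)


def compare_metric(obs_windows: pd.DataFrame, model_windows: pd.DataFrame,
                   metric: str) -> MetricComparison:
    """OLS of the model metric on the observed metric over matched windows.

    Windows are matched on (site_id, window_start); ``metric`` is
    ``biweekly_mean`` or ``biweekly_cv``.
    """
    col = {"biweekly_mean": "mean", "biweekly_cv": "cv"}.get(metric)
    if col is None:
        raise ValueError("metric must be 'biweekly_mean' or 'biweekly_cv'")
    merged = obs_windows.merge(model_windows, on=["site_id", "window_start"],
                               suffixes=("_obs", "_model"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} matched windows; need >= 3")
    x = merged[f"{col}_obs"].to_numpy(dtype=float)
    y = merged[f"{col}_model"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("observed metric is constant; regression degenerate")
    res = stats.linregress(x, y)
    return MetricComparison(metric=metric, slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), n=len(merged))
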