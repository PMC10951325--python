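"""Additive bias surface: model-minus-observation error vs. space and time.

Fits bias = model − obs as a Gaussian additive model with the term types
used for this kind of skill decomposition: cubic regression splines for
depth and distance to shore, a cyclic cubic spline for day of year (so the
fitted seasonal error is continuous across the New Year), year as a
categorical block referenced to the earliest year, and an isotropic tensor
product of latitude and longitude for residual spatial structure.
Smoothness is selected by REML (see :mod:`reefskill.pspline`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairing import exclude_spinup
from .pspline import FittedAdditiveModel, SmoothSpec, fit_additive_model
from .series import PairedDataset

logger = logging.getLogger("reefskill")

#: Predictor name -> paired-dataset column for the univariate smooths.
SMOOTH_COLUMNS = {
    "depth": "depth_m",
    "distance": "distance_to_shore_m",
    "day_of_year": "day_of_year",
}


@dataclass
class PartialEffect:
    """Centered partial contribution of one predictor, with 95% bands."""

    predictor: str
    grid: np.ndarray
    effect: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid": self.grid, "effect": self.effect,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


@dataclass
class BiasModel:
    """Fitted additive bias model plus the metadata needed for reporting."""

    fit: FittedAdditiveModel
    intercept: float
    terms: list                       # smooth predictor names actually fitted
    year_levels: list                 # all years, baseline first
    year_effects: dict                # year -> offset °C (baseline 0)
    year_se: dict                     # year -> standard error (baseline 0)
    deviance_explained: float
    edf: dict
    p_values: dict
    ranges: dict = field(default_factory=dict)   # predictor -> (lo, hi)
    n: int = 0

    def summary(self) -> dict:
        return {
            "n": self.n,
            "intercept": self.intercept,
            "deviance_explained": self.deviance_explained,
            "terms": self.terms,
            "edf": self.edf,
            "approx_p_values": self.p_values,
            "year_effects": {str(k): v for k, v in self.year_effects.items()},
            "lambdas": self.fit.lambdas,
        }


def fit_bias_gam(
    ds: PairedDataset,
    k_univariate: int = 10,
    k_tensor: tuple[int, int] = (5, 5),
    apply_spinup: bool = True,
) -> BiasModel:
    """Fit the additive bias model on a paired dataset.

    The response is model − obs per matchup.  Smooth terms whose predictor
    has fewer than two distinct values (or is entirely missing) are dropped
    with a warning; rows with missing values in a used predictor are
    dropped.  Year requires at least two distinct years, otherwise the
    categorical block is dropped with a warning.
    """
    if apply_spinup:
        ds = exclude_spinup(ds)
    frame = ds.frame
    y = (frame["model"] - frame["obs"]).to_numpy(dtype=float)

    smooth_blocks, terms, ranges = [], [], {}
    use_cols = {}
    for name, col in SMOOTH_COLUMNS.items():
        vals = frame[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() == 0 or len(np.unique(vals[ok])) < 2:
            logger.warning("fit_bias_gam: dropping smooth '%s' "
                           "(missing or single-valued predictor)", name)
            continue
        use_cols[name] = col
    lat = frame["lat"].to_numpy(dtype=float)
    lon = frame["lon"].to_numpy(dtype=float)
    use_tensor = (len(np.unique(lat)) >= 2 and len(np.unique(lon)) >= 2)
    if not use_tensor:
        logger.warning("fit_bias_gam: dropping location tensor "
                       "(single latitude or longitude)")

    # drop rows with missing values in any used predictor
    keep = np.isfinite(y)
    for name, col in use_cols.items():
        keep &= np.isfinite(frame[col].to_numpy(dtype=float))
    frame = frame.loc[keep]
    y = y[keep]
    lat, lon = lat[keep], lon[keep]

    for name, col in use_cols.items():
        vals = frame[col].to_numpy(dtype=float)
        if name == "day_of_year":
            spec = SmoothSpec(name=name, kind="cyclic", k=k_univariate,
                              bounds=(1.0, 366.0), period=365.0)
            ranges[name] = (1.0, 366.0)
        else:
            lo, hi = float(vals.min()), float(vals.max())
            spec = SmoothSpec(name=name, kind="bs", k=k_univariate,
                              bounds=(lo, hi))
            ranges[name] = (lo, hi)
        smooth_blocks.append((spec, (vals,)))
        terms.append(name)
    if use_tensor:
        b1 = (float(lat.min()), float(lat.max()))
        b2 = (float(lon.min()), float(lon.max()))
        spec = SmoothSpec(name="location", kind="tensor", k=k_tensor,
                          bounds=(b1, b2))
        smooth_blocks.append((spec, (lat, lon)))
        terms.append("location")
        ranges["location"] = (b1, b2)

    years = np.sort(frame["year"].unique()).tolist()
    linear_blocks = [("intercept", np.ones((len(y), 1)))]
    if len(years) >= 2:
        dummies = np.column_stack([
            (frame["year"].to_numpy() == yr).astype(float) for yr in years[1:]
        ])
        linear_blocks.append(("year", dummies))
    else:
        logger.warning("fit_bias_gam: single year of data; "
                       "year block dropped")

    fit = fit_additive_model(y, linear_blocks, smooth_blocks)

    intercept = float(fit.block_beta("intercept")[0])
    year_effects = {years[0]: 0.0} if years else {}
    year_se = {years[0]: 0.0} if years else {}
    if "year" in fit.blocks and len(years) >= 2:
        b = fit.block_beta("year")
        se = np.sqrt(np.diag(fit.block_cov("year")))
        for yr, bb, ss in zip(years[1:], b, se):
            year_effects[int(yr)] = float(bb)
            year_se[int(yr)] = float(ss)

    return BiasModel(
        fit=fit, intercept=intercept, terms=terms,
        year_levels=[int(v) for v in years],
        year_effects=year_effects, year_se=year_se,
        deviance_explained=fit.deviance_explained,
        edf=fit.edf, p_values=fit.term_p_values, ranges=ranges, n=fit.n,
    )


def partial_effect(model: BiasModel, predictor: str,
                   grid=None, margin: float = 0.05) -> PartialEffect:
    """Centered partial contribution of one predictor with 95% bands.

    ``predictor`` is depth, distance, day_of_year or year.  Year returns the
    discrete offsets relative to the baseline (earliest) year.  For smooths,
    a grid outside the observed range by more than ``margin`` (as a fraction
    of the range) is refused.
    """
    if predictor == "year":
        years = model.year_levels
        eff = np.array([model.year_effects[y] for y in years])
        se = np.array([model.year_se[y] for y in years])
        return PartialEffect(predictor, np.array(years, dtype=float), eff,
                             eff - 1.96 * se, eff + 1.96 * se)
    if predictor not in model.terms:
        raise ValueError(f"predictor {predictor!r} not fitted "
                         f"(available: {model.terms + ['year']})")
    if predictor == "location":
        raise ValueError("use location_effect() for the lat-lon surface")
    lo, hi = model.ranges[predictor]
    if grid is None:
        grid = np.linspace(lo, hi, 200)
    grid = np.asarray(grid, dtype=float)
    if predictor != "day_of_year":
        slack = margin * (hi - lo)
        if grid.min() < lo - slack or grid.max() > hi + slack:
            raise ValueError(
                f"grid extends beyond observed range [{lo}, {hi}] "
                f"by more than the {margin:.0%} margin")
    f, low, high = model.fit.smooth_values(predictor, grid, with_ci=True)
    return PartialEffect(predictor, grid, f, low, high)


def location_effect(model: BiasModel, n_grid: int = 25) -> pd.DataFrame:
    """The fitted lat-lon tensor surface on a regular grid."""
    if "location" not in model.terms:
        raise ValueError("location tensor was not fitted")
    (lat_b, lon_b) = model.ranges["location"]
    lats = np.linspace(lat_b[0], lat_b[1], n_grid)
    lons = np.linspace(lon_b[0], lon_b[1], n_grid)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    f = model.fit.smooth_values("location", glat.ravel(), glon.ravel())
    return pd.DataFrame({"lat": glat.ravel(), "lon": glon.ravel(), "effect": f})


def deviance_explained(model: BiasModel) -> float:
    """1 − residual deviance / null deviance (Gaussian: 1 − RSS/TSS)."""
    return model.deviance_explained
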