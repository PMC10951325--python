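"""Model-skill statistics: agreement metrics, Deming regression, Taylor stats.

Conventions
-----------
* Differences are model − observation, so positive bias means a warm model.
* Sample (n−1) standard deviations are used throughout; the Taylor identity
  crmsd² = sd_m² + sd_o² − 2·sd_m·sd_o·r is then exact in the same convention.
* The Deming error-variance ratio λ is estimated from the data as
  (CV_model·mean_model)² / (CV_obs·mean_obs)², which reduces to the ratio of
  the two sample variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .series import PairedDataset
from .pairing import exclude_spinup


@dataclass
class SkillReport:
    """Pairwise agreement metrics for one stratum of matchups."""

    r: float          # Pearson correlation (NaN when either series is constant)
    bias: float       # mean(model − obs), °C
    mae: float        # mean |model − obs|, °C
    rmse: float       # sqrt(mean (model − obs)²), °C
    n: int
    group_key: Optional[str] = None


@dataclass
class DemingFit:
    """Errors-in-variables line model = alpha·obs + beta."""

    alpha: float
    beta: float
    lam: float        # error-variance ratio λ used for the fit
    n: int
    p_value: float    # slope ≠ 0, jackknife SE (see docs)
    se_alpha: float


@dataclass
class TaylorStat:
    """Centered pattern statistics for a Taylor diagram."""

    r: float
    sd_obs: float
    sd_model: float
    sd_ratio: float      # sd_model / sd_obs
    crmsd: float         # centered RMS difference, °C
    crmsd_norm: float    # crmsd / sd_obs


def _arrays(ds) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ds, PairedDataset):
        return ds.obs, ds.model
    obs, model = ds
    return np.asarray(obs, dtype=float), np.asarray(model, dtype=float)


def error_ratio_lambda(ds) -> float:
    """λ = (CV_model·mean_model)² / (CV_obs·mean_obs)² = var(model)/var(obs)."""
    obs, model = _arrays(ds)
    if len(obs) < 2:
        raise ValueError("need at least 2 pairs to estimate λ")
    v_obs = np.var(obs, ddof=1)
    if v_obs == 0:
        raise ValueError("observed series is constant; λ undefined")
    return float(np.var(model, ddof=1) / v_obs)


def _deming_alpha(s_oo, s_mm, s_om, lam):
    disc = (s_mm - lam * s_oo) ** 2 + 4.0 * lam * s_om**2
    return (s_mm - lam * s_oo + np.sqrt(disc)) / (2.0 * s_om)


def deming_fit(ds, lam: Optional[float] = None) -> DemingFit:
    """Deming regression of model on observation with error ratio λ.

    Minimizes the λ-weighted sum of squared distances in both variables;
    solved in closed form from the sample moments.  When ``lam`` is None it
    is estimated from the data via :func:`error_ratio_lambda`.  The slope
    standard error and p-value (slope = 0) come from a delete-one jackknife
    in which λ is re-estimated for every leave-one-out sample.
    """
    obs, model = _arrays(ds)
    n = len(obs)
    if n < 3:
        raise ValueError("need at least 3 pairs for a Deming fit")
    if lam is None:
        lam = error_ratio_lambda((obs, model))
        lam_fixed = False
    else:
        lam_fixed = True
    if lam <= 0:
        raise ValueError("λ must be positive")
    s_oo = np.var(obs, ddof=1)
    s_mm = np.var(model, ddof=1)
    s_om = np.cov(obs, model, ddof=1)[0, 1]
    if s_om == 0:
        raise ValueError("zero covariance between obs and model; slope undefined")
    alpha = _deming_alpha(s_oo, s_mm, s_om, lam)
    beta = model.mean() - alpha * obs.mean()

    # Delete-one jackknife via downdated sums (O(n)).
    So, Sm = obs.sum(), model.sum()
    Soo, Smm, Som = (obs**2).sum(), (model**2).sum(), (obs * model).sum()
    n1 = n - 1
    mo = (So - obs) / n1
    mm = (Sm - model) / n1
    s_oo_i = (Soo - obs**2 - n1 * mo**2) / (n1 - 1)
    s_mm_i = (Smm - model**2 - n1 * mm**2) / (n1 - 1)
    s_om_i = (Som - obs * model - n1 * mo * mm) / (n1 - 1)
    lam_i = np.full(n, lam) if lam_fixed else s_mm_i / s_oo_i
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_i = _deming_alpha(s_oo_i, s_mm_i, s_om_i, lam_i)
    alpha_i = alpha_i[np.isfinite(alpha_i)]
    k = len(alpha_i)
    se = float(np.sqrt((k - 1) / k * np.sum((alpha_i - alpha_i.mean()) ** 2)))
    if se > 0:
        p = float(2.0 * stats.t.sf(abs(alpha) / se, df=k - 1))
    else:
        p = 0.0 if alpha != 0 else 1.0
    return DemingFit(alpha=float(alpha), beta=float(beta), lam=float(lam),
                     n=n, p_value=p, se_alpha=se)


def skill_summary(ds, group_key: Optional[str] = None) -> SkillReport:
    """Correlation, bias, MAE and RMSE of model against observation."""
    obs, model = _arrays(ds)
    n = len(obs)
    if n < 1:
        raise ValueError("empty dataset")
    diff = model - obs
    bias = float(diff.mean())
    mae = float(np.abs(diff).mean())
    rmse = float(np.sqrt((diff**2).mean()))
    if n >= 2 and np.ptp(obs) > 0 and np.ptp(model) > 0:
        r = float(np.corrcoef(obs, model)[0, 1])
    else:
        r = float("nan")
    return SkillReport(r=r, bias=bias, mae=mae, rmse=rmse, n=n, group_key=group_key)


def taylor_stats(ds) -> TaylorStat:
    """Centered (mean-removed) pattern statistics for a Taylor diagram."""
    obs, model = _arrays(ds)
    if len(obs) < 2:
        raise ValueError("need at least 2 pairs for Taylor statistics")
    sd_o = float(np.std(obs, ddof=1))
    sd_m = float(np.std(model, ddof=1))
    if sd_o == 0:
        raise ValueError("observed series is constant; Taylor statistics undefined")
    do = obs - obs.mean()
    dm = model - model.mean()
    crmsd = float(np.sqrt(np.sum((dm - do) ** 2) / (len(obs) - 1)))
    r = float(np.corrcoef(obs, model)[0, 1]) if sd_m > 0 else float("nan")
    return TaylorStat(r=r, sd_obs=sd_o, sd_model=sd_m,
                      sd_ratio=sd_m / sd_o, crmsd=crmsd, crmsd_norm=crmsd / sd_o)


GROUPINGS = ("depth", "distance_band", "island", "season", "year")


def grouped_skill(ds: PairedDataset, grouping: str,
                  min_n: int = 10,
                  distance_edges=None,
                  apply_spinup: bool = True) -> pd.DataFrame:
    """Per-group skill and Taylor statistics.

    ``grouping`` is one of depth, distance_band, island, season or year.
    Distance bands default to quartiles of distance-to-shore unless explicit
    ``distance_edges`` are given.  Spin-up matchups are excluded first (the
    grouped/Taylor stage convention); pass ``apply_spinup=False`` to keep
    them.  Groups with fewer than ``min_n`` matchups are flagged.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")
    if apply_spinup:
        ds = exclude_spinup(ds)
    frame = ds.frame
    if grouping == "depth":
        keys = frame["depth_m"]
    elif grouping == "distance_band":
        dist = frame["distance_to_shore_m"]
        if dist.isna().all():
            raise ValueError("distance_to_shore_m missing from metadata")
        if distance_edges is None:
            keys = pd.qcut(dist, 4, duplicates="drop")
        else:
            keys = pd.cut(dist, bins=distance_edges, include_lowest=True)
        keys = keys.astype(str)
    else:
        keys = frame[grouping]

    rows = []
    for key, grp in frame.groupby(keys, sort=True, observed=True):
        pair = (grp["obs"].to_numpy(), grp["model"].to_numpy())
        rep = skill_summary(pair, group_key=str(key))
        tay = taylor_stats(pair) if len(grp) >= 2 and grp["obs"].nunique() > 1 else None
        rows.append({
            "group": str(key), "n": rep.n, "r": rep.r, "bias": rep.bias,
            "mae": rep.mae, "rmse": rep.rmse,
            "sd_obs": tay.sd_obs if tay else np.nan,
            "sd_model": tay.sd_model if tay else np.nan,
            "sd_ratio": tay.sd_ratio if tay else np.nan,
            "crmsd": tay.crmsd if tay else np.nan,
            "crmsd_norm": tay.crmsd_norm if tay else np.nan,
            "small_sample": rep.n < min_n,
        })
    return pd.DataFrame(rows)


def taylor_coordinates(table: pd.DataFrame) -> pd.DataFrame:
    """Polar → Cartesian coordinates for drawing a normalized Taylor diagram.

    x = sd_ratio·r, y = sd_ratio·sin(arccos r); the reference point is (1, 0).
    """
    r = table["r"].to_numpy(dtype=float)
    s = table["sd_ratio"].to_numpy(dtype=float)
    out = table[["group", "n", "r", "sd_ratio", "crmsd_norm"]].copy()
    out["x"] = s * r
    out["y"] = s * np.sin(np.arccos(np.clip(r, -1.0, 1.0)))
    return out
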