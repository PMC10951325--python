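"""Synthetic paired reef-temperature data with known, injectable model errors.

Generates a high-frequency "truth" series per site — annual, diurnal and
tidal harmonics over an AR(1)+white noise background, emulating a fixed
subsurface temperature logger — and degrades it into a co-located "model"
series of instantaneous 3-hourly snapshots with configurable constant bias,
seasonal bias, high-frequency variance attenuation and extra noise.  Because
every error is injected with a known value, the downstream statistics can be
tested by parameter recovery.

The degradation step deliberately subsamples (it never averages): gridded
reanalysis archives store snapshots of the state, so short-lived events such
as internal-bore cooling pulses present in the truth can fall between
snapshots.  Optional bore pulses (off by default) exist to demonstrate this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .series import SiteMeta, TemperatureSeries

#: Reference instant for harmonic phases; co-located series share it so that
#: a harmonic has identical phase in truth and model.
EPOCH = pd.Timestamp("2000-01-01T00:00:00Z")

#: Mean length of the tropical year in hours (365.25 d); used as the
#: "annual harmonic" period so the seasonal cycle has closed-form variance.
ANNUAL_PERIOD_H = 8766.0

#: Principal lunar semidiurnal (M2) tidal period, hours.
M2_PERIOD_H = 12.42


@dataclass(frozen=True)
class HarmonicComponent:
    """One sinusoidal component: A·cos(2π t / T + φ), t in hours."""

    period_hours: float
    amplitude: float
    phase: float = 0.0

    def __post_init__(self):
        if self.period_hours <= 0:
            raise ValueError(f"period_hours must be positive, got {self.period_hours}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
        object.__setattr__(self, "phase", float(self.phase) % (2.0 * np.pi))


def default_harmonics(
    annual_amp: float = 1.8,
    diurnal_amp: float = 0.15,
    m2_amp: float = 0.25,
    s2_amp: float = 0.10,
    o1_amp: float = 0.08,
) -> list[HarmonicComponent]:
    """Annual + diurnal + the dominant tidal constituents (M2, S2, O1).

    Amplitudes default to values typical of shallow Hawaiian reef sites:
    ~1.8 °C seasonal half-range and tenths-of-a-degree diurnal/tidal bands,
    the bands in which observed reef spectra peak.
    """
    return [
        HarmonicComponent(ANNUAL_PERIOD_H, annual_amp, 0.0),
        HarmonicComponent(24.0, diurnal_amp, 0.7),
        HarmonicComponent(M2_PERIOD_H, m2_amp, 1.3),
        HarmonicComponent(12.0, s2_amp, 2.1),
        HarmonicComponent(25.82, o1_amp, 4.0),
    ]


@dataclass
class SyntheticSiteConfig:
    """Configuration of one synthetic logger site.

    ``noise_sd`` is white instrument/environment noise; ``rednoise_sd`` and
    ``rednoise_rho`` set a stationary AR(1) background (marginal sd and
    lag-one coefficient at the sampling cadence) providing the red
    low-frequency continuum real reef spectra show.  Bore pulses are
    negative half-sine cooling events at ``bore_rate_per_day`` (0 disables).
    """

    site_id: str
    lat: float
    lon: float
    depth_m: float
    start: str | pd.Timestamp
    end: str | pd.Timestamp
    mean_temp: float = 25.5
    harmonics: Sequence[HarmonicComponent] = field(default_factory=default_harmonics)
    noise_sd: float = 0.05
    rednoise_sd: float = 0.20
    rednoise_rho: float = 0.98
    sample_interval_min: int = 5
    island: str = ""
    distance_to_shore_m: float = float("nan")
    bore_rate_per_day: float = 0.0
    bore_amp: float = 1.0
    bore_duration_h: float = 2.0

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.start.tz is None:
            self.start = self.start.tz_localize("UTC")
        if self.end.tz is None:
            self.end = self.end.tz_localize("UTC")
        if self.end <= self.start:
            raise ValueError("end must be after start")
        if self.sample_interval_min not in (5, 30):
            raise ValueError("sample_interval_min must be 5 or 30")
        if self.noise_sd < 0 or self.rednoise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0.0 <= self.rednoise_rho < 1.0:
            raise ValueError("rednoise_rho must be in [0, 1)")
        self.harmonics = [
            h if isinstance(h, HarmonicComponent) else HarmonicComponent(**h)
            for h in self.harmonics
        ]

    def meta(self) -> SiteMeta:
        return SiteMeta(
            site_id=self.site_id, lat=self.lat, lon=self.lon,
            depth_m=self.depth_m, island=self.island,
            distance_to_shore_m=self.distance_to_shore_m,
        )


@dataclass
class ModelErrorConfig:
    """Errors injected when degrading truth into a model-like series.

    ``hf_attenuation`` multiplies the amplitude of every harmonic whose
    period is shorter than ``attenuation_cutoff_hours`` (1 = no attenuation),
    emulating a model that underrepresents energy in the sub-daily bands.
    The seasonal bias is ``amp·sin(2π·(day of year)/365.2425 + phase)``.
    """

    constant_bias: float = 0.0
    seasonal_bias_amp: float = 0.0
    seasonal_bias_phase: float = 0.0
    hf_attenuation: float = 1.0
    attenuation_cutoff_hours: float = 30.0
    extra_noise_sd: float = 0.0
    snapshot_interval_hours: float = 3.0

    def __post_init__(self):
        if not 0.0 <= self.hf_attenuation <= 1.0:
            raise ValueError("hf_attenuation must be in [0, 1]")
        if self.snapshot_interval_hours <= 0:
            raise ValueError("snapshot_interval_hours must be positive")
        if self.extra_noise_sd < 0:
            raise ValueError("extra_noise_sd must be non-negative")


@dataclass
class SyntheticProvenance:
    """Attached to generated truth series so degradation can rescale the
    deterministic harmonics while reusing the realized stochastic part."""

    config: SyntheticSiteConfig
    residual: np.ndarray  # realized AR(1)+white+bore component, °C


def _hours_since_epoch(index: pd.DatetimeIndex) -> np.ndarray:
    return (index - EPOCH).total_seconds().to_numpy() / 3600.0


def _harmonic_sum(t_hours: np.ndarray, harmonics, scale=None) -> np.ndarray:
    out = np.zeros_like(t_hours, dtype=float)
    for k, h in enumerate(harmonics):
        a = h.amplitude * (1.0 if scale is None else scale[k])
        if a != 0.0:
            out += a * np.cos(2.0 * np.pi * t_hours / h.period_hours + h.phase)
    return out


def _ar1(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) sample with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -rho], eps, zi=[rho * x0])
    return out


def _bore_pulses(index: pd.DatetimeIndex, cfg: SyntheticSiteConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Negative half-sine cooling pulses at Poisson-distributed times."""
    out = np.zeros(len(index))
    if cfg.bore_rate_per_day <= 0 or len(index) == 0:
        return out
    t_h = _hours_since_epoch(index)
    span_days = (t_h[-1] - t_h[0]) / 24.0
    n_events = rng.poisson(cfg.bore_rate_per_day * span_days)
    starts = rng.uniform(t_h[0], t_h[-1], size=n_events)
    depths = cfg.bore_amp * rng.uniform(0.5, 1.0, size=n_events)
    for t0, d in zip(starts, depths):
        u = (t_h - t0) / cfg.bore_duration_h
        in_pulse = (u >= 0.0) & (u <= 1.0)
        out[in_pulse] -= d * np.sin(np.pi * u[in_pulse])
    return out


def generate_true_series(config: SyntheticSiteConfig, seed) -> TemperatureSeries:
    """Simulate the high-frequency "truth" record a logger would observe.

    value(t) = mean + Σ_k A_k cos(2π t/T_k + φ_k) + AR(1) + white noise
    (+ optional bore pulses), sampled every ``sample_interval_min`` minutes
    over [start, end).  Deterministic given (config, seed).
    """
    index = pd.date_range(config.start, config.end,
                          freq=f"{config.sample_interval_min}min",
                          inclusive="left")
    if len(index) == 0:
        raise ValueError("time range shorter than one sampling interval")
    rng = np.random.default_rng(seed)
    t_h = _hours_since_epoch(index)
    det = config.mean_temp + _harmonic_sum(t_h, config.harmonics)
    residual = (
        _ar1(len(index), config.rednoise_sd, config.rednoise_rho, rng)
        + (rng.normal(0.0, config.noise_sd, size=len(index))
           if config.noise_sd > 0 else 0.0)
        + _bore_pulses(index, config, rng)
    )
    data = pd.Series(det + residual, index=index)
    return TemperatureSeries(
        meta=config.meta(), source="observed", data=data,
        cadence_min=config.sample_interval_min,
        provenance=SyntheticProvenance(config=config, residual=residual),
    )


def seasonal_bias(index: pd.DatetimeIndex, err: ModelErrorConfig) -> np.ndarray:
    """The injected day-of-year bias: amp·sin(2π·doy/365.2425 + phase)."""
    doy = (index.dayofyear - 1
           + (index - index.normalize()).total_seconds() / 86400.0)
    return err.seasonal_bias_amp * np.sin(
        2.0 * np.pi * np.asarray(doy) / 365.2425 + err.seasonal_bias_phase)


def degrade_to_model(truth: TemperatureSeries, err: ModelErrorConfig, seed) -> TemperatureSeries:
    """Turn a synthetic truth series into a co-located "model" series.

    Instantaneous snapshots every ``snapshot_interval_hours`` (no window
    averaging).  Harmonics with period below the attenuation cutoff are
    rescaled by ``hf_attenuation`` *before* sampling; the realized noise of
    the truth is carried through at the snapshot instants so that a
    zero-error configuration reproduces the truth exactly at those instants.
    """
    prov = truth.provenance
    if not isinstance(prov, SyntheticProvenance):
        raise TypeError("degrade_to_model requires a series from generate_true_series")
    cfg = prov.config
    step_min = err.snapshot_interval_hours * 60.0
    if step_min % cfg.sample_interval_min != 0:
        raise ValueError("truth cadence does not divide the snapshot interval")
    step = int(step_min // cfg.sample_interval_min)
    span_min = (truth.timestamps[-1] - truth.timestamps[0]).total_seconds() / 60.0
    if span_min < step_min:
        raise ValueError("truth series too short for a single snapshot interval")
    idx = np.arange(0, len(truth), step)
    index = truth.timestamps[idx]
    t_h = _hours_since_epoch(index)
    scale = [
        err.hf_attenuation if h.period_hours < err.attenuation_cutoff_hours else 1.0
        for h in cfg.harmonics
    ]
    det = cfg.mean_temp + _harmonic_sum(t_h, cfg.harmonics, scale=scale)
    seasonal = seasonal_bias(index, err)
    rng = np.random.default_rng(seed)
    noise = (rng.normal(0.0, err.extra_noise_sd, size=len(idx))
             if err.extra_noise_sd > 0 else 0.0)
    values = det + prov.residual[idx] + err.constant_bias + seasonal + noise
    return TemperatureSeries(
        meta=cfg.meta(), source="model",
        data=pd.Series(values, index=index),
        cadence_min=err.snapshot_interval_hours * 60.0,
    )


def make_paired_dataset(
    site_configs: Sequence[SyntheticSiteConfig],
    err: ModelErrorConfig,
    seed,
) -> tuple[list[TemperatureSeries], list[TemperatureSeries]]:
    """Generate one (truth, model) series pair per site.

    Per-site sub-seeds are spawned from the master seed, so adding or
    reordering sites never perturbs another site's realization order within
    the returned lists.
    """
    if len(site_configs) == 0:
        raise ValueError("need at least one site configuration")
    ids = [c.site_id for c in site_configs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate site_id(s): {dupes}")
    children = np.random.SeedSequence(seed).spawn(len(site_configs))
    obs_list, model_list = [], []
    for cfg, child in zip(site_configs, children):
        truth_seed, model_seed = child.spawn(2)
        truth = generate_true_series(cfg, truth_seed)
        model = degrade_to_model(truth, err, model_seed)
        obs_list.append(truth)
        model_list.append(model)
    return obs_list, model_list


def write_series_csv(series_list: Sequence[TemperatureSeries], path) -> None:
    """Write series in the tabledap-style CSV layout the ingest module reads."""
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "site_id": s.meta.site_id,
            "latitude": s.meta.lat,
            "longitude": s.meta.lon,
            "depth": s.meta.depth_m,
            "island": s.meta.island,
            "distance_to_shore_m": s.meta.distance_to_shore_m,
            "time": s.timestamps.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "temperature": s.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
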