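"""Periodogram estimation with Daniell-kernel smoothing.

The raw periodogram is computed by FFT after mean removal, scaled so that
the area under the one-sided density equals the series variance (the ×2
one-sided convention), with the frequency axis converted to cycles per hour
by dividing the per-sample frequency by the sampling interval.  Smoothing
uses iterated *modified* Daniell kernels (centered moving averages with
half-weight endpoints); edge bins are handled by whole-sample reflection,
which conserves total area exactly.

For 3-hourly snapshot archives the Nyquist limit is 1/6 cycles per hour, so
no period shorter than 6 h is resolvable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .series import PairedDataset, TemperatureSeries

logger = logging.getLogger("reefskill")


@dataclass
class Spectrum:
    """One-sided, variance-scaled power spectral density."""

    frequency: np.ndarray      # cycles per hour, strictly increasing
    density: np.ndarray        # °C² per cycle-per-hour (×2 one-sided scaling)
    n: int                     # series length used
    dt_hours: float            # sampling interval
    variance: float            # series variance (mean-removed, 1/n convention)
    spans: tuple = ()          # Daniell spans applied, in application order
    detrended: bool = False
    interpolated_gaps: int = 0

    @property
    def period_hours(self) -> np.ndarray:
        return 1.0 / self.frequency

    def area(self) -> float:
        """Integral of density over frequency (== variance for the raw
        periodogram, conserved by smoothing)."""
        df = self.frequency[1] - self.frequency[0] if len(self.frequency) > 1 else 0.0
        return float(np.sum(self.density) * df)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_cph": self.frequency,
                             "period_hours": self.period_hours,
                             "density": self.density})


def _regularize(data: pd.Series, gap_limit_hours: float):
    """Return (values, dt_hours, n_filled) on a regular grid.

    Gaps up to ``gap_limit_hours`` are filled by linear interpolation (and
    counted); longer gaps raise.
    """
    idx = data.index
    diffs_h = np.diff(idx.asi8) / 3.6e12
    dt = float(np.median(diffs_h))
    if dt <= 0:
        raise ValueError("cannot infer a positive cadence")
    if np.max(diffs_h) > gap_limit_hours:
        raise ValueError(
            f"gap of {np.max(diffs_h):.1f} h exceeds the {gap_limit_hours} h "
            "interpolation limit; split the series at long gaps first")
    off_grid = np.abs(diffs_h / dt - np.round(diffs_h / dt)) > 1e-6
    if off_grid.any():
        raise ValueError("irregular cadence beyond tolerance")
    full = pd.date_range(idx[0], idx[-1], freq=pd.Timedelta(hours=dt))
    aligned = data.reindex(full)
    n_filled = int(aligned.isna().sum())
    if n_filled:
        logger.info("periodogram: linearly interpolating %d missing samples", n_filled)
        aligned = aligned.interpolate(method="time")
    return aligned.to_numpy(dtype=float), dt, n_filled


def periodogram(series, gap_limit_hours: float = 24.0,
                taper: bool = False) -> Spectrum:
    """Raw one-sided periodogram of a regularly sampled temperature series.

    The mean is removed; density is scaled ×2 (one-sided) so its integral
    over frequency equals the series variance; frequencies are cycles per
    hour (per-sample frequency divided by the sampling interval).  An
    optional 10% split-cosine taper is available; off by default.
    """
    data, _ = (series.data, None) if isinstance(series, TemperatureSeries) \
        else (series, None)
    if len(data) < 4:
        raise ValueError("series too short for a periodogram")
    x, dt, n_filled = _regularize(data.dropna(), gap_limit_hours)
    n = len(x)
    x = x - x.mean()
    variance = float(np.mean(x**2))
    if taper:
        w = signal.windows.tukey(n, alpha=0.1)
        x = x * w
        norm = np.mean(w**2)
    else:
        norm = 1.0
    X = np.fft.rfft(x)
    k = np.arange(1, len(X))
    freq = k / (n * dt)                       # cycles per hour
    power = np.abs(X[1:])**2
    density = 2.0 * dt * power / (n * norm)
    if n % 2 == 0:
        density[-1] /= 2.0                     # Nyquist bin is not doubled
    return Spectrum(frequency=freq, density=density, n=n, dt_hours=dt,
                    variance=variance, detrended=True,
                    interpolated_gaps=n_filled)


def _modified_daniell_kernel(span: int) -> np.ndarray:
    """Modified Daniell kernel of odd width ``span`` (half-weight endpoints)."""
    if span % 2 == 0 or span < 1:
        raise ValueError(f"spans must be odd and >= 1, got {span}")
    m = span // 2
    if m == 0:
        return np.array([1.0])
    w = np.full(2 * m + 1, 1.0 / (2 * m))
    w[0] = w[-1] = 1.0 / (4 * m)
    return w


def smooth_daniell(spec: Spectrum, spans: Sequence[int] = (9, 9)) -> Spectrum:
    """Smooth a periodogram with iterated modified Daniell kernels.

    ``spans`` are odd window widths applied in sequence (their kernels are
    convolved into one).  Endpoints are handled by whole-sample reflection,
    so the total area under the density is conserved exactly.
    """
    kernel = np.array([1.0])
    for s in spans:
        kernel = np.convolve(kernel, _modified_daniell_kernel(int(s)))
    half = len(kernel) // 2
    if half == 0:
        return replace(spec, spans=tuple(spec.spans) + tuple(spans))
    padded = np.pad(spec.density, half, mode="symmetric")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return replace(spec, density=smoothed,
                   spans=tuple(spec.spans) + tuple(int(s) for s in spans))


def find_peaks(spec: Spectrum, min_prominence: float | None = None
               ) -> list[tuple[float, float]]:
    """Local density maxima as (period_hours, density), densest first.

    ``min_prominence`` is in density units.  The default is 10× the median
    density, which tracks the continuum level of red reef spectra better
    than a fraction of the (annual-cycle-dominated) maximum; for spectra
    with negligible continuum it falls back to 1% of the maximum.  A flat
    spectrum yields no peaks regardless.
    """
    d = spec.density
    if len(d) == 0 or np.ptp(d) == 0:
        return []
    if min_prominence is None:
        med = float(np.median(d))
        min_prominence = 10.0 * med if med > 0 else 0.01 * float(d.max())
    idx, _ = signal.find_peaks(d, prominence=min_prominence)
    peaks = [(float(1.0 / spec.frequency[i]), float(d[i])) for i in idx]
    return sorted(peaks, key=lambda p: -p[1])


def spectrum_from_pairs(ds: PairedDataset, source: str,
                        spans: Sequence[int] = (9, 9),
                        gap_limit_hours: float = 24.0) -> Spectrum:
    """Average smoothed spectrum across the sites of a paired dataset.

    Each site's 3-hourly matchup series gets its own periodogram; densities
    are interpolated onto the frequency grid of the longest series and
    averaged, then smoothed.
    """
    col = {"observed": "obs", "model": "model"}[source]
    specs = []
    for site, grp in ds.frame.groupby("site_id"):
        s = pd.Series(grp[col].to_numpy(), index=pd.DatetimeIndex(grp["time"]))
        try:
            specs.append(periodogram(s, gap_limit_hours=gap_limit_hours))
        except ValueError as exc:
            logger.warning("spectrum_from_pairs: skipping %s (%s)", site, exc)
    if not specs:
        raise ValueError("no site yielded a periodogram")
    ref = max(specs, key=lambda s: s.n)
    acc = np.zeros_like(ref.density)
    for s in specs:
        acc += np.interp(ref.frequency, s.frequency, s.density)
    avg = replace(ref, density=acc / len(specs),
                  variance=float(np.mean([s.variance for s in specs])))
    return smooth_daniell(avg, spans)
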