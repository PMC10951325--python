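# Methods

`reefskill` quantifies how well a gridded, data-assimilative ocean
reanalysis — archived as instantaneous 3-hourly temperature snapshots on
fixed depth strata — reproduces the water temperatures that fixed subsurface
loggers record on coral reefs, and whether the reanalysis can stand in for
loggers when computing the heat-stress metrics used in bleaching monitoring.
This note documents the models, conventions and numerical choices behind
each stage, and what the synthetic test bed does and does not demonstrate.

## The synthetic paired archive

Real validation archives are multi-gigabyte server extracts; the package
therefore ships a generator that reproduces the *statistical structure* of
the problem at desk scale with known injected errors, so that every
downstream statistic can be tested by parameter recovery.

Truth (logger) series per site:

    T(t) = μ + Σ_k A_k cos(2π t / P_k + φ_k) + ε_AR(t) + ε_w(t)

* Harmonics default to the observed peak bands: annual (8766 h), diurnal
  (24 h), M2 (12.42 h), S2 (12 h) and O1 (25.82 h). The annual cycle is a
  harmonic rather than a spline so its variance (A²/2) is closed-form for
  tests. Default amplitudes are typical shallow Hawaiian-reef values
  (≈1.8 °C annual, tenths of a degree in the diurnal/tidal bands); the
  study conditions draw tidal/diurnal amplitudes per site from realistic
  ranges (M2 0.1–0.5 °C, diurnal 0.05–0.3 °C) because internal-tide energy
  varies strongly between reef sites — and because several qualitative
  findings (see biweekly CV below) only arise when it does.
* ε_AR is stationary AR(1) at the sampling cadence (default marginal sd
  0.20 °C, lag-one coefficient 0.98 at 5 min), the simplest process giving
  the red low-frequency continuum reef spectra show. ε_w is white
  (default 0.05 °C). Both defaults are free parameters, not estimates of
  any instrument: the loggers themselves are accurate to ±0.002 °C, so the
  "noise" here stands for unmodeled environmental variability.
* Optional internal-bore cooling events (negative half-sine pulses at a
  Poisson rate, off by default) exist to demonstrate that instantaneous
  3-hourly snapshots miss short-lived cold events; nothing else uses them.

The model-like series is an instantaneous subsample (never an average)
every 3 h, with four injectable errors: a constant bias; a day-of-year
sinusoidal bias; amplitude attenuation of every harmonic with period below
a cutoff (default 30 h), emulating under-resolved sub-daily energy; and
extra white noise. The truth's realized noise is carried through at the
snapshot instants, so a zero-error configuration reproduces the truth
exactly there — which is what makes injected-bias recovery an exact test.

What the generator does *not* emulate: spatial covariance between sites,
instrument drift and biofouling, episodic gaps other than those a test
constructs, and any actual ocean dynamics. Passing recovery tests therefore
demonstrates the correctness of the statistics, not the skill of any real
reanalysis.

## Pairing

Loggers sample every 5 min (some recovered deployments, every 30 min); the
archive stores 3-hourly snapshots. Logger values are averaged in a window
centered on each snapshot: ±10 min for 5-min records and ±1 h for 30-min
records, endpoints inclusive — five logger samples per matchup when the
record is gap-free. Matchups are emitted only inside the overlap of the two
series; windows with fewer samples than a threshold (default 3) are
dropped, and the per-window count is kept for auditing. Matchups before
2011-01-01 (reanalysis spin-up) are excluded from the Taylor and bias-GAM
stages but kept in the raw comparison, matching standard practice of
evaluating the full record while restricting structural analyses to the
equilibrated period. Deployment depths map to the nearest model stratum,
ties to the shallower one; grid cells are chosen by great-circle distance,
ties to the lower index. All timestamps are UTC.

## Agreement statistics

With model value M_i and windowed observation O_i over n matchups:

* r (Pearson), bias = mean(M − O), MAE = mean|M − O|,
  RMSE = √mean((M − O)²); positive bias means a warm model.
* Taylor statistics: sample (n−1) standard deviations, the ratio
  sd_M/sd_O, and the centered RMS difference computed in the same
  convention, so crmsd² = sd_M² + sd_O² − 2·sd_M·sd_O·r is an identity
  (tested to 1e−9 relative). Normalization divides by the observed sd of
  the same group.
* Deming regression M = αO + β with error-variance ratio
  λ = var(M)/var(O) (the CV-based definition reduces to this). The slope
  is the closed-form root of the moment quadratic:

      α = [s_MM − λ s_OO + √((s_MM − λ s_OO)² + 4 λ s_OM²)] / (2 s_OM)

  λ = 1 is orthogonal regression; λ → ∞/0 recover the two OLS limits
  (both verified against independent oracles). λ is estimated once from
  the full paired set before any grouping. The slope's standard error and
  p-value come from a delete-one jackknife in which λ is re-estimated per
  leave-one-out sample, computed in O(n) by moment downdates; this is a
  package choice, made because the jackknife needs no distributional
  assumptions about either error term.

Grouped reports (depth, distance band, island, season, year) flag groups
under a minimum n (default 10). Distance bands default to quartiles.

## The additive bias model

Bias (M − O) is modeled as a Gaussian additive model: cubic regression
splines in depth and distance to shore (10 basis functions), a cyclic cubic
spline in day of year, year as a categorical block referenced to the
earliest year, and a tensor product of latitude and longitude (5×5) with a
single isotropic smoothing parameter so neither direction is favored.
The engine is penalized least squares over B-spline bases with second-order
difference (P-spline) penalties; the cyclic basis wraps uniform B-splines
so the fit is C² across the year boundary, with day 366 identified with
day 1 (hence f(1) = f(366) exactly). Smoothing parameters maximize the
restricted likelihood (REML), profiled over the error variance and
optimized over log-λ by Nelder–Mead; each evaluation is O(p³) on
precomputed moments, so fits at n ≈ 10⁵ take well under a second.

Identifiability: every smooth carries a sum-to-zero constraint over the
training data, which defines the intercept and centers the partial effects.
A 1e−7 proportional ridge inside each penalty block keeps the system
well-posed when the site geometry cannot identify the tensor term's
bilinear null space (few or collinear sites) — at that scale it is
numerically invisible in identifiable directions. With five or fewer sites
the spatial terms (depth, distance, location) are mutually confounded no
matter the method, since any of them can interpolate the per-site offsets;
recovery tests use ≥8 scattered sites for this reason, and real-archive
fits should treat spatial partials from sparse networks with the same
caution. Partial effects come with pointwise 95% bands from the Bayesian
posterior covariance σ²(X'X + S_λ)⁻¹; grids extending beyond the observed
predictor range by more than a configurable margin (default 5%) are
refused. Per-term Wald p-values are reported for orientation only.
Deviance explained is 1 − RSS/TSS. The cyclic smoother is cross-checked
against R mgcv (REML, cyclic cubic spline) in the test suite.

## Heat-stress metrics

Each source is always referenced to itself: observed anomalies use the
observed climatology, model anomalies the model climatology, so the
comparison isolates departures rather than absolute offsets.

* Monthly climatology: mean per calendar month over a baseline (default
  2010–2017); anomalies are monthly means minus the same-source
  climatology. An empty month in the baseline is an error.
* Daily detrending: daily means (pooled across sites by default; per-site
  mode averages site-day means) are fit by the cyclic day-of-year smoother
  and the residuals are the detrended temperatures. Fewer than 180
  distinct days of year is an error (the cycle is unidentifiable).
* Biweekly variability: consecutive non-overlapping 14-day blocks anchored
  at the series start; per block the mean and CV = sd/mean (on °C —
  scale-dependent, following field usage). A trailing block with under 7
  days of data is dropped. Non-overlapping blocks were chosen over a
  rolling window to keep the obs-vs-model comparison regressions free of
  induced autocorrelation; a rolling variant can be built from the same
  primitives. The peak-bleaching subset is the month filter {7, 8, 9, 10}.
* Comparisons are OLS of the model metric on the observed metric over
  windows matched by (site, window start).

A structural point the synthetic experiments expose: snapshot archives
underestimate biweekly CV only in the regression-slope sense when windows
differ in how much high-frequency energy they contain. If every window lost
the same variance the slope would exceed 1 (cv_m = √(cv_o² − c) steepens),
even though every model CV is individually too low.

## Spectra

Raw periodograms are computed by FFT after mean removal (no taper by
default; an optional 10% split-cosine taper renormalizes power). The
one-sided density is scaled ×2 and the frequency axis expressed in cycles
per hour (per-sample frequency divided by the sampling interval), so the
integral of density over frequency equals the series variance exactly
(Nyquist bin handled; tested to 2% on all synthetic inputs and to machine
precision on gap-free ones). Smoothing uses iterated modified Daniell
kernels — centered moving averages with half-weight endpoints — with edge
bins handled by whole-sample reflection, which conserves total area
exactly; default spans are [9, 9] and always recorded on the output.
Gaps up to 24 h are linearly interpolated and counted; longer gaps are an
error at the single-series level (split the series instead — silently
averaging unequal segment grids would corrupt the variance bookkeeping),
while the cross-site average in `spectrum_from_pairs` interpolates per-site
spectra onto the longest grid. Peak reporting returns local maxima above a
prominence threshold, by default 10× the median density: red reef spectra
are dominated by the annual peak, so a max-relative threshold would hide
the tidal band. For 3-hourly data nothing below a 6 h period is resolvable.

## Problem sizes

The recovery studies run at 25 sites × 1 year of 5-min truth
(≈2.6 M truth samples, 73 000 matchups) for the skill stage, 8 sites ×
3 years of 30-min truth (≈70 000 matchups) for the additive model, and a
10 000-matchup null for the penalization check — sizes at which every
Monte-Carlo tolerance in the test suite holds with margin while the whole
suite runs in well under a minute.

## Known limitations

* The Deming p-value method is a package choice (jackknife); other
  implementations may report likelihood- or bootstrap-based values.
* Tensor-product smoothing is isotropic in (lat, lon) degrees, not meters;
  at Hawaiian latitudes a degree of longitude is ≈6% shorter than one of
  latitude, a distortion far below the smooth's resolution.
* Biweekly windows are anchored at each series' start, so two archives
  starting on different dates window differently.
* `distance_to_shore` is taken from metadata when present; the coastline
  helper computes distance to the nearest polyline vertex, not to segment
  interiors — supply a densified coastline for metric accuracy.
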