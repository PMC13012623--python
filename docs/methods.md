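# Methods

This note documents the models and numerical conventions behind
`spiketau`: what the simulator generates, how each estimator is defined at
the edges, how the exponential fit and its confidence interval are
computed, and which design choices were genuinely open.

## Ground-truth simulator

Synthetic units are univariate Hawkes processes with exponential kernel,

λ(t) = μ + Σ_{tᵢ<t} (α/τ_kernel) · exp(−(t−tᵢ)/τ_kernel),

simulated by Ogata thinning. For this kernel the intensity only decays
between events, so the post-event intensity is a valid dominating bound:
the sampler draws an exponential waiting time at the current bound,
accepts with probability λ/bound, and on rejection continues with the
decayed intensity as the new (tighter) bound. This is exact and O(events);
the excitation state is maintained recursively, never re-summed.

Target parametrization: a unit is specified by its stationary rate `f`
(Hz), intrinsic timescale `tau` (ms), excitation strength `alpha` ∈ [0,1)
and duration (ms). Internally μ = f(1−α) and τ_kernel = τ(1−α), so the
long-run rate is μ/(1−α) = f and the autocorrelation decay constant is
τ_kernel/(1−α) = τ. α ≥ 1 is refused (supercritical); a 10⁷-event cap
guards near-critical settings. α = 0 is special-cased as a homogeneous
Poisson draw (vectorized, statistically identical to thinning with no
excitation). All times are milliseconds; rates are converted from Hz
internally.

The default benchmark grid samples f ∈ [0.01, 10] Hz, α ∈ [0.1, 0.9] and
τ ∈ [50, 300] ms uniformly, with 600 s signals and 40 × 1000 ms
pseudo-trials — the regime of spontaneous cortical single-unit activity
(median rates of a few Hz, Lv from regular to bursty). A dataset-level
seed draws parameters and spawns one integer seed per unit, so any unit
is reproducible in isolation.

**What the simulator does not emulate:** non-stationary baselines,
refractoriness, oscillations, multi-timescale dynamics, and recording
artifacts (drift, sorting contamination). Passing benchmarks here shows
the estimators recover the timescale of a clean, single-timescale,
self-exciting process — not that real recordings satisfy those
assumptions.

Pseudo-trials are sampled as non-overlapping windows by rejection
sampling of start times (uniform, bounded attempts); whether windows may
overlap is genuinely open for this kind of resampling, so overlap is
allowed behind a flag (`allow_overlap=True`), but the default avoids
counting a spike in two trials.

## Estimators

All four estimators share the reference hyperparameters
(`STTCConfig.default()`): Δt = 25 ms, lag_shift = 50 ms, nlags = 20,
bin size = 50 ms, padding = 3000 ms, so every curve spans 0–1000 ms.

* **Tiling geometry.** T is the length of the union of closed ±Δt tiles,
  merged and clipped to the signal window, divided by the signal length —
  the only reading under which it is a proportion. The P-term coincidence
  test is inclusive (|t_a−t_b| ≤ Δt), symmetric with the closed tiles.
* **Degenerate STTC denominators.** 1−P·T = 0 makes a half-term 0/0; the
  value is genuinely undefined and propagates as NaN rather than being
  clamped.
* **Empty trains.** `sttc` on an empty train is NaN (no comparison
  exists). The trial-based fixed-T variant differs deliberately: there an
  empty concatenated segment means "no spikes were observed in this
  window in any trial", an informative outcome for which the P term takes
  its natural limit 0 and the value stays finite. Without this, every
  low-rate unit's trial curve would contain NaN at large lags and be
  excluded from fitting wholesale, which both cripples the estimator on
  sparse data and contradicts its observed inclusiveness.
* **Trial lag grid.** A lag at or beyond the trial duration leaves no
  data in either segment — the value does not exist, as opposed to failed
  — so such lags are omitted. At the defaults the trial curve has lags
  0–950 ms (20 points), the same length as the trial-averaged Pearson
  curve.
* **Padding invariance.** The T terms of the trial variant are computed
  inside each original trial over the effective duration (trial length −
  lag) and averaged; P is unaffected by padding because no ±Δt tile can
  bridge a ≥ trial-length gap. The curve is therefore identical (to
  float tolerance) for any padding ≥ one trial length — verified exactly
  in the tests.
* **Binning.** Half-open bins [k·bs, (k+1)·bs), floor(length/bs) bins; a
  spike at the last bin edge is dropped. The classic ACF uses the
  unadjusted estimator (full-series denominator, r(0) = 1), delegated to
  `statsmodels.tsa.stattools.acf` and cross-checked against a literal
  double-loop in the tests. A constant count series has no defined
  autocorrelation (all-NaN).
* **Trial-averaged Pearson.** Across-trial correlations for bin pairs
  (i, j), j > i, diagonal fixed at 1, lag value = mean of the k-th
  superdiagonal. Zero-variance bins give NaN pairwise entries; a lag is
  NaN only when its whole superdiagonal is, preserving partial
  information for QC while the fit-stage NaN rule still excludes
  NaN-containing curves.
* **Lag axes** are in ms everywhere (k·lag_shift or k·bin_size), so
  fitted timescales come out in ms without rescaling.

## Timescale fit

y(t) = a(e^(−bt) + c) — note the plateau is a·c — fitted by
trust-region-reflective least squares (`scipy.optimize.curve_fit`,
tolerances 1e-8, ≤ 5000 evaluations, deterministic initial values:
a₀ = first fitted value clipped to [1e-3, 2], b₀ = 1/(5·lag_shift),
c₀ = 0) with b ≥ 1e-6 /ms. Unit-level fits start at lag 1 (lag 0 is 1 by
construction and would dominate); pooled fits across many units — the
area-level use case — start at lag 2 and stack all (lag, value) points of
NaN-free curves into one fit.

τ = 1/b; σ_τ = σ_b/b² by error propagation from the parameter covariance;
the CI is τ ± t_{α/2, n−3}·σ_τ. R² is the ordinary coefficient of
determination over the fitted lags and may be negative.

Failure taxonomy: `fit_failed` (NaN in the fitted range, fewer than four
points, non-convergence, non-finite covariance) and `negative_r2`
(converged, worse than the mean). A fit whose decay rate lands on the
positivity bound is a converged, absurdly slow decay — effectively
infinite τ — and is classified by its R² like any other fit; the quality
criteria (CI excluding zero, R² ≥ 0.5) are the mechanism that flags such
estimates. Treating them as hard failures instead would inflate rejection
rates on epoched data well beyond the estimator's observed behavior and
would conflate "no estimate" with "poor estimate".

## Quality criteria and error metrics

* REE = (IT_est − IT_gt)/IT_gt × 100, signed; interval summaries use
  |REE|. Pseudo-REE (for data without ground truth) substitutes the
  full-signal estimate of the matching family.
* Lv = 3/(n−1) Σ((Iᵢ−Iᵢ₊₁)/(Iᵢ+Iᵢ₊₁))²: 0 regular, 1 Poisson, > 1
  bursty; used as an observable proxy for excitation strength.
* Decline criterion: the 50–200 ms "declining ACF" test is
  operationalized as value(last lag ≤ 200 ms) < value(first lag ≥ 50 ms)
  on the native lag grid — minimal, parameter-free, and monotone-
  consistent. A strict monotone-over-window variant is available via
  `mode="monotone"`; the exact operationalization is not standardized in
  the literature.
* CI-excludes-zero uses the strict lower-bound test τ_lower > 0.
* A unit is "rejected" iff its fit failed or converged with negative R²;
  the three pass-flags are reported per fit and aggregated per method by
  the benchmark summary (denominator: all units of the method).

## Problem sizes and determinism

The benchmark defaults (600 s signals, 40 × 1 s trials, 2000-unit grid in
the acceptance script, smaller grids in the test suite) keep a full run
in the minutes range on a single core while leaving the per-condition
sampling error well inside the tolerances checked; all randomness flows
from explicit integer seeds (dataset seed → per-unit seeds → per-trial
seeds), so every table is bit-reproducible. Fits are deterministic (fixed
initial values, no restarts).

## Known limitations

* Single-exponential model only: multi-timescale or oscillatory
  autocorrelations are mis-modelled by design; no model-free (zero
  crossing, integral) extraction.
* The Student-t CI assumes approximately Gaussian, independent residuals;
  ACF residuals are autocorrelated, so coverage is only approximately
  nominal (checked loosely in the tests).
* Univariate only — no cross-correlations between units, no mutually
  exciting processes, no inhomogeneous baselines.
* The trial-based estimators inherit the fundamental data loss of
  epoching; their errors are an order of magnitude larger than
  full-signal estimates, which is a property of the data regime, not a
  bug in the estimators.
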