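# spiketau

Estimation of **intrinsic neural timescales** from single-unit spike trains.

The intrinsic timescale (IT) of a neuron is the decay constant τ of its
spike-count autocorrelation: ACF(Δ) ∝ exp(−|Δ|/τ). It is a widely used
summary of how long a neuron "remembers" its own activity, and it is
notoriously sensitive to how the autocorrelation is estimated — especially
for low-rate, bursty units and for epoched (trial-based) recordings.

`spiketau` implements four ACF(-like) estimators behind a common interface,
fits the exponential decay with confidence intervals, applies the standard
inclusion criteria, and ships a self-exciting point-process simulator so
every estimator can be benchmarked against a known ground truth. It is
aimed at systems/computational neuroscientists estimating ITs from
extracellular single-unit recordings (e.g. Neuropixels spike-sorted data).

## Methods

| data | binned counts | raw spike times |
|---|---|---|
| unsegmented | classic ACF | iSTTC |
| trials | trial-averaged Pearson | iSTTC (trials) |

* **Classic ACF** — unadjusted sample autocorrelation
  r(k) = Σₜ(xₜ−x̄)(xₜ₋ₖ−x̄) / Σₜ(xₜ−x̄)² of 50 ms spike counts.
* **iSTTC** — the spike time tiling coefficient
  STTC = ½[(P_A−T_B)/(1−P_A T_B) + (P_B−T_A)/(1−P_B T_A)]
  computed between a spike train and lag-shifted, truncated copies of
  itself. P_A is the fraction of A's spikes within ±Δt of a spike of B;
  T_A the fraction of the signal tiled by A's ±Δt windows. No binning, and
  insensitive to firing rate.
* **Trial-averaged Pearson** — across-trial Pearson correlation between
  pairs of time bins, averaged along the superdiagonals of the resulting
  lag matrix.
* **iSTTC (trials)** — trials concatenated with zero padding (≥ one trial
  length) so tiles never bridge trials, with the T terms computed inside
  the original trials and averaged, making the curve exactly invariant to
  the padding length.

The IT is then obtained by nonlinear least squares of y(t) = a(e^(−bt)+c)
from lag 1 onward, τ = 1/b, with σ_τ = σ_b/b² and a Student-t confidence
interval at dof = n−3. A Hawkes process with exponential kernel
(λ(t) = μ + Σ (α/τ_k) e^(−(t−tᵢ)/τ_k), μ = f(1−α), τ_k = τ(1−α)) provides
ground truth: its stationary rate is f and its ACF decays with constant τ.

## Worked example

```python
from spiketau import (HawkesParams, simulate_hawkes, extract_pseudo_trials,
                      isttc_acf, isttc_trials, fit_exponential,
                      local_variation, relative_estimation_error)

params = HawkesParams(rate=5, tau=200, alpha=0.5, duration=600_000, seed=42)
train = simulate_hawkes(params)
print(f"simulated {train.n_spikes} spikes "
      f"({train.firing_rate:.2f} Hz, Lv = {local_variation(train):.2f})")

curve = isttc_acf(train, nlags=20, lag_shift=50.0, dt=25.0)
fit = fit_exponential(curve, fit_start_lag=1)
print(f"iSTTC (full signal):  tau = {fit.tau:.1f} ms, "
      f"95% CI [{fit.ci[1]:.1f}, {fit.ci[2]:.1f}], R^2 = {fit.r_squared:.3f}")
print(f"REE vs ground truth:  {relative_estimation_error(fit.tau, params.tau):+.1f}%")

trials = extract_pseudo_trials(train, n_trials=40, trial_len=1000.0, seed=7)
tcurve = isttc_trials(trials, nlags=20, lag_shift=50.0, dt=25.0, pad=3000.0)
tfit = fit_exponential(tcurve, fit_start_lag=1)
print(f"iSTTC (40 x 1 s trials): tau = {tfit.tau:.1f} ms, R^2 = {tfit.r_squared:.3f}")
```

prints

```
simulated 3121 spikes (5.20 Hz, Lv = 1.15)
iSTTC (full signal):  tau = 202.5 ms, 95% CI [168.0, 236.9], R^2 = 0.982
REE vs ground truth:  +1.2%
iSTTC (40 x 1 s trials): tau = 135.1 ms, R^2 = 0.657
```

The unit was simulated with a ground-truth τ of 200 ms at 5 Hz with strong
self-excitation (α = 0.5, hence the bursty Lv > 1). The full-signal iSTTC
estimate recovers τ to ~1%; the same unit reduced to 40 × 1 s pseudo-trials
gives a much rougher estimate — exactly the unsegmented-vs-epoched gap the
benchmark suite quantifies.

A command-line interface covers the same pipeline on text files
(`spiketau simulate | make-trials | estimate | benchmark | stability`;
see `spiketau --help`).

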