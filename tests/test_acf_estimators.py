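"""The four curve estimators: brute-force oracles and structural invariants."""

import numpy as np
import pytest
from scipy.stats import pearsonr as scipy_pearsonr

from spiketau.estimators import (BinnedTrain, STTCConfig, acf_classic,
                                 average_tiling, bin_spike_train, bin_trials,
                                 concatenate_with_padding, isttc_acf,
                                 isttc_trials, pearsonr_trial_avg)
from spiketau.fitting import fit_exponential
from spiketau.hawkes import HawkesParams, SpikeTrain, TrialSet, simulate_hawkes


def brute_force_acf(x, nlags):
    """Unadjusted sample autocorrelation, written as the literal double loop."""
    x = np.asarray(x, dtype=float)
    xbar = x.mean()
    denom = np.sum((x - xbar) ** 2)
    out = [1.0]
    for k in range(1, nlags + 1):
        num = sum((x[t] - xbar) * (x[t - k] - xbar) for t in range(k, len(x)))
        out.append(num / denom)
    return np.array(out)


def brute_force_trial_pearson(mat, nlags):
    """Pairwise across-trial Pearson + superdiagonal averaging, element by element."""
    r = np.full((nlags, nlags), np.nan)
    np.fill_diagonal(r, 1.0)
    for i in range(nlags):
        for j in range(i + 1, nlags):
            xi, xj = mat[:, i].astype(float), mat[:, j].astype(float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            r[i, j] = scipy_pearsonr(xi, xj)[0]
    out = []
    for k in range(nlags):
        diag = np.diagonal(r, offset=k)
        finite = diag[np.isfinite(diag)]
        out.append(finite.mean() if finite.size else np.nan)
    return np.array(out)


# ---------------------------------------------------------------- binning

def test_binning_basic():
    tr = SpikeTrain(times=np.array([10.0, 60.0, 110.0]), length=150.0)
    b = bin_spike_train(tr, 50.0)
    np.testing.assert_array_equal(b.counts, [1, 1, 1])


def test_binning_edge_goes_to_later_bin_and_conserves():
    tr = SpikeTrain(times=np.array([49.9, 50.0, 99.0]), length=150.0)
    b = bin_spike_train(tr, 50.0)
    np.testing.assert_array_equal(b.counts, [1, 2, 0])
    assert b.counts.sum() == tr.n_spikes


def test_binning_rejects_oversized_bin():
    tr = SpikeTrain(times=np.array([1.0]), length=100.0)
    with pytest.raises(ValueError):
        bin_spike_train(tr, 200.0)


# ------------------------------------------------------------ classic ACF

@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("n", [30, 200])
def test_acf_matches_brute_force(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.poisson(2.0, size=n)
    if np.ptp(x) == 0:
        x[0] += 1
    got = acf_classic(BinnedTrain(counts=x, bin_size=50.0), 10)
    np.testing.assert_allclose(got.values, brute_force_acf(x, 10), atol=1e-12)
    assert got.values[0] == pytest.approx(1.0)
    np.testing.assert_allclose(got.lags, np.arange(11) * 50.0)


def test_acf_alternating_series():
    # x = 1,0,1,0,... of length 10: r(1) = -(N-1)/N = -0.9
    b = BinnedTrain(counts=np.array([1, 0] * 5), bin_size=50.0)
    assert acf_classic(b, 3).values[1] == pytest.approx(-0.9)


def test_acf_constant_series_is_nan():
    b = BinnedTrain(counts=np.full(30, 2), bin_size=50.0)
    assert np.isnan(acf_classic(b, 5).values).all()


# ----------------------------------------------------------------- iSTTC

def test_isttc_lag_zero_is_one():
    rng = np.random.default_rng(3)
    tr = SpikeTrain(times=np.sort(rng.uniform(0, 60_000, 200)), length=60_000.0)
    c = isttc_acf(tr, 10, 50.0, 25.0)
    assert c.values[0] == 1.0


def test_isttc_periodic_train_is_one_at_multiples_of_period():
    times = np.arange(50.0, 60_000.0, 100.0)
    tr = SpikeTrain(times=times, length=60_000.0)
    c = isttc_acf(tr, 10, 100.0, 25.0)
    np.testing.assert_allclose(c.values, 1.0, atol=1e-12)


def test_isttc_poisson_decorrelates():
    """Nonzero-lag iSTTC of Poisson trains averages to ~0 across units."""
    vals = []
    for s in range(100):
        p = HawkesParams(rate=5, tau=100, alpha=0.0, duration=60_000, seed=s)
        c = isttc_acf(simulate_hawkes(p), 5, 50.0, 25.0)
        vals.append(c.values[1:])
    assert np.abs(np.nanmean(vals, axis=0)).max() < 0.01


def test_isttc_empty_train_all_nan():
    tr = SpikeTrain(times=np.empty(0), length=10_000.0)
    c = isttc_acf(tr, 5, 50.0, 25.0)
    assert np.isnan(c.values).all()


# -------------------------------------------------------------- PearsonR

@pytest.mark.parametrize("seed", [0, 5])
def test_pearson_trial_avg_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    mat = rng.poisson(1.0, size=(12, 20))
    got = pearsonr_trial_avg(mat, 20, 50.0)
    np.testing.assert_allclose(got.values, brute_force_trial_pearson(mat, 20),
                               atol=1e-12)
    assert got.values[0] == 1.0


def test_pearson_two_trials_perfectly_correlated():
    got = pearsonr_trial_avg(np.array([[1, 2], [2, 4]]), 2, 50.0)
    assert got.values[1] == pytest.approx(1.0)


def test_pearson_constant_bin_yields_nan_lag():
    # second bin constant across trials -> lag-1 superdiagonal all NaN
    mat = np.array([[1, 3], [2, 3], [4, 3]])
    got = pearsonr_trial_avg(mat, 2, 50.0)
    assert got.values[0] == 1.0
    assert np.isnan(got.values[1])


def test_pearson_requires_two_trials():
    with pytest.raises(ValueError):
        pearsonr_trial_avg(np.ones((1, 20)), 20, 50.0)


# -------------------------------------------- trial concatenation / iSTTC

def _trials_from(seed, n_trials=40, rate=5.0):
    p = HawkesParams(rate=rate, tau=150, alpha=0.4, duration=600_000, seed=seed)
    tr = simulate_hawkes(p)
    from spiketau.hawkes import extract_pseudo_trials
    return extract_pseudo_trials(tr, n_trials, 1000.0, seed=seed + 1)


def test_average_tiling_examples():
    one = TrialSet(trials=(np.array([100.0]),), trial_duration=1000.0)
    assert average_tiling(one, 1000.0, 25.0) == pytest.approx(0.05)
    two = TrialSet(trials=(np.array([100.0]), np.array([100.0, 300.0, 500.0])),
                   trial_duration=1000.0)
    assert average_tiling(two, 1000.0, 25.0) == pytest.approx((0.05 + 0.15) / 2)
    empty = TrialSet(trials=(np.empty(0), np.empty(0)), trial_duration=1000.0)
    assert average_tiling(empty, 1000.0, 25.0) == 0.0


def test_concatenation_offsets_and_gaps():
    ts = TrialSet(trials=(np.array([10.0, 20.0]), np.array([5.0])),
                  trial_duration=1000.0)
    cat = concatenate_with_padding(ts, 3000.0)
    np.testing.assert_allclose(cat.times, [10.0, 20.0, 4005.0])
    assert cat.length == 8000.0
    assert cat.n_spikes == ts.n_spikes
    # no spikes inside the padding gap [1000, 4000)
    assert not np.any((cat.times >= 1000.0) & (cat.times < 4000.0))
    with pytest.raises(ValueError):
        concatenate_with_padding(ts, 500.0)


def test_isttc_trials_padding_invariance():
    ts = _trials_from(11)
    ref = isttc_trials(ts, 20, 50.0, 25.0, 1000.0)
    for pad in (2000.0, 3000.0, 10_000.0):
        got = isttc_trials(ts, 20, 50.0, 25.0, pad)
        np.testing.assert_allclose(got.values, ref.values, atol=1e-12)


def test_isttc_trials_single_trial_equals_unsegmented():
    """With one trial, the padded-concatenation algorithm must reduce
    exactly to the unsegmented lag-shift algorithm on that trial."""
    ts = _trials_from(7, n_trials=1, rate=8.0)
    got = isttc_trials(ts, 10, 50.0, 25.0, 1000.0)
    tr = SpikeTrain(times=ts.trials[0], length=1000.0)
    ref = isttc_acf(tr, 10, 50.0, 25.0)
    np.testing.assert_allclose(got.values, ref.values[: got.values.size],
                               atol=1e-12)


def test_isttc_trials_lag_zero_and_lag_grid():
    ts = _trials_from(3)
    c = isttc_trials(ts, 20, 50.0, 25.0, 3000.0)
    assert c.values[0] == pytest.approx(1.0)
    # lags at/above the trial duration carry no data and are omitted
    assert c.lags[-1] == 950.0
    assert c.lags.size == 20


def test_isttc_trials_all_empty_is_nan():
    ts = TrialSet(trials=(np.empty(0),) * 5, trial_duration=1000.0)
    c = isttc_trials(ts, 10, 50.0, 25.0, 1000.0)
    assert np.isnan(c.values).all()


# ----------------------------------------------------- estimator agreement

def test_unsegmented_estimators_agree_on_ground_truth():
    """On long, high-rate simulations the decay constants fitted to the
    classic ACF and to the iSTTC curve both recover the known timescale."""
    taus_acf, taus_isttc = [], []
    for s in range(12):
        p = HawkesParams(rate=10, tau=200, alpha=0.3, duration=600_000, seed=s)
        tr = simulate_hawkes(p)
        ca = acf_classic(bin_spike_train(tr, 50.0), 20)
        ci = isttc_acf(tr, 20, 50.0, 25.0)
        taus_acf.append(fit_exponential(ca).tau)
        taus_isttc.append(fit_exponential(ci).tau)
    assert np.median(taus_acf) == pytest.approx(200.0, rel=0.25)
    assert np.median(taus_isttc) == pytest.approx(200.0, rel=0.25)
    assert np.median(taus_acf) == pytest.approx(np.median(taus_isttc), rel=0.15)
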