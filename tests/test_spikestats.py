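"""Correlation/synchrony estimator against analytic and sampling oracles."""

import math

import numpy as np
import pytest

from critnet.fixtures import EnsembleSpec, generate, mip_expected_synchrony
from critnet.spikestats import (CorrelationConfig, UndefinedPairError,
                                first_side_peak, pair_admissible,
                                pair_correlation, population_correlation,
                                synchrony_timecourse, windows_as_trials)


class TestAdmissibility:
    def test_printed_bound_value(self):
        bound = 1.0 / math.sqrt(200 * 0.1 * 0.001)
        assert bound == pytest.approx(7.0710678, abs=1e-6)
        assert pair_admissible(10.0, 10.0, 200, 100.0, 1.0)
        assert not pair_admissible(7.0, 7.0, 200, 100.0, 1.0)

    def test_zero_rate_and_symmetry(self):
        assert not pair_admissible(0.0, 50.0, 200, 100.0, 1.0)
        a = pair_admissible(4.0, 30.0, 200, 100.0, 1.0)
        b = pair_admissible(30.0, 4.0, 200, 100.0, 1.0)
        assert a == b


class TestPairCorrelation:
    def test_duplicated_trains_value(self):
        """Identical trains with per-bin probability q give c(0)=1/q-1."""
        rng = np.random.default_rng(1)
        cfg = CorrelationConfig(window=1000.0, bin=1.0, max_lag=5.0)
        trains = [np.sort(rng.uniform(0, 1000.0, 10)) for _ in range(80)]
        c = pair_correlation(trains, trains, 0.0, cfg)
        q = 0.01
        assert c[len(c) // 2] == pytest.approx(1.0 / q - 1.0, rel=0.05)

    def test_independent_pairs_unbiased(self):
        """Mean C(0) over 200 Monte-Carlo independent ensembles is within
        3 SE of zero."""
        rng = np.random.default_rng(5)
        cfg = CorrelationConfig(window=100.0, bin=1.0, max_lag=3.0)
        vals = []
        for _ in range(200):
            tr_i = [np.sort(rng.uniform(0, 100.0, rng.poisson(1.5)))
                    for _ in range(120)]
            tr_j = [np.sort(rng.uniform(0, 100.0, rng.poisson(1.5)))
                    for _ in range(120)]
            c = pair_correlation(tr_i, tr_j, 0.0, cfg)
            vals.append(c[len(c) // 2])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3.0 * se

    def test_oscillation_modulated_pair_has_20ms_side_peaks(self):
        """Doubly stochastic trains sharing a 50 Hz rate give c(tau) with
        period-20 ms structure: maxima at 0 and +-20 ms."""
        data = generate(EnsembleSpec(n_neurons=2, rate=30.0, duration=400.0,
                                     n_trials=600,
                                     structure="rate_modulated", f_mod=50.0,
                                     depth=0.8, seed=21))
        cfg = CorrelationConfig(window=400.0, bin=1.0, max_lag=30.0)
        c = pair_correlation([t[0] for t in data.trials],
                             [t[1] for t in data.trials], 0.0, cfg)
        lags = cfg.lags
        mid = len(lags) // 2
        assert c[mid] > 0
        # the +-20 ms values beat the +-10 ms troughs
        def at(lag):
            return c[mid + int(lag)]
        assert at(20) > at(10)
        assert at(-20) > at(-10)
        # side maxima located near +-20 ms
        pos = lags >= 12
        assert abs(lags[pos][np.argmax(c[pos])] - 20.0) <= 3.0

    def test_all_trials_excluded_raises(self):
        cfg = CorrelationConfig(window=100.0, bin=1.0, max_lag=3.0)
        empty = [np.array([])] * 10
        busy = [np.array([5.0, 50.0])] * 10
        with pytest.raises(UndefinedPairError):
            pair_correlation(empty, busy, 0.0, cfg)


class TestPopulationCorrelation:
    def test_common_input_recovers_closed_form(self):
        """Multiple-interaction ensemble: measured synchrony matches the
        analytic expectation within 10% at K=500."""
        rate, eps = 10.0, 0.1
        data = generate(EnsembleSpec(n_neurons=12, rate=rate, duration=500.0,
                                     n_trials=500, structure="common_input",
                                     eps=eps, seed=31))
        cfg = CorrelationConfig(window=100.0, bin=1.0, max_lag=10.0)
        est = population_correlation(data, 200.0, cfg)
        assert est.synchrony == pytest.approx(
            mip_expected_synchrony(rate, eps), rel=0.10)

    def test_pair_count_bounded_by_admissible(self):
        data = generate(EnsembleSpec(n_neurons=10, rate=12.0, duration=400.0,
                                     n_trials=150, seed=41))
        cfg = CorrelationConfig(window=100.0, bin=1.0, max_lag=5.0)
        est = population_correlation(data, 100.0, cfg)
        n_adm = 0
        rates = {}
        for i in range(10):
            n = sum(np.count_nonzero((t[i] >= 100) & (t[i] < 200))
                    for t in data.trials)
            rates[i] = n / (150 * 0.1)
        for i in range(10):
            for j in range(i + 1, 10):
                n_adm += pair_admissible(rates[i], rates[j], 150, 100.0, 1.0)
        assert est.n_pairs <= n_adm
        assert est.n_pairs > 0

    def test_no_admissible_pairs_raises(self):
        data = generate(EnsembleSpec(n_neurons=5, rate=1.0, duration=300.0,
                                     n_trials=10, seed=51))
        cfg = CorrelationConfig(window=100.0, bin=1.0, max_lag=5.0)
        with pytest.raises(UndefinedPairError):
            population_correlation(data, 0.0, cfg)


class TestTimecourse:
    def test_stationary_poisson_flat(self):
        data = generate(EnsembleSpec(n_neurons=10, rate=20.0, duration=900.0,
                                     n_trials=200, seed=61))
        cfg = CorrelationConfig(window=100.0, bin=1.0, max_lag=5.0)
        course = synchrony_timecourse(data, cfg, stride=100.0)
        sync = course["synchrony"].to_numpy()
        se = course["synchrony_se"].to_numpy()
        assert np.all(np.isfinite(sync))
        assert np.all(np.abs(sync) < 4.0 * se + 0.05)
        # rate column is per-neuron Hz
        assert course["rate"].mean() == pytest.approx(20.0, rel=0.1)

    def test_window_reslicing_preserves_spikes(self):
        data = generate(EnsembleSpec(n_neurons=3, rate=10.0, duration=1000.0,
                                     n_trials=2, seed=71))
        res = windows_as_trials(data, 200.0)
        assert res.n_trials == 10
        total = sum(len(t) for tr in res.trials for t in tr)
        orig = sum(len(t) for tr in data.trials for t in tr)
        assert total == orig

    def test_side_peak_locator_on_synthetic_correlogram(self):
        lags = np.arange(-30.0, 31.0)
        C = 0.2 * np.cos(2 * np.pi * lags / 20.0) * np.exp(-np.abs(lags) / 40)
        est_cfg = CorrelationConfig(window=100.0, bin=1.0, max_lag=30.0)
        from critnet.spikestats import CorrelationEstimate
        est = CorrelationEstimate(lags=lags, C=C, SE=np.full_like(C, 0.01),
                                  n_pairs=10, n_excluded_trials=0,
                                  config=est_cfg)
        pk = first_side_peak(est)
        assert pk["lag"] == pytest.approx(20.0, abs=1.0)
        assert pk["significant"]
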