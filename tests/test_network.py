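"""Direct network simulation: topology, integration, rates, spectra."""

import numpy as np
import pytest
from scipy import stats

from critnet.fixtures import EnsembleSpec, generate
from critnet.meanfield import ConductanceSet
from critnet.network import (ExternalDriveProfile, build_network,
                             population_rate_and_spectrum, simulate)

from conftest import e_rate, i_rate


class TestTopology:
    def test_zero_probability_gives_no_edges(self):
        topo = build_network(50, 0.0, 10, seed=0)
        assert len(topo.targets) == 0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_network(100, 1.5, 10, seed=0)
        with pytest.raises(ValueError):
            build_network(1, 0.2, 10, seed=0)

    def test_no_self_connections_and_reproducibility(self):
        topo = build_network(300, 0.2, 10, seed=7)
        for j in range(topo.N):
            assert j not in topo.targets[topo.offsets[j]:topo.offsets[j + 1]]
        topo2 = build_network(300, 0.2, 10, seed=7)
        np.testing.assert_array_equal(topo.targets, topo2.targets)

    def test_in_degree_distribution_binomial(self):
        """Chi-square goodness of fit of in-degrees vs Binomial(N-1, p)."""
        N, p = 800, 0.2
        deg = build_network(N, p, 10, seed=11).in_degrees()
        lo, hi = int(deg.min()), int(deg.max())
        edges = np.linspace(lo - 0.5, hi + 0.5, 12)
        obs, _ = np.histogram(deg, bins=edges)
        binom = stats.binom(N - 1, p)
        exp = np.diff(binom.cdf(edges)) * N
        keep = exp > 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.01

    def test_mean_in_degree_matches_pN(self, topology):
        assert topology.in_degrees().mean() == pytest.approx(
            topology.p * topology.N, rel=0.05)


class TestSimulation:
    def test_zero_conductances_silent(self):
        topo = build_network(100, 0.2, 10, seed=0)
        g0 = ConductanceSet(*([0.0] * 8))
        data = simulate(topo, g0, ExternalDriveProfile.constant(5.0),
                        duration=300.0, seed=1)
        assert sum(len(t) for t in data.trials[0]) == 0

    def test_seed_determinism_and_trial_independence(self, steady_net):
        _, g, _, _ = steady_net
        topo = build_network(5000, 0.2, 800, seed=3)
        drive = ExternalDriveProfile.constant(5.0)
        a = simulate(topo, g, drive, duration=300.0, seed=9, n_trials=2)
        b = simulate(topo, g, drive, duration=300.0, seed=9, n_trials=2)
        for i in range(a.n_neurons):
            np.testing.assert_array_equal(a.trials[0][i], b.trials[0][i])
        # distinct trials differ
        assert any(len(a.trials[0][i]) != len(a.trials[1][i])
                   or not np.array_equal(a.trials[0][i], a.trials[1][i])
                   for i in range(a.n_neurons))

    def test_refractoriness_exact(self, steady_sims, constants):
        data = steady_sims[0]
        tau_rp = {"E": constants.neuron_e.tau_rp,
                  "I": constants.neuron_i.tau_rp}
        for i in range(data.n_neurons):
            t = data.trials[0][i]
            if len(t) > 1:
                assert np.all(np.diff(t) >= tau_rp[data.labels[i]] - 1e-9)

    def test_steady_rates_match_mean_field(self, steady_sims, steady_net):
        """Theory-simulation consistency within 25%."""
        _, _, state, _ = steady_net
        assert e_rate(steady_sims) == pytest.approx(state.nu_e, rel=0.25)
        assert i_rate(steady_sims) == pytest.approx(state.nu_i, rel=0.25)

    def test_critical_baseline_rates_match_mean_field(self, topology,
                                                      critical_net,
                                                      constants):
        _, g, state, _ = critical_net
        data = simulate(topology, g, ExternalDriveProfile.constant(5.0),
                        duration=2200.0, constants=constants, seed=301)
        assert data.mean_rate("E", 200.0) == pytest.approx(state.nu_e,
                                                           rel=0.25)
        assert data.mean_rate("I", 200.0) == pytest.approx(state.nu_i,
                                                           rel=0.25)

    def test_step_size_robustness(self, topology, steady_net, constants):
        """Halving dt changes population mean rates by < 3% (two seeds per
        step size to average out realization noise)."""
        _, g, _, _ = steady_net
        drive = ExternalDriveProfile.constant(5.0)
        r = {}
        for dt in (0.1, 0.05):
            r[dt] = np.mean([
                simulate(topology, g, drive, duration=2200.0,
                         constants=constants, dt=dt,
                         seed=s).mean_rate("E", 200.0)
                for s in (77, 78)])
        assert r[0.05] == pytest.approx(r[0.1], rel=0.03)

    def test_synchronous_regime_fano_exceeds_steady(self, steady_sims,
                                                    critical_up_sims):
        """Population-count Fano factor (1-ms bins, 100-ms windows) is
        larger in the synchronous condition."""
        def fano(data):
            edges = np.arange(200.0, data.duration + 1.0, 1.0)
            counts = np.zeros(len(edges) - 1)
            for i in data.neurons("E"):
                c, _ = np.histogram(data.trials[0][i], bins=edges)
                counts += c
            win = 100
            f = []
            for k in range(0, len(counts) - win, win):
                seg = counts[k:k + win]
                f.append(seg.var() / seg.mean())
            return np.mean(f)

        f_steady = np.mean([fano(d) for d in steady_sims])
        f_sync = np.mean([fano(d) for d in critical_up_sims])
        assert f_sync > f_steady


class TestSpectrum:
    def test_poisson_ensemble_flat_spectrum(self):
        data = generate(EnsembleSpec(n_neurons=200, rate=15.0,
                                     duration=3000.0, n_trials=4,
                                     structure="independent_poisson", seed=8))
        sp = population_rate_and_spectrum(data, "E")
        assert sp["peak_ratio"] < 3.0

    def test_modulated_ensemble_peak_recovered(self):
        data = generate(EnsembleSpec(n_neurons=150, rate=20.0,
                                     duration=4000.0, n_trials=6,
                                     structure="rate_modulated", f_mod=40.0,
                                     depth=0.5, seed=9))
        sp = population_rate_and_spectrum(data, "E")
        assert sp["peak_freq"] == pytest.approx(40.0, abs=1.0)
        assert sp["peak_ratio"] > 3.0

    def test_empty_data_rejected(self):
        from critnet.spikedata import SpikeData
        with pytest.raises(ValueError):
            population_rate_and_spectrum(
                SpikeData(trials=[], labels=np.array([]), duration=0.0), "E")


class TestDriveProfile:
    def test_trapezoid_profile_levels(self):
        prof = ExternalDriveProfile.trapezoid(5.0, low=0.97, high=1.05,
                                              t_on=100.0)
        t = np.array([0.0, 100.0, 200.0, 500.0, 600.0, 700.0, 900.0])
        r = prof.rate(t) / 5.0
        assert r[0] == pytest.approx(0.97)
        assert r[2] == pytest.approx(1.05)
        assert r[3] == pytest.approx(1.05)
        assert r[-1] == pytest.approx(0.97)

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            ExternalDriveProfile(nu_x_base=5.0, segments=[(0.0, -1.0)])
        with pytest.raises(ValueError):
            ExternalDriveProfile(nu_x_base=0.0)
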