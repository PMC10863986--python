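"""Shared fixtures: solved reference networks and cached simulations.

The expensive direct simulations are session-scoped so that the rate,
spectrum, synchrony and regime-concordance tests all reuse the same runs.
"""

import numpy as np
import pytest

from critnet.network import ExternalDriveProfile, build_network, simulate
from critnet.params import load_defaults
from critnet.perturbation import critical_coefficients
from critnet.scenarios import (ScenarioConfig, primary_network,
                               run_pre_response_scenario,
                               run_primary_network_scenario)


@pytest.fixture(scope="session")
def constants():
    return load_defaults()


@pytest.fixture(scope="session")
def steady_net(constants):
    """(spec, conductances, mean-field state, stability) of the steady
    primary network."""
    return primary_network("steady", constants)


@pytest.fixture(scope="session")
def critical_net(constants):
    """Critical primary network, q3 refined onto the critical line."""
    return primary_network("critical", constants)


@pytest.fixture(scope="session")
def coeffs(critical_net):
    _, g, state, stab = critical_net
    return critical_coefficients(state, stab)


@pytest.fixture(scope="session")
def topology(constants):
    return build_network(constants.N, constants.p, constants.CX, seed=1)


def _run_rates(topology, g, level, seeds, duration, constants):
    drive = ExternalDriveProfile.constant(5.0, level=level)
    return [simulate(topology, g, drive, duration=duration,
                     constants=constants, seed=s) for s in seeds]


@pytest.fixture(scope="session")
def steady_sims(topology, steady_net, constants):
    """Three baseline-drive realizations of the steady network, 2.2 s."""
    _, g, _, _ = steady_net
    return _run_rates(topology, g, 1.0, (101, 102, 103), 2200.0, constants)


@pytest.fixture(scope="session")
def critical_up_sims(topology, critical_net, constants):
    """Three +5%-drive realizations of the critical network, 2.2 s."""
    _, g, _, _ = critical_net
    return _run_rates(topology, g, 1.05, (201, 202, 203), 2200.0, constants)


# 20.4 s gives ~100 windows: the admissibility bound (7.04 Hz) then reaches
# below the extreme high-rate tail, which dilutes the shared-input baseline
# correlation and sharpens the naive/drug contrast
_STATIONARY_CFG = ScenarioConfig(duration=20400.0, n_analysis_neurons=80,
                                 seed=5)


@pytest.fixture(scope="session")
def naive_bundle(constants, topology):
    """Stationary drug-naive condition: critical net, 1.03x drive,
    1.25x NMDA."""
    return run_primary_network_scenario("critical", 1.03, 1.25,
                                        config=_STATIONARY_CFG,
                                        constants=constants,
                                        topology=topology)


@pytest.fixture(scope="session")
def drug_bundle(constants, topology):
    """Stationary drug condition: critical net, 1.03x drive, NMDA blocked."""
    return run_primary_network_scenario("critical", 1.03, 0.0,
                                        config=_STATIONARY_CFG,
                                        constants=constants,
                                        topology=topology)


@pytest.fixture(scope="session")
def corner_bundles(constants, topology, naive_bundle, drug_bundle):
    """The four probe/pre-response x drug-naive/drug corner conditions.

    Long stationary runs so the synchrony estimator has admissible pairs at
    the low rates of the drug/low-drive corners.
    """
    cfg = ScenarioConfig(duration=14400.0, n_analysis_neurons=70, seed=6)
    low_naive = run_primary_network_scenario("critical", 0.97, 1.25,
                                             config=cfg, constants=constants,
                                             topology=topology)
    low_drug = run_primary_network_scenario("critical", 0.97, 0.0,
                                            config=cfg, constants=constants,
                                            topology=topology)
    return {(0.97, 1.25): low_naive, (1.03, 1.25): naive_bundle,
            (0.97, 0.0): low_drug, (1.03, 0.0): drug_bundle}


@pytest.fixture(scope="session")
def preresponse_naive(constants, topology):
    """Trial-structured pre-response epoch, NMDA at 1.25x."""
    return run_pre_response_scenario(1.25, constants=constants,
                                     topology=topology, n_trials=75, seed=8)


@pytest.fixture(scope="session")
def preresponse_drug(constants, topology):
    """Trial-structured pre-response epoch, NMDA blocked."""
    return run_pre_response_scenario(0.0, constants=constants,
                                     topology=topology, n_trials=75, seed=9)


def e_rate(sims, t_start=200.0):
    return float(np.mean([d.mean_rate("E", t_start=t_start) for d in sims]))


def i_rate(sims, t_start=200.0):
    return float(np.mean([d.mean_rate("I", t_start=t_start) for d in sims]))
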