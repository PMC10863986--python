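"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's analytical machinery: the LIF rate
oracle integrates the effective membrane equation driven by an
exponentially correlated Gaussian current with Euler steps and counts
threshold crossings.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _ou_lif_rate(mu, sigma, tau, tau_syn, theta_rel, vrst_rel, tau_rp,
                 duration_ms, dt, seed):
    """Monte-Carlo rate (Hz) of tau dV/dt = -(V-VL) + mu + sigma sqrt(tau) eta.

    eta is Ornstein-Uhlenbeck with correlation time tau_syn and stationary
    variance 1/(2 tau_syn), matching the white-noise normalisation as
    tau_syn -> 0.  Voltages measured relative to VL.
    """
    np.random.seed(seed)
    n = int(duration_ms / dt)
    v = 0.0
    eta = np.random.normal() * np.sqrt(1.0 / (2.0 * tau_syn))
    refr = 0.0
    count = 0
    sq = np.sqrt(dt) / tau_syn
    amp = sigma * np.sqrt(tau)
    for _ in range(n):
        eta += -eta * dt / tau_syn + sq * np.random.normal()
        if refr > 0.0:
            refr -= dt
            v = vrst_rel
            continue
        v += dt * (-(v) + mu + amp * eta) / tau
        if v >= theta_rel:
            count += 1
            v = vrst_rel
            refr = tau_rp
    return count / (duration_ms * 1e-3)


def mc_lif_rate(mu, sigma, tau, tau_syn, neuron, duration_ms=100_000.0,
                dt=0.01, seed=0):
    """Wrapper taking a NeuronPopulationParams."""
    return _ou_lif_rate(mu, sigma, tau, tau_syn,
                        neuron.theta - neuron.VL, neuron.Vrst - neuron.VL,
                        neuron.tau_rp, duration_ms, dt, seed)
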