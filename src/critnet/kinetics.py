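"""Single-synapse gating primitives and the NMDA voltage nonlinearity.

The gating cascade is the linear two-stage filter

    tau_r dx/dt = -x + tau_star * sum_k delta(t - t_k - tau_l)
    tau_d ds/dt = -s + x

whose impulse response integrates to tau_star.  Within an integration step
the pair (x, s) is propagated exactly (the 2x2 system is linear with known
eigenstructure); spike arrivals, already latency-shifted by the caller, are
applied as jumps x += tau_star/tau_r at step boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import NMDAVoltageParams, ReceptorKinetics

__all__ = ["SynapticState", "nmda_gate_factor", "step_gating", "gating_propagator"]


@dataclass
class SynapticState:
    """Aggregated (x, s) pair for one (neuron, receptor-type) channel."""

    x: float = 0.0
    s: float = 0.0


def nmda_gate_factor(v: float | np.ndarray, params: NMDAVoltageParams) -> float | np.ndarray:
    """Fraction of NMDAR conductance unblocked by Mg2+ at potential `v` (mV).

    Returns 1 / (1 + [Mg]/gamma * exp(-beta V)), a value in (0, 1) that
    increases monotonically with V.
    """
    return 1.0 / (1.0 + params.mg / params.gamma * np.exp(-params.beta * np.asarray(v, dtype=float)))


def gating_propagator(kin: ReceptorKinetics, dt: float) -> tuple[float, float, float]:
    """Exact one-step propagator of the two-stage filter.

    Returns (er, ed, c) such that over a step of length `dt` (ms)

        x  ->  er * x
        s  ->  ed * s + c * x

    with er = exp(-dt/tau_r), ed = exp(-dt/tau_d) and
    c = tau_r/(tau_r - tau_d) * (er - ed).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    er = math.exp(-dt / kin.tau_r)
    ed = math.exp(-dt / kin.tau_d)
    if abs(kin.tau_r - kin.tau_d) < 1e-12 * kin.tau_d:
        # degenerate equal-time-constant limit: c = dt/tau * exp(-dt/tau)
        c = dt / kin.tau_d * ed
    else:
        c = kin.tau_r / (kin.tau_r - kin.tau_d) * (er - ed)
    return er, ed, c


def step_gating(state: SynapticState, kin: ReceptorKinetics, dt: float,
                n_arrivals: int = 0) -> SynapticState:
    """Advance the gating pair by `dt` ms, then add `n_arrivals` spikes.

    Arrivals are assumed latency-shifted by tau_l by the caller (the
    simulator's delay ring buffer); each adds tau_star/tau_r to x.
    """
    er, ed, c = gating_propagator(kin, dt)
    x = er * state.x
    s = ed * state.s + c * state.x
    if n_arrivals:
        x += n_arrivals * kin.tau_star / kin.tau_r
    return SynapticState(x=x, s=s)
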