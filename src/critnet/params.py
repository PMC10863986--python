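"""Model constants: neuron populations, receptor kinetics, NMDA voltage block.

All quantities use the repo-wide unit convention mV, ms, nS, nF, Hz; currents
are reported in nA.  Defaults mirror the versioned ``defaults.yaml`` document
shipped with the package; any scenario config may override individual keys.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import yaml

__all__ = [
    "NeuronPopulationParams",
    "ReceptorKinetics",
    "NMDAVoltageParams",
    "ModelConstants",
    "load_defaults",
]


@dataclass(frozen=True)
class NeuronPopulationParams:
    """Leaky integrate-and-fire constants for one population (E or I)."""

    Cm: float      # membrane capacitance, nF
    gm: float      # leak conductance, nS
    VL: float      # resting potential, mV
    theta: float   # spike threshold, mV
    Vrst: float    # reset potential, mV
    tau_rp: float  # absolute refractory period, ms
    label: str = "E"

    def __post_init__(self) -> None:
        if not (self.Vrst < self.theta):
            raise ValueError("reset potential must lie below threshold")
        if self.tau_rp <= 0 or self.Cm <= 0 or self.gm <= 0:
            raise ValueError("Cm, gm and tau_rp must be positive")

    @property
    def tau_m(self) -> float:
        """Membrane time constant Cm/gm in ms."""
        return 1e3 * self.Cm / self.gm


@dataclass(frozen=True)
class ReceptorKinetics:
    """Two-stage gating cascade constants for one receptor type.

    The postsynaptic gating variable s follows a latency + rise + decay
    cascade whose impulse response integrates to ``tau_star`` regardless of
    the rise/decay constants; the charge per spike is therefore
    g_R * tau_star * (driving force).
    """

    tau_l: float          # latency, ms
    tau_r: float          # rise, ms
    tau_d: float          # decay, ms
    receptor: str = "AMPA"
    tau_star: float = 1.0  # charge normalisation, ms

    def __post_init__(self) -> None:
        if min(self.tau_l, self.tau_r, self.tau_d, self.tau_star) <= 0:
            raise ValueError("all receptor time constants must be positive")

    @property
    def tau_eff(self) -> float:
        """Effective synaptic time constant tau_l + tau_r + tau_d (ms)."""
        return self.tau_l + self.tau_r + self.tau_d


@dataclass(frozen=True)
class NMDAVoltageParams:
    """Magnesium-block voltage dependence of the NMDAR conductance."""

    beta: float = 0.062   # 1/mV
    gamma: float = 3.57   # mM
    mg: float = 1.0       # mM

    def kappa(self, v_mean: float) -> float:
        """Linearisation factor kappa = 1 + [Mg]/gamma * exp(-beta <V>)."""
        import math

        return 1.0 + self.mg / self.gamma * math.exp(-self.beta * v_mean)


@dataclass(frozen=True)
class ModelConstants:
    """Bundle of every constant the theory and the simulator share."""

    neuron_e: NeuronPopulationParams
    neuron_i: NeuronPopulationParams
    kinetics: dict  # receptor tag -> ReceptorKinetics, tags X/AMPA/NMDA/GABA
    nmda: NMDAVoltageParams
    VE: float
    VI: float
    N: int
    f_exc: float
    p: float
    CX: int

    @property
    def NE(self) -> int:
        return int(round(self.f_exc * self.N))

    @property
    def NI(self) -> int:
        return self.N - self.NE

    @property
    def CE(self) -> float:
        return self.p * self.NE

    @property
    def CI(self) -> float:
        return self.p * self.NI

    def neuron(self, label: str) -> NeuronPopulationParams:
        return self.neuron_e if label == "E" else self.neuron_i

    def with_network(self, *, N: int | None = None, p: float | None = None,
                     CX: int | None = None) -> "ModelConstants":
        return replace(
            self,
            N=self.N if N is None else N,
            p=self.p if p is None else p,
            CX=self.CX if CX is None else CX,
        )


def load_defaults(overrides: dict | None = None) -> ModelConstants:
    """Load the shipped default constants, optionally updated by `overrides`.

    `overrides` uses the same nested keys as ``defaults.yaml``.
    """
    raw = yaml.safe_load(
        resources.files("critnet").joinpath("defaults.yaml").read_text()
    )
    if overrides:
        _deep_update(raw, overrides)

    tau_star = float(raw["tau_star"])
    kin = {}
    for tag in ("AMPA", "NMDA", "GABA"):
        d = raw["kinetics"][tag]
        kin[tag] = ReceptorKinetics(
            tau_l=float(d["tau_l"]), tau_r=float(d["tau_r"]),
            tau_d=float(d["tau_d"]), receptor=tag, tau_star=tau_star,
        )
    # external synapses are AMPAR-mediated
    kin["X"] = replace(kin["AMPA"], receptor="X")

    net = raw["network"]
    return ModelConstants(
        neuron_e=NeuronPopulationParams(label="E", **raw["neuron_E"]),
        neuron_i=NeuronPopulationParams(label="I", **raw["neuron_I"]),
        kinetics=kin,
        nmda=NMDAVoltageParams(**{k: float(v) for k, v in raw["nmda"].items()}),
        VE=float(raw["VE"]),
        VI=float(raw["VI"]),
        N=int(net["N"]),
        f_exc=float(net["f_exc"]),
        p=float(net["p"]),
        CX=int(net["CX"]),
    )


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
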