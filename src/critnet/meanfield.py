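"""Self-consistent mean-field description of the E/I network.

The population-level reduction replaces per-synapse inputs by their average
plus Gaussian fluctuations, giving for each population alpha in {E, I} an
effective one-dimensional membrane equation

    tau_a dV/dt = -(V - VL) + mu_a + sigma_a sqrt(tau_a) eta_a(t)

with effective membrane time constant tau_a = tau_m / S_a (S_a the total
conductance factor), mean input mu_a, fluctuation magnitude sigma_a and
colored noise eta_a of correlation time tau_syn_a.  The stationary firing
rate is the colored-noise-corrected first-passage rate ``transfer_rate``.

Two solvers are provided:

* :func:`solve_rates` — forward: conductances -> self-consistent (nu_E, nu_I);
* :func:`solve_conductances` — inverse: balance ratios (q1, q2, q3) plus
  prescribed rates -> the eight maximal conductances.

Units: mV, ms, nS, nF, Hz; currents in nA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize
from scipy.special import erfcx

from .params import ModelConstants, NeuronPopulationParams, load_defaults

__all__ = [
    "BalanceSpec",
    "ConductanceSet",
    "PopulationState",
    "MeanFieldState",
    "transfer_rate",
    "transfer_rate_deterministic",
    "solve_rates",
    "solve_conductances",
    "MeanFieldError",
]

RECEPTORS = ("X", "AMPA", "NMDA", "GABA")

_GL_NODES, _GL_WEIGHTS = leggauss(160)


class MeanFieldError(RuntimeError):
    """Raised when a self-consistent solve fails to converge."""


@dataclass(frozen=True)
class BalanceSpec:
    """Operating-point specification by current-balance ratios.

    q1 = I_NMDA/I_GABA, q2 = I_AMPA/I_GABA, q3 = I_X,E/I_theta,E (ratios of
    absolute values of mean component currents), together with the prescribed
    population rates and the background external rate.
    """

    q1: float
    q2: float
    q3: float
    nu_e_star: float = 5.0   # Hz
    nu_i_star: float = 20.0  # Hz
    nu_x_star: float = 5.0   # Hz

    def __post_init__(self) -> None:
        if min(self.nu_e_star, self.nu_i_star, self.nu_x_star) <= 0:
            raise ValueError("prescribed rates must be positive")

    def check_regime(self) -> None:
        """Warn if outside the low-rate asynchronous-regime bounds."""
        if self.q1 + self.q2 >= 1.0:
            warnings.warn(
                f"q1+q2={self.q1 + self.q2:.3f} >= 1: inhibition no longer "
                "dominates recurrent excitation", stacklevel=3)
        if self.q3 < 1.0:
            warnings.warn(
                f"q3={self.q3:.3f} < 1: external drive below threshold "
                "current", stacklevel=3)


@dataclass(frozen=True)
class ConductanceSet:
    """The eight maximal synaptic conductances (nS), g[receptor][population]."""

    g_x_e: float
    g_x_i: float
    g_ampa_e: float
    g_ampa_i: float
    g_nmda_e: float
    g_nmda_i: float
    g_gaba_e: float
    g_gaba_i: float

    def g(self, receptor: str, pop: str) -> float:
        return getattr(self, f"g_{receptor.lower()}_{pop.lower()}")

    def scaled(self, *, nmda: float = 1.0, ampa: float = 1.0,
               gaba: float = 1.0, x: float = 1.0) -> "ConductanceSet":
        """Scale receptor conductances (E and I targets by the same factor)."""
        return ConductanceSet(
            g_x_e=self.g_x_e * x, g_x_i=self.g_x_i * x,
            g_ampa_e=self.g_ampa_e * ampa, g_ampa_i=self.g_ampa_i * ampa,
            g_nmda_e=self.g_nmda_e * nmda, g_nmda_i=self.g_nmda_i * nmda,
            g_gaba_e=self.g_gaba_e * gaba, g_gaba_i=self.g_gaba_i * gaba,
        )

    def as_dict(self) -> dict:
        return {
            "g_x_e": self.g_x_e, "g_x_i": self.g_x_i,
            "g_ampa_e": self.g_ampa_e, "g_ampa_i": self.g_ampa_i,
            "g_nmda_e": self.g_nmda_e, "g_nmda_i": self.g_nmda_i,
            "g_gaba_e": self.g_gaba_e, "g_gaba_i": self.g_gaba_i,
        }


@dataclass
class PopulationState:
    """Derived mean-field quantities of one population."""

    mu: float          # effective mean input, mV
    sigma: float       # input fluctuation magnitude, mV
    tau: float         # effective membrane time constant, ms
    tau_syn: float     # effective synaptic noise time constant, ms
    S: float           # total conductance factor, >= 1
    v_mean: float      # <V>, mV
    kappa: float       # NMDA linearisation factor at <V>
    T: dict = field(default_factory=dict)    # dimensionless-conductance terms (s)
    J: dict = field(default_factory=dict)    # charge per spike, pA*ms
    I0: dict = field(default_factory=dict)   # |mean component currents|, nA

    @property
    def i_syn(self) -> float:
        """Net mean synaptic current I_X + I_AMPA + I_NMDA - I_GABA (nA)."""
        return self.I0["X"] + self.I0["AMPA"] + self.I0["NMDA"] - self.I0["GABA"]


@dataclass
class MeanFieldState:
    """Self-consistent population rates with all derived quantities."""

    nu_e: float
    nu_i: float
    nu_x: float
    pops: dict                 # "E"/"I" -> PopulationState
    conductances: ConductanceSet
    constants: ModelConstants
    residual: float = 0.0      # |nu - phi(nu)| at the reported rates, Hz

    @property
    def i_theta_e(self) -> float:
        """DC current driving the leak-only E neuron to threshold (nA)."""
        ne = self.constants.neuron_e
        return 1e-3 * ne.gm * (ne.theta - ne.VL)

    def current_ratios(self) -> dict:
        """Population-independent balance ratios of mean currents."""
        e = self.pops["E"]
        return {
            "q1": e.I0["NMDA"] / e.I0["GABA"],
            "q2": e.I0["AMPA"] / e.I0["GABA"],
            "q3": e.I0["X"] / self.i_theta_e,
            "IX_IGABA": e.I0["X"] / e.I0["GABA"],
        }


# ---------------------------------------------------------------------------
# transfer function
# ---------------------------------------------------------------------------

def _siegert_integral(a: float, b: float) -> float:
    """sqrt(pi) * integral_a^b exp(x^2)(1+erf(x)) dx via fixed Gauss-Legendre.

    The integrand equals sqrt(pi)*erfcx(-x), smooth on any finite interval.
    """
    if b <= a:
        return -_siegert_integral(b, a) if b < a else 0.0
    half = 0.5 * (b - a)
    mid = 0.5 * (b + a)
    x = mid + half * _GL_NODES
    return math.sqrt(math.pi) * half * float(np.dot(_GL_WEIGHTS, erfcx(-x)))


def transfer_rate(mu: float, sigma: float, tau: float, tau_syn: float,
                  neuron: NeuronPopulationParams) -> float:
    """Stationary rate (Hz) of the noise-driven LIF neuron.

    First-passage rate with the colored-noise threshold correction: the upper
    integration bound carries the sqrt(tau_syn/tau) shift that accounts for
    synaptic filtering of the input fluctuations.  Strictly increasing in
    `mu`, bounded above by the refractory ceiling 1/tau_rp.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive; use "
                         "transfer_rate_deterministic for the noiseless limit")
    if tau <= 0 or tau_syn <= 0:
        raise ValueError("tau and tau_syn must be positive")
    r = tau_syn / tau
    a = (neuron.Vrst - neuron.VL - mu) / sigma
    b = ((neuron.theta - neuron.VL - mu) / sigma) * (1.0 + 0.5 * r) \
        + 1.03 * math.sqrt(r) - 0.5 * r
    # Deep suprathreshold the colored-noise shift can push b below a (the
    # correction is derived for the fluctuation-driven regime); the rate is
    # then refractory-limited.
    integral = _siegert_integral(a, b) if b > a else 0.0
    # times in ms -> rate in kHz -> Hz
    return 1e3 / (neuron.tau_rp + tau * integral)


def transfer_rate_deterministic(mu: float, tau: float,
                                neuron: NeuronPopulationParams) -> float:
    """Noiseless (sigma -> 0) limit of the LIF rate (Hz)."""
    dtheta = neuron.theta - neuron.VL
    if mu <= dtheta:
        return 0.0
    t_isi = neuron.tau_rp + tau * math.log(
        (mu - (neuron.Vrst - neuron.VL)) / (mu - dtheta))
    return 1e3 / t_isi


# ---------------------------------------------------------------------------
# forward evaluation of the mean-field quantities
# ---------------------------------------------------------------------------

def population_state(g: ConductanceSet, pop: str, nu_e: float, nu_i: float,
                     nu_x: float, constants: ModelConstants,
                     v_init: float = -60.0, damping: float = 0.5,
                     tol: float = 1e-9, max_iter: int = 500) -> PopulationState:
    """Evaluate all mean-field quantities of population `pop` at given rates.

    Runs the inner <V>/kappa self-consistency (damped fixed-point iteration):
    kappa is evaluated at the population's own mean potential, which in turn
    depends on mu and the firing rate.
    """
    neuron = constants.neuron(pop)
    v = v_init
    state = None
    for _ in range(max_iter):
        state = _population_quantities(g, pop, nu_e, nu_i, nu_x, constants, v)
        nu_a = nu_e if pop == "E" else nu_i
        v_new = _v_mean(state.mu, nu_a, state.tau, neuron)
        if abs(v_new - v) < tol:
            v = v_new
            break
        v = damping * v_new + (1.0 - damping) * v
    else:
        raise MeanFieldError(
            f"<V> self-consistency for population {pop} did not converge "
            f"(last <V>={v:.6f} mV)")
    return _population_quantities(g, pop, nu_e, nu_i, nu_x, constants, v)


def _v_mean(mu: float, nu: float, tau: float,
            neuron: NeuronPopulationParams) -> float:
    """Mean potential of the spiking neuron (times in ms, nu in Hz)."""
    nu_k = nu * 1e-3  # kHz so nu*tau is dimensionless
    return (mu + neuron.VL
            - (neuron.theta - neuron.Vrst) * nu_k * tau
            - (mu + neuron.VL - neuron.Vrst) * nu_k * neuron.tau_rp)


def _population_quantities(g: ConductanceSet, pop: str, nu_e: float,
                           nu_i: float, nu_x: float,
                           constants: ModelConstants, v: float) -> PopulationState:
    neuron = constants.neuron(pop)
    kin = constants.kinetics
    tau_star_s = kin["AMPA"].tau_star * 1e-3  # s, shared across receptors
    kappa = constants.nmda.kappa(v)
    beta = constants.nmda.beta
    VE, VI, VL = constants.VE, constants.VI, neuron.VL
    CE, CI, CX = constants.CE, constants.CI, constants.CX

    # dimensionless-conductance terms, units of seconds (T * nu_Hz unitless)
    T = {
        "X": g.g("X", pop) * CX * tau_star_s / neuron.gm,
        "AMPA": g.g("AMPA", pop) * CE * tau_star_s / neuron.gm,
        "NMDA1": g.g("NMDA", pop) * CE * tau_star_s / (neuron.gm * kappa),
        "NMDA2": (beta * g.g("NMDA", pop) * CE * tau_star_s
                  * (v - VE) * (kappa - 1.0) / (neuron.gm * kappa ** 2)),
        "GABA": g.g("GABA", pop) * CI * tau_star_s / neuron.gm,
    }
    S = (1.0 + T["X"] * nu_x + (T["AMPA"] + T["NMDA1"] + T["NMDA2"]) * nu_e
         + T["GABA"] * nu_i)
    if S <= 0:
        raise MeanFieldError(
            f"total conductance factor S_{pop} = {S:.3f} <= 0 (NMDA "
            "voltage-derivative term dominates); parameters out of range")
    mu = ((T["X"] * nu_x + T["AMPA"] * nu_e + T["NMDA1"] * nu_e) * (VE - VL)
          + T["NMDA2"] * nu_e * (v - VL)
          + T["GABA"] * nu_i * (VI - VL)) / S
    tau = neuron.tau_m / S  # ms

    # effective synaptic strengths (charge per presynaptic spike, pA*ms)
    tau_star = kin["AMPA"].tau_star  # ms
    J = {
        "X": g.g("X", pop) * (v - VE) * tau_star,
        "AMPA": g.g("AMPA", pop) * (v - VE) * tau_star,
        "NMDA": g.g("NMDA", pop) / kappa * (v - VE) * tau_star,
        "GABA": g.g("GABA", pop) * (v - VI) * tau_star,
    }
    S0 = {"X": CX * nu_x, "AMPA": CE * nu_e, "NMDA": CE * nu_e,
          "GABA": CI * nu_i}  # 1/s

    tau_s = tau * 1e-3
    sig2 = {r: (J[r] / neuron.Cm) ** 2 * 1e-6 * S0[r] * tau_s
            for r in RECEPTORS}  # mV^2
    sigma2 = sum(sig2.values())
    # Noise correlation time: variance-weighted average of the receptors'
    # decay constants — the timescale of the gating autocorrelation.  The
    # latency is a pure delay (it shifts but does not decorrelate the input)
    # and the rise stages are fast against the decays, so neither enters.
    tau_corr = {"X": kin["AMPA"].tau_d, "AMPA": kin["AMPA"].tau_d,
                "NMDA": kin["NMDA"].tau_d, "GABA": kin["GABA"].tau_d}
    if sigma2 > 0:
        tau_syn = sum(sig2[r] * tau_corr[r] for r in RECEPTORS) / sigma2
    else:
        tau_syn = tau_corr["AMPA"]

    I0 = {r: abs(J[r]) * S0[r] * 1e-6 for r in RECEPTORS}  # nA

    return PopulationState(mu=mu, sigma=math.sqrt(sigma2), tau=tau,
                           tau_syn=tau_syn, S=S, v_mean=v, kappa=kappa,
                           T=T, J=J, I0=I0)


def _rates_from_state(g: ConductanceSet, nu_e: float, nu_i: float,
                      nu_x: float, constants: ModelConstants) -> tuple[float, float, dict]:
    pops = {p: population_state(g, p, nu_e, nu_i, nu_x, constants)
            for p in ("E", "I")}
    phi = {}
    for p in ("E", "I"):
        st = pops[p]
        phi[p] = transfer_rate(st.mu, st.sigma, st.tau, st.tau_syn,
                               constants.neuron(p))
    return phi["E"], phi["I"], pops


def solve_rates(g: ConductanceSet, nu_x: float,
                constants: ModelConstants | None = None,
                init: tuple[float, float] | None = None,
                tol: float = 1e-9) -> MeanFieldState:
    """Self-consistent stationary rates for a given conductance set.

    Solves nu = phi(nu) for both populations (including the inner <V>/kappa
    self-consistency).  Raises :class:`MeanFieldError` with the final
    residuals if no fixed point is found from any initial guess.
    """
    constants = constants or load_defaults()

    def residual(nu):
        ne, ni = max(nu[0], 1e-9), max(nu[1], 1e-9)
        try:
            pe, pi_, _ = _rates_from_state(g, ne, ni, nu_x, constants)
        except (MeanFieldError, ValueError):
            return [1e3, 1e3]
        return [pe - ne, pi_ - ni]

    guesses = []
    if init is not None:
        guesses.append(tuple(init))
    guesses += [(5.0, 20.0), (1.0, 5.0), (15.0, 45.0), (0.2, 1.0), (40.0, 90.0)]

    last = None
    for g0 in guesses:
        sol = optimize.root(residual, g0, method="hybr",
                            options={"xtol": 1e-12})
        res = float(np.max(np.abs(sol.fun)))
        last = (sol, res)
        if res < max(tol, 1e-6) and min(sol.x) > 0:
            nu_e, nu_i = float(sol.x[0]), float(sol.x[1])
            _, _, pops = _rates_from_state(g, nu_e, nu_i, nu_x, constants)
            return MeanFieldState(nu_e=nu_e, nu_i=nu_i, nu_x=nu_x, pops=pops,
                                  conductances=g, constants=constants,
                                  residual=res)
    raise MeanFieldError(
        "self-consistent rate equations did not converge; final residual "
        f"{last[1]:.3e} Hz at nu={tuple(last[0].x)}")


# ---------------------------------------------------------------------------
# inverse problem: balance spec -> conductances
# ---------------------------------------------------------------------------

def solve_conductances(spec: BalanceSpec,
                       constants: ModelConstants | None = None,
                       verify: bool = True) -> ConductanceSet:
    """Derive the eight conductances realising a :class:`BalanceSpec`.

    The cross-population balance equalities make the current ratios
    population-independent, so the eight conductances reduce to four unknowns:
    the GABA current magnitudes u_E, u_I and the mean potentials <V_E>, <V_I>.
    Component currents then follow from (q1, q2, q3) by construction, and the
    two rate equations plus the two <V> consistency conditions close the
    system.  A forward :func:`solve_rates` call verifies the round trip.
    """
    constants = constants or load_defaults()
    spec.check_regime()
    ne_p = constants.neuron_e
    i_theta_e = 1e-3 * ne_p.gm * (ne_p.theta - ne_p.VL)  # nA
    i_x_e = spec.q3 * i_theta_e

    def build(u_e, u_i, v_e, v_i) -> ConductanceSet:
        tau_star = constants.kinetics["AMPA"].tau_star  # ms
        CE, CI, CX = constants.CE, constants.CI, constants.CX
        VE, VI = constants.VE, constants.VI
        out = {}
        for pop, u, v in (("E", u_e, v_e), ("I", u_i, v_i)):
            kappa = constants.nmda.kappa(v)
            s_gaba = CI * spec.nu_i_star
            s_exc = CE * spec.nu_e_star
            s_x = CX * spec.nu_x_star
            i_x = i_x_e if pop == "E" else u_i * (i_x_e / u_e)
            # g = I[nA]*1e6 / (|dV| * tau*[ms] * S0[1/s])
            out[f"g_gaba_{pop.lower()}"] = u * 1e6 / ((v - VI) * tau_star * s_gaba)
            out[f"g_ampa_{pop.lower()}"] = spec.q2 * u * 1e6 / ((VE - v) * tau_star * s_exc)
            out[f"g_nmda_{pop.lower()}"] = spec.q1 * u * kappa * 1e6 / ((VE - v) * tau_star * s_exc)
            out[f"g_x_{pop.lower()}"] = i_x * 1e6 / ((VE - v) * tau_star * s_x)
        return ConductanceSet(**out)

    def residual(x):
        if np.max(np.abs(x[:2])) > 8.0:  # |I_GABA| outside (0.3 pA, 3 uA)
            return [1e3] * 4
        u_e, u_i = math.exp(x[0]), math.exp(x[1])
        v_e, v_i = x[2], x[3]
        if v_e >= constants.VE or v_i >= constants.VE:
            return [1e3] * 4
        g = build(u_e, u_i, v_e, v_i)
        res = []
        try:
            for pop, v, nu in (("E", v_e, spec.nu_e_star),
                               ("I", v_i, spec.nu_i_star)):
                st = _population_quantities(g, pop, spec.nu_e_star,
                                            spec.nu_i_star, spec.nu_x_star,
                                            constants, v)
                phi = transfer_rate(st.mu, st.sigma, st.tau, st.tau_syn,
                                    constants.neuron(pop))
                res.append(phi - nu)
                res.append(_v_mean(st.mu, nu, st.tau, constants.neuron(pop)) - v)
        except (MeanFieldError, ValueError):
            return [1e3] * 4
        return res

    u0 = max(i_x_e - 0.7 * i_theta_e, 0.05 * i_theta_e) / max(1.0 - spec.q1 - spec.q2, 0.05)
    rng = np.random.default_rng(12345)
    starts = [(math.log(u0), math.log(u0), -60.0, -60.0)]
    for scale in (0.5, 2.0, 5.0, 0.2, 10.0):
        j = rng.normal(0, 0.1, 2)
        starts.append((math.log(u0 * scale) + j[0], math.log(u0 * scale) + j[1],
                       -60.0, -60.0))

    best = None
    for x0 in starts:
        sol = optimize.root(residual, x0, method="hybr",
                            options={"xtol": 1e-13})
        res = float(np.max(np.abs(sol.fun)))
        if best is None or res < best[1]:
            best = (sol, res)
        if res < 1e-8:
            break
    sol, res = best
    if res > 1e-6:
        raise MeanFieldError(
            f"conductance inversion failed for {spec}: residual {res:.3e} "
            "(rate equations / <V> consistency)")
    g = build(math.exp(sol.x[0]), math.exp(sol.x[1]), sol.x[2], sol.x[3])

    if verify:
        state = solve_rates(g, spec.nu_x_star, constants,
                            init=(spec.nu_e_star, spec.nu_i_star))
        err_e = abs(state.nu_e - spec.nu_e_star) / spec.nu_e_star
        err_i = abs(state.nu_i - spec.nu_i_star) / spec.nu_i_star
        if max(err_e, err_i) > 1e-3:
            raise MeanFieldError(
                f"round-trip verification failed: got rates "
                f"({state.nu_e:.4f}, {state.nu_i:.4f}) Hz for {spec}")
    return g


def mean_field_state_at(g: ConductanceSet, nu_e: float, nu_i: float,
                        nu_x: float,
                        constants: ModelConstants | None = None) -> MeanFieldState:
    """Evaluate the mean-field state at externally imposed rates (no solve)."""
    constants = constants or load_defaults()
    pe, pi_, pops = _rates_from_state(g, nu_e, nu_i, nu_x, constants)
    return MeanFieldState(nu_e=nu_e, nu_i=nu_i, nu_x=nu_x, pops=pops,
                          conductances=g, constants=constants,
                          residual=float(max(abs(pe - nu_e), abs(pi_ - nu_i))))
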