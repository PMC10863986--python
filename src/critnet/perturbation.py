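"""First-order theory of the instability growth rate around the critical point.

Linearising the mean-field rate equations and the loop (stability) equations
around a critical-state network (lambda = 0) yields

    dlam  = L_A (dg_A/g* + dphi'_E/phi'_E) + L_N (dg_N/g* + dphi'_E/phi'_E)
            - L_G (dg_G/g* + dphi'_I/phi'_I)

with receptor constants Lambda_R (and Omega_R for the frequency shift)
determined by the critical network's loop factors, and the relative slope
changes given by

    dphi'_a/phi'_a = U_a (I_X/I_G dnu_x + I_A/I_G dg_A + I_N/I_G dg_N - dg_G)

where the slope-sensitivity vector U = -a~ W + b~0 combines the linearised
rate response W = -(a - I)^-1 b0 with the curvature of the current-frequency
response function.  The AMPA term dominates lambda: NMDA is attenuated by
its slow decay, GABA by a near-90-degree synaptic phase lag, so NMDAR and
external drive act almost purely through the operating point (the slope
terms) — the circuit mechanism for drive-induced synchronisation and its
abolition by NMDAR blockade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .meanfield import MeanFieldState, transfer_rate
from .stability import StabilityResult, synaptic_filter

__all__ = [
    "PerturbationCoefficients",
    "ParameterDelta",
    "critical_coefficients",
    "linearized_growth_rate",
    "linearized_rate_change",
]

_REC = ("AMPA", "NMDA", "GABA")


@dataclass(frozen=True)
class ParameterDelta:
    """Relative changes of the four perturbable parameters.

    Components of the Delta-p vector: d_nu_x = dnu_X/nu_X*, and the relative
    conductance changes (E and I targets scaled by the same factor).
    """

    d_nu_x: float = 0.0
    d_g_ampa: float = 0.0
    d_g_nmda: float = 0.0
    d_g_gaba: float = 0.0

    def __post_init__(self) -> None:
        if min(self.d_g_ampa, self.d_g_nmda, self.d_g_gaba) < -1.0:
            raise ValueError("conductances cannot fall below zero "
                             "(relative change < -1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.d_nu_x, self.d_g_ampa, self.d_g_nmda,
                         self.d_g_gaba])


@dataclass
class PerturbationCoefficients:
    """All constants of the first-order expansion at the critical network."""

    Lambda: dict               # receptor -> 1/s per unit relative change
    Omega: dict                # receptor -> rad/s per unit relative change
    tau1: dict                 # filter-derivative time scales (s)
    tau2: dict
    tau_plus: dict
    tau_minus: dict
    T_plus: float
    T_minus: float
    T0: float
    Phi0: float
    W: np.ndarray              # (W_E, W_I), Hz per unit bracket
    U: np.ndarray              # (U_E, U_I), dimensionless
    a: np.ndarray              # 2x2 rate-linearisation matrix
    b0: np.ndarray             # 2-vector
    a_tilde: np.ndarray
    b_tilde0: np.ndarray
    ratios: dict               # I_X/I_GABA, I_AMPA/I_GABA, I_NMDA/I_GABA
    omega_c: float             # critical angular frequency (rad/s)
    I0: float                  # proportionality constant dI_syn per bracket (nA)

    @property
    def U_E(self) -> float:
        return float(self.U[0])

    @property
    def U_I(self) -> float:
        return float(self.U[1])

    def bracket(self, delta: ParameterDelta) -> float:
        """The common current combination multiplying W and U."""
        r = self.ratios
        return (r["X"] * delta.d_nu_x + r["AMPA"] * delta.d_g_ampa
                + r["NMDA"] * delta.d_g_nmda - delta.d_g_gaba)


# ---------------------------------------------------------------------------
# derivatives of the transfer function
# ---------------------------------------------------------------------------

def _phi_derivs(state: MeanFieldState, pop: str) -> dict:
    """phi'_mu, phi'_tau, phi''_mumu, phi''_taumu by nested central differences.

    Relative steps 1e-3 (outer) / 1e-4 (inner) with a step-halving
    (Richardson) consistency check on the second derivatives.
    """
    st = state.pops[pop]
    neuron = state.constants.neuron(pop)

    def phi(mu, tau):
        return transfer_rate(mu, st.sigma, tau, st.tau_syn, neuron)

    mu0, tau0 = st.mu, st.tau
    h_mu_in = 1e-4 * abs(mu0)
    h_mu_out = 1e-3 * abs(mu0)
    h_tau = 1e-3 * tau0

    def d_mu(mu, h=h_mu_in):
        return (phi(mu + h, tau0) - phi(mu - h, tau0)) / (2 * h)

    def d_tau(tau):
        return (phi(mu0, tau + h_tau) - phi(mu0, tau - h_tau)) / (2 * h_tau)

    def d2_mumu(h):
        return (phi(mu0 + h, tau0) - 2 * phi(mu0, tau0)
                + phi(mu0 - h, tau0)) / h ** 2

    def d2_taumu(h):
        # d/dtau of phi'_mu
        hi = (phi(mu0 + h_mu_in, tau0 + h) - phi(mu0 - h_mu_in, tau0 + h)) / (2 * h_mu_in)
        lo = (phi(mu0 + h_mu_in, tau0 - h) - phi(mu0 - h_mu_in, tau0 - h)) / (2 * h_mu_in)
        return (hi - lo) / (2 * h)

    d2m = d2_mumu(h_mu_out)
    d2m_half = d2_mumu(0.5 * h_mu_out)
    if abs(d2m - d2m_half) > 0.05 * max(abs(d2m_half), 1e-12):
        d2m = d2m_half
    d2tm = d2_taumu(h_tau)
    d2tm_half = d2_taumu(0.5 * h_tau)
    if abs(d2tm - d2tm_half) > 0.05 * max(abs(d2tm_half), 1e-12):
        d2tm = d2tm_half

    return {"mu": d_mu(mu0), "tau": d_tau(tau0),
            "mumu": d2m, "taumu": d2tm}


def _linearisation_blocks(state: MeanFieldState) -> dict:
    """The a^mu/a^tau/b^mu/b^tau coefficient blocks for both populations.

    a-blocks: response of (mu_a, tau_a) to the population rates (per Hz);
    b-blocks: response to unit relative changes of (nu_X, g_A, g_N, g_G).
    """
    c = state.constants
    nu_e, nu_i, nu_x = state.nu_e, state.nu_i, state.nu_x
    out = {}
    for pop in ("E", "I"):
        st = state.pops[pop]
        T, S, mu = st.T, st.S, st.mu
        VE, VI, VL = c.VE, c.VI, c.neuron(pop).VL
        v0 = st.v_mean
        tau_s = st.tau * 1e-3  # a^tau entries in s so Delta-tau is in s

        a_mu = {
            "E": ((T["AMPA"] + T["NMDA1"]) * (VE - VL) + T["NMDA2"] * (v0 - VL)
                  - mu * (T["AMPA"] + T["NMDA1"] + T["NMDA2"])) / S,
            "I": T["GABA"] * (VI - mu - VL) / S,
        }
        b_mu = {
            "AMPA": T["AMPA"] * (VE - mu - VL) * nu_e / S,
            "NMDA": (T["NMDA1"] * (VE - mu - VL)
                     + T["NMDA2"] * (v0 - mu - VL)) * nu_e / S,
            "GABA": T["GABA"] * (VI - mu - VL) * nu_i / S,
            "X": T["X"] * (VE - mu - VL) * nu_x / S,
        }
        a_tau = {
            "E": -(T["AMPA"] + T["NMDA1"] + T["NMDA2"]) * tau_s / S,
            "I": -T["GABA"] * tau_s / S,
        }
        b_tau = {
            "AMPA": -T["AMPA"] * tau_s * nu_e / S,
            "NMDA": -(T["NMDA1"] + T["NMDA2"]) * tau_s * nu_e / S,
            "GABA": -T["GABA"] * tau_s * nu_i / S,
            "X": -T["X"] * tau_s * nu_x / S,
        }
        out[pop] = {"a_mu": a_mu, "b_mu": b_mu, "a_tau": a_tau, "b_tau": b_tau}
    return out


def critical_coefficients(state: MeanFieldState,
                          stability: StabilityResult,
                          lam_tol: float = 1e-3) -> PerturbationCoefficients:
    """Compute every constant of the expansion at a critical network.

    `state` must be the mean-field operating point of a network on the
    critical line (|lambda| < `lam_tol` 1/s); `stability` its stability
    solve.  Both printed forms of the (Lambda_R, Omega_R) constants are
    evaluated and asserted to agree.
    """
    if abs(stability.lam) > lam_tol:
        raise ValueError(
            f"reference network is not critical: lambda = {stability.lam:.3g} "
            f"1/s exceeds {lam_tol}")
    c = state.constants
    omega = stability.omega

    # --- loop-equation side: Lambda_R / Omega_R ---------------------------
    tau1, tau2, taup, taum, X, Phi = {}, {}, {}, {}, {}, {}
    for r in _REC:
        kin = c.kinetics[r]
        tl, tr, td = kin.tau_l * 1e-3, kin.tau_r * 1e-3, kin.tau_d * 1e-3
        tau1[r] = (tl + tr / (1 + (omega * tr) ** 2)
                   + td / (1 + (omega * td) ** 2))
        tau2[r] = (omega * tr ** 2 / (1 + (omega * tr) ** 2)
                   + omega * td ** 2 / (1 + (omega * td) ** 2))
        q, phi = synaptic_filter(0.0, omega, kin)
        X[r] = stability.X[r]
        Phi[r] = phi
        taup[r] = tau1[r] * math.sin(phi) + tau2[r] * math.cos(phi)
        taum[r] = tau1[r] * math.cos(phi) - tau2[r] * math.sin(phi)

    sgn = {"AMPA": 1.0, "NMDA": 1.0, "GABA": -1.0}
    T_plus = sum(sgn[r] * X[r] * taup[r] for r in _REC)
    T_minus = sum(sgn[r] * X[r] * taum[r] for r in _REC)
    T0 = math.hypot(T_plus, T_minus)
    Phi0 = -math.atan2(T_plus, T_minus)

    Lambda, Omega = {}, {}
    for r in _REC:
        lam_r = X[r] / T0 ** 2 * (T_plus * math.sin(Phi[r])
                                  + T_minus * math.cos(Phi[r]))
        om_r = X[r] / T0 ** 2 * (T_plus * math.cos(Phi[r])
                                 - T_minus * math.sin(Phi[r]))
        lam_r2 = X[r] / T0 * math.cos(Phi[r] + Phi0)
        om_r2 = -X[r] / T0 * math.sin(Phi[r] + Phi0)
        if not (math.isclose(lam_r, lam_r2, rel_tol=1e-9, abs_tol=1e-12)
                and math.isclose(om_r, om_r2, rel_tol=1e-9, abs_tol=1e-12)):
            raise AssertionError(
                f"the two printed forms of (Lambda, Omega)_{r} disagree: "
                f"({lam_r}, {om_r}) vs ({lam_r2}, {om_r2})")
        Lambda[r], Omega[r] = lam_r, om_r

    # --- mean-field side: W and U ----------------------------------------
    blocks = _linearisation_blocks(state)
    derivs = {p: _phi_derivs(state, p) for p in ("E", "I")}

    a = np.empty((2, 2))
    a_t = np.empty((2, 2))
    for i, pop in enumerate(("E", "I")):
        bl, d = blocks[pop], derivs[pop]
        st = state.pops[pop]
        tau_s = st.tau * 1e-3
        for j, src in enumerate(("E", "I")):
            a[i, j] = d["mu"] * bl["a_mu"][src] + d["tau"] * bl["a_tau"][src] * 1e3
            # a_tau entries are in s; phi'_tau is per ms -> convert
            a_t[i, j] = (d["mumu"] / d["mu"] * bl["a_mu"][src]
                         + (d["taumu"] / d["mu"] + 1.0 / st.tau)
                         * bl["a_tau"][src] * 1e3)

    b0 = np.empty(2)
    b_t0 = np.empty(2)
    for i, pop in enumerate(("E", "I")):
        st = state.pops[pop]
        d = derivs[pop]
        gm = c.neuron(pop).gm
        i_gaba_mV = 1e3 * st.I0["GABA"] / (gm * st.S)  # nA/nS -> mV
        b0[i] = d["mu"] * i_gaba_mV
        b_t0[i] = d["mumu"] / d["mu"] * i_gaba_mV

    W = -np.linalg.solve(a - np.eye(2), b0)
    # U combines the rate response with the slope curvature: substituting
    # dnu = W * bracket into the slope-change expansion gives
    # dphi'/phi' = (a~ W + b~0) * bracket.  (Sign fixed by the requirement
    # that the expansion reproduce exact re-solves as |dp| -> 0.)
    U = a_t @ W + b_t0

    e = state.pops["E"]
    ratios = {"X": e.I0["X"] / e.I0["GABA"],
              "AMPA": e.I0["AMPA"] / e.I0["GABA"],
              "NMDA": e.I0["NMDA"] / e.I0["GABA"]}

    return PerturbationCoefficients(
        Lambda=Lambda, Omega=Omega, tau1=tau1, tau2=tau2, tau_plus=taup,
        tau_minus=taum, T_plus=T_plus, T_minus=T_minus, T0=T0, Phi0=Phi0,
        W=W, U=U, a=a, b0=b0, a_tilde=a_t, b_tilde0=b_t0, ratios=ratios,
        omega_c=omega, I0=e.I0["GABA"],
    )


def linearized_growth_rate(coeffs: PerturbationCoefficients,
                           delta: ParameterDelta,
                           warn_beyond: float = 0.3) -> dict:
    """First-order growth rate and frequency shift for a parameter change.

    Returns lam_approx (1/s), omega_shift (rad/s), the three-term breakdown
    whose AMPA/NMDA/GABA entries sum exactly to lam_approx, and the reduced
    form valid when only the external rate and the NMDAR conductance move.
    """
    import warnings

    dp = delta.as_array()
    if np.max(np.abs(dp)) > warn_beyond:
        warnings.warn("parameter change beyond the first-order validity "
                      f"domain (|dp| > {warn_beyond})", stacklevel=2)
    bracket = coeffs.bracket(delta)
    dphi_E = coeffs.U_E * bracket
    dphi_I = coeffs.U_I * bracket

    terms = {
        "AMPA": coeffs.Lambda["AMPA"] * (delta.d_g_ampa + dphi_E),
        "NMDA": coeffs.Lambda["NMDA"] * (delta.d_g_nmda + dphi_E),
        "GABA": -coeffs.Lambda["GABA"] * (delta.d_g_gaba + dphi_I),
    }
    lam = sum(terms.values())
    omega_shift = (coeffs.Omega["AMPA"] * (delta.d_g_ampa + dphi_E)
                   + coeffs.Omega["NMDA"] * (delta.d_g_nmda + dphi_E)
                   - coeffs.Omega["GABA"] * (delta.d_g_gaba + dphi_I))
    # reduced form: lambda/L_A = U_E (I_X/I_G dnu_x + I_N/I_G dg_N)
    reduced = (coeffs.Lambda["AMPA"] * coeffs.U_E
               * (coeffs.ratios["X"] * delta.d_nu_x
                  + coeffs.ratios["NMDA"] * delta.d_g_nmda))
    return {"lam_approx": lam, "omega_shift": omega_shift,
            "terms": terms, "reduced_lam": reduced,
            "dphi_rel": {"E": dphi_E, "I": dphi_I}}


def linearized_rate_change(coeffs: PerturbationCoefficients,
                           delta: ParameterDelta) -> tuple[float, float]:
    """First-order population-rate changes (d nu_E, d nu_I) in Hz."""
    bracket = coeffs.bracket(delta)
    return float(coeffs.W[0] * bracket), float(coeffs.W[1] * bracket)
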