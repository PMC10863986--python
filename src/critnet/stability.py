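"""Linear stability of the asynchronous state and state-diagram mapping.

Small oscillatory perturbations nu_a(t) = nu_a0 (1 + eps_a exp(lambda t + i omega t))
of the stationary rates are filtered by the two-stage synaptic cascades.
Writing Q_R, Phi_R for the gain and phase of receptor R's cascade at
(lambda, omega) and A_a for the dimensionless slope of the current-frequency
response, self-consistency of the loop requires

    X_A cos Phi_A + X_N cos Phi_N - X_G cos Phi_G = 1
    X_A sin Phi_A + X_N sin Phi_N - X_G sin Phi_G = 0

with X_R = A_aR (I_R / I_syn) Q_R (aR = E for glutamatergic, I for GABA).
The dominant root (largest lambda) gives the growth rate and the network
frequency f_ntwrk = omega / 2 pi; the critical line is the locus lambda = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .meanfield import (BalanceSpec, ConductanceSet, MeanFieldError,
                        MeanFieldState, mean_field_state_at,
                        solve_conductances, solve_rates, transfer_rate)
from .params import ModelConstants, ReceptorKinetics, load_defaults

__all__ = [
    "StabilityResult",
    "StateDiagram",
    "synaptic_filter",
    "response_slope",
    "solve_instability",
    "map_state_diagram",
    "critical_line_crossing",
    "StabilityError",
]


class StabilityError(RuntimeError):
    pass


@dataclass
class StabilityResult:
    """Growth rate and frequency of the dominant oscillatory mode."""

    lam: float                 # 1/s
    omega: float               # rad/s
    A_E: float
    A_I: float
    Q: dict                    # receptor -> gain at (lam, omega)
    Phi: dict                  # receptor -> phase (rad)
    X: dict                    # receptor -> loop factor
    residual: float
    eps_ratio: float           # |eps_E / eps_I| = A_E / A_I (zero phase lag)

    @property
    def f_ntwrk(self) -> float:
        """Oscillation frequency omega / 2 pi in Hz."""
        return self.omega / (2.0 * math.pi)


@dataclass
class StateDiagram:
    """lambda and omega fields over a 2-D parameter grid."""

    plane: str
    x_values: np.ndarray
    y_values: np.ndarray
    lam_field: np.ndarray      # shape (len(y), len(x)), NaN where infeasible
    omega_field: np.ndarray
    feasible: np.ndarray
    critical_line: list = field(default_factory=list)  # (x, y) polyline points

    def to_frame(self):
        import pandas as pd

        xg, yg = np.meshgrid(self.x_values, self.y_values)
        return pd.DataFrame({
            "x": xg.ravel(), "y": yg.ravel(),
            "lam": self.lam_field.ravel(),
            "omega": self.omega_field.ravel(),
            "feasible": self.feasible.ravel(),
        })


def synaptic_filter(lam: float, omega: float,
                    kin: ReceptorKinetics) -> tuple[float, float]:
    """Gain Q and phase Phi (rad) of the gating cascade at (lambda, omega).

    lam in 1/s, omega in rad/s; kinetics constants in ms.  At (0, 0) the
    filter is transparent: Q = 1, Phi = 0.
    """
    tl, tr, td = kin.tau_l * 1e-3, kin.tau_r * 1e-3, kin.tau_d * 1e-3
    q = math.exp(-lam * tl) / math.sqrt(
        ((1.0 + lam * tr) ** 2 + (omega * tr) ** 2)
        * ((1.0 + lam * td) ** 2 + (omega * td) ** 2))
    phi = (omega * tl + math.atan2(omega * tr, 1.0 + lam * tr)
           + math.atan2(omega * td, 1.0 + lam * td))
    return q, phi


def response_slope(state: MeanFieldState, pop: str,
                   rel_step: float = 1e-4) -> float:
    """Dimensionless slope A_a = (I_syn/nu) dphi/dI_syn at the operating point.

    dphi/dI_syn is evaluated through the linear relation d(mu) = dI/(gm S)
    between total current and effective mean input, by central differences on
    mu with a step-halving consistency check.
    """
    st = state.pops[pop]
    neuron = state.constants.neuron(pop)
    i_syn = st.i_syn
    # dmu (mV) corresponding to a relative current step
    dmu_per_nA = 1e3 / (neuron.gm * st.S)  # mV per nA

    def slope(h_nA):
        h_mu = h_nA * dmu_per_nA
        hi = transfer_rate(st.mu + h_mu, st.sigma, st.tau, st.tau_syn, neuron)
        lo = transfer_rate(st.mu - h_mu, st.sigma, st.tau, st.tau_syn, neuron)
        return (hi - lo) / (2.0 * h_nA)  # Hz/nA

    h = max(abs(i_syn), 0.1) * rel_step
    d1, d2 = slope(h), slope(0.5 * h)
    if abs(d1 - d2) > 1e-3 * max(abs(d2), 1e-12):
        d2 = slope(0.25 * h)  # one more halving if not yet converged
    nu = state.nu_e if pop == "E" else state.nu_i
    return i_syn / nu * d2


def _loop_factors(state: MeanFieldState) -> tuple[float, float, dict]:
    a_e = response_slope(state, "E")
    a_i = response_slope(state, "I")
    e = state.pops["E"]
    ratios = {r: e.I0[r] / e.i_syn for r in ("AMPA", "NMDA", "GABA")}
    return a_e, a_i, ratios


def _residual(lam, omega, a_e, a_i, ratios, kin):
    xs, terms = {}, np.zeros(2)
    for r, a in (("AMPA", a_e), ("NMDA", a_e), ("GABA", a_i)):
        q, phi = synaptic_filter(lam, omega, kin[r])
        sgn = -1.0 if r == "GABA" else 1.0
        x = a * ratios[r] * q
        xs[r] = (x, q, phi)
        terms[0] += sgn * x * math.cos(phi)
        terms[1] += sgn * x * math.sin(phi)
    return np.array([terms[0] - 1.0, terms[1]]), xs


def solve_instability(state: MeanFieldState,
                      f_band: tuple[float, float] = (5.0, 200.0),
                      tol: float = 1e-10) -> StabilityResult:
    """Dominant (lambda, omega) root of the loop equations at `state`.

    The root search seeds a damped Newton solve on a grid of candidate
    frequencies and growth rates and reports the root with the largest
    lambda whose frequency lies inside `f_band` (Hz).
    """
    a_e, a_i, ratios = _loop_factors(state)
    kin = state.constants.kinetics

    def fun(z):
        return _residual(z[0], z[1], a_e, a_i, ratios, kin)[0]

    roots = []
    for f0 in (10, 20, 30, 40, 50, 58, 70, 80, 100, 120):
        for lam0 in (-100.0, 0.0, 100.0):
            z0 = np.array([lam0, 2.0 * math.pi * f0])
            sol = optimize.root(fun, z0, method="hybr",
                                options={"xtol": 1e-13})
            if not sol.success:
                continue
            lam, omega = float(sol.x[0]), float(sol.x[1])
            res = float(np.max(np.abs(sol.fun)))
            if res > 1e-8:
                continue
            f = abs(omega) / (2 * math.pi)
            if not (f_band[0] <= f <= f_band[1]):
                continue
            omega = abs(omega)  # roots come in conjugate pairs
            if not any(abs(lam - r[0]) < 1e-4 and abs(omega - r[1]) < 1e-4
                       for r in roots):
                roots.append((lam, omega, res))
    if not roots:
        # diagnostic: residual extrema over the scanned band
        grid = [(lam0, 2 * math.pi * f0)
                for f0 in range(int(f_band[0]), int(f_band[1]), 10)
                for lam0 in (-200, -100, 0, 100, 200)]
        norms = sorted((float(np.linalg.norm(fun(np.array(z)))), z) for z in grid)
        raise StabilityError(
            "no (lambda, omega) root found in the search band; smallest "
            f"residuals at (lam, omega)={[(n[1], round(n[0], 3)) for n in norms[:3]]}")

    lam, omega, res = max(roots, key=lambda r: r[0])
    _, xs = _residual(lam, omega, a_e, a_i, ratios, kin)
    return StabilityResult(
        lam=lam, omega=omega, A_E=a_e, A_I=a_i,
        Q={r: xs[r][1] for r in xs}, Phi={r: xs[r][2] for r in xs},
        X={r: xs[r][0] for r in xs}, residual=res,
        eps_ratio=a_e / a_i,
    )


# ---------------------------------------------------------------------------
# state diagrams
# ---------------------------------------------------------------------------

def _solve_point_q_plane(q2: float, q3: float, base: BalanceSpec,
                         constants: ModelConstants):
    import dataclasses

    spec = dataclasses.replace(base, q2=q2, q3=q3)
    g = solve_conductances(spec, constants, verify=False)
    state = mean_field_state_at(g, spec.nu_e_star, spec.nu_i_star,
                                spec.nu_x_star, constants)
    return solve_instability(state)


def _solve_point_drive_plane(nu_x_rel: float, g_nmda_rel: float,
                             g_ref: ConductanceSet, nu_x_star: float,
                             constants: ModelConstants):
    g = g_ref.scaled(nmda=g_nmda_rel)
    state = solve_rates(g, nu_x_rel * nu_x_star, constants)
    return solve_instability(state)


def map_state_diagram(plane: str, x_values, y_values,
                      base: BalanceSpec | None = None,
                      g_ref: ConductanceSet | None = None,
                      nu_x_star: float = 5.0,
                      constants: ModelConstants | None = None,
                      refine_critical: bool = True,
                      lam_tol: float = 1e-3) -> StateDiagram:
    """Map lambda and omega over a grid in one of the two parameter planes.

    plane="q" :    x = q2 = I_AMPA/I_GABA, y = q3 = I_X,E/I_theta,E; every
                   grid point re-derives its conductances from `base`.
    plane="drive": x = nu_X/nu_X*, y = g_NMDA/g_NMDA*; conductances are
                   scaled from the reference set `g_ref` (same factor for E
                   and I targets) and the operating point is re-solved.

    Infeasible cells (no mean-field solution) are marked NaN, not fatal.
    The critical line is traced by bisection between sign-change brackets
    along grid rows and columns, to |lambda| < `lam_tol` (1/s).
    """
    constants = constants or load_defaults()
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)

    if plane == "q":
        if base is None:
            raise ValueError("plane='q' requires a base BalanceSpec")
        point = lambda x, y: _solve_point_q_plane(x, y, base, constants)
    elif plane == "drive":
        if g_ref is None:
            raise ValueError("plane='drive' requires reference conductances")
        point = lambda x, y: _solve_point_drive_plane(x, y, g_ref, nu_x_star,
                                                      constants)
    else:
        raise ValueError(f"unknown plane {plane!r}")

    ny, nx = len(y_values), len(x_values)
    lam = np.full((ny, nx), np.nan)
    omg = np.full((ny, nx), np.nan)
    ok = np.zeros((ny, nx), dtype=bool)
    for iy, y in enumerate(y_values):
        for ix, x in enumerate(x_values):
            try:
                r = point(x, y)
            except (MeanFieldError, StabilityError):
                continue
            lam[iy, ix] = r.lam
            omg[iy, ix] = r.omega
            ok[iy, ix] = True
    if not ok.any():
        raise StabilityError("entire grid infeasible")

    line = []
    if refine_critical:
        def bisect(p_lo, p_hi, fixed, along):
            """Bisect lambda=0 between two grid points along one axis."""
            f = lambda t: point(*((t, fixed) if along == "x" else (fixed, t))).lam
            lo, hi = p_lo, p_hi
            flo = f(lo)
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                fm = f(mid)
                if abs(fm) < lam_tol:
                    return mid
                if (fm > 0) == (flo > 0):
                    lo, flo = mid, fm
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        for iy in range(ny):
            row = lam[iy]
            for ix in range(nx - 1):
                if ok[iy, ix] and ok[iy, ix + 1] and row[ix] * row[ix + 1] < 0:
                    try:
                        xc = bisect(x_values[ix], x_values[ix + 1],
                                    y_values[iy], "x")
                        line.append((float(xc), float(y_values[iy])))
                    except (MeanFieldError, StabilityError):
                        pass
        for ix in range(nx):
            col = lam[:, ix]
            for iy in range(ny - 1):
                if ok[iy, ix] and ok[iy + 1, ix] and col[iy] * col[iy + 1] < 0:
                    try:
                        yc = bisect(y_values[iy], y_values[iy + 1],
                                    x_values[ix], "y")
                        line.append((float(x_values[ix]), float(yc)))
                    except (MeanFieldError, StabilityError):
                        pass

    return StateDiagram(plane=plane, x_values=x_values, y_values=y_values,
                        lam_field=lam, omega_field=omg, feasible=ok,
                        critical_line=sorted(line))


def critical_line_crossing(base: BalanceSpec, q2: float,
                           q3_bracket: tuple[float, float] = (1.0, 1.3),
                           constants: ModelConstants | None = None,
                           lam_tol: float = 1e-3) -> tuple[float, StabilityResult]:
    """Find q3 on the critical line (lambda = 0) at fixed q2 by bisection."""
    import dataclasses

    constants = constants or load_defaults()

    def lam_at(q3):
        return _solve_point_q_plane(q2, q3, base, constants)

    lo, hi = q3_bracket
    rlo, rhi = lam_at(lo), lam_at(hi)
    if rlo.lam * rhi.lam > 0:
        raise StabilityError(
            f"no lambda sign change in q3 bracket {q3_bracket} at q2={q2}: "
            f"lam({lo})={rlo.lam:.2f}, lam({hi})={rhi.lam:.2f}")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        rm = lam_at(mid)
        if abs(rm.lam) < lam_tol:
            return mid, rm
        if (rm.lam > 0) == (rlo.lam > 0):
            lo, rlo = mid, rm
        else:
            hi = mid
    return mid, rm
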