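# Methods

## Model

The circuit is a sparsely connected recurrent network of N leaky
integrate-and-fire neurons, N_E = 0.8N excitatory and N_I = 0.2N
inhibitory, each pair connected independently with probability p (defaults
N = 5000, p = 0.2, so C_E = 800, C_I = 200 mean in-degrees).  Below
threshold,

    C_m dV/dt = −g_m (V − V_L) − i_syn(t),
    i_syn = i_AMPA + i_NMDA + i_GABA + i_X,

with a spike emitted at θ = −50 mV, reset to V_rst = −55 mV and an absolute
refractory period τ_rp (E: 2 ms, I: 1 ms).  E: C_m = 0.5 nF, g_m = 25 nS;
I: 0.2 nF, 20 nS; V_L = −70 mV.  Each current is a maximal conductance
times a gating variable times the driving force; the NMDA current carries
the magnesium-block factor 1/(1 + [Mg]/γ · e^{−βV}) (β = 0.062 mV⁻¹,
γ = 3.57 mM, [Mg] = 1 mM), used in full (non-linearized) form by the
simulator.  Gating follows a latency + rise + decay cascade
(τ_l/τ_r/τ_d: AMPA 1/0.2/2, NMDA 1/2/100, GABA 1/0.5/5 ms) whose impulse
response integrates to τ* regardless of shape; external synapses are
AMPAR-mediated.  Units repo-wide: mV, ms, nS, nF, Hz; currents in nA.

Two conventions close gaps the constants table leaves open, and both cancel
identically between theory and simulation because the inverse solver
produces conductances under the same conventions the simulator uses:
τ* = 1 ms (only g_R·τ* carries charge), and the external in-degree
C_X = C_E = 800 (external afferents stand for an excitatory population of
the same size as the recurrent one).

## Simulator

Heun (RK2) integration of the membrane equation at Δt = 0.1 ms, with the
synaptic gating advanced by the *exact* exponential propagator of the
linear two-stage filter inside each step and spike arrivals applied as
jumps x ← x + τ*/τ_r at step boundaries.  We verified that naively applying
RK2 to the gating cascade as well systematically inflates the effective
AMPA charge (τ_r = 0.2 ms is comparable to Δt) and with it the recurrent
excitation, so exact propagation is used throughout.  Threshold crossings
are located by linear interpolation inside the step; the neuron is clamped
at V_rst until the refractory period (measured from the interpolated spike
time) has elapsed.  Because all synapses of one receptor type share
kinetics, each neuron keeps one aggregated (x, s) pair per receptor type —
exactly equivalent to per-synapse states.  Recurrent arrivals pass through
a per-receptor ring buffer implementing the 1 ms latency in units of Δt.
External drive is one aggregate Poisson process per neuron of rate
C_X·ν_X(t), independent across neurons and trials (the superposition of C_X
independent afferents); a shared-afferent pool was evaluated and rejected —
its common-mode input is cancelled by the balanced recurrent feedback and
measurably suppresses the stationary rates below the mean-field
prescription.  Trial seeds derive from one master seed by counter-based
splitting.

## Mean field

Population-averaged inputs give each population an effective membrane
equation with mean drive μ_α, noise magnitude σ_α, time constant
τ_α = τ_m/S_α (S_α the total conductance factor), and a colored-noise
correlation time τ_syn,α.  The NMDA voltage dependence is linearized around
the population mean potential ⟨V_α⟩ with κ = 1 + [Mg]/γ·e^{−β⟨V⟩}; ⟨V_α⟩
itself is solved self-consistently (damped fixed-point iteration, damping
0.5, tolerance 1e−9 mV) together with the rate-dependent reset/refractory
correction.  The stationary rate is the first-passage result

    φ = [τ_rp + τ √π ∫_a^b e^{x²}(1 + erf x) dx]⁻¹,
    a = (V_rst − V_L − μ)/σ,
    b = (θ − V_L − μ)/σ · (1 + 0.5 r) + 1.03 √r − 0.5 r,  r = τ_syn/τ,

evaluated with 160-node Gauss–Legendre quadrature of erfcx.  A Monte-Carlo
first-passage oracle (Euler integration of the OU-driven neuron) confirms
the formula within ~3% at operating-regime rates (5–45 Hz); the threshold
correction loses accuracy below a few Hz (~15% at 1.5 Hz), a known property
of the small-(τ_syn/τ) expansion.  Deep suprathreshold the correction can
invert the integration bounds; the rate is then refractory-limited and the
integral is clamped at zero.

**Noise correlation time.**  τ_syn,α is the variance-weighted average of
the receptors' *decay* constants, Σ_R σ²_R τ_{R,d} / σ².  The latency is a
pure delay — it shifts the input but does not decorrelate it — and the rise
stages are fast against the decays.  This choice also reproduces the
internally consistent set of downstream constants (critical point at
q₃* = 1.090, onset frequency ~60 Hz, U_E ≈ 2.44), which the
all-three-constants sum does not.

**Inversion.**  With the cross-population balance equalities, the eight
conductances reduce to four unknowns — the GABA current magnitudes u_E, u_I
and the mean potentials ⟨V_E⟩, ⟨V_I⟩.  I_X,E = q₃·I_θ,E is pinned directly
(I_θ,E = g_m,E(θ−V_L) = 0.5 nA, the DC current driving the leak-only E
neuron to threshold), all component currents follow from (q₁, q₂), and a
4-dimensional Newton solve (log-positive current variables, jittered
restarts) enforces the two rate equations and the two ⟨V⟩ consistency
conditions.  Every inversion is verified by a forward rate solve; the
round-trip error is < 0.1% across the regime grid.

## Stability and the critical line

Small oscillatory rate perturbations ∝ e^{(λ+iω)t} pass through each
receptor cascade with gain Q_R and phase Φ_R; self-consistency of the E–I
loop gives two equations in (λ, ω) whose dominant root (largest λ, seeded
from a frequency×growth-rate grid, damped Newton, residual < 1e−8) is
reported.  The dimensionless response slopes A_α =
(I_syn/ν)·φ′_μ/(g_m S) use central differences with step-halving checks.
The critical-state reference network is constructed by bisecting q₃ on the
critical line at q₂ = 0.4 to |λ| < 1e−3 s⁻¹; the result (q₃* = 1.0900)
matches the nominal 1.09 at its quoted precision.  On the critical line the
onset frequency *falls* with the AMPA/GABA balance (≈100 Hz at q₂ = 0.3 to
≈45 Hz at q₂ = 0.5, 58 Hz at 0.4): strengthening the fast excitatory loop
slows the oscillation, the pure-GABA loop being fastest.  The frequency is
nearly independent of the NMDA/GABA balance (< 10% across q₁ = 0.05–0.25).

State diagrams are mapped either in the (q₂, q₃) plane (each cell re-runs
the inversion) or in the (ν_X/ν_X*, g_NMDA/g_NMDA*) plane (conductances
scaled from the reference network, the E and I targets by the same factor;
the operating point re-solved per cell); the critical line is refined by
bisection between sign-change brackets.

## Perturbation theory

Linearizing the rate equations around the critical point gives the
rate-response vector W = −(a − I)⁻¹b₀ and, one derivative order up, the
slope-sensitivity vector U = ãW + b̃₀, where ã and b̃₀ carry the curvature
terms φ″_μμ/φ′_μ and φ″_τμ/φ′_μ + 1/τ (nested central differences,
relative steps 1e−3/1e−4, Richardson step-halving checks).  The sign
convention of U is fixed by requiring that the expansion reproduce exact
re-solves as |Δp| → 0, which it then does to < 1%.  Linearizing the loop
equations gives the receptor constants Λ_R, Ω_R from the filter-derivative
time scales τ_R^(1,2); the two algebraically equivalent printed forms are
computed and asserted to agree at every call.  The first-order Δλ is within
10% of exact stability re-solves for |Δp| ≤ 0.05; the rate linearization is
accurate to ~10% at 3% drive steps but degrades faster (the response grows
superlinearly approaching the instability).  At the critical network
U_E ≈ 2.44 and I_AMPA/I_GABA = 0.4, so U_E·(I_A/I_G) ≈ 1: the indirect
(operating-point) AMPA contribution to λ equals the direct one.  In sweep
contributions the NMDA term is < 2% and the GABA term < 10% of the AMPA
term — NMDAR conductance and external rate move λ almost purely by shifting
the operating point, which is why raised drive synchronizes the intact
network and fails to do so when g_NMDA = 0.

## Spike synchrony estimator

Within a ΔT window (default 100 ms; 200 ms for the stationary-scenario
correlograms), spike trains are binarized at Δt = 1 ms (multiple spikes
clip to 1).  Per pair and trial, ρ_ij(τ)/(ν_i ν_j) is formed in per-bin
probability units with a shrinking-overlap lag convention; trials where
either neuron is silent are excluded for that pair (the ratio is undefined;
exclusions are counted and reported).  Trial averages minus 1 give
c_ij(τ); pair averages give C(τ) with across-pair standard errors;
synchrony is C(0).  Pairs enter only if √(ν_i ν_j) > 1/√(K·ΔT·Δt)
(≈ 7.07 Hz at K = 200, ΔT = 100 ms, Δt = 1 ms) — below that the expected
joint-spike count is under one and the estimate is shot-noise dominated.
Stationary runs are resliced into consecutive windows serving as trials.
Scenario-level pairwise analyses use the highest-rate excitatory neurons as
the analysis pool, mirroring both the admissibility logic and experimental
pair selection.  Side peaks are located on the symmetrized, 3-point-smoothed
correlogram within 10–35 ms; their *prominence* (height above the trough
between lag 0 and the peak) distinguishes an oscillatory modulation from a
flat baseline offset.  The pre-response scenario averages the correlogram
over three half-overlapping window placements before locating the peak
(the pair-averaged correlogram's noise is shared across pairs, so only
more windows reduce it), and a damped-cosine fit supplies the rhythm
frequency as a diagnostic (its period runs 1–2 ms above the peak lag: the
decaying envelope shifts the first maximum of e^{−t/τ_d} cos ωt slightly
early).

## Synthetic ensembles

The fixture generators produce trial-structured ensembles with known
correlation structure: independent Poisson (the null — the estimator is
unbiased within Monte-Carlo error); a multiple-interaction common-input
process (mother train of rate ν/ε, copy probability ε) whose binarized
0-lag correlation has the exact closed form ρ/q² − 1 with
ρ = 1 − 2e^{−νdt} + e^{−νdt(2−ε)}, q = 1 − e^{−νdt}; and doubly stochastic
trains sharing a sinusoidal rate modulation, giving a spectral line at
f_mod and correlogram side peaks at the modulation period.  They emulate
trial structure, low rates and controllable correlations of cortical
ensemble recordings but none of the refractoriness, rate heterogeneity or
non-stationarity of real data — passing these tests validates the
estimator, not any claim about recordings.

## The pre-response epoch and metastability

Two phenomena shape how the drug-naive/drug correlogram contrast is
measured.  First, under long stationary supercritical drive some
connectivity realizations escape, after a few seconds, into a runaway
large-amplitude attractor (population rates tens of Hz, rhythm slowed to
~30 Hz) — the linear gating cascades place no ceiling on the slow NMDA
drive, so the saturated oscillation is bistable near onset.  Second, even
on the moderate branch the mature rhythm runs ~10–20% below the onset
frequency.  The pre-response condition of the task is, however, a *young*
epoch: the drive rises and the rhythm is observed within a couple of
hundred milliseconds.  The pre-response scenario therefore simulates many
short trials (baseline drive 0.97x for 250 ms, a 50 ms ramp to 1.03x, and
a 200 ms analysis window ~100–300 ms after the rise).  In that window the
rhythm sits at the marginal-mode frequency (~48–52 Hz, correlogram period
~20–21 ms, stable across connectivity realizations) and no trial lasts
long enough to reach the runaway attractor.  A small flat positive
correlogram offset (~0.02–0.04) from shared recurrent afferents
(C/N = 0.2) is present in *both* drug conditions in short-trial protocols;
it carries no side-peak prominence and so does not affect the oscillation
contrast.

Regime classification of simulations uses the synchrony estimator
(zero-lag correlation above 3 SE and an absolute floor of 0.05) rather
than a population-rate spectral-peak ratio: near the critical line,
finite-size noise excites the weakly damped mode on the stable side too
(quality factor ~6 at lambda = −30 s⁻¹), so both sides of the line show
gamma-band spectral peaks and only their entrainment amplitude separates
them.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use N = 5000, p = 0.2,
Δt = 0.1 ms; stationary rate estimates use 2.2 s runs (200 ms transient
discarded) averaged over 3 seeds, and the stationary correlogram scenarios
use 20.4 s single runs analysed as ~100 consecutive 200 ms windows over the
80 highest-rate E neurons.  The transient trapezoid protocol (drive
0.97 → 1.05 → 0.97, 100 ms ramps, 400 ms hold, 200 ms padding) defaults to
100 repeats; the test suite runs 30.  Spectra are Welch periodograms of
mean-subtracted 1 ms population-rate series (nperseg ≤ 512); the
oscillatory-regime classifier asks for a 30–80 Hz peak ≥ 3× the median band
power.

## Known limitations

* The mean-field/stability theory carries the standard sparse-network
  approximations (no input correlations, no in-degree heterogeneity), so
  the *simulated* network's effective critical point sits a few percent of
  drive above the theoretical line; near the line, where the saturated
  oscillation amplitude is exquisitely sensitive to that offset, simulated
  rates in the synchronous regime can differ substantially between equally
  faithful implementations (our +5%-drive critical network fires at
  ~9–10 Hz; at +8% it reaches ~12 Hz with a strong ~50 Hz rhythm).
* The colored-noise transfer function is accurate only to a few percent,
  and worse below ~3 Hz (see above); the inversion absorbs this into the
  conductances, so simulated stationary rates still match prescriptions.
* The perturbative theory is first-order: useful to |Δp| ≈ 0.05–0.3
  depending on the observable.
* No finite-size corrections, no spatial structure, no plasticity, no
  GABA_B, single-compartment neurons.
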