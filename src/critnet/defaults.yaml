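# Default model constants (version 1).
# Units repo-wide: mV, ms, nS, nF, Hz; currents reported in nA.
version: 1

# Leaky integrate-and-fire populations
neuron_E:
  Cm: 0.5        # nF
  gm: 25.0       # nS
  VL: -70.0      # mV
  theta: -50.0   # mV
  Vrst: -55.0    # mV
  tau_rp: 2.0    # ms
neuron_I:
  Cm: 0.2
  gm: 20.0
  VL: -70.0
  theta: -50.0
  Vrst: -55.0
  tau_rp: 1.0

# Synaptic reversal potentials (mV)
VE: 0.0
VI: -70.0

# Receptor gating kinetics: latency / rise / decay (ms).
# External (X) synapses are AMPAR-mediated and share AMPA kinetics.
kinetics:
  AMPA: {tau_l: 1.0, tau_r: 0.2, tau_d: 2.0}
  NMDA: {tau_l: 1.0, tau_r: 2.0, tau_d: 100.0}
  GABA: {tau_l: 1.0, tau_r: 0.5, tau_d: 5.0}

# Charge-normalisation constant of the gating cascade (ms); the time integral
# of s(t) after one presynaptic spike.  Only g_R * tau_star enters currents,
# so its value is a pure convention shared by simulator and theory.
tau_star: 1.0

# NMDAR magnesium block
nmda:
  beta: 0.062    # 1/mV
  gamma: 3.57    # mM
  mg: 1.0        # mM

# Network topology
network:
  N: 5000
  f_exc: 0.8     # NE = f_exc * N
  p: 0.2
  # External in-degree; external afferents mimic an excitatory population of
  # the same size as the recurrent one, hence CX = CE = p * NE by default.
  CX: 800
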