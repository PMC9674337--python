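# Channel-set v1: per-region maximal conductance densities (S/cm^2) for the
# reduced LGMD model. HH-style kinetics are defined in neuron_model.py
# (GATE_KINETICS); the densities below were tuned once with
# scripts/tune_model.py so that the cell rests near -65 mV and the reference
# black loom produces a firing profile peaking near projected collision.
densities:
  na:
    SIZ: 0.30
    axon: 0.30
  kdr:
    SIZ: 0.060
    axon: 0.060
  hcn:
    A: 0.00025
    trunk: 0.00005
  kd:
    A: 0.0270
  m:
    axon: 0.0008
  cat:
    SIZ: 0.00012
  kca:
    SIZ: 0.0006
ca_tau_ms: 80.0
ca_phi: 0.2
kca_half: 0.5
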