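# Default experiment configuration for the adapted DA tonic spiker.
model: DA
sampling_ranges:
  Na: [0.0, 60.0]       # assumed (not printed)
  Kd: [0.0, 20.0]       # printed axis maximum
  CaL: [0.0, 0.1]       # printed axis maximum
  CaN: [0.0, 0.12]      # printed axis maximum
  ERG: [0.0, 0.25]      # printed axis maximum
  leak: [0.001, 0.02]   # printed axis maximum (upper); lower assumed
acceptance:
  pattern: tonic
  peak_V_min: 0.0
  hyperpol_V_max: -50.0
  spike_freq: [0.5, 8.0]   # Hz: slow tonic spiking
  duration: 15000.0
  transient: 3000.0
dic_generator:
  free_ranges:
    Na: [0.0, 60.0]
    Kd: [0.0, 8.0]      # calibrated: narrower than the sampling box
    CaL: [0.0, 0.1]
    CaN: [0.0, 0.06]    # calibrated: narrower than the sampling box
    ERG: [0.0, 0.25]
    leak: [0.005, 0.02]
  solve_channels: [Na, CaL, ERG]   # one per timescale: fast, slow, ultraslow
  targets:
    V_th: -61.0
    gf: 0.0
    gs: -1.2
    gu: 4.0
neuromodulation:
  modulated_pair: [CaL, CaN]
  gs_states:            # provenance: calibrated by firing-pattern sweep
    spiking: -1.2
    light_bursting: -2.4
    strong_bursting: -3.4
analysis:
  V_ref: -70.0
  correlation_threshold: null
  sim_duration: 20000.0
  sim_transient: 4000.0
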