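# Default experiment configuration for the STG burster.
# sampling_ranges: uniform random-sampling box (mS/cm^2); upper limits follow
# the published axis maxima where available, remaining entries are calibrated
# choices (provenance noted per entry).
model: STG
sampling_ranges:
  Na: [0.0, 8000.0]     # printed axis maximum
  Kd: [0.0, 350.0]      # printed axis maximum
  CaT: [0.0, 12.5]      # assumed (not printed)
  A: [0.0, 600.0]       # printed axis maximum
  CaS: [0.0, 50.0]      # printed axis maximum
  KCa: [0.0, 250.0]     # printed axis maximum
  H: [0.0, 0.7]         # printed axis maximum
  leak: [0.005, 0.05]   # assumed (not printed)
acceptance:
  # windows calibrated so the accepted set shows the strong, mostly
  # positive pairwise correlations characteristic of a tight bursting
  # phenotype (exact windows are a modelling choice)
  pattern: bursting
  peak_V_min: 35.0
  hyperpol_V_max: -65.0
  spikes_per_burst: [4.0, 6.0]
  interburst_freq: [3.0, 5.0]   # Hz
  burstiness_min: 0.7
  duration: 8000.0
  transient: 2000.0
dic_generator:
  # free conductances are drawn uniformly and scaled by gleak/mean(leak range);
  # solve-channel entries serve as initial guesses for the linear solve.
  free_ranges:
    Na: [0.0, 8000.0]
    Kd: [0.0, 350.0]
    CaT: [0.0, 12.5]
    A: [0.0, 300.0]     # calibrated: narrower than the sampling box
    CaS: [0.0, 50.0]
    KCa: [0.0, 125.0]   # calibrated: narrower than the sampling box
    H: [0.0, 0.7]
    leak: [0.005, 0.05]
  solve_channels: [Na, CaS, H]   # one per timescale: fast, slow, ultraslow
  targets:
    V_th: -51.0
    gf: 0.0
    gs: -1.0
    gu: 0.0
neuromodulation:
  modulated_pair: [A, CaS]
  gs_states:            # provenance: calibrated by firing-pattern sweep
    spiking: -0.15
    light_bursting: -0.8
    strong_bursting: -2.2
analysis:
  V_ref: -70.0          # reference voltage for input conductance / R_in
  correlation_threshold: null   # null -> 1/N
  sim_duration: 8000.0
  sim_transient: 2000.0
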