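# Dopaminergic (DA) neuron model, adapted: a slow tonic spiker with six ion
# channels plus leak.  SK channels are absent (pharmacologically blocked in
# the source preparation, which enables bursting); NMDA channels are
# simulated at a fixed baseline conductance but excluded from the analysis
# conductance space, so the analysis dimension is N=6 (Na, Kd, CaL, CaN,
# ERG, leak).  The kinetics below are an adaptation written for this
# package: parameter values were calibrated to produce slow tonic spiking
# with the canonical timescale structure of the cell type -- fast sodium
# spike upstroke, delayed-rectifier repolarisation, slow subthreshold L- and
# N-type calcium depolarisation (slow positive feedback), and ultraslow ERG
# potassium feedback that paces the slow rhythm and terminates bursts.
# Units: mV, ms, mS/cm^2.
name: DA
N: 6
C: 1.0
E_leak: -60.0
channels:
  - name: Na
    a: 3
    b: 1
    reversal: 60.0
    m_inf: {form: boltz, p: [-30.1, -9.7]}
    tau_m: {form: sigtau, p: [0.05, 0.4, -40.0, 6.0]}
    h_inf: {form: boltz, p: [-54.0, 5.5]}
    tau_h: {form: biexptau, p: [0.4, 12.0, -50.0, 15.0, -50.0, -15.0]}
  - name: Kd
    a: 3
    b: 0
    reversal: -85.0
    m_inf: {form: boltz, p: [-25.0, -12.0]}
    tau_m: {form: sigtau, p: [2.0, 45.0, -30.0, 8.0]}
  - name: CaL
    a: 2
    b: 0
    reversal: 60.0
    m_inf: {form: boltz, p: [-45.0, -7.0]}
    tau_m: {form: sigtau, p: [20.0, 80.0, -40.0, 10.0]}
  - name: CaN
    a: 1
    b: 1
    reversal: 60.0
    m_inf: {form: boltz, p: [-42.0, -6.0]}
    tau_m: {form: sigtau, p: [10.0, 40.0, -40.0, 10.0]}
    h_inf: {form: boltz, p: [-58.0, 5.0]}
    tau_h: {form: sigtau, p: [700.0, 500.0, -60.0, 10.0]}
  - name: ERG
    a: 1
    b: 0
    reversal: -85.0
    m_inf: {form: boltz, p: [-45.0, -6.0]}
    tau_m: {form: sigtau, p: [400.0, 800.0, -40.0, 10.0]}
baseline_channels:
  - name: NMDA
    a: 1
    b: 0
    reversal: 0.0
    baseline_gbar: 0.002
    m_inf: {form: mgblock, p: [0.28, -0.062]}
    tau_m: {form: const, p: [0.05]}
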