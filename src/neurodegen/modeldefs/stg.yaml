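# Crab stomatogastric-ganglion (STG) neuron model: seven gated channels plus
# leak, with first-order intracellular calcium driving the KCa channel and a
# Nernst-style calcium reversal.  Kinetics follow the classic isolated-STG
# parameterisation.  Units: mV, ms, mS/cm^2, uM.
#
# Rate-function forms:
#   boltz    [Vh, k]                 -> 1/(1+exp((V-Vh)/k))
#   sigtau   [A, B, Vh, k]           -> A + B/(1+exp((V-Vh)/k))
#   biexptau [A, B, V1, k1, V2, k2]  -> A + B/(exp((V-V1)/k1)+exp((V-V2)/k2))
#   prodsig  [A, V1, k1, B, C, V2, k2]
#            -> (A/(1+exp((V-V1)/k1))) * (B + C/(1+exp((V-V2)/k2)))
#   caboltz  [Kd_Ca, Vh, k]          -> (Ca/(Ca+Kd_Ca)) * 1/(1+exp((V-Vh)/k))
name: STG
N: 8
C: 1.0
E_leak: -50.0
calcium:
  tau: 20.0
  f: 0.94
  ca_rest: 0.05
  ca_out: 3000.0
  nernst_mV: 12.199
channels:
  - name: Na
    a: 3
    b: 1
    reversal: 50.0
    m_inf: {form: boltz, p: [-25.5, -5.29]}
    tau_m: {form: sigtau, p: [1.32, -1.26, -120.0, -25.0]}
    h_inf: {form: boltz, p: [-48.9, 5.18]}
    tau_h: {form: prodsig, p: [0.67, -62.9, -10.0, 1.5, 1.0, -34.9, 3.6]}
  - name: Kd
    a: 4
    b: 0
    reversal: -80.0
    m_inf: {form: boltz, p: [-12.3, -11.8]}
    tau_m: {form: sigtau, p: [7.2, -6.4, -28.3, -19.2]}
  - name: CaT
    a: 3
    b: 1
    reversal: calcium
    calcium_source: true
    m_inf: {form: boltz, p: [-27.1, -7.2]}
    tau_m: {form: sigtau, p: [21.7, -21.3, -68.1, -20.5]}
    h_inf: {form: boltz, p: [-32.1, 5.5]}
    tau_h: {form: sigtau, p: [105.0, -89.8, -55.0, -16.9]}
  - name: A
    a: 3
    b: 1
    reversal: -80.0
    m_inf: {form: boltz, p: [-27.2, -8.7]}
    tau_m: {form: sigtau, p: [11.6, -10.4, -32.9, -15.2]}
    h_inf: {form: boltz, p: [-56.9, 4.9]}
    tau_h: {form: sigtau, p: [38.6, -29.2, -38.9, -26.5]}
  - name: CaS
    a: 3
    b: 1
    reversal: calcium
    calcium_source: true
    m_inf: {form: boltz, p: [-33.0, -8.1]}
    tau_m: {form: biexptau, p: [1.4, 7.0, -27.0, 10.0, -70.0, -13.0]}
    h_inf: {form: boltz, p: [-60.0, 6.2]}
    tau_h: {form: biexptau, p: [60.0, 150.0, -55.0, 9.0, -65.0, -16.0]}
  - name: KCa
    a: 4
    b: 0
    reversal: -80.0
    depends_on_calcium: true
    m_inf: {form: caboltz, p: [3.0, -28.3, -12.6]}
    tau_m: {form: sigtau, p: [90.3, -75.1, -46.0, -22.7]}
  - name: H
    a: 1
    b: 0
    reversal: -20.0
    m_inf: {form: boltz, p: [-75.0, 5.5]}
    tau_m: {form: biexptau, p: [0.0, 2.0, -169.7, -11.6, 26.7, 14.3]}
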