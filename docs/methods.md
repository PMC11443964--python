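# Methods

## Scope and model

`neurodegen` studies ion-channel degeneracy in single-compartment
conductance-based neuron models: many different maximal-conductance vectors
ḡ = (ḡ_Na, …, g_leak) produce the same electrophysiological phenotype. The
membrane equation is

    C dV/dt = −Σ_ion ḡ_ion m_ion^a h_ion^b (V − E_ion) − g_leak (V − E_leak) + I_ext,

with first-order gating kinetics dX/dt = (X_∞(V) − X)/τ_X(V) and, where a
channel requires it, a first-order intracellular-calcium pool
τ_Ca dCa/dt = −f·I_Ca − Ca + Ca_rest feeding a Nernst-style calcium
reversal and calcium-gated potassium activation.

Two models ship as model-definition YAML files (`src/neurodegen/modeldefs/`):

* **STG** — the isolated crab stomatogastric-ganglion neuron: seven gated
  channels (Na, Kd, CaT, A, CaS, KCa, H) + leak, N = 8 analysis
  conductances, nominal phenotype periodic bursting. Gating functions
  follow the classic published parameterisation of this model.
* **DA** — an *adapted* dopaminergic neuron: analysis channels Na, Kd,
  CaL, CaN, ERG + leak (N = 6), with NMDA simulated at a fixed baseline
  conductance (0.002 mS/cm²) but excluded from the conductance space, and
  SK absent (pharmacologically blocked, which enables bursting). The
  kinetics file is an adaptation written for this package: the canonical
  timescale/feedback structure of the cell type (fast Na upstroke, slow
  delayed-rectifier, slow L-/N-type calcium depolarisation, ultraslow ERG
  potassium brake), with parameter values calibrated to produce slow tonic
  spiking (0.5–8 Hz) across a physiological conductance box and to respect
  the scaling property below. Its numbers are not transcriptions of any
  single published table; conclusions drawn from the DA model are
  conclusions about this adaptation.

Units throughout: mS/cm², mV, ms, µA/cm², µF/cm², µM.

### Integration

The engine packs any model into flat arrays consumed by one numba-compiled
exponential-Euler loop: every gate (and the calcium pool and the voltage)
relaxes exactly toward its instantaneous equilibrium over each step. This
scheme is the standard for this model family because the states span four
decades of time constants; it is unconditionally stable for the gates.
Default step 0.05 ms (halving `dt` is the accuracy control; population
statistics are unchanged at 0.025 ms). States are initialised at their
steady-state values for V(0) = −65 mV and a transient (2 s STG, 3–5 s DA)
is discarded, so firing metrics carry no initialisation bias. Simulations
are bitwise deterministic given inputs.

### Firing metrics

Spikes are upward crossings of 0 mV with a 2 ms refractory minimum. Bursts
are groups separated by interspike intervals > 3 × median ISI; if no such
gap exists the train is tonic. Burstiness is 1 − (#bursts)/(#spikes): 0
for tonic, →1 for long bursts. (The source literature's exact burstiness
formula is not public; this monotone surrogate is configurable.) A trace
is classified silent / tonic / bursting / irregular from the spike count,
the burst structure, and the ISI coefficient of variation (tonic requires
CV ≤ 0.3).

## Dynamic input conductances

The three DICs g_f(V), g_s(V), g_u(V) aggregate every gating variable's
first-order feedback on V̇ into fast/slow/ultraslow components:

    [g_f; g_s; g_u](V) = S(V)·ḡ,
    S_ij(V) ∝ Σ_{X∈gates(j)} w_i(τ_X) · ∂I/∂X · ∂X_∞/∂V / g_leak,

plus each channel's instantaneous conductance (and the leak) in the fast
row. Positive = restorative. The weights w are a piecewise-linear
partition of unity in log τ between three reference timescales: τ_f = τ_m
of fast sodium, τ_s = τ_m of the delayed rectifier, τ_u = the slowest
gating τ of the model, all functions of V. The threshold voltage V_th is
the subthreshold zero crossing of g_f (onset of net fast positive
feedback), found by grid bracketing + refinement to 10⁻³ mV.

**Calcium handling.** Intracellular calcium is evaluated at its fixed
point Ca_∞(V) (damped Newton, vectorised over V) and treated as a
first-order variable of timescale τ_Ca: calcium-gated channels get a chain
term through dCa_∞/dV (assigned the combined relaxation τ_gate + τ_Ca) and
calcium-reversal channels get the restorative Nernst-drift term. These
terms matter: without them the slow/ultraslow DICs misjudge KCa-heavy STG
neurons and the generated populations lose phenotype coherence. Passing
`frozen_ca` pins the calcium background instead, which makes S·ḡ exactly
linear in ḡ — the convention used by the finite-difference and linearity
oracles, and the sense in which homogeneous scaling leaves all DICs
exactly invariant.

### Compensation and generation

`compensate` solves three conductances (one per timescale; defaults
STG = Na/CaS/H, DA = Na/CaL/ERG) from S(V_th)·ḡ = (g_f*, g_s*, g_u*).
Because V_th is *defined* by g_f = 0, the generator fixes g_f* = 0, which
pins every generated neuron's threshold at the configured V_th. For the
STG model the solve is fixed-point iterated (with vector-secant
acceleration) until the calcium background is self-consistent; residuals
are < 10⁻⁸. Ill-conditioned blocks (cond > 10⁸) and negative solutions
are reject-and-resample signals, not errors.

The DIC-constrained generator draws g_leak ~ U(min, max), draws the N−4
free conductances uniformly *scaled by g_leak/mean(g_leak range)* — this
proportionality combines homogeneous-scaling variability (through g_leak)
with conductance-ratio variability (through the ratios) — and solves the
remaining three. The two separated subsets: *scaling-only* builds one base
neuron and scales it homogeneously by each member's g_leak (members exactly
proportional; for the STG model the calcium background makes exact
proportionality and exact per-member DIC targets mutually exclusive, and
proportionality is the subset's defining property, so it wins);
*ratio-only* fixes g_leak and randomises the free conductances, so members
differ only along DIC zero-sensitivity directions.

## Population analysis

Pairwise Pearson correlations (undefined for zero-variance channels,
reported as NaN, never imputed); correlation graphs threshold |r| at 1/N.

**PCA** is centered and *standardised* (correlation-matrix PCA) by
default. The shipped models span four decades of conductance magnitude
between channels (ḡ_Na up to 8000, ḡ_H up to 0.7 mS/cm²); covariance PCA
on raw values degenerates to "PC1 = the widest channel" (> 99% of
variance), which carries no structural information. Standardisation puts
channels on an equal footing; both switches are exposed. Loadings carry a
deterministic sign (largest-magnitude entry positive). Directions are
mapped back to conductance units (σ ⊙ v) for comparisons in raw 2D panes.

The **homogeneous-scaling direction** is the unit vector from the
conductance-space origin to the population mean (equivalently the
total-least-squares regression direction without intercept); for
comparison with standardised loadings it is expressed in the same
standardised coordinates. **Alignment** of two directions is |u·v|,
sign-invariant. **R_in normalisation** multiplies each member by its own
input resistance (slope of the steady-state I–V curve at V_ref = −70 mV;
members with a non-positive slope there are excluded and logged), which
removes scaling variability and leaves ratio variability; TLS regressions
of the normalised data align with the secondary PCs of the raw data and
with the slow-DIC zero-sensitivity directions.

## Neuromodulation

A neuromodulatory state is a target value for the slow DIC at threshold;
the ultraslow DIC is held at each member's own value (preserving
burst/period timing), and a fixed pair of conductances (STG: A/CaS, DA:
CaL/CaN) is re-solved from the 2×2 (slow, ultraslow) block. The
sensitivity matrix is evaluated once per member, at its *pre-modulation*
threshold voltage and calcium background: the indirect rule is the local
linear map of that state. This makes the solve a single linear system and
continuous neuromodulatory paths exactly straight lines in the pair plane
(direction constant per neuron, varying between neurons); a fully
self-consistent iteration would bend the paths by ~10⁻³ relative, which
contradicts the straight-path property this rule is meant to express.

The three shipped states (spiking / light bursting / strong bursting) have
slow-DIC targets calibrated once per model by sweeping a generated
population and reading off the firing patterns; they live in the config
files with provenance "calibrated". On scaling-only subsets the modulation
is exactly multiplicative (a rotation in conductance space); on ratio-only
subsets exactly additive (a translation); `classify_rule` fits both and
reports residuals.

## Synthetic populations: what they emulate and what they do not

The random-sampling generator emulates the study design: uniform draws in
a conductance box (axis maxima from the published figure ranges where
printed; remaining bounds are calibrated choices recorded in the config
files) followed by simulation-based post-processing on firing metrics.
The exact acceptance windows of the original study are not public; the
shipped windows were calibrated so that the accepted sets show the
qualitative signature reported there (strong, mostly positive pairwise
correlations with a minority of negative pairs). Population statistics —
variance fractions, alignments, state-dependent correlations — are
sensitive to these windows and to the models' kinetics at the level of
±0.1–0.2; passing tests demonstrate the pipeline's internal consistency
and the qualitative phenomena (two variability mechanisms, their
interference, reliable indirect neuromodulation), not agreement of every
decimal with any particular dataset. Real neurons additionally vary in
kinetics, capacitance and morphology, which these populations do not
emulate.

## Numerical choices and degenerate inputs

* Exponential Euler, dt = 0.05 ms; traces recorded at 0.1 ms.
* Calcium fixed point: Newton, tol 10⁻¹³ relative, floor 10⁻⁹ µM.
* d/dV of gating curves: central differences, 10⁻³ mV.
* Threshold: 0.5 mV scan + bracket refinement, tol 10⁻³ mV; "no
  threshold" is an error for passive membranes (no g_f zero crossing).
* Solves reject cond > 10⁸ and negative conductances (resample signals).
* Zero-variance channels: correlations undefined; PCA standardisation
  refuses them.
* Problem sizes: shipped analyses use 100-member random-sampling
  populations and 120–200-member DIC populations (the original study used
  200 and 500); statistics quoted in the README were produced at these
  sizes.

## Known limitations

* The DA model is an adaptation, not a transcription; its alignment
  between PC1 and homogeneous scaling (~0.5–0.6) is weaker than the
  original report (~0.9), and correlations in its neuromodulated strong-
  bursting state overshoot zero. Both are documented, seed-stable
  behaviours of this parameterisation.
* Homogeneous scaling preserves firing patterns only approximately at the
  lower edge of the conductance box (the membrane time constant is not
  negligible against the fastest gates there), so the STG PC1 fraction and
  its alignment with scaling fluctuate noticeably between seeds at n=100.
* The burstiness metric is a surrogate (see above); absolute burstiness
  values are not comparable to other implementations, orderings are.
* The DIC construction is first-order and local in V; it is a good
  phenotype predictor near threshold but not a bifurcation analysis.
  DIC-constrained generation therefore controls the phenotype only
  approximately: 50–80% of generated members pass the full simulation
  acceptance windows, the rest sit at window edges.
* In the DA adaptation the R_in-normalised random-sampling variability is
  not dominated by the slow-DIC zero-sensitivity direction in the
  (ḡ_CaL, ḡ_CaN) plane (its TLS slope is positive where the null
  direction's is negative); the corresponding cross-check holds for the
  STG model only.
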