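# Model and methods

## Overview

`tcloop` simulates a pair of interacting thalamocortical sub-circuits — the
focal, driving *core* and the diffuse, modulatory *matrix* — for a rodent
(600 neurons) and a primate (800 neurons, adding local thalamic
interneurons), and quantifies the resulting population activity with the
band-PCA synchrony angle, mean propagation time (MPT), sleep-spindle
metrics and power spectral density.

Each circuit contains 100 cortical (Ctx), 100 thalamocortical relay (TC)
and 100 reticular (TRN) neurons; the primate adds 100 local inhibitory
interneurons (IN) per circuit.  Activity is initiated by a brief 50 ms
current pulse into the center TRN neuron of each circuit after a 500 ms
settling period, and runs are integrated for up to 7 s.

## Membrane and intrinsic currents

All cells are single-compartment, with every current written
outward-positive:

    Cm dV/dt = -I_L - I_Na - I_K - I_intrinsic - I_syn + I_ext

- **HH currents** (all cells): I_Na = g_Na m^3 h (V-E_Na),
  I_K = g_K n^4 (V-E_K), I_L = g_L (V-E_L), with Traub-style rate functions
  shifted by a per-kind threshold parameter V_T.
- **Low-threshold Ca2+ current I_T** (TRN and TC): I_T = g_Ca m^k h (V-E_Ca)
  with activation exponent k = 2 for TRN and k = 3 for TC.  Activation
  relaxes as dm/dt = (m_inf - m)/tau_m; the inactivation gate, whose ODE is
  not part of the printed model, uses the same first-order form with the
  canonical h_inf / tau_h for each cell class (Huguenard–Prince-style TRN
  kinetics, Destexhe-style TC kinetics, temperature-adjusted).  E_Ca is a
  fixed reversal (120 mV); no intracellular Ca2+ dynamics.
- **H-current I_H** (TC only): I_H = g_H (S1+S2)(F1+F2)(V-E_H) with slow (S)
  and fast (F) gates, each having an open state (S1, F1) and a locked state
  (S2, F2).  Open states relax voltage-dependently
  (alpha_X = h_inf/tau_X, beta_X = (1-h_inf)/tau_X) and exchange with the
  locked states at voltage-independent rates k2 (locked->open) and C
  (open->locked).  The locked-state closure dX2/dt = C·X1 - k2·X2 is the
  unique first-order scheme conserving each gate's total fraction.  The
  model's F-gate equation is implemented symmetrically (the -C·F1 term);
  a `strict_printed_form` switch reproduces the asymmetric -C·S1 variant.

Defaults (see `data/default_params.json`, schema `tcloop-params-1`, all
overridable): g_Ca = 3.0 mS/cm² and g_H = 0.04 mS/cm² for TC cells — at the
upper end of the canonical range, chosen so that a relay cell released from
a 60–100 ms IPSP fires a multi-spike rebound burst and re-depolarizes
within ~50 ms, which sets the ~10 Hz loop rhythm.  Resting potentials are
not prescribed; each cell kind starts at the hyperpolarized zero of its
steady-state I–V curve (located by a grid scan plus bisection), with every
gate at its fixed point for that voltage.

## Synapses

Transmitter concentration is an instantaneous sigmoid of presynaptic
voltage, T(V) = T_max / (1 + exp(-(V - V_t)/K_p)) with T_max = 1 mM,
V_t = 2 mV, K_p = 5 mV — the standard kinetic-synapse pulse model.  Each
projection carries one gating state per presynaptic neuron; the
postsynaptic current is the projection's normalized weight matrix applied
to those gates times the local driving force.

- **Ionotropic** (AMPA, NMDA, GABA_A): dm/dt = alpha·T·(1-m) - beta·m,
  I = g·m·(V-E).  Kinetic constants are the canonical first-order fits
  (AMPA 1.1 /mM/ms, 0.19 /ms; NMDA 0.072, 0.0066; GABA_A 5.0, 0.18).  The
  NMDA Mg2+ block is omitted (pure first-order kinetics).
- **Metabotropic** (GABA_B, mGluR): receptor activation
  dr/dt = K1·T·(1-r) - K2·r drives second messenger ds/dt = K3·r - K4·s,
  and the channel opens with Hill saturation s^n/(s^n + Kd);
  K1 = 1.3, K2 = 0.006, K3 = 0.09, K4 = 0.0064 (model constants),
  Kd = 100, n = 4 (canonical cascade values).  mGluR reuses the GABA_B
  cascade with E = 0 mV (equal to E_AMPA), making it excitatory.

## Connectivity

Receptor assignment per circuit: core Ctx→TC is metabotropic (mGluR) and
core TC→Ctx ionotropic (AMPA); the matrix arrangement is reversed (NMDA
down, mGluR up).  Thalamocortical (TC→Ctx) projections spread with a
normalized Gaussian kernel — core sigma = 1 neuron index, matrix sigma = 10
(an order of magnitude wider); difference-of-Gaussians kernels are
available.  Kernels are clip-convolved (no wrap-around).  All other
connections are one-to-one: Ctx→TC, Ctx→TRN, TC→TRN, TRN→TC, TC→IN, IN→TC
and the cortico-cortical core↔matrix mixing pair.  Because kernel rows are
normalized, total synaptic mass onto a neuron is invariant to population
size.

TRN→TC inhibition is GABA_A with a small GABA_B component on the same
edges (weight ratio 100:1).  The GABA_A component drives the rebound
rhythm; the GABA_B component acts as a stabilizer that suppresses marginal
rebounds.  Larger GABA_B fractions silence the loop entirely — with the
printed cascade constants the messenger saturates within one or two cycles
(its relaxation times are ~160 ms), so it cannot produce slow multi-second
waxing and waning; see Limitations.

Loops: *closed* — TRN_i inhibits TC_i, TC_i excites TRN_i; *open* — TRN_i
inhibits TC_{(i+5) mod 100} while TC→TRN stays aligned, giving zero
reciprocal pairs; *hybrid* — a deterministic alternation of the two motifs
(closed fraction 0.5, accumulator interleave, so exactly 50 reciprocal
pairs at n = 100).

The parameter cube scales core TC→Ctx weight (x), matrix TC→Ctx weight (y)
and the cortico-cortical mixing weight (z) with multipliers 0.5 (low),
1.0 (control) and 2.0 (high).  The control case is the balanced operating
point between inactivity and saturation; the base weights at that point
are calibrated per species and loop (`CONTROL_CALIBRATION`), mirroring the
per-configuration control-case choice of the study design — the loop wiring
changes how much thalamocortical drive a circuit needs to spread activity
without locking into tonic firing.

## Integration

Fixed-step RK4 at dt = 0.025 ms over one flat state vector (membrane,
gating and synaptic states fully coupled; transmitter evaluated at the
presynaptic stage voltage).  Runs are deterministic — repeated calls are
bit-identical.  Spikes are -20 mV upward crossings with a 2 ms refractory;
voltage traces are recorded at 1 ms.  A numerical guard aborts with the
first offending neuron and time if |V| exceeds 200 mV.

## Analysis

- **Band segmentation** (unprinted in the source model; our design):
  population rate in 1 ms bins, 5 ms boxcar smoothing, threshold at 10 % of
  the maximum, supra-threshold runs merged across gaps < 10 ms.  The merge
  gap must stay below one oscillation cycle (~80–110 ms at spindle
  frequencies); larger values bridge successive cycle volleys and collapse
  a run into one band.
- **Band PCA**: events (time, neuron) are z-scored and PC1 extracted from
  the 2×2 covariance; theta is measured from the time axis (vertical = 90°),
  deviation = |90° - theta| ∈ [0, 90].  The shared reference frame is
  global z-scoring (the whole rastergram's standard deviations); per-band
  unit-variance scaling makes the covariance [[1, ρ], [ρ, 1]], whose
  leading eigenvector is ±45° for any correlated band — a degenerate
  metric — and is kept only as an option.  An exactly mirror-symmetric band
  has zero covariance and tied variances; PC1 is then resolved to vertical,
  which is precisely the symmetric-band ("boomerang") artifact.
- **Half-band correction**: PCA restricted to events above the band's
  median neuron index; applied on request or automatically when the
  mirror-symmetry score (correlation of upper-arm vs reflected lower-arm
  mean lags) exceeds 0.8.
- **MPT**: band time extent along the PC1 embedding divided by the number
  of distinct active neurons (an `n_minus_1` divisor variant is provided).
- **Spindles**: membrane-voltage averages of 5 core, 5 matrix or 10 mixed
  cortical neurons; 9–13 Hz zero-phase 4th-order Butterworth; events are
  analytic-envelope peaks ≥ 30 % of the largest peak, ≥ 0.5 s apart
  (greedy by descending amplitude); duration spans the flanking envelope
  minima; density is the count per trace.
- **PSD**: periodogram of the averaged signal, reported in 8–20 Hz.
- **Group comparison**: Kruskal–Wallis with tie correction
  (scipy.stats.kruskal), validated against a direct rank-formula oracle.

## Synthetic fixtures

The `fixtures` module generates rasters with planted band geometry
(vertical, linear-lag, mirror-symmetric boomerang; seeded Gaussian jitter)
and sigma-band signals with planted Gaussian-envelope bursts plus seeded
white noise.  They emulate the *geometry* the analyses must recover, not
the biophysics: no refractoriness, no waxing–waning fine structure, no
1/f background.  Passing the fixture suite therefore shows the estimators
are correct on known ground truth, not that the simulator reproduces any
particular biological recording.

## Emergent dynamics and calibration

At the control case the closed loop ignites a bidirectional recruitment
wave from the stimulated column (a boomerang in the raster), after which
each recruited column oscillates at ~10 Hz; cycle volleys appear as
discrete near-vertical bands whose arms lag toward the edges.  Full-band
PCA reports these bands as artificially vertical; the half-band correction
recovers arm tilts of tens of degrees.  The open loop's offset inhibition
produces dominant traveling waves (large MPT); the hybrid loop, at its
calibrated control case, produces the most synchronous bands.  Simulated
problem sizes in the shipped tests and the acceptance script are
desk-scaled to 3–3.5 s runs (500 ms settling excluded from analysis);
the full 7 s protocol is available through the API and CLI.

## Known limitations

- The printed model contains no slow spindle-termination mechanism (no
  Ca2+-regulated I_H, no adaptation); with the fixed cascade constants the
  GABA_B messenger equilibrates within ~2 cycles.  Once ignited, network
  oscillation therefore persists rather than waxing and waning in discrete
  multi-second epochs, and after a few seconds of progressive recruitment
  the population approaches tonic saturation; band metrics are reported on
  the pre-saturation window.
- All biophysical rate constants are canonical published values, not the
  source study's (unavailable) parameter tables; quantitative band metrics
  are expected to differ from the printed ones even where the qualitative
  phenomenology matches.
- One-to-one cortico-cortical mixing cannot ignite a silent circuit
  (single presynaptic spikes are subthreshold by design to avoid runaway
  ping-pong excitation); both circuits are therefore initiated directly.
- 1-D neuron arrays; no conduction delays; no cortical inhibition, so the
  mixing gain must stay below the self-sustaining threshold.
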