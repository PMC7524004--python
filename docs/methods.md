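# Methods

## Model

Each of the 500 network nodes is a FitzHugh–Nagumo excitable unit

    dx_i/dt = x_i (a − x_i)(x_i − 1) − y_i + Σ_{j≠i} C_ij h(x_j(t − τ)) + I_i(t)
    dy_i/dt = b x_i − γ y_i,          h(x) = (1 + tanh x)/2

with a = 0.8, b = 0.008, γ = 0.0033 identical for all nodes.  The cubic
leaves the origin as the only stable rest state of an isolated node; a
suprathreshold input elicits a brief spike followed by a slow recovery
set by γ (≈ 0.18 s in renormalized time), which is what places the
collective rhythm of a recurrently coupled population in the 7–8 Hz band
of rat spike-and-wave discharges (SWDs).  The sigmoid h bounds each
synaptic drive to (0, 1); coupling weights are ±0.1 only, so single
inputs are subthreshold (the excitation threshold of a resting node is
≈ 0.105) and collective behavior is a genuine network effect.

Integration is explicit Euler with a fixed step of 0.5 in model time;
model time is renormalized by 1/1700, giving a 3400 Hz sampling rate.
The conduction delay τ is a whole number of samples (9–13, ≈ 2.6–3.8 ms)
shared by all edges of a matrix and handled by a ring buffer whose
pre-zero history is the constant extension of the initial state.  The
system is strictly deterministic: no noise term exists anywhere, so any
run can be reproduced bit-for-bit and any protocoled run has an exact
protocol-free twin.

Initial conditions are uniform perturbations of the origin in
[−0.1, 0.1]² per node, drawn from the simulation seed; the first 2 s are
treated as burn-in.

## Connectivity generation

Nodes are organised into cortical pyramidal (PY) and interneuron (IN)
populations, thalamocortical relay (TC/VPM) and reticular (RE/RTN)
populations, and an external trigeminal input compartment (NT), each
(except NT) split into a focal and a surrounding region (40/10/40/40
focal, 160/40/80/80 surrounding, 10 NT — 500 total).  Directed edges are
drawn independently per ordered pair with per-pathway probabilities
(focal targets four times denser than surrounding ones; NT projects only
to focal TC, with probability 0.18).  Edge sign follows the source
population: +0.1 from PY/TC/NT, −0.1 from IN/RE.

**Collateral completion.**  After sampling, every directed edge is
completed by a reciprocal edge (no edges into NT are ever created).  The
completion rule is the one genuinely open design choice in this model,
and it controls the network's excitability regime:

* signing every reciprocal by its own source population (`dale`) keeps
  Dale's principle but leaves every random draw subcritical — networks
  produce only low-amplitude irregular activity or fall silent;
* copying the forward edge's signed value (`copy`) symmetrizes the
  matrix and makes every draw lock permanently into a high-amplitude
  7–8 Hz rhythm;
* the default `mixed` rule completes each reciprocal by copy with
  probability `copy_fraction` and by Dale-sign otherwise (decided
  reproducibly from the matrix seed, symmetrically per node pair).

`copy_fraction = 0.15` is the package's reference operating point,
chosen once from a transition scan: it places the composed 500-node
circuit near its synchronization threshold, where the interictal state
is sustained, irregular and broadband while transient 4–12 Hz
discharges can be induced and maintained by the protocol-level coupling
changes.  Far below this value discharges cannot be elicited at all;
far above it the circuit is permanently rhythmic.

## Screening

Random draws near the transition are heterogeneous, and the model
follows a generate-and-select procedure.  `classify_surrounding`
accepts a surrounding matrix iff its cortex LFP is non-decaying
(standard deviation above a floor) and has no well-established main
frequency, operationalized as the largest 3–15 Hz Welch peak carrying
less than a threshold fraction (default 0.25) of total 1–100 Hz power.
`classify_focal` accepts a focal matrix iff, embedded in a composed
network beside a criteria-specified reference surrounding matrix, the
0.3 s intracortical-excitability ramp elicits a detected SWD that
terminates spontaneously within 60 s.  The embedding is necessary
because a focal subnetwork alone cannot express the interictal
background that initiation presupposes.  `screen_batch` derives
per-candidate seeds from a master seed and is fully deterministic; the
default candidate budget is desk-scale (hundreds), with the full-scale
budget a parameter.  Accepted focal/surrounding matrices are paired
only when their conduction delays match.

The shipped reference pairs (`swdnet.experiments.REFERENCE_PAIRS`) are
the first pairs accepted by this pipeline in screening order; they are
stored as seeds and regenerated deterministically, not as data files.

## Discharge protocols

* **Initiation, intracortical excitability**: focal PY→PY weights ramp
  linearly from 0.1 to 0.115 over 0.3 s, then return instantly to
  baseline.  Discharges begin after the ramp ends — the near-critical
  network amplifies slowly during the ramp.
* **Initiation, trigeminal drive**: NT→TC weights step from 0.1 to 0.2
  for 0.3 s.
* **Initiation, low-frequency stimulation**: a unit-amplitude 8 Hz
  sinusoid added to dx/dt of all cortical nodes for 0.3 s; discharges
  begin within the stimulation window (entrainment is immediate).
* **Maintenance**: the corticothalamic feedforward (PY→TC) magnitude is
  raised by 15% for 5 s starting 0.5 s after the (estimated) onset.
  The alternative reticular-to-cortex pathway is implemented but damps
  rather than sustains the cortical rhythm in this network, so the
  corticothalamic pathway is the default.  Maintenance dominates the
  duration distribution: without it a discharge outlives its stimulus
  only by the network's relaxation time (≲ 1 s).
* **Termination, high-frequency stimulation**: a 130 Hz train of 0.6 ms
  unit-amplitude pulses for 1 s on all focal cortical nodes,
  4 s after onset by default; it desynchronizes the rhythm within the
  stimulation window in most network states.

A known limitation: because the synchronization transition is smooth,
the maintenance-level coupling increase applied *alone* to interictal
activity already shifts the operating amplitude enough to cross the
detector's threshold.  Maintenance is therefore gated on a detected
initiation in all reference experiments; an isolated maintenance event
is not a null perturbation in this implementation.

## Observables and detection

LFPs are plain sums of node activities: Cortex = ΣPY + ΣIN, VPM = ΣTC,
RTN = ΣRE.  The SWD detector computes a 0.5 s moving RMS of the
mean-subtracted Cortex channel and calibrates on an interictal baseline
segment: onset when RMS exceeds baseline mean + 3 SD, offset when it
stays below mean + 2 SD for 0.5 s, a 1 s minimum duration, a 4–12 Hz
dominant-frequency requirement, and a half-window edge correction for
the RMS smear.  All thresholds are relative to baseline, so detection
is invariant under positive rescaling of the signal.  Duration
statistics use 1 s bins.

## Coupling analysis

The adapted nonlinear Granger causality uses polynomial (order P = 2)
least-squares autoregressions over D_s = 4 lags of the target channel,
with horizon T/12 and lag T/24 samples where T = f_samp/f0 and f0 =
8 Hz (at 3400 Hz: T = 425, horizon 35, lag 18; rounding half away from
zero).  The joint model adds D_a = 1 lagged driver term; prediction
improvement is PI = 1 − ε²_joint/ε²_single, which is in [0, 1] for the
nested least-squares pair on a common window.  PI is evaluated in 1 s
windows (a value at t summarizes [t−w, t]); significance is the
one-sided 95th percentile of the baseline-interval windows (the
background 10–3 s before onset).  Windows are z-scored internally for
conditioning; errors are reported on the original scale.

**Duration measurement.**  The reference duration experiment initiates
with the low-frequency stimulation mechanism: its detected onset
coincides with the stimulus, so measured durations do not depend on the
detector's onset lag.  Under the excitability ramp the slowly growing
discharge crosses the detection threshold roughly half a second after
the true transition, which shifts measured durations down by about that
much; the initiation mechanism is an explicit parameter of the
experiment.  The detector's onset resolution for sharp events is half
its RMS window (0.25 s).

## What the generator does and does not emulate

The synthetic circuits reproduce the architecture, weights, delays and
protocol magnitudes of the target model and the qualitative state
structure (irregular interictal activity; induced, maintained,
spontaneously-terminating 7–8 Hz discharges with harmonics; passive
recruitment of the surrounding region).  They do not reproduce:
anatomical geometry or distance-dependent delays; heterogeneous node
parameters; the experimental LFP's 1/f background and measurement
noise; or genuinely autonomous multi-second discharge transients — in
this implementation the multi-second timescale of a discharge is
carried by the maintenance window plus the near-critical relaxation
tail, not by a free-running chaotic transient.  Passing tests
demonstrate internal consistency of the model and pipeline, not
biological validity.

## Numerical choices

Euler at step 0.5 is part of the model definition, not an approximation
to be refined.  Blow-up is checked every 200 steps against a 1e6 bound
and reported with the step index.  The history ring buffer holds
τ + 1 samples.  Screening decisions include a margin floor of 1e-6 on
the baseline SD so threshold comparisons are not decided by float
round-off.  Protocol events are applied at the sample indices nearest
their times; coupling-scale events never mutate the matrix (the scaled
contribution is added as a separate term), so baseline restoration
after an event is exact by construction.

## Problem sizes in the shipped tests and acceptance runs

The test suite and acceptance script run the full 500-node circuit but
scale replication down: 4 reference pairs with ~10 initiation trials
each for the duration distribution (the published distribution uses 100
discharges per matrix), 1–2 pairs for stimulated-termination counts,
and a reduced candidate budget for screening demonstrations.  These
sizes are the package's reference desk-scale experiment; every count is
a parameter.
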