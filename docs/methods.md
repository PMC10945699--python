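# Model and methods

## Scope

`ubcsim` models the feed-forward microcircuits formed by cerebellar
unipolar brush cells (UBCs): single-compartment conductance-based ON and
OFF UBC neurons, glutamate volume transmission from presynaptic release
sites to AMPA and mGluR2 receptors, and one- or two-cell chains driven
by a presynaptic spike train.  The purpose of the model family is to
reproduce, from a fixed parameterization, the four signal
transformations these chains implement: burst extension (ON→ON), pause
extension (ON→OFF), delayed pause (OFF→ON) and delayed burst (OFF→OFF).

## Membrane model

Each UBC is a single isopotential compartment,

    C_m dV/dt = −Σ_i g_i·x_i(V,t)·(V − E_i) + (I_inj + I_bias − I_syn)/A,

with channels Na (m³h), delayed-rectifier K (n⁴), a slow
non-inactivating K conductance (gate s), a hyperpolarization-activated
cation conductance Ih (gate q) and a passive leak.  Conductance
densities, reversal potentials, diameters (20 µm ON, 27 µm OFF) and the
1 µF/cm² specific capacitance are the reference model values; membrane
area uses the cylinder-of-length-equal-diameter convention (π·d²,
no end caps), giving 12.6 pF (ON) and 22.9 pF (OFF), which bracket the
measured whole-cell capacitances.

Gating steady states are Boltzmann functions and time constants are
Gaussian bumps of voltage, `tau(V) = t0 + ta·exp(−((V−tv)/tw)²)`.  The
rate constants of the original model are not available (its schemes
live in cited prior work), so they are free parameters here, fixed once
by calibration (below) and exposed in the config.  Two deliberate
asymmetries between the subtypes:

* **ON** Na activation midpoint −39.3 mV: low rheobase (~25 pA), so the
  slow rebound synaptic current can re-ignite firing after a single
  release event.  At rest (−65 mV, set by the leak) the cell is
  quiescent, including under the 5 µM ambient glutamate of its synapse.
* **OFF** Na activation midpoint −41.5 mV: the sodium window current
  destabilizes the −58 mV rest state and the cell becomes an intrinsic
  pacemaker (8.8 Hz, ISI coefficient of variation < 1e-3).  An unstable
  rest state is essential, not cosmetic: the mGluR2-evoked pause ends by
  a *slow* ramp of decaying K current, and a cell with a coexisting
  stable rest state parks there and never resumes firing.
* The OFF Ih midpoint sits far below rest (−116 mV vs −78 mV for ON), so
  that despite the 31× larger gH density the standing Ih is small and
  the voltage sag appears only on strong hyperpolarizing steps, as in
  the recordings (OFF sag > ON sag under −100 pA).

The slow K gate (s, τ = 30 ms, midpoint −45 mV) and the slow component
of the delayed-rectifier recovery (n, τ up to 34 ms near −60 mV)
together produce type-II-like firing: an abrupt onset near 25–30 Hz at
rheobase and a compressed frequency–intensity curve.  This matches the
reference burst statistics (12 spikes/358 ms ≈ 33 Hz) and makes burst
terminations sharp rather than trailing off.

## Glutamate diffusion

Release is a point source in porous neuropil:

    C(r,t) = N / (α (4π D* t)^{3/2}) · exp(−r²/(4 D* t)),  D* = D/λ²,

with N = 3e6 molecules at r = 0.75 µm for the AMPA synapse and N = 3e5
at r = 1.75 µm for mGluR2 (receptors farther from the release site),
λ = 1.55, α = 0.21, ambient 5 µM at the AMPA synapse.  The reference table lists
the diffusion coefficient as 0.33 cm²/s, a unit slip of 1e5; it
is interpreted here as 0.33 µm²/ms, the standard value for glutamate in
tissue.  Analytic properties used as test oracles: time-to-peak
r²λ²/(6D) (0.68 ms / 3.7 ms), peak concentrations 4.14 mM / 32.6 µM,
and mass conservation of the Gaussian.  Per-event transients are
precomputed on the integration grid and superposed; every presynaptic
spike releases the full molecule count after a 1.24 ms synaptic delay
(the measured mossy-fiber→UBC latency); there is no short-term
plasticity or transporter uptake.

## Receptor schemes

**AMPA (ON UBC).**  A four-state cyclic Markov scheme

    C --kb·T^2--> O --kd--> D --krs--> S --kc--> C,    O --ku--> C,

with two conducting states: O carries the fast EPSC and S, a slowly
closing open conformation entered on recovery from desensitization,
carries the slow rebound EPSC that drives the ON UBC's prolonged burst.
Sustained stimulation piles occupancy into D and S (net desensitization
of the fast response); when transmission stops, S drains with
τ = 1/kc ≈ 394 ms, in the range of the measured slow-EPSC decay
(358 ± 214 ms).  Binding is cooperative (T², two glutamate molecules to
open): mM-scale synaptic transients gate the receptor effectively while
the µM-scale diffusion tail and ambient glutamate barely move it.  This
is what lets a tonically firing presynaptic OFF cell drive the ON cell
without saturating the slow pool — the property behind the ~370 ms
delayed pause.  The current is I = g_syn·(O+S)·(V−0 mV) with
g_syn = 4 nS.

**mGluR2 (OFF UBC).**  A G-protein cascade in the GABA-B style:

    dR/dt = k1·T^2·(1−R) − k2·R,    dG/dt = k3·R − k4·G,
    I = g_syn·G⁴/(G⁴ + K_d)·(V + 90 mV),  g_syn = 10 nS.

The unbinding rate is fixed at the reference value k2 = 0.0215 ms⁻¹
(τ = 46.5 ms); k1, k3, k4 and K_d are calibration outputs.  The T²
binding is an effective cooperativity (the receptor functions as a
dimer) serving the same tonic-versus-phasic separation as for AMPA.
The reference synaptic conductances are given in S/cm²; multiplying by
the compartment area would yield femtosiemens-scale conductances, so
they are read as absolute conductances (4 nS, 10 nS), the only
physically workable interpretation.

## Circuits and stimulation

A circuit is one stimulus source plus one or two UBCs in a chain.  The
receptor on an edge is dictated by the postsynaptic subtype (ON ⇒ AMPA,
OFF ⇒ mGluR2).  Because the graph is feed-forward, integrating the
nodes in topological order on a common grid is exact co-integration;
every presynaptic spike (stimulus or UBC, including spikes during the
settling window) schedules one release event on each outgoing edge.

The stimulus module generates the standard protocols: a 3-spike burst
spanning 19.6 ms (9.8 ms inter-spike interval), regular trains of 1–10
spikes at 50 Hz, the 10-event 50 Hz calibration train, and current
steps (−100 pA sag, −5 pA input resistance, 0–60 pA × 500 ms
frequency–intensity).  These are deterministic; a seed field exists for
optional stimulus jitter and defaults to none.  The generator emulates
regular electrical-stimulation protocols only — it does not model
physiological mossy-fiber statistics (irregular inter-spike intervals,
rate modulation), so passing tests demonstrate fidelity to the slice
protocols, not to in-vivo input.

## Numerics

* Fixed-step integration, default dt = 0.005 ms.  Gates and the
  membrane potential use exponential-Euler updates; the AMPA scheme a
  backward-Euler step whose update matrix has unit column sums, so
  occupancy is conserved to machine precision; the mGluR2 cascade exact
  exponential updates of its two linear ODEs.
* Burst/pause metrics are converged at the default step (a coarser
  0.025 ms grid can move the marginal final spike of a burst); driven
  spike times shift < 0.1 ms under dt halving.
* Release events snap to the grid (error ≤ dt/2).
* Circuits settle for 2–3 s before t = 0 so that pacemaker phase,
  receptor occupancies (pre-equilibrated to ambient glutamate) and the
  slow synaptic pools reach their operating point; single-cell
  measurements discard a 0.5–1 s settling window.
* Spike detection: upward crossing of 0 mV with a 1 ms refractory
  lockout.

## Metric definitions

The source text does not define its burst/pause measurements
operationally, so the package fixes these conventions:

* **Burst**: spikes after stimulus onset, terminated at the first
  inter-spike interval exceeding max(100 ms, 5× the median within-burst
  ISI); duration is first-to-last spike.  For disinhibition firing of a
  silent OFF cell (OFF→OFF motif) the floor is raised to 300 ms because
  firing resumes at the ~9 Hz pacemaker rate.
* **Pause**: the first gap starting within 200 ms of stimulus onset
  exceeding 3× the median baseline ISI, measured last-spike-before to
  first-spike-after; undefined (NaN) if firing never resumes.
* **Delayed-pause latency (OFF→ON)**: stimulus onset to the
  postsynaptic cell's last spike before its (late-starting) pause; the
  gap search window is 2 s because the pause is delayed by design.
* **Delayed-burst latency (OFF→OFF)**: intermediate cell's last
  pre-pause spike to the postsynaptic cell's first spike.

## Calibration

Free parameters (gating kinetics, AMPA rates, mGluR2 cascade rates)
were fixed by a staged, deterministic procedure: (1) passive and
firing-mode properties (input resistance, sag ordering, ON quiescence,
OFF tonic regularity); (2) receptor kinetics against the two
single-cell anchors — a 10-event train must give an ~865 ms ON burst
and an ~1545 ms OFF pause; (3) chain-level verification of the
two-cell transformations.  The shipped defaults are the output of this
procedure (Nelder–Mead refinement on log-rates at the converged
integration step), so `calibrate_receptors()` on the defaults verifies
the anchors and returns immediately.  With them the model reproduces,
out of sample: 12 spikes/402 ms and 37 spikes/1053 ms in the ON→ON
chain (reference: 12/358.0 and 35/1175.3), a 442 ms delayed pause onset
(reference ~370 ms), and a 1224 ms delayed-burst latency (reference
1082.7 ms).

## Known limitations

* **Pause extension magnitude.**  The mean pause extension produced by
  an intermediate ON UBC over 1–10 input spikes is ~735 ms in this
  implementation versus the reference ~940 ms.  The extension decomposes
  into (intermediate burst length − input span) plus a G-protein decay
  term; with the ON burst durations pinned by the 358/865 ms anchors
  and the mGluR2 decay pinned by the 1545/1082.7 ms pause and latency
  values, the achievable mean saturates below the reference figure in
  this scheme family.  All individual extensions are positive and
  roughly constant for ≥3 input spikes, as described.
* **Rebound saturation.**  The description that the rebound EPSC
  saturates by ~100 ms of stimulation conflicts, within any scheme
  whose slow pool is filled by release events, with the reference 358 ms
  (3-event) versus 865 ms (10-event, 180 ms train) burst durations,
  which require continued pool growth.  The calibration follows the
  reference durations; rebound charge grows with decelerating increments
  instead of saturating sharply at 100 ms.
* **Relative excitability.**  Recorded ON UBCs fire faster than OFF
  UBCs at a +40 pA step; in this model family the OFF cell, being an
  intrinsic pacemaker riding a depolarized leak, is the faster one at
  equal injected current.
* No mGluR1/TRP ("late-onset") conductances, no NMDA receptors, no
  Golgi/Purkinje inhibition, no short-term plasticity, no stochastic
  channel or release noise, single compartments only, chains of at
  most two UBCs.  Temperature corrections are not modelled.
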