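# Methods

## The plasticity rule

`glunplast` implements a phenomenological, voltage-based model of long-term
plasticity at CA3–CA1 synapses in which the induction of LTP and LTD is
routed through the two dominant hippocampal NMDAR subunit types.  The
synaptic weight `w` (the AMPAR strength, dimensionless, `w(0) = 1`) obeys
soft-bounded antagonistic dynamics

    dw/dt = A₊ φ₊ V̄₊ (w_max − w)  −  A₋ φ₋ V̄₋ X̄ (w − w_min)

with the following ingredients, all advanced at dt = 0.025 ms:

- **Subunit kinetic conductances.**  Each presynaptic spike triggers a 1 ms
  saturating transmitter pulse.  During the pulse the open fraction of each
  subunit population relaxes toward `α/(α+β)` with time constant
  `1/(α+β)`; at pulse offset it is handed to an off-pool that decays with
  the unbinding rate `β` (the standard kinetic-release formalism).  With
  the default rates (GluN2A: α = 0.5, β = 0.024 ms⁻¹; GluN2B: α = 0.1,
  β = 0.0075 ms⁻¹) GluN2A activates fast and decays with ≈ 42 ms while
  GluN2B activates slowly and decays with ≈ 133 ms.  Both conductances are
  gated by the Jahr–Stevens magnesium unblock
  `f = 1/(1 + exp(−0.062 V)·[Mg]/3.57)` at the dendritic potential and
  scaled by a maximal conductance ĝ = 10⁻² nS.
- **Pathway mixing.**  The LTP pathway senses
  `g₊ = 0.8·g_2B + 0.2·g_2A` (GluN2B-dominated), the LTD pathway
  `g₋ = 0.2·g_2B + 0.8·g_2A`.  GluN2B blockade (ifenprodil-like
  hypofunction) scales ĝ_2B by the remaining fraction, in the synaptic
  current and in both pathways.
- **Conductance filters and Hill activations.**  `g₊` is low-passed with
  20 ms (tracking individual release events) and `g₋` with 1000 ms
  (integrating whole induction protocols).  Each filtered conductance
  drives a Hill function (`n₊ = 4`, `K_a₊ = 11·10⁻⁵`; `n₋ = 2`,
  `K_a₋ = 9·10⁻⁵`) minus a moving threshold, rectified at zero.  These
  activations stand in for CaMKII-like (LTP) and phosphatase-like (LTD)
  signaling without modelling calcium explicitly.
- **Competition.**  The moving thresholds are cross-coupled low-passes
  (τ = 100 ms): sustained φ₊ raises the LTD threshold with gain
  `b_θφ₋ = 10³` (a strong veto — any appreciable LTP activity silences
  depression) and sustained φ₋ raises the LTP threshold with gain
  `b_θφ₊` (see *Calibration*).
- **Voltage traces.**  `V̄₊/V̄₋` are 10 ms low-passes of the rectified
  dendritic depolarization above θ₊ = −65 mV / θ₋ = −67 mV.  The host
  neuron rests just *below* θ₋, so both traces are event-driven
  (back-propagating spikes and EPSPs), which is what gives depression its
  timing specificity.
- **Presynaptic trace.**  `X̄` decays with τ_δ = 15 ms and is incremented
  by `presyn_scale/τ_δ` per presynaptic spike.  It gates the LTD term
  only: depression requires presynaptic activity near postsynaptic
  depolarization.
- **Bounds.**  Soft bounds `(w_max − w)`, `(w − w_min)` plus a hard clamp
  to [w_min, w_max] = [0.4, 2.0] after each Euler step guard against
  overshoot at finite dt.

All linear filters and gating variables use exponential-Euler updates
(exact for piecewise-constant input); voltages, calcium and the weight use
forward Euler.  The whole system is advanced by a single numba-compiled
kernel, so a 13 s induction protocol (520 000 steps) runs in well under a
second and full protocol batteries take seconds.

## Host neuron

The host is a two-compartment pyramidal-cell model of the Pinsky–Rinzel
family with smooth (continuous) rate functions on an absolute voltage
scale.  The soma carries Na, delayed-rectifier K, a small high-threshold
Ca, C-type KCa and AHP currents; the dendrite carries Ca, KCa and AHP; the
compartments are coupled with g_c = 10.5 mS/cm² (strong coupling: regular
spiking, large back-propagating action potentials at the dendritic
synapse).  The leak reversal (−67.5 mV) places rest at −67.4 mV, just
below θ₋, for the reason given above.  Somatic action potentials are
commanded by 2 ms current pulses whose amplitude is auto-calibrated by
bisection (then set 25 % above threshold and verified 1:1 for 1–4 pulse
trains at 10 ms intervals); pulse onsets are advanced by the measured
spike latency so the commanded spike times are realized.  The neuron
follows 1:1 commands down to ≈ 8 ms intervals; shorter intervals are
refractory and are reported as a protocol error.

A `NeuronBackend` protocol (step, synapse-site voltage, somatic voltage)
defines the adapter surface for morphologically detailed hosts.  The
recipe for such an experiment — a cluster of 50 synapses at 0.8
synapses/µm placed 140 µm from the soma in stratum radiatum, AMPAR/NMDAR
current ratio of 4 measured at −65 mV / +40 mV — is documented here for
external simulators but is not executed by this package.

## Protocols

- **STDP pairing**: presynaptic input paired with 1–4 commanded
  postsynaptic spikes, `n` repetitions at a pairing frequency.  ΔT > 0
  means the presynaptic spike precedes the reference postsynaptic spike
  (the *second* spike of a doublet, per the measurement convention of the
  underlying experiments; the first/only spike otherwise).  The doublet
  intra-burst interval defaults to 10 ms.  Each run starts from the
  relaxed resting state, appends 1 s of relaxation, audits the generated
  schedule (declared ΔT realized within one dt) and verifies the somatic
  spike count.
- **Frequency conditioning**: presynaptic stimulation at 100 Hz for 1 s
  (LTP protocol) or 1 Hz for 100 s (LTD protocol), with a single EPSP test
  pulse 2 s before and 2 s after conditioning; the outcome is the ratio of
  somatic EPSP peaks (percent of baseline).  Spontaneous spiking during a
  test window is an error (the EPSP would be unmeasurable).
- **Scans**: ΔT grids, pairing-frequency scans (single-post, ΔT = +10 ms,
  20 repetitions), postsynaptic-spike-count scans (30 repetitions at 5 Hz,
  ΔT to the first spike) and GluN2B-blockade scans.  Crossovers are located
  by sign-change bracketing (bisection) between grid points; everything is
  deterministic, so reruns are bit-identical.

## Calibration

Three constants are not fixed by the published parameter tables and were
calibrated once, against the model's two stated validation landmarks on
the two-compartment host (the causal STDP boundary at ΔT = 40 ms for 60
doublet pairings at 5 Hz, and the pairing-frequency crossover at 5 Hz for
single-post pairings at ΔT = +10 ms):

- `g_scale = 0.0665` — the conversion between the nS conductances of the
  synapse model and the unit in which the Hill constants `K_a±` are
  expressed (the parameter table mixes µS/cm² and nS; only the ratio
  `K_a/(g_scale·g)` enters the rule).
- `presyn_scale = 0.1` — the per-spike increment of `X̄` in units of
  1/τ_δ.  The delta-increment convention is not fixed by the rule's
  definition; this constant sets the overall drive of the depression
  pathway.  Without it the timing-dependent LTD is an order of magnitude
  too strong and short trains (5 pairings) depress where they should be
  neutral.
- `b_θφ₊ = 18` — the LTP-threshold competition gain, whose published
  candidates span 0.1–100 across alternative configurations.  This veto is
  what terminates the causal LTP window: during a long doublet train the
  slowly accumulating φ₋ raises the LTP threshold, and the gain determines
  where on the causal side potentiation gives way to depression.

The AMPAR conductance (biexponential, τ_rise = 0.5 ms, τ_decay = 3 ms,
E_rev = 0 mV, gmax = 0.5 nS) and the nS→mS/cm² synaptic coupling
(`k_syn = 0.05`) are set so a unit-weight EPSP depolarizes the dendrite
(and, with strong coupling, the soma) by ≈ 1.9 mV; only relative EPSP
ratios matter for the protocol outcomes.
`glunplast calibrate` re-measures all landmarks (rest, command amplitude
and latency, unit EPSP, both crossovers) from scratch.

With these constants the calibrated model yields a causal crossover of
40.1 ms and a frequency crossover of 5.02 Hz, and the entire protocol
battery (pairing-count and frequency modulation, spike-count threshold,
blockade phenotype) falls out without further adjustment.

## Parameter sets

The published parameter table lists up to three values per parameter
(plain plus two parenthesized alternates) without mapping them to
experiments.  The package ships them as named sets: `stdp-2c` (the plain
column with the calibrated constants above; the default used by every
protocol runner and by the tests) and `alt-1` / `alt-2` (the parenthesized
columns, provided for exploration; they are not calibrated against the
two-compartment host).

## Numerical choices and conventions

- dt = 0.025 ms everywhere; `step_neuron` refuses dt > 0.05 ms.  Halving
  dt changes the somatic trajectory by < 0.5 mV RMS over a stimulated
  200 ms window.
- Spike detection: upward crossing of −20 mV at the soma with a 2 ms
  refractory period.
- Weight-change outcomes are classified with a ±2 % band around 1.0
  (relative change below 0.98 = depression, above 1.02 = potentiation,
  otherwise no change) — the resolution we attribute to published
  weight-change curves, adopted before the battery was finalized.
- Receptor bookkeeping: the default "hand-off" scheme moves the open
  fraction from the on-pool to the off-pool at pulse offset, and the
  active fraction is their sum; a new pulse restarts the on-phase from the
  current open fraction, keeping it bounded by 1.  A literal
  `Ron − Roff` difference mode (the off-pool as a decaying shadow of
  pre-pulse activation, loaded at pulse onset) is available via
  `SynapseConfig(mode="difference")` for sensitivity analysis; it is not
  used by any default.
- With a 1 ms transmitter pulse GluN2A loads to 0.39 of saturation but
  GluN2B only to 0.095, so the per-event *charge* is larger for GluN2A
  even though GluN2B inactivates more slowly; GluN2B charge dominance
  holds at equal loading (or for pulses ≳ 3 ms).  The slow GluN2B tail,
  not its per-event charge, is what drives the frequency dependence of
  potentiation.

## What the model does and does not capture

The rule is phenomenological: φ₊/φ₋ summarize kinase/phosphatase cascades
without modelling calcium, dendritic spines or receptor trafficking, and
the host neuron is a two-compartment caricature of a CA1 cell.  Passing
protocol tests therefore demonstrate that the *rule* reproduces the
targeted induction phenomenology on this host — not that the parameters
are biophysically unique, nor that the quantitative weight changes
transfer to morphologically detailed neurons (where synapse location and
local depolarization reshape outcomes).  The strong saturation of `w` at
its bounds under sustained drive means relative-change magnitudes carry
less information than their signs and crossover locations, which is why
calibration and acceptance both target sign structure and crossovers.
Known limitations: no GluN2C/D or presynaptic NMDARs, no mGluR/astrocyte
signalling, no stochastic release — the simulator is fully deterministic.
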