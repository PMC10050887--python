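# glunplast

Simulation of **GluN2A/GluN2B-subunit-dependent synaptic plasticity** at
hippocampal CA3–CA1 synapses.  The package implements a phenomenological,
voltage-based plasticity rule in which LTP induction is routed mainly
through slow GluN2B-NMDAR conductances and LTD through fast GluN2A-NMDAR
conductances, embeds it at a dendritic synapse of a two-compartment
(Pinsky–Rinzel-style) CA1 pyramidal neuron, and ships the full battery of
induction protocols used to characterize such rules: spike-timing-dependent
plasticity (STDP) pairings, pairing-frequency and spike-count scans,
high/low-frequency conditioning with somatic EPSP readout, and
GluN2B-blockade (ifenprodil-like hypofunction) scans.

It is aimed at computational neuroscientists who want a cheap, fully
deterministic synapse model that is sensitive to NMDAR subunit composition
— e.g. for studying learning rules under GluN2B hypofunction — without
simulating calcium dynamics or biochemical cascades.

## The model in brief

The AMPAR weight `w ∈ [w_min, w_max]` follows

```
dw/dt = A₊ φ₊(ḡ₊) V̄₊ (w_max − w) − A₋ φ₋(ḡ₋) V̄₋ X̄ (w − w_min)
```

where `ḡ₊, ḡ₋` are low-pass filters (20 ms / 1000 ms) of the
subunit-weighted NMDAR conductances `g₊ = 0.8·g_2B + 0.2·g_2A` and
`g₋ = 0.2·g_2B + 0.8·g_2A`; `φ±` are rectified Hill activations with
cross-coupled moving thresholds that implement LTP/LTD competition;
`V̄±` are filtered rectified dendritic depolarizations above −65 / −67 mV;
and `X̄` is a presynaptic spike trace gating depression.  Each subunit
conductance is a two-state kinetic scheme driven by 1 ms transmitter
pulses and gated by Jahr–Stevens Mg²⁺ unblock.  See `docs/methods.md` for
the complete description, parameters and calibration.

## Worked example

```python
from glunplast import (Model, PairingProtocol, BlockadeSpec, run_pairing,
                       stdp_causal_crossover, frequency_crossover)

model = Model()  # two-compartment host, "stdp-2c" parameter set

# Classic pre-post vs post-pre doublet pairing, 60x at 5 Hz
for dT in (+10.0, -10.0):
    res = run_pairing(PairingProtocol(delta_t=dT), model=model)
    print(f"dT = {dT:+.0f} ms -> w_final/w_initial = {res.relative_change:.3f}")

# Where does causal LTP give way to LTD?  Where does frequency rescue LTP?
print(f"causal STDP boundary : {stdp_causal_crossover(model):.1f} ms")
print(f"frequency crossover  : {frequency_crossover(model):.2f} Hz")

# Full GluN2B blockade abolishes LTP at dT = +20 ms
res = run_pairing(PairingProtocol(delta_t=20.0), BlockadeSpec(0.0), model)
print(f"dT = +20 ms, GluN2B blocked -> {res.relative_change:.3f}")
```

prints

```
dT = +10 ms -> w_final/w_initial = 1.850
dT = -10 ms -> w_final/w_initial = 0.479
causal STDP boundary : 40.1 ms
frequency crossover  : 5.02 Hz
dT = +20 ms, GluN2B blocked -> 0.400
```

A pre-before-post doublet pairing potentiates (w rises 1 → 1.85, clipped
at w_max = 2), the reversed timing depresses, potentiation switches to
depression for causal delays beyond ≈ 40 ms and pairing frequencies above
≈ 5 Hz rescue potentiation for single-spike pairings — and removing the
GluN2B conductance converts the LTP protocol into depression (w falls to
w_min = 0.4), while LTD protocols are unaffected.

## Command line

Every experiment family is also a CLI subcommand writing a CSV (one row
per protocol point) and a JSON summary, both stamped with the hash of the
validated YAML configuration:

```
glunplast stdp-curve --grid="-100:100:10"
glunplast freq-scan --freqs 1,2,3,5,7,10,20
glunplast blockade-scan --fractions 1.0,0.7,0.3,0.0
glunplast frequency --config ltp100hz.yaml
glunplast rule-standalone --scenario doublet-pairing
glunplast calibrate
```

`rule-standalone` runs the plasticity rule by itself on a CSV voltage
trace (`time,V,presyn_spike,g2A,g2B`), so externally recorded membrane
potentials can drive the rule without the bundled neuron.

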