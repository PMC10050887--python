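"""Two-compartment Pinsky-Rinzel-style CA1 pyramidal host neuron.

Soma: Na, delayed-rectifier K, a small high-threshold Ca, Ca-dependent K
(fast C-type and slow AHP) plus leak.  Dendrite: Ca, Ca-dependent K (C and
AHP) plus leak.  Compartments are coupled by ``g_c``; the plastic synapse
sits on the dendrite.  Gating kinetics follow the smooth (continuous)
Pinsky-Rinzel rate functions with voltages on an absolute scale; the leak
reversal and conductance balance are set so that rest sits just below the
plasticity-rule voltage thresholds (about -67.4 mV), making the filtered
voltage traces event-driven, and a brief somatic pulse elicits a single
action potential rather than a burst.

Conductance densities in mS/cm^2, capacitance in uF/cm^2, currents in
uA/cm^2, time in ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from . import _kernel as K

DEFAULT_DT = 0.025  #: integration step (ms)

#: spike detection: upward crossing of this somatic potential (mV)
SPIKE_THRESHOLD = -20.0


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Passive and active membrane parameters of both compartments."""

    cm: float = 3.0
    g_c: float = 10.5
    p: float = 0.5
    g_leak_soma: float = 0.1
    g_leak_dend: float = 0.1
    e_leak: float = -67.5
    g_na: float = 30.0
    e_na: float = 60.0
    g_kdr: float = 15.0
    e_k: float = -75.0
    g_ca_soma: float = 0.5
    e_ca: float = 80.0
    g_kca_soma: float = 2.0
    g_kahp_soma: float = 0.2
    g_ca_dend: float = 3.0
    g_kca_dend: float = 8.0
    g_kahp_dend: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("somatic area fraction p must lie in (0, 1)")
        for name in ("cm", "g_c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_leak_soma", "g_leak_dend", "g_na", "g_kdr",
                     "g_ca_soma", "g_kca_soma", "g_kahp_soma", "g_ca_dend",
                     "g_kca_dend", "g_kahp_dend"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_array(self) -> np.ndarray:
        n = np.zeros(K.N_NPAR)
        n[K.NP_CM] = self.cm
        n[K.NP_GC] = self.g_c
        n[K.NP_P] = self.p
        n[K.NP_GLS] = self.g_leak_soma
        n[K.NP_GLD] = self.g_leak_dend
        n[K.NP_EL] = self.e_leak
        n[K.NP_GNA] = self.g_na
        n[K.NP_ENA] = self.e_na
        n[K.NP_GKDR] = self.g_kdr
        n[K.NP_EK] = self.e_k
        n[K.NP_GCAS] = self.g_ca_soma
        n[K.NP_ECA] = self.e_ca
        n[K.NP_GKCS] = self.g_kca_soma
        n[K.NP_GKAHPS] = self.g_kahp_soma
        n[K.NP_GCAD] = self.g_ca_dend
        n[K.NP_GKCD] = self.g_kca_dend
        n[K.NP_GKAHPD] = self.g_kahp_dend
        return n

    def _key(self) -> tuple:
        return tuple(self.to_array())


@dataclass
class TwoCompartmentState:
    """Voltages, gating variables and calcium of both compartments."""

    Vs: float = -66.0
    Vd: float = -66.0
    h: float = 0.999
    n: float = 0.001
    s_soma: float = 0.0
    c_soma: float = 0.0
    q_soma: float = 0.0
    Ca_soma: float = 0.0
    s_dend: float = 0.0
    c_dend: float = 0.0
    q_dend: float = 0.0
    Ca_dend: float = 0.0

    def to_vector(self, y: "np.ndarray | None" = None) -> np.ndarray:
        if y is None:
            y = np.zeros(K.NSTATE)
        y[K.IVS] = self.Vs
        y[K.IVD] = self.Vd
        y[K.IH] = self.h
        y[K.IN] = self.n
        y[K.ISS] = self.s_soma
        y[K.ICS] = self.c_soma
        y[K.IQS] = self.q_soma
        y[K.ICAS] = self.Ca_soma
        y[K.ISD] = self.s_dend
        y[K.ICD] = self.c_dend
        y[K.IQD] = self.q_dend
        y[K.ICAD] = self.Ca_dend
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "TwoCompartmentState":
        return cls(Vs=float(y[K.IVS]), Vd=float(y[K.IVD]),
                   h=float(y[K.IH]), n=float(y[K.IN]),
                   s_soma=float(y[K.ISS]), c_soma=float(y[K.ICS]),
                   q_soma=float(y[K.IQS]), Ca_soma=float(y[K.ICAS]),
                   s_dend=float(y[K.ISD]), c_dend=float(y[K.ICD]),
                   q_dend=float(y[K.IQD]), Ca_dend=float(y[K.ICAD]))


class NeuronBackend(Protocol):
    """Adapter surface for alternative host neurons.

    The protocol runners only require stepping the membrane forward,
    reading the voltage at the synapse site (the Mg-gate and plasticity
    input) and reading the somatic voltage (spike detection and EPSP
    readout).  An external-simulator adapter (e.g. a morphologically
    detailed cell driven through its own integrator) can implement this
    interface; the bundled implementation is the two-compartment model.
    """

    def advance(self, dt: float, i_soma: float,
                i_syn_dend: float) -> None: ...

    def synapse_voltage(self) -> float: ...

    def soma_voltage(self) -> float: ...


class NeuronBlowupError(RuntimeError):
    """Numerical blow-up (|V| > 200 mV) during integration."""


class CalibrationError(RuntimeError):
    """Spike-command calibration failed to find 1:1 pulse-to-spike mapping."""


def step_neuron(state: TwoCompartmentState, params: TwoCompartmentParams,
                I_soma: float = 0.0, I_syn_dend: float = 0.0,
                dt: float = DEFAULT_DT) -> TwoCompartmentState:
    """Advance the neuron one step; injected somatic current and dendritic
    synaptic current in uA/cm^2 (I_syn_dend positive outward)."""
    if not 0.0 < dt <= 0.05:
        raise ValueError("dt must lie in (0, 0.05] ms")
    y = state.to_vector()
    status = K.neuron_step(y, params.to_array(), dt, I_soma, I_syn_dend)
    if status != 0:
        raise NeuronBlowupError("membrane potential exceeded 200 mV")
    return TwoCompartmentState.from_vector(y)


def _passive_synapse_spar() -> np.ndarray:
    s = np.zeros(K.N_SPAR)
    s[K.SP_A2A] = s[K.SP_A2B] = 0.1
    s[K.SP_B2A] = s[K.SP_B2B] = 0.01
    s[K.SP_MG] = 1.0
    s[K.SP_PULSE] = 1.0
    s[K.SP_ATAUR] = 0.5
    s[K.SP_ATAUD] = 3.0
    return s


def _inert_ppar() -> np.ndarray:
    # valid (division-safe) plasticity parameters for plasticity-off runs
    p = np.ones(K.N_PPAR)
    p[K.PP_WMIN] = 0.0
    p[K.PP_WMAX] = 2.0
    p[K.PP_AP] = p[K.PP_AM] = 0.0
    return p


_EMPTY = np.zeros(0, dtype=np.int64)
_EMPTYF = np.zeros(0, dtype=np.float64)


def run_passive(y: np.ndarray, params: TwoCompartmentParams, duration: float,
                dt: float = DEFAULT_DT,
                pulse_on: np.ndarray = _EMPTY,
                pulse_dur: np.ndarray = _EMPTY,
                pulse_amp: np.ndarray = _EMPTYF,
                rec_stride: int = 0):
    """Advance the neuron (no synapse, no plasticity) in-place for
    ``duration`` ms; returns (rec, spike_times)."""
    n_steps = int(round(duration / dt))
    status, rec, spikes, nspk = K.simulate(
        n_steps, dt, y, params.to_array(), _passive_synapse_spar(),
        _inert_ppar(), _EMPTY, pulse_on, pulse_dur, pulse_amp,
        rec_stride, False)
    if status != 0:
        raise NeuronBlowupError("membrane potential exceeded 200 mV")
    return rec, spikes


_RESTING_CACHE: dict[tuple, TwoCompartmentState] = {}


def resting_state(params: TwoCompartmentParams = TwoCompartmentParams(),
                  dt: float = DEFAULT_DT,
                  settle_ms: float = 2000.0) -> TwoCompartmentState:
    """Unstimulated equilibrium, found by relaxing for ``settle_ms``.

    Raises if the terminal drift exceeds 0.01 mV/ms in either compartment.
    """
    key = params._key() + (dt,)
    if key in _RESTING_CACHE:
        return _RESTING_CACHE[key]
    y = TwoCompartmentState().to_vector()
    run_passive(y, params, settle_ms, dt)
    before = (y[K.IVS], y[K.IVD])
    run_passive(y, params, 1.0, dt)
    drift_s = abs(y[K.IVS] - before[0]) / 1.0
    drift_d = abs(y[K.IVD] - before[1]) / 1.0
    if drift_s > 0.01 or drift_d > 0.01:
        raise NeuronBlowupError(
            f"no resting equilibrium after {settle_ms} ms "
            f"(dVs/dt={drift_s:.3g}, dVd/dt={drift_d:.3g} mV/ms)")
    state = TwoCompartmentState.from_vector(y)
    _RESTING_CACHE[key] = state
    return state


# ------------------------------------------------------- spike command

PULSE_MS = 2.0  #: somatic command pulse duration


def _count_spikes_for_amp(params: TwoCompartmentParams, amp: float,
                          dt: float, n_pulses: int = 1,
                          interval: float = 10.0):
    rest = resting_state(params, dt)
    y = rest.to_vector()
    onsets = 20.0 + interval * np.arange(n_pulses)
    on = np.rint(onsets / dt).astype(np.int64)
    dur = np.full(n_pulses, int(round(PULSE_MS / dt)), dtype=np.int64)
    ampv = np.full(n_pulses, amp, dtype=np.float64)
    duration = onsets[-1] + 60.0
    rec, spikes = run_passive(y, params, duration, dt, on, dur, ampv)
    return spikes, onsets


_COMMAND_CACHE: dict[tuple, tuple] = {}


def calibrate_spike_command(params: TwoCompartmentParams = TwoCompartmentParams(),
                            dt: float = DEFAULT_DT) -> tuple[float, float]:
    """Find (amplitude uA/cm^2, spike latency ms) for the 2 ms somatic pulse.

    The amplitude is set 25% above the single-spike threshold found by
    bisection and verified to drive 1:1 spiking for 1..4 pulse trains at
    10 ms intervals.
    """
    key = params._key() + (dt,)
    if key in _COMMAND_CACHE:
        return _COMMAND_CACHE[key]
    lo, hi = 0.1, 80.0
    spikes, _ = _count_spikes_for_amp(params, hi, dt)
    if spikes.size == 0:
        raise CalibrationError("no spike even at maximal pulse amplitude")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        spikes, _ = _count_spikes_for_amp(params, mid, dt)
        if spikes.size >= 1:
            hi = mid
        else:
            lo = mid
    for factor in (1.25, 1.5, 2.0, 2.5, 3.0):
        amp = hi * factor
        ok = True
        latency = np.nan
        for n_pulses in (1, 2, 4):
            spikes, onsets = _count_spikes_for_amp(params, amp, dt, n_pulses)
            if spikes.size != n_pulses:
                ok = False
                break
            lats = spikes - onsets
            if np.any(lats < 0) or np.any(lats > PULSE_MS + 8.0):
                ok = False
                break
            latency = float(np.mean(lats))
        if ok:
            _COMMAND_CACHE[key] = (amp, latency)
            return amp, latency
    raise CalibrationError("could not achieve 1:1 pulse-to-spike mapping")


def somatic_spike_command(n_spikes: int, first_time: float,
                          intra_burst_interval: float = 10.0,
                          params: TwoCompartmentParams = TwoCompartmentParams(),
                          dt: float = DEFAULT_DT):
    """Current-pulse schedule placing ``n_spikes`` somatic APs at
    ``first_time + k * intra_burst_interval``.

    Returns (onset_times ms, durations ms, amplitudes uA/cm^2).
    """
    if not 1 <= n_spikes <= 4:
        raise ValueError("n_spikes must be in 1..4")
    amp, latency = calibrate_spike_command(params, dt)
    onsets = first_time - latency + intra_burst_interval * np.arange(n_spikes)
    if np.any(onsets < 0):
        raise ValueError("schedule starts before t=0; shift first_time")
    durations = np.full(n_spikes, PULSE_MS)
    amps = np.full(n_spikes, amp)
    return onsets, durations, amps
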