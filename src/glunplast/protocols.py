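"""Induction protocols and experiment runners.

Every experiment starts from the unstimulated resting state of the host
neuron with w = 1 and all plasticity traces at zero, runs a declarative
stimulation schedule (STDP pairings or frequency conditioning), relaxes,
and reports the relative weight change w_final / w_initial — and, for the
frequency protocols, the ratio of somatic EPSP peaks measured by single
test pulses before and after conditioning.

Timing convention: a positive pairing offset dT means the presynaptic
spike precedes the reference postsynaptic spike (the second spike of a
doublet, or the spike itself / the first spike where stated) by dT ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernel as K
from .neuron import (DEFAULT_DT, NeuronBlowupError, TwoCompartmentParams,
                     TwoCompartmentState, calibrate_spike_command, PULSE_MS,
                     resting_state)
from .rule import PlasticityParams, get_params
from .synapses import SynapseConfig

#: relaxation appended after every induction schedule (ms)
RELAX_MS = 1000.0

#: gap between an EPSP test pulse and the conditioning train (ms)
TEST_GAP_MS = 2000.0

#: window after a test pulse within which the EPSP peak is measured (ms)
EPSP_WINDOW_MS = 150.0

#: offset of the first postsynaptic spike within each pairing period (ms);
#: large enough that anti-causal pairings down to dT = -100 ms fit
PAIRING_PAD_MS = 120.0


@dataclass(frozen=True)
class Model:
    """Host neuron + synapse + plasticity rule + integration step."""

    neuron: TwoCompartmentParams = TwoCompartmentParams()
    synapse: SynapseConfig = SynapseConfig()
    plasticity: PlasticityParams = field(
        default_factory=lambda: get_params("stdp-2c"))
    dt: float = DEFAULT_DT


@dataclass(frozen=True)
class PairingProtocol:
    """One STDP pairing experiment.

    delta_t > 0: presynaptic spike precedes the reference postsynaptic
    spike.  The reference is the second spike of a doublet ("second") or
    the first postsynaptic spike ("first").
    """

    delta_t: float
    n_pairings: int = 60
    pairing_freq: float = 5.0
    n_post_spikes: int = 2
    intra_burst_interval: float = 10.0
    reference_spike: Literal["first", "second"] = "second"

    def __post_init__(self) -> None:
        if self.n_pairings < 0:
            raise ValueError("n_pairings must be >= 0")
        if not 1 <= self.n_post_spikes <= 4:
            raise ValueError("n_post_spikes must be in 1..4")
        if self.reference_spike == "second" and self.n_post_spikes < 2:
            raise ValueError("'second' reference needs >= 2 post spikes")
        if self.pairing_freq <= 0:
            raise ValueError("pairing_freq must be positive")
        burst = (self.n_post_spikes - 1) * self.intra_burst_interval
        if 1000.0 / self.pairing_freq <= burst:
            raise ValueError("pairing period must exceed burst duration")

    @property
    def reference_index(self) -> int:
        return 1 if self.reference_spike == "second" else 0


@dataclass(frozen=True)
class FrequencyProtocol:
    """Presynaptic conditioning at ``rate`` Hz for ``duration`` s."""

    rate: float
    duration: float

    def __post_init__(self) -> None:
        if self.rate * self.duration < 1 and self.duration != 0:
            raise ValueError("rate * duration must be >= 1")


@dataclass(frozen=True)
class BlockadeSpec:
    """Remaining fraction of the GluN2B maximal conductance in [0, 1]."""

    glun2b_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.glun2b_fraction <= 1.0:
            raise ValueError("glun2b_fraction must lie in [0, 1]")


@dataclass
class WeightChangeResult:
    w_initial: float
    w_final: float
    relative_change: float
    trace: "pd.DataFrame | None" = None
    spike_times: "np.ndarray | None" = None


@dataclass
class EPSPRatioResult:
    epsp_before: float
    epsp_after: float
    ratio: float  #: percent of baseline


class ProtocolError(RuntimeError):
    """A protocol contract was violated during simulation."""


_REC_COLS = ["time", "Vs", "Vd", "g2A", "g2B", "g_ampa", "w",
             "gbar_plus", "gbar_minus", "phi_plus", "phi_minus",
             "theta_phi_plus", "theta_phi_minus", "vbar_plus", "vbar_minus",
             "xbar"]


def _rec_frame(rec: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(rec, columns=_REC_COLS)


def _initial_vector(model: Model) -> np.ndarray:
    y = resting_state(model.neuron, model.dt).to_vector()
    y[K.IW] = 1.0
    return y


def _simulate(model: Model, blockade: BlockadeSpec, duration: float,
              pre_times: np.ndarray, pulse_on: np.ndarray,
              pulse_dur: np.ndarray, pulse_amp: np.ndarray,
              record_stride_ms: float = 0.0):
    """Run the engine from combined rest; returns (y, rec, spikes)."""
    dt = model.dt
    n_steps = int(round(duration / dt))
    y = _initial_vector(model)
    pre_steps = np.rint(np.sort(np.asarray(pre_times, float)) / dt
                        ).astype(np.int64)
    on = np.rint(np.asarray(pulse_on, float) / dt).astype(np.int64)
    dur = np.rint(np.asarray(pulse_dur, float) / dt).astype(np.int64)
    amp = np.asarray(pulse_amp, float)
    stride = int(round(record_stride_ms / dt)) if record_stride_ms > 0 else 0
    status, rec, spikes, nspk = K.simulate(
        n_steps, dt, y, model.neuron.to_array(),
        model.synapse.to_array(blockade.glun2b_fraction),
        model.plasticity.to_array(), pre_steps, on, dur, amp, stride, True)
    if status != 0:
        raise NeuronBlowupError("membrane potential exceeded 200 mV")
    return y, rec, spikes


def pairing_schedule(protocol: PairingProtocol, model: Model,
                     t_start: float = 100.0):
    """Event times for a pairing train.

    Returns (pre_times, pulse_on, pulse_dur, pulse_amp, post_spike_times)
    where post_spike_times are the commanded somatic spike times.
    """
    amp, latency = calibrate_spike_command(model.neuron, model.dt)
    period = 1000.0 / protocol.pairing_freq
    n = protocol.n_pairings
    ibi = protocol.intra_burst_interval
    k = np.arange(n)
    first_post = t_start + PAIRING_PAD_MS + k * period
    post_times = (first_post[:, None]
                  + ibi * np.arange(protocol.n_post_spikes)[None, :])
    ref = post_times[:, protocol.reference_index] if n else np.zeros(0)
    pre_times = ref - protocol.delta_t
    pulse_on = (post_times - latency).ravel()
    if n and (pulse_on.min() < 0 or pre_times.min() < 0):
        raise ValueError("schedule extends before t=0; increase t_start")
    pulse_dur = np.full(pulse_on.size, PULSE_MS)
    pulse_amp = np.full(pulse_on.size, amp)
    return pre_times, pulse_on, pulse_dur, pulse_amp, post_times


def audit_schedule(protocol: PairingProtocol, pre_times: np.ndarray,
                   post_times: np.ndarray, dt: float) -> None:
    """Verify the generated schedule realizes the declared dT within dt."""
    if protocol.n_pairings == 0:
        return
    ref = post_times[:, protocol.reference_index]
    err = np.abs((ref - pre_times) - protocol.delta_t)
    if np.any(err > dt):
        raise ProtocolError(
            f"schedule dT off by up to {err.max():.4f} ms")


def run_pairing(protocol: PairingProtocol,
                blockade: BlockadeSpec = BlockadeSpec(),
                model: Model = Model(),
                record_stride_ms: float = 0.0,
                relax_ms: float = RELAX_MS) -> WeightChangeResult:
    """Simulate a full pairing train plus relaxation; report weight change.

    Raises :class:`ProtocolError` if the somatic spike count does not match
    the commanded count.
    """
    pre, on, dur, amp, post = pairing_schedule(protocol, model)
    audit_schedule(protocol, pre, post, model.dt)
    if protocol.n_pairings == 0:
        return WeightChangeResult(1.0, 1.0, 1.0)
    duration = max(pre.max(), post.max()) + relax_ms
    y, rec, spikes = _simulate(model, blockade, duration, pre, on, dur, amp,
                               record_stride_ms)
    expected = protocol.n_pairings * protocol.n_post_spikes
    if spikes.size != expected:
        raise ProtocolError(
            f"commanded {expected} somatic spikes but detected {spikes.size}")
    w_final = float(y[K.IW])
    return WeightChangeResult(
        w_initial=1.0, w_final=w_final, relative_change=w_final,
        trace=_rec_frame(rec) if record_stride_ms > 0 else None,
        spike_times=spikes)


def stdp_curve(delta_t_grid: Sequence[float],
               protocol: PairingProtocol = PairingProtocol(delta_t=0.0),
               blockade: BlockadeSpec = BlockadeSpec(),
               model: Model = Model()) -> pd.DataFrame:
    """One run_pairing per dT; returns columns (delta_t, relative_change)."""
    from dataclasses import replace
    grid = list(delta_t_grid)
    if not grid:
        raise ValueError("delta_t_grid must be non-empty")
    rows = []
    for dT in grid:
        res = run_pairing(replace(protocol, delta_t=float(dT)),
                          blockade, model)
        rows.append((float(dT), res.relative_change))
    return pd.DataFrame(rows, columns=["delta_t", "relative_change"])


def frequency_scan(freqs: Sequence[float],
                   delta_t: float = 10.0,
                   n_pairings: int = 20,
                   blockade: BlockadeSpec = BlockadeSpec(),
                   model: Model = Model()) -> pd.DataFrame:
    """Single-post pairings at fixed dT across pairing frequencies."""
    rows = []
    for f in freqs:
        proto = PairingProtocol(delta_t=delta_t, n_pairings=n_pairings,
                                pairing_freq=float(f), n_post_spikes=1,
                                reference_spike="first")
        res = run_pairing(proto, blockade, model)
        rows.append((float(f), res.relative_change))
    return pd.DataFrame(rows, columns=["frequency", "relative_change"])


def spike_count_scan(n_post_range: Sequence[int] = (1, 2, 3, 4),
                     delta_t: float = 10.0,
                     n_pairings: int = 30,
                     pairing_freq: float = 5.0,
                     blockade: BlockadeSpec = BlockadeSpec(),
                     model: Model = Model()) -> pd.DataFrame:
    """Weight change vs number of postsynaptic spikes (dT to first spike)."""
    rows = []
    for n in n_post_range:
        proto = PairingProtocol(delta_t=delta_t, n_pairings=n_pairings,
                                pairing_freq=pairing_freq,
                                n_post_spikes=int(n),
                                reference_spike="first")
        res = run_pairing(proto, blockade, model)
        rows.append((int(n), res.relative_change))
    return pd.DataFrame(rows, columns=["n_post_spikes", "relative_change"])


def _epsp_from_rec(rec: np.ndarray, spikes: np.ndarray, onset: float,
                   dt_rec: float) -> float:
    t = rec[:, K.REC_T]
    vs = rec[:, K.REC_VS]
    sel = (t >= onset - 5.0) & (t <= onset + EPSP_WINDOW_MS)
    if np.any((spikes >= onset - 5.0) & (spikes <= onset + EPSP_WINDOW_MS)):
        raise ProtocolError("spontaneous spiking during EPSP test pulse")
    base = vs[(t >= onset - 5.0) & (t < onset)].mean()
    peak = vs[sel].max()
    epsp = float(peak - base)
    if epsp <= 0:
        raise ProtocolError("non-positive test EPSP")
    return epsp


def run_frequency(protocol: FrequencyProtocol,
                  blockade: BlockadeSpec = BlockadeSpec(),
                  model: Model = Model(),
                  record_stride_ms: float = 0.0
                  ) -> tuple[WeightChangeResult, EPSPRatioResult]:
    """Frequency conditioning with EPSP test pulses before and after.

    A single presynaptic test pulse is delivered ``TEST_GAP_MS`` before the
    conditioning train and again ``TEST_GAP_MS`` after it; the EPSP peak is
    measured at the soma relative to the pre-pulse baseline.
    """
    t_test1 = 300.0
    t_cond = t_test1 + TEST_GAP_MS
    dur_ms = protocol.duration * 1000.0
    n_cond = int(round(protocol.rate * protocol.duration))
    cond = t_cond + np.arange(n_cond) * (1000.0 / protocol.rate) \
        if n_cond else np.zeros(0)
    t_test2 = t_cond + dur_ms + TEST_GAP_MS
    duration = t_test2 + EPSP_WINDOW_MS + RELAX_MS
    pre = np.concatenate([[t_test1], cond, [t_test2]])
    stride = record_stride_ms if record_stride_ms > 0 else 0.5
    y, rec, spikes = _simulate(model, blockade, duration, pre,
                               np.zeros(0), np.zeros(0), np.zeros(0),
                               stride)
    epsp1 = _epsp_from_rec(rec, spikes, t_test1, stride)
    epsp2 = _epsp_from_rec(rec, spikes, t_test2, stride)
    w_final = float(y[K.IW])
    wres = WeightChangeResult(
        w_initial=1.0, w_final=w_final, relative_change=w_final,
        trace=_rec_frame(rec) if record_stride_ms > 0 else None,
        spike_times=spikes)
    eres = EPSPRatioResult(epsp_before=epsp1, epsp_after=epsp2,
                           ratio=100.0 * epsp2 / epsp1)
    return wres, eres


def blockade_scan(fractions: Sequence[float],
                  protocol: "PairingProtocol | FrequencyProtocol",
                  model: Model = Model()) -> pd.DataFrame:
    """Outcome per remaining GluN2B fraction for one protocol."""
    rows = []
    for f in fractions:
        spec = BlockadeSpec(glun2b_fraction=float(f))
        if isinstance(protocol, PairingProtocol):
            res = run_pairing(protocol, spec, model)
            rows.append((float(f), res.relative_change, np.nan))
        else:
            wres, eres = run_frequency(protocol, spec, model)
            rows.append((float(f), wres.relative_change, eres.ratio))
    return pd.DataFrame(rows, columns=["glun2b_fraction", "relative_change",
                                       "epsp_ratio_percent"])
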