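"""Calibration landmarks and crossover measurements.

Two dimensionless conversion constants of the rule (``g_scale``,
``presyn_scale``) plus the competition gain ``b_theta_plus`` are not
determined by the published parameter tables alone; they are fixed once so
that the two validation landmarks of the model hold on the two-compartment
host: the causal STDP boundary (LTP switches to LTD at dT = 40 ms for 60
doublet pairings at 5 Hz) and the pairing-frequency crossover (single-post
pairings at dT = 10 ms switch from depression to potentiation at 5 Hz).
This module measures those landmarks from scratch by sign-change
bracketing, so the calibration is reproducible and auditable.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from . import _kernel as K
from .neuron import calibrate_spike_command, resting_state
from .protocols import (BlockadeSpec, Model, PairingProtocol, run_pairing)


def bracket_crossing(f: Callable[[float], float], lo: float, hi: float,
                     iters: int = 12) -> float:
    """Bisection root of a sign change of f on [lo, hi].

    f(lo) and f(hi) must have opposite signs; f is deterministic, so plain
    bisection converges to (hi-lo)/2**iters.
    """
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise ValueError(f"no sign change on [{lo}, {hi}]")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if np.sign(fm) == np.sign(flo):
            lo, flo = mid, fm
        else:
            hi, fhi = mid, fm
    return 0.5 * (lo + hi)


def stdp_causal_crossover(model: Model = Model(),
                          blockade: BlockadeSpec = BlockadeSpec(),
                          n_pairings: int = 60, pairing_freq: float = 5.0,
                          lo: float = 10.0, hi: float = 100.0,
                          iters: int = 12) -> float:
    """Causal-side dT (ms) at which 60 doublet pairings at 5 Hz switch from
    potentiation to depression."""
    def f(dT: float) -> float:
        proto = PairingProtocol(delta_t=float(dT), n_pairings=n_pairings,
                                pairing_freq=pairing_freq)
        return run_pairing(proto, blockade, model).relative_change - 1.0
    return bracket_crossing(f, lo, hi, iters)


def frequency_crossover(model: Model = Model(),
                        blockade: BlockadeSpec = BlockadeSpec(),
                        delta_t: float = 10.0, n_pairings: int = 20,
                        lo: float = 3.0, hi: float = 30.0,
                        iters: int = 12) -> float:
    """Pairing frequency (Hz) at which single-post pairings at dT = 10 ms
    switch from net depression to net potentiation."""
    def f(freq: float) -> float:
        proto = PairingProtocol(delta_t=delta_t, n_pairings=n_pairings,
                                pairing_freq=float(freq), n_post_spikes=1,
                                reference_spike="first")
        return run_pairing(proto, blockade, model).relative_change - 1.0
    return bracket_crossing(f, lo, hi, iters)


def unit_epsp(model: Model = Model()) -> dict:
    """Somatic and dendritic EPSP peaks (mV) of a single release at w = 1."""
    from .protocols import _simulate
    y, rec, spikes = _simulate(model, BlockadeSpec(), 400.0,
                               np.array([100.0]), np.zeros(0), np.zeros(0),
                               np.zeros(0), record_stride_ms=0.1)
    t = rec[:, K.REC_T]
    pre = t < 100.0
    post = (t >= 100.0) & (t <= 250.0)
    return {
        "epsp_soma_mv": float(rec[post, K.REC_VS].max()
                              - rec[pre, K.REC_VS][-10:].mean()),
        "epsp_dend_mv": float(rec[post, K.REC_VD].max()
                              - rec[pre, K.REC_VD][-10:].mean()),
    }


def calibration_report(model: Model = Model(),
                       measure_crossovers: bool = True) -> dict:
    """Resting point, spike command, unit EPSP and (optionally) the two
    validation landmarks of the given model configuration."""
    rest = resting_state(model.neuron, model.dt)
    amp, latency = calibrate_spike_command(model.neuron, model.dt)
    report = {
        "rest_vs_mv": rest.Vs,
        "rest_vd_mv": rest.Vd,
        "command_amplitude_ua_cm2": amp,
        "command_latency_ms": latency,
        **unit_epsp(model),
    }
    if measure_crossovers:
        report["stdp_causal_crossover_ms"] = stdp_causal_crossover(model)
        report["frequency_crossover_hz"] = frequency_crossover(model)
    return report
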