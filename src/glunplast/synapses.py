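"""GluN2A/GluN2B NMDAR kinetic conductances and the AMPAR waveform.

Each NMDAR subunit type is a two-state (open/closed) channel driven by a
brief saturating transmitter pulse per presynaptic spike (Destexhe-style
release).  During the pulse the open fraction relaxes toward its steady
state ``alpha/(alpha+beta)`` with time constant ``1/(alpha+beta)``; after
the pulse it decays with the unbinding rate ``beta``.  The channel is
additionally gated by the voltage-dependent Mg2+ unblock of Jahr & Stevens.

GluN2B carries slower kinetics (longer tail) than GluN2A, which is what the
plasticity rule exploits to separate LTP- and LTD-inducing drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from . import _kernel as K

OpenFractionMode = Literal["handoff", "difference"]

_MODE_CODE = {"handoff": 0, "difference": 1}

#: transmitter pulse duration per presynaptic spike (ms)
TRANSMITTER_PULSE_MS = 1.0


@dataclass(frozen=True)
class SubunitKinetics:
    """Binding kinetics and maximal conductance of one GluN2 subunit type.

    alpha / beta are forward / backward transmitter binding rates (1/ms),
    ghat the maximal conductance (nS).
    """

    name: str
    alpha: float
    beta: float
    ghat: float

    def __post_init__(self) -> None:
        if self.name not in ("GluN2A", "GluN2B"):
            raise ValueError(f"unknown subunit name {self.name!r}")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("binding rates must be positive")
        if self.ghat < 0:
            raise ValueError("ghat must be non-negative")


#: fast subunit: tau_on ~ 1.9 ms, off-tail 1/beta ~ 42 ms
GLUN2A = SubunitKinetics("GluN2A", alpha=0.5, beta=0.024, ghat=1e-2)
#: slow subunit: tau_on ~ 9.3 ms, off-tail 1/beta ~ 133 ms
GLUN2B = SubunitKinetics("GluN2B", alpha=0.1, beta=0.0075, ghat=1e-2)


@dataclass
class ReceptorState:
    """Open-fraction bookkeeping of one subunit population."""

    Ron: float = 0.0
    Roff: float = 0.0
    pulse_remaining: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.Ron <= 1.0 and 0.0 <= self.Roff <= 1.0):
            raise ValueError("open fractions must lie in [0, 1]")
        if self.pulse_remaining < 0:
            raise ValueError("pulse_remaining must be >= 0")


@dataclass(frozen=True)
class MgEnvironment:
    """Extracellular magnesium concentration (mM)."""

    mg_conc: float = 1.0

    def __post_init__(self) -> None:
        if not self.mg_conc > 0:
            raise ValueError("mg_conc must be positive")


@dataclass(frozen=True)
class AMPARParams:
    """Biexponential AMPAR conductance; the plastic weight scales gmax."""

    gmax: float = 0.5
    tau_rise: float = 0.5
    tau_decay: float = 3.0
    e_rev: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.gmax < 0:
            raise ValueError("gmax must be non-negative")

    @property
    def peak_time(self) -> float:
        """Time after onset at which the unit waveform peaks (ms)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)


def mg_gate(V: float, env: MgEnvironment = MgEnvironment()) -> float:
    """Fraction of NMDAR conductance unblocked by Mg2+ at potential V (mV).

    f = 1 / (1 + exp(-0.062 V) [Mg]/3.57); strictly increasing in V.
    """
    if not np.isfinite(V):
        raise ValueError("membrane potential must be finite")
    return K.mg_gate_scalar(float(V), env.mg_conc)


def steady_state_open(kin: SubunitKinetics) -> float:
    """Open fraction reached under saturating transmitter, alpha/(alpha+beta)."""
    return kin.alpha / (kin.alpha + kin.beta)


def kinetic_time_constant(kin: SubunitKinetics) -> float:
    """Relaxation time constant during transmitter presence, 1/(alpha+beta) ms."""
    return 1.0 / (kin.alpha + kin.beta)


def open_fraction(state: ReceptorState,
                  mode: OpenFractionMode = "handoff") -> float:
    """Active open fraction entering the conductance."""
    return K.open_fraction_scalar(state.Ron, state.Roff, _MODE_CODE[mode])


def advance_receptor(state: ReceptorState, kin: SubunitKinetics, dt: float,
                     presyn_event: bool = False,
                     pulse_ms: float = TRANSMITTER_PULSE_MS,
                     mode: OpenFractionMode = "handoff") -> ReceptorState:
    """Advance the receptor state one step of dt ms.

    A presynaptic event (re)starts a transmitter pulse of ``pulse_ms``
    from the current open fraction; at pulse offset the open fraction is
    handed to the decaying off pool (default mode).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mcode = _MODE_CODE[mode]
    y = np.zeros(K.NSTATE)
    y[K.IRON_A] = state.Ron
    y[K.IROFF_A] = state.Roff
    pulse = state.pulse_remaining
    if presyn_event:
        if mcode == 1:
            y[K.IROFF_A] += y[K.IRON_A]
            y[K.IRON_A] = 0.0
        else:
            y[K.IRON_A] += y[K.IROFF_A]
            y[K.IROFF_A] = 0.0
        pulse = pulse_ms
    in_pulse = pulse > 0.0
    K.receptor_step(y, K.IRON_A, K.IROFF_A, kin.alpha, kin.beta, dt,
                    in_pulse, mcode)
    if in_pulse:
        pulse -= dt
        if pulse <= 0.0:
            pulse = 0.0
            if mcode == 0:
                y[K.IROFF_A] += y[K.IRON_A]
                y[K.IRON_A] = 0.0
    return ReceptorState(Ron=float(y[K.IRON_A]), Roff=float(y[K.IROFF_A]),
                         pulse_remaining=pulse)


def subunit_conductance(state: ReceptorState, kin: SubunitKinetics, V: float,
                        env: MgEnvironment = MgEnvironment(),
                        mode: OpenFractionMode = "handoff") -> float:
    """Instantaneous subunit conductance g = f_Mg(V) * open * ghat (nS)."""
    return mg_gate(V, env) * open_fraction(state, mode) * kin.ghat


def combined_nmda_conductance(g2A: float, g2B: float, k2B: float) -> float:
    """Pathway conductance: convex mix k2B*g2B + (1-k2B)*g2A.

    The LTP pathway weights GluN2B heavily (k2B+ = 0.8), the LTD pathway
    weakly (k2B- = 0.2).
    """
    if not 0.0 <= k2B <= 1.0:
        raise ValueError("k2B must lie in [0, 1]")
    if g2A < 0 or g2B < 0:
        raise ValueError("conductances must be non-negative")
    return k2B * g2B + (1.0 - k2B) * g2A


def ampar_conductance(t_since_events: Sequence[float],
                      params: AMPARParams, w: float = 1.0) -> float:
    """AMPAR conductance (nS) from elapsed times since presynaptic events.

    Peak-normalized biexponential per event, linearly superposed, scaled by
    w * gmax.  Negative elapsed times (future events) contribute nothing.
    """
    t = np.asarray(t_since_events, dtype=float)
    t = t[t >= 0.0]
    if t.size == 0:
        return 0.0
    wave = np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise)
    norm = K.ampa_norm(params.tau_rise, params.tau_decay)
    return float(w * params.gmax * wave.sum() / norm)


@dataclass(frozen=True)
class SynapseConfig:
    """Everything synapse-level bundled for the simulation engine.

    ``k_syn`` converts nS of synaptic conductance into a membrane
    conductance density (mS/cm^2) on the dendritic compartment; it is the
    single knob that sets the EPSP size of the host neuron and is fixed by
    calibration (unit EPSP depolarizes the dendrite by ~1-2 mV).
    """

    glun2a: SubunitKinetics = GLUN2A
    glun2b: SubunitKinetics = GLUN2B
    mg: MgEnvironment = MgEnvironment()
    ampar: AMPARParams = AMPARParams()
    pulse_ms: float = TRANSMITTER_PULSE_MS
    k_syn: float = 0.05
    e_nmda: float = 0.0
    mode: OpenFractionMode = "handoff"

    def to_array(self, glun2b_fraction: float = 1.0) -> np.ndarray:
        if not 0.0 <= glun2b_fraction <= 1.0:
            raise ValueError("glun2b_fraction must lie in [0, 1]")
        s = np.zeros(K.N_SPAR)
        s[K.SP_A2A] = self.glun2a.alpha
        s[K.SP_B2A] = self.glun2a.beta
        s[K.SP_G2A] = self.glun2a.ghat
        s[K.SP_A2B] = self.glun2b.alpha
        s[K.SP_B2B] = self.glun2b.beta
        s[K.SP_G2B] = self.glun2b.ghat
        s[K.SP_MG] = self.mg.mg_conc
        s[K.SP_PULSE] = self.pulse_ms
        s[K.SP_BLOCK] = glun2b_fraction
        s[K.SP_AGMAX] = self.ampar.gmax
        s[K.SP_ATAUR] = self.ampar.tau_rise
        s[K.SP_ATAUD] = self.ampar.tau_decay
        s[K.SP_AEREV] = self.ampar.e_rev
        s[K.SP_ENMDA] = self.e_nmda
        s[K.SP_KSYN] = self.k_syn
        s[K.SP_MODE] = _MODE_CODE[self.mode]
        return s


def blocked(kin: SubunitKinetics, fraction: float) -> SubunitKinetics:
    """Subunit with its maximal conductance scaled to ``fraction`` of baseline,
    modelling ifenprodil-like partial blockade."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("remaining fraction must lie in [0, 1]")
    return replace(kin, ghat=kin.ghat * fraction)
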