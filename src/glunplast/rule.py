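"""NMDAR-subunit-dependent voltage-based synaptic plasticity rule.

The weight obeys soft-bounded antagonistic drive

    dw/dt = A+ phi+ Vbar+ (wmax - w)  -  A- phi- Vbar- Xbar (w - wmin)

where phi+/- are rectified Hill activations of low-pass-filtered,
subunit-weighted NMDAR conductances (the LTP pathway weights GluN2B by
k2B+ = 0.8 and filters fast, tau = 20 ms; the LTD pathway weights GluN2A
and filters slowly, tau = 1000 ms, so it integrates over whole induction
protocols), Vbar+/- are low-passed rectified dendritic depolarizations
above the thresholds theta+/-, and Xbar is a low-passed presynaptic spike
trace that gates depression on presynaptic activity.  Cross-coupled moving
thresholds let a strongly active LTP pathway veto depression and vice
versa, implementing LTP/LTD competition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel as K


@dataclass(frozen=True)
class PlasticityParams:
    """Parameters of the plasticity rule (times in ms, voltages in mV).

    ``g_scale`` converts the nS conductances delivered by the synapse model
    to the unit in which the half-activation constants ``Ka_plus/minus``
    are expressed; only the ratio ``Ka / (g_scale * g)`` enters the rule.
    ``presyn_scale`` scales the per-spike increment of the presynaptic
    trace (increment = presyn_scale / tau_delta), i.e. the overall drive of
    the depression pathway.  Both are dimensionless conversion constants
    fixed once by calibration (see :mod:`glunplast.calibrate`).
    """

    A_plus: float = 1.0
    A_minus: float = 1e2
    Ka_plus: float = 11e-5
    Ka_minus: float = 9e-5
    n_plus: float = 4.0
    n_minus: float = 2.0
    tau_nmda_plus: float = 20.0
    tau_nmda_minus: float = 1000.0
    tau_theta_plus: float = 100.0
    tau_theta_minus: float = 100.0
    b_theta_plus: float = 18.0
    b_theta_minus: float = 1e3
    theta_plus: float = -65.0
    theta_minus: float = -67.0
    tau_plus: float = 10.0
    tau_minus: float = 10.0
    tau_delta: float = 15.0
    w_min: float = 0.4
    w_max: float = 2.0
    k2B_plus: float = 0.8
    k2B_minus: float = 0.2
    g_scale: float = 0.0665
    presyn_scale: float = 0.1

    def __post_init__(self) -> None:
        for name in ("tau_nmda_plus", "tau_nmda_minus", "tau_theta_plus",
                     "tau_theta_minus", "tau_plus", "tau_minus", "tau_delta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be below w_max")
        if self.n_plus < 1 or self.n_minus < 1:
            raise ValueError("Hill coefficients must be >= 1")
        for name in ("k2B_plus", "k2B_minus"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (self.Ka_plus > 0 and self.Ka_minus > 0):
            raise ValueError("half-activation constants must be positive")

    def to_array(self) -> np.ndarray:
        p = np.zeros(K.N_PPAR)
        p[K.PP_AP] = self.A_plus
        p[K.PP_AM] = self.A_minus
        p[K.PP_KAP] = self.Ka_plus
        p[K.PP_KAM] = self.Ka_minus
        p[K.PP_NP] = self.n_plus
        p[K.PP_NM] = self.n_minus
        p[K.PP_TGP] = self.tau_nmda_plus
        p[K.PP_TGM] = self.tau_nmda_minus
        p[K.PP_TTHP] = self.tau_theta_plus
        p[K.PP_TTHM] = self.tau_theta_minus
        p[K.PP_BTHP] = self.b_theta_plus
        p[K.PP_BTHM] = self.b_theta_minus
        p[K.PP_THVP] = self.theta_plus
        p[K.PP_THVM] = self.theta_minus
        p[K.PP_TVP] = self.tau_plus
        p[K.PP_TVM] = self.tau_minus
        p[K.PP_TX] = self.tau_delta
        p[K.PP_WMIN] = self.w_min
        p[K.PP_WMAX] = self.w_max
        p[K.PP_K2BP] = self.k2B_plus
        p[K.PP_K2BM] = self.k2B_minus
        p[K.PP_GSCALE] = self.g_scale
        p[K.PP_XSC] = self.presyn_scale
        return p


#: The three published value-columns shipped as named sets.  "stdp-2c" is
#: the configuration used with the two-compartment host neuron throughout
#: the protocol battery; the alternates are provided for exploration.
PARAM_SETS: dict[str, PlasticityParams] = {
    "stdp-2c": PlasticityParams(),
    "alt-1": PlasticityParams(
        A_plus=8e-4, A_minus=2e4, Ka_plus=5e-2, Ka_minus=2e-2,
        b_theta_plus=1e2, b_theta_minus=1e2, theta_plus=-67.0,
        w_min=0.2, w_max=2.5),
    "alt-2": PlasticityParams(
        A_plus=9e-2, A_minus=9e-1, Ka_plus=7e-3, Ka_minus=4e-3,
        b_theta_plus=1e-1, b_theta_minus=1e-1, theta_plus=-67.0,
        w_min=0.2, w_max=2.5),
}


def get_params(name_or_params: "str | PlasticityParams",
               **overrides) -> PlasticityParams:
    """Resolve a named parameter set, optionally overriding fields."""
    if isinstance(name_or_params, PlasticityParams):
        p = name_or_params
    else:
        try:
            p = PARAM_SETS[name_or_params]
        except KeyError:
            raise KeyError(
                f"unknown parameter set {name_or_params!r}; "
                f"available: {sorted(PARAM_SETS)}") from None
    return replace(p, **overrides) if overrides else p


@dataclass
class PlasticityState:
    """All dynamic variables of the rule."""

    w: float = 1.0
    gbar_plus: float = 0.0
    gbar_minus: float = 0.0
    phi_plus: float = 0.0
    phi_minus: float = 0.0
    theta_phi_plus: float = 0.0
    theta_phi_minus: float = 0.0
    vbar_plus: float = 0.0
    vbar_minus: float = 0.0
    xbar: float = 0.0


# --------------------------------------------------------------- single ops

def filter_conductance(gbar: float, g_nmda: float, tau: float,
                       dt: float) -> float:
    """First-order low-pass of the pathway conductance (exponential Euler)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return K.lowpass_scalar(gbar, g_nmda, dt, tau)


def hill_activation(gbar: float, Ka: float, n: float,
                    theta_phi: float = 0.0) -> float:
    """Rectified Hill activation max(0, 1/(1+(Ka/gbar)^n) - theta_phi)."""
    if gbar < 0:
        raise ValueError("filtered conductance must be non-negative")
    if Ka <= 0 or n < 1 or theta_phi < 0:
        raise ValueError("need Ka > 0, n >= 1, theta_phi >= 0")
    return max(0.0, K.hill_scalar(gbar, Ka, n) - theta_phi)


def update_moving_threshold(theta_phi_minus: float, theta_phi_plus: float,
                            phi_plus: float, phi_minus: float,
                            params: PlasticityParams,
                            dt: float) -> tuple[float, float]:
    """Cross-coupled threshold relaxation: phi+ raises the LTD threshold,
    phi- raises the LTP threshold.  Returns (theta_phi_minus, theta_phi_plus)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    new_m = K.lowpass_scalar(theta_phi_minus, params.b_theta_minus * phi_plus,
                             dt, params.tau_theta_minus)
    new_p = K.lowpass_scalar(theta_phi_plus, params.b_theta_plus * phi_minus,
                             dt, params.tau_theta_plus)
    return new_m, new_p


def filter_voltage(vbar: float, V: float, theta: float, tau: float,
                   dt: float) -> float:
    """Low-pass of the rectified thresholded potential [V - theta]+."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return K.lowpass_scalar(vbar, max(0.0, V - theta), dt, tau)


def update_presyn_trace(xbar: float, spike_now: bool, tau_delta: float,
                        dt: float, increment: "float | None" = None) -> float:
    """Presynaptic trace: decay with tau_delta, plus ``increment`` per
    spike (default the unit-area convention 1/tau_delta; the full rule uses
    presyn_scale/tau_delta).  The increment is applied before the decay."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if spike_now:
        xbar += (1.0 / tau_delta) if increment is None else increment
    return xbar * np.exp(-dt / tau_delta)


def weight_derivative(state: PlasticityState,
                      params: PlasticityParams) -> float:
    """Soft-bounded weight derivative (1/ms); LTD alone carries the
    presynaptic trace."""
    ltp = params.A_plus * state.phi_plus * state.vbar_plus \
        * (params.w_max - state.w)
    ltd = params.A_minus * state.phi_minus * state.vbar_minus * state.xbar \
        * (state.w - params.w_min)
    return ltp - ltd


def step_plasticity(state: PlasticityState, g2A: float, g2B: float, V: float,
                    presyn_spike: bool, params: PlasticityParams,
                    dt: float) -> PlasticityState:
    """Advance the full rule one step of dt ms.

    g2A, g2B are the instantaneous subunit conductances (nS, already
    Mg-gated); V is the dendritic membrane potential at the synapse.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(g2A) and np.isfinite(g2B) and np.isfinite(V)):
        raise ValueError("inputs must be finite")
    y = np.zeros(K.NSTATE)
    y[K.IW] = state.w
    y[K.IGBP] = state.gbar_plus
    y[K.IGBM] = state.gbar_minus
    y[K.ITHP] = state.theta_phi_plus
    y[K.ITHM] = state.theta_phi_minus
    y[K.IVBP] = state.vbar_plus
    y[K.IVBM] = state.vbar_minus
    y[K.IXB] = state.xbar
    if presyn_spike:
        y[K.IXB] += params.presyn_scale / params.tau_delta
    phi_p, phi_m = K.plasticity_step(y, params.to_array(), g2A, g2B, V, dt)
    return PlasticityState(
        w=float(y[K.IW]),
        gbar_plus=float(y[K.IGBP]), gbar_minus=float(y[K.IGBM]),
        phi_plus=float(phi_p), phi_minus=float(phi_m),
        theta_phi_plus=float(y[K.ITHP]), theta_phi_minus=float(y[K.ITHM]),
        vbar_plus=float(y[K.IVBP]), vbar_minus=float(y[K.IVBM]),
        xbar=float(y[K.IXB]))


def run_rule_on_trace(trace: pd.DataFrame,
                      params: "PlasticityParams | str" = "stdp-2c",
                      state: "PlasticityState | None" = None) -> pd.DataFrame:
    """Run the rule standalone over a recorded trace.

    ``trace`` needs columns ``time`` (ms, uniformly spaced), ``V`` (mV),
    ``presyn_spike`` (0/1), ``g2A`` and ``g2B`` (nS).  Returns one row of
    all state variables per input row.
    """
    params = get_params(params)
    required = {"time", "V", "presyn_spike", "g2A", "g2B"}
    missing = required - set(trace.columns)
    if missing:
        raise ValueError(f"trace is missing columns {sorted(missing)}")
    t = trace["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trace must have at least two samples")
    dt = float(t[1] - t[0])
    if dt <= 0 or not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-9):
        raise ValueError("trace time stamps must be uniformly spaced")

    st = state or PlasticityState()
    ppar = params.to_array()
    y = np.zeros(K.NSTATE)
    y[K.IW] = st.w
    y[K.IGBP] = st.gbar_plus
    y[K.IGBM] = st.gbar_minus
    y[K.ITHP] = st.theta_phi_plus
    y[K.ITHM] = st.theta_phi_minus
    y[K.IVBP] = st.vbar_plus
    y[K.IVBM] = st.vbar_minus
    y[K.IXB] = st.xbar

    v = trace["V"].to_numpy(dtype=float)
    spikes = trace["presyn_spike"].to_numpy(dtype=float) > 0.5
    g2a = trace["g2A"].to_numpy(dtype=float)
    g2b = trace["g2B"].to_numpy(dtype=float)
    out = np.zeros((len(t), 10))
    for i in range(len(t)):
        if spikes[i]:
            y[K.IXB] += params.presyn_scale / params.tau_delta
        phi_p, phi_m = K.plasticity_step(y, ppar, g2a[i], g2b[i], v[i], dt)
        out[i] = (y[K.IW], y[K.IGBP], y[K.IGBM], phi_p, phi_m,
                  y[K.ITHP], y[K.ITHM], y[K.IVBP], y[K.IVBM], y[K.IXB])
    cols = ["w", "gbar_plus", "gbar_minus", "phi_plus", "phi_minus",
            "theta_phi_plus", "theta_phi_minus", "vbar_plus", "vbar_minus",
            "xbar"]
    res = pd.DataFrame(out, columns=cols)
    res.insert(0, "time", t)
    return res
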