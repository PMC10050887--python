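"""Configuration schema, result serialization and synthetic fixture traces.

Config files are YAML validated against a strict schema (unknown keys are
rejected); every output file embeds the SHA-256 hash of the canonical
config so archived runs can be reproduced and verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .neuron import TwoCompartmentParams
from .protocols import (BlockadeSpec, FrequencyProtocol, Model,
                        PairingProtocol)
from .rule import PARAM_SETS, get_params
from .synapses import AMPARParams, GLUN2A, GLUN2B, MgEnvironment, SynapseConfig


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["pairing", "frequency"] = "pairing"
    # pairing fields
    delta_t: float = 10.0
    n_pairings: int = 60
    pairing_freq: float = 5.0
    n_post_spikes: int = 2
    intra_burst_interval: float = 10.0
    reference_spike: Literal["first", "second"] = "second"
    # frequency fields
    rate: float = 100.0
    duration: float = 1.0

    def build(self) -> "PairingProtocol | FrequencyProtocol":
        if self.kind == "frequency":
            return FrequencyProtocol(rate=self.rate, duration=self.duration)
        return PairingProtocol(
            delta_t=self.delta_t, n_pairings=self.n_pairings,
            pairing_freq=self.pairing_freq, n_post_spikes=self.n_post_spikes,
            intra_burst_interval=self.intra_burst_interval,
            reference_spike=self.reference_spike)


class BlockadeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    glun2b_fraction: float = Field(default=1.0, ge=0.0, le=1.0)


class RunConfig(BaseModel):
    """Validated description of one simulation run."""

    model_config = ConfigDict(extra="forbid")

    parameter_set: str = "stdp-2c"
    plasticity_overrides: dict[str, float] = Field(default_factory=dict)
    neuron_overrides: dict[str, float] = Field(default_factory=dict)
    synapse_overrides: dict[str, float] = Field(default_factory=dict)
    neuron_model: Literal["two-compartment"] = "two-compartment"
    dt: float = Field(default=0.025, gt=0.0, le=0.05)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    blockade: BlockadeConfig = Field(default_factory=BlockadeConfig)
    relax_ms: float = Field(default=1000.0, ge=0.0)
    record_stride_ms: float = Field(default=0.0, ge=0.0)
    output_dir: str = "results"
    #: reserved; the simulator is deterministic
    seed: int = 0

    @field_validator("parameter_set")
    @classmethod
    def _known_set(cls, v: str) -> str:
        if v not in PARAM_SETS:
            raise ValueError(
                f"unknown parameter_set {v!r}; available: {sorted(PARAM_SETS)}")
        return v

    def plasticity_params(self):
        # dataclass __post_init__ raises naming the offending key
        return get_params(self.parameter_set, **self.plasticity_overrides)

    def build_model(self) -> Model:
        neuron = TwoCompartmentParams(**self.neuron_overrides)
        syn_kwargs = dict(self.synapse_overrides)
        ampar_fields = {f.name for f in dataclasses.fields(AMPARParams)}
        ampar_kwargs = {k: syn_kwargs.pop(k) for k in list(syn_kwargs)
                        if k in ampar_fields}
        mg = syn_kwargs.pop("mg_conc", None)
        ghat2a = syn_kwargs.pop("ghat_glun2a", None)
        ghat2b = syn_kwargs.pop("ghat_glun2b", None)
        synapse = SynapseConfig(
            glun2a=dataclasses.replace(GLUN2A, **(
                {"ghat": ghat2a} if ghat2a is not None else {})),
            glun2b=dataclasses.replace(GLUN2B, **(
                {"ghat": ghat2b} if ghat2b is not None else {})),
            mg=MgEnvironment(mg) if mg is not None else MgEnvironment(),
            ampar=AMPARParams(**ampar_kwargs), **syn_kwargs)
        return Model(neuron=neuron, synapse=synapse,
                     plasticity=self.plasticity_params(), dt=self.dt)

    def blockade_spec(self) -> BlockadeSpec:
        return BlockadeSpec(self.blockade.glun2b_fraction)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: "str | Path | None" = None) -> RunConfig:
    """Load and validate a YAML config; None gives the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    cfg = RunConfig.model_validate(raw)
    cfg.plasticity_params()  # surface invalid overrides at load time
    cfg.build_model()
    return cfg


def dump_config(cfg: RunConfig, path: "str | Path") -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


def write_csv(df: pd.DataFrame, path: "str | Path",
              config_hash: str = "") -> None:
    """CSV with a leading ``# config_hash=...`` comment line (readable with
    pandas ``comment='#'``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={config_hash} glunplast={__version__}\n")
        df.to_csv(fh, index=False)


def read_csv(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_summary(summary: dict, path: "str | Path",
                  config_hash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config_hash": config_hash, "glunplast_version": __version__,
               **summary}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# -------------------------------------------------------- fixture traces

FIXTURE_SCENARIOS = ("rest", "single-epsp", "doublet-pairing")


def generate_fixture_traces(scenario: str, dt: float = 0.1,
                            delta_t: float = 10.0) -> pd.DataFrame:
    """Deterministic synthetic traces for exercising the standalone rule
    without the host neuron.

    Columns match the standalone-rule input contract: time (ms), V (mV),
    presyn_spike (0/1), g2A, g2B (nS).  The voltage is a stereotyped
    caricature (resting -65 mV, 2 mV EPSP bumps, 85 mV triangular spikes);
    the receptor conductances are generated by the kinetic synapse model.
    """
    if scenario not in FIXTURE_SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: {FIXTURE_SCENARIOS}")
    duration = 500.0
    t = np.arange(0.0, duration, dt)
    v = np.full(t.size, -65.0)
    presyn = np.zeros(t.size)

    pre_times: list[float] = []
    spike_times: list[float] = []
    if scenario == "single-epsp":
        pre_times = [100.0]
    elif scenario == "doublet-pairing":
        pre_times = [100.0]
        # doublet; dT measured from pre to the second spike
        spike_times = [100.0 + delta_t - 10.0, 100.0 + delta_t]

    for tp in pre_times:
        presyn[int(round(tp / dt))] = 1.0
        tau_r, tau_d = 2.0, 12.0
        rel = t - tp
        mask = rel >= 0
        bump = np.exp(-rel[mask] / tau_d) - np.exp(-rel[mask] / tau_r)
        v[mask] += 2.0 * bump / bump.max()
    for ts in spike_times:
        rel = t - ts
        up = (rel >= 0) & (rel < 1.0)
        down = (rel >= 1.0) & (rel < 3.0)
        v[up] += 85.0 * (rel[up] / 1.0)
        v[down] += 85.0 * (1.0 - (rel[down] - 1.0) / 2.0)

    from .synapses import (GLUN2A, GLUN2B, MgEnvironment, ReceptorState,
                           advance_receptor, open_fraction, mg_gate)
    g2a = np.zeros(t.size)
    g2b = np.zeros(t.size)
    sa, sb = ReceptorState(), ReceptorState()
    env = MgEnvironment()
    for i in range(t.size):
        ev = presyn[i] > 0
        sa = advance_receptor(sa, GLUN2A, dt, ev)
        sb = advance_receptor(sb, GLUN2B, dt, ev)
        fmg = mg_gate(v[i], env)
        g2a[i] = fmg * open_fraction(sa) * GLUN2A.ghat
        g2b[i] = fmg * open_fraction(sb) * GLUN2B.ghat
    return pd.DataFrame({"time": t, "V": v, "presyn_spike": presyn,
                         "g2A": g2a, "g2B": g2b})
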