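"""Run configuration: a validated, fully materialized, round-trippable snapshot.

Configs are plain YAML with four sections (instance, schedule, chaos, engine)
plus variant/seed.  Unknown keys are rejected — no silent typo tolerance —
and every defaulted field is materialized on save, so a persisted snapshot
plus a seed replays its run bit for bit.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .engine import VARIANTS, RunResult, run
from .landscapes import Landscape, planted_landscape
from .protein import ProteinLandscape, enumerate_variables, read_fasta
from .schedule import ConfigurationError, ScheduleParams

import numpy as np


def _from_mapping(cls, data: Dict, context: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{context} must be a mapping; got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class InstanceConfig:
    kind: str = "planted"            # "planted" | "fasta"
    fasta: Optional[str] = None
    record: Optional[str] = None
    sequence: Optional[str] = None   # inline alternative to a FASTA path
    angle_set: List[str] = field(default_factory=lambda: ["phi", "psi", "chi"])
    ends: str = "charged"
    m: int = 19
    n_traps: int = 5
    depth: float = 1.0
    landscape_seed: int = 0

    def validate(self) -> "InstanceConfig":
        if self.kind not in ("planted", "fasta"):
            raise ConfigurationError(f"instance.kind must be planted or fasta; got {self.kind!r}")
        if self.kind == "fasta" and not (self.fasta or self.sequence):
            raise ConfigurationError("instance.kind=fasta requires a fasta path or sequence")
        return self


@dataclass
class ChaosConfig:
    map: str = "M3"
    amplitude_deg: float = 90.0
    guard: float = 1e-6
    x0: float = 0.7

    def validate(self) -> "ChaosConfig":
        if self.map not in ("M1", "M2", "M3", "M4"):
            raise ConfigurationError(f"chaos.map must be one of M1..M4; got {self.map!r}")
        if self.amplitude_deg < 0:
            raise ConfigurationError("chaos.amplitude_deg must be non-negative")
        if not (0 < self.guard < 0.5):
            raise ConfigurationError("chaos.guard must lie in (0, 0.5)")
        if not (self.guard < self.x0 < 1 - self.guard):
            raise ConfigurationError("chaos.x0 must lie strictly inside the guarded interval")
        return self


@dataclass
class EngineConfig:
    metropolis_length: Optional[int] = None   # default 10*m
    dep_window: int = 30
    dep_epsilon: float = 1e-3
    m_chaot: Optional[int] = None             # default m
    max_evals: Optional[int] = None

    def validate(self) -> "EngineConfig":
        if self.metropolis_length is not None and self.metropolis_length < 1:
            raise ConfigurationError("engine.metropolis_length must be at least 1")
        if self.dep_window < 3:
            raise ConfigurationError("engine.dep_window must be at least 3")
        if self.dep_epsilon <= 0:
            raise ConfigurationError("engine.dep_epsilon must be positive")
        if self.m_chaot is not None and self.m_chaot < 0:
            raise ConfigurationError("engine.m_chaot must be non-negative")
        if self.max_evals is not None and self.max_evals < 1:
            raise ConfigurationError("engine.max_evals must be at least 1")
        return self


@dataclass
class RunConfig:
    variant: str = "cmqa"
    seed: int = 0
    out_dir: Optional[str] = None
    instance: InstanceConfig = field(default_factory=InstanceConfig)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    chaos: ChaosConfig = field(default_factory=ChaosConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)

    def validate(self) -> "RunConfig":
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"variant must be one of {VARIANTS}; got {self.variant!r}")
        self.instance.validate()
        self.schedule.validate()
        self.chaos.validate()
        self.engine.validate()
        return self

    @classmethod
    def from_dict(cls, data: Optional[Dict]) -> "RunConfig":
        data = dict(data or {})
        known = {"variant", "seed", "out_dir", "instance", "schedule", "chaos", "engine"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown top-level keys: {sorted(unknown)}")
        cfg = cls(
            variant=data.get("variant", "cmqa"),
            seed=int(data.get("seed", 0)),
            out_dir=data.get("out_dir"),
            instance=_from_mapping(InstanceConfig, data.get("instance"), "instance"),
            schedule=_from_mapping(ScheduleParams, data.get("schedule"), "schedule"),
            chaos=_from_mapping(ChaosConfig, data.get("chaos"), "chaos"),
            engine=_from_mapping(EngineConfig, data.get("engine"), "engine"),
        )
        return cfg.validate()

    def to_dict(self) -> Dict:
        return {
            "variant": self.variant,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "instance": dataclasses.asdict(self.instance),
            "schedule": dataclasses.asdict(self.schedule),
            "chaos": dataclasses.asdict(self.chaos),
            "engine": dataclasses.asdict(self.engine),
        }


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields pure defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    """Persist a config with every default materialized (full provenance)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def build_landscape(cfg: RunConfig) -> Landscape:
    """Materialize the landscape a config describes."""
    inst = cfg.instance.validate()
    if inst.kind == "planted":
        return planted_landscape(
            m=inst.m,
            n_traps=inst.n_traps,
            depth=inst.depth,
            rng=np.random.default_rng(inst.landscape_seed),
        )
    if inst.sequence:
        sequence = inst.sequence
    else:
        _, sequence = read_fasta(inst.fasta, record=inst.record)
    protein = enumerate_variables(sequence, tuple(inst.angle_set), ends=inst.ends)
    return ProteinLandscape(protein)


def run_from_config(cfg: RunConfig, landscape: Optional[Landscape] = None) -> RunResult:
    """Execute the run a config describes; the result embeds the snapshot."""
    cfg.validate()
    landscape = landscape if landscape is not None else build_landscape(cfg)
    return run(
        landscape,
        variant=cfg.variant,
        seed=cfg.seed,
        params=cfg.schedule,
        chaos_map=cfg.chaos.map,
        chaos_x0=cfg.chaos.x0,
        chaos_amplitude=cfg.chaos.amplitude_deg,
        chaos_guard=cfg.chaos.guard,
        L=cfg.engine.metropolis_length,
        m_chaot=cfg.engine.m_chaot,
        dep_window=cfg.engine.dep_window,
        dep_epsilon=cfg.engine.dep_epsilon,
        max_evals=cfg.engine.max_evals,
        config_snapshot=cfg.to_dict(),
    )
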