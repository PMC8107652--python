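"""Run configuration: YAML schema with strict (unknown keys rejected) loading.

Times in config files are given in milliseconds (the conventional unit on
scanners) and converted to seconds internally.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Dict, Optional

import yaml


def _strict(cls, d: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class TrajectoryConfig:
    n_spokes: int = 1020
    n_samples: int = 129
    spokes_per_frame: int = 20
    tr_ms: float = 4.1
    angle_order: int = 1  # tiny-golden-angle order; 1 = golden ratio
    base_angle: float = 0.0


@dataclass
class PhantomConfig:
    name: str = "t1_tubes"
    n_coils: int = 8
    coil_order: int = 2
    noise_rel_sigma: float = 0.01  # fraction of the per-coil DC magnitude


@dataclass
class ReconConfig:
    model: str = "t1"  # t1 | t2 | waterfat | flow
    grid_size: int = 128
    newton_steps: int = 10
    lambda0: float = 1.0
    reduction_q: float = 0.5
    inner_iters: int = 50
    inner_solver: str = "FISTA"
    wavelet_strength: float = 0.09
    l2_strength: float = 0.1


@dataclass
class SubspaceRunConfig:
    basis: str = "svd"  # svd | fourier
    n_coeff: int = 4
    l2_strength: float = 0.1
    iters: int = 50


@dataclass
class RunConfig:
    seed: int = 42
    output_dir: str = "."
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    subspace: SubspaceRunConfig = field(default_factory=SubspaceRunConfig)

    def to_dict(self) -> Dict:
        return asdict(self)


def load_config(path: Optional[str]) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    sub = {}
    for name, cls in (("trajectory", TrajectoryConfig),
                      ("phantom", PhantomConfig), ("recon", ReconConfig),
                      ("subspace", SubspaceRunConfig)):
        sub[name] = _strict(cls, raw.pop(name, {}), name)
    cfg = _strict(RunConfig, {**raw, **sub}, "run config")
    return cfg
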