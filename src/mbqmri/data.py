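"""In-memory k-space data container shared by simulator, I/O and recon."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .trajectories import Trajectory


@dataclass
class KSpaceData:
    """Multi-coil radial k-space with trajectory and timing metadata.

    ``y`` is complex, indexed (frame_or_echo, spoke, sample, coil);
    ``times`` holds one time stamp per frame/echo in seconds.
    """

    y: np.ndarray
    traj: Trajectory
    times: np.ndarray
    model_id: str = ""
    sigma: float = 0.0
    seed: int = 0
    meta: Dict = field(default_factory=dict)
    spoke_times: Optional[np.ndarray] = None

    def __post_init__(self):
        self.y = np.asarray(self.y, complex)
        self.times = np.asarray(self.times, float)
        expected = (self.traj.n_frames, self.traj.n_spokes,
                    self.traj.n_samples)
        if self.y.shape[:3] != expected:
            raise ValueError(
                f"data shape {self.y.shape[:3]} does not match trajectory "
                f"{expected}")
        if self.times.shape[0] != self.traj.n_frames:
            raise ValueError("times length must equal frame count")

    @property
    def n_coils(self) -> int:
        return self.y.shape[-1]
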