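"""Radial k-space trajectories and frame binning.

Spoke angles are measured counterclockwise from the +kx axis, in degrees,
taken mod 360.  Each spoke spans the full diameter ``[-kmax, +kmax]`` in
cycles/FOV with ``kmax = N/2`` for an ``N x N`` grid.  Frame time stamps
follow the centre-of-acquisition-window convention
``t_k = (k*S + S/2) * TR`` for ``S`` spokes per frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0


def tiny_golden_angle(order: int) -> float:
    """Tiny golden angle psi_N = 180 / (phi + N - 1) in degrees.

    ``order=1`` gives the standard small golden angle (~111.246 deg).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    return 180.0 / (GOLDEN_RATIO + order - 1)


@dataclass
class Trajectory:
    """Radial trajectory: coords (frames, spokes, samples, 2) in cycles/FOV."""

    coords: np.ndarray
    angles: np.ndarray  # degrees, shape (frames, spokes)
    kmax: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[-1] != 2:
            raise ValueError("coords must be (frames, spokes, samples, 2)")
        if np.max(np.abs(self.coords)) > self.kmax + 1e-9:
            raise ValueError("coordinates exceed kmax")
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != self.coords.shape[:2]:
            raise ValueError("angle array must match (frames, spokes)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_spokes(self) -> int:
        return self.coords.shape[1]

    @property
    def n_samples(self) -> int:
        return self.coords.shape[2]


@dataclass
class FrameBinning:
    spokes_per_frame: int
    frame_times: np.ndarray = field(default=None)

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")


def radial_trajectory(n_spokes: int, n_samples: int,
                      angle_increment: float, base_angle: float = 0.0,
                      kmax: float = None) -> Trajectory:
    """All spokes in a single frame; bin with :func:`bin_frames` afterwards."""
    if n_spokes < 1 or n_samples < 1:
        raise ValueError("counts must be >= 1")
    if kmax is None:
        raise ValueError("kmax is required")
    angles = (base_angle + angle_increment * np.arange(n_spokes)) % 360.0
    radii = np.linspace(-kmax, kmax, n_samples)
    rad = np.deg2rad(angles)
    direction = np.stack([np.cos(rad), np.sin(rad)], axis=-1)  # (S, 2)
    coords = radii[None, :, None] * direction[:, None, :]  # (S, samples, 2)
    return Trajectory(coords[None], angles[None], kmax)


def multi_echo_trajectory(n_excitations: int, n_echoes: int, n_samples: int,
                          angle_increment: float, kmax: float,
                          angle_mode: str = "per_excitation") -> Trajectory:
    """Multi-echo radial trajectory, echo index as the leading (frame) axis.

    ``per_excitation``: the whole echo train of one excitation shares one
    spoke angle (ME-FLASH).  ``per_echo``: angle advances across both echo
    and excitation index so each echo sees its own golden-angle set (ME-SE).
    """
    exc = np.arange(n_excitations)
    if angle_mode == "per_excitation":
        ang = (angle_increment * exc) % 360.0
        angles = np.tile(ang, (n_echoes, 1))
    elif angle_mode == "per_echo":
        idx = np.arange(n_echoes)[:, None] * n_excitations + exc[None, :]
        angles = (angle_increment * idx) % 360.0
    else:
        raise ValueError(f"unknown angle_mode {angle_mode!r}")
    radii = np.linspace(-kmax, kmax, n_samples)
    rad = np.deg2rad(angles)
    direction = np.stack([np.cos(rad), np.sin(rad)], axis=-1)  # (E, X, 2)
    coords = radii[None, None, :, None] * direction[:, :, None, :]
    return Trajectory(coords, angles, kmax)


def bin_frames(traj: Trajectory, spokes_per_frame: int, TR: float):
    """Reshape a single-frame trajectory into frames of S spokes each.

    Frame k gets the time stamp ``t_k = (k*S + S/2) * TR`` (centre of the
    acquisition window).  Trailing spokes that do not fill a frame are
    dropped with a warning.
    """
    if traj.n_frames != 1:
        raise ValueError("bin_frames expects an unbinned (1-frame) trajectory")
    total = traj.n_spokes
    if spokes_per_frame > total:
        raise ValueError("spokes_per_frame exceeds the number of spokes")
    n_frames = total // spokes_per_frame
    used = n_frames * spokes_per_frame
    if used != total:
        log.warning("dropping %d trailing spokes (%d do not divide %d)",
                    total - used, spokes_per_frame, total)
    coords = traj.coords[0, :used].reshape(
        n_frames, spokes_per_frame, traj.n_samples, 2)
    angles = traj.angles[0, :used].reshape(n_frames, spokes_per_frame)
    S = spokes_per_frame
    times = (np.arange(n_frames) * S + S / 2.0) * TR
    return (Trajectory(coords, angles, traj.kmax),
            FrameBinning(spokes_per_frame=S, frame_times=times))


def per_spoke_times(n_spokes: int, TR: float) -> np.ndarray:
    """Time stamp of every readout (centre convention, single-shot)."""
    return (np.arange(n_spokes) + 0.5) * TR
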