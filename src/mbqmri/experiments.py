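"""Standard simulated acquisition protocols for the builtin phantoms.

These assemble trajectory + phantom + coils + noise into ready-to-use
k-space datasets: single-shot IR radial FLASH for T1, multi-echo spin-echo
radial for T2, multi-echo FLASH for water/fat, and a two-encoding
phase-contrast acquisition for flow.  Sequence timing defaults follow
typical scanner protocols (TR 4.1 ms IR-FLASH; echo spacing 9.9 ms ME-SE;
TE1/dTE 1.37/1.34 ms ME-FLASH).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .data import KSpaceData
from .phantom import (PhantomSpec, builtin_phantoms, circular_coil_model,
                      dc_magnitude, simulate_kspace)
from .signal_models import VelocityEncoding, default_fat_spectrum
from .trajectories import (bin_frames, multi_echo_trajectory, per_spoke_times,
                           radial_trajectory, tiny_golden_angle)


def sim_t1_dataset(grid_size: int = 128, n_spokes: int = 1020,
                   n_samples: int = None, spokes_per_frame: int = 20,
                   tr: float = 4.1e-3, n_coils: int = 8,
                   angle_order: int = 1, noise_rel: float = 0.01,
                   seed: int = 42
                   ) -> Tuple[KSpaceData, np.ndarray, PhantomSpec]:
    """Single-shot IR radial FLASH acquisition of the T1 tube phantom.

    The model signal is evaluated at each spoke's own time stamp, so the
    frame binning used in reconstruction is a genuine approximation.
    Returns (data, coil maps on the grid, phantom spec).
    """
    kmax = grid_size / 2
    n_samples = n_samples or grid_size + 1
    flat = radial_trajectory(n_spokes, n_samples,
                             tiny_golden_angle(angle_order), kmax=kmax)
    traj, binning = bin_frames(flat, spokes_per_frame, tr)
    used = traj.n_frames * spokes_per_frame
    st = per_spoke_times(used, tr).reshape(traj.n_frames, spokes_per_frame)
    spec = builtin_phantoms("t1_tubes")
    coils = circular_coil_model(n_coils)
    sigma = noise_rel * dc_magnitude(spec, coils)
    y = simulate_kspace(spec, coils, traj, binning.frame_times,
                        noise_sigma=sigma, seed=seed, spoke_times=st)
    data = KSpaceData(y, traj, binning.frame_times, "IR_FLASH", sigma, seed,
                      meta={"tr": tr, "n_coils": n_coils},
                      spoke_times=st)
    return data, coils.grid_maps(grid_size), spec


def sim_t2_dataset(grid_size: int = 128, n_excitations: int = 25,
                   n_echoes: int = 16, echo_spacing: float = 9.9e-3,
                   n_samples: int = None, n_coils: int = 8,
                   noise_rel: float = 0.01, seed: int = 42
                   ) -> Tuple[KSpaceData, np.ndarray, PhantomSpec]:
    """Multi-echo spin-echo radial acquisition of the T2 tube phantom."""
    kmax = grid_size / 2
    n_samples = n_samples or grid_size + 1
    traj = multi_echo_trajectory(n_excitations, n_echoes, n_samples,
                                 tiny_golden_angle(1), kmax,
                                 angle_mode="per_echo")
    times = echo_spacing * (1 + np.arange(n_echoes))
    spec = builtin_phantoms("t2_tubes")
    coils = circular_coil_model(n_coils)
    sigma = noise_rel * dc_magnitude(spec, coils)
    y = simulate_kspace(spec, coils, traj, times, noise_sigma=sigma,
                        seed=seed)
    data = KSpaceData(y, traj, times, "SE", sigma, seed,
                      meta={"echo_spacing": echo_spacing,
                            "n_coils": n_coils})
    return data, coils.grid_maps(grid_size), spec


def sim_waterfat_dataset(grid_size: int = 64, n_excitations: int = 33,
                         n_echoes: int = 7, te1: float = 1.37e-3,
                         dte: float = 1.34e-3, n_samples: int = None,
                         n_coils: int = 8, noise_rel: float = 0.0,
                         seed: int = 42, phantom: str = "waterfat_liver_toy"
                         ) -> Tuple[KSpaceData, np.ndarray, PhantomSpec]:
    """Multi-echo radial FLASH acquisition of a water/fat toy phantom.

    One spoke angle per excitation shared across its echo train; 33 spokes
    per echo and 7 echoes by default.
    """
    kmax = grid_size / 2
    n_samples = n_samples or grid_size + 1
    traj = multi_echo_trajectory(n_excitations, n_echoes, n_samples,
                                 tiny_golden_angle(1), kmax,
                                 angle_mode="per_excitation")
    times = te1 + dte * np.arange(n_echoes)
    spec = builtin_phantoms(phantom)
    coils = circular_coil_model(n_coils)
    spectrum = default_fat_spectrum(spec.extras.get("field_strength", 3.0))
    sigma = noise_rel * dc_magnitude(spec, coils)
    y = simulate_kspace(spec, coils, traj, times, noise_sigma=sigma,
                        seed=seed, spectrum=spectrum)
    data = KSpaceData(y, traj, times, "MEGRE", sigma, seed,
                      meta={"field_strength":
                            spec.extras.get("field_strength", 3.0),
                            "n_coils": n_coils})
    return data, coils.grid_maps(grid_size), spec


def sim_fmssfp_dataset(grid_size: int = 64, n_frames: int = 32,
                       n_spokes_per_frame: int = 9, n_samples: int = None,
                       n_coils: int = 4, banding: float = 0.9,
                       noise_rel: float = 0.0, seed: int = 42):
    """Frequency-swept SSFP banding fixture.

    Wedge-like patches carry different off-resonance phases theta, so each
    patch's signal sweeps through the banding profile at a different point
    of the modulation period.  ``times`` is the sweep phase in [0, 1).
    This is a documented approximation: the magnitude profile
    amp/(1 - b cos(2 pi t + theta)) stands in for the full bSSFP response.
    """
    from .phantom import Ellipse, PhantomSpec, simulate_kspace, dc_magnitude
    kmax = grid_size / 2
    n_samples = n_samples or grid_size + 1
    ga = tiny_golden_angle(1)
    radii = np.linspace(-kmax, kmax, n_samples)
    angles = (ga * (np.arange(n_frames * n_spokes_per_frame))) % 360.0
    angles = angles.reshape(n_frames, n_spokes_per_frame)
    rad = np.deg2rad(angles)
    direction = np.stack([np.cos(rad), np.sin(rad)], axis=-1)
    coords = radii[None, None, :, None] * direction[:, :, None, :]
    from .trajectories import Trajectory
    traj = Trajectory(coords, angles, kmax)
    # patches on a ring, each with its own off-resonance phase
    n_patch = 6
    bg = (Ellipse((0.0, 0.0), (0.42, 0.42)),
          {"amp": 0.3, "b": banding, "theta": 0.0})
    regions = []
    for i in range(n_patch):
        ang = 2 * np.pi * i / n_patch
        c = (0.26 * np.cos(ang), 0.26 * np.sin(ang))
        regions.append((Ellipse(c, (0.11, 0.11)),
                        {"amp": 0.3, "b": banding,
                         "theta": 2 * np.pi * i / n_patch}))
    spec = PhantomSpec("SSFP", bg, regions)
    coils = circular_coil_model(n_coils)
    times = np.arange(n_frames) / n_frames  # sweep phase
    sigma = noise_rel * dc_magnitude(spec, coils)
    y = simulate_kspace(spec, coils, traj, times, noise_sigma=sigma,
                        seed=seed)
    data = KSpaceData(y, traj, times, "SSFP", sigma, seed,
                      meta={"banding": banding, "n_coils": n_coils})
    return data, coils.grid_maps(grid_size), spec


def sim_flow_dataset(grid_size: int = 64, n_spokes: int = 99,
                     n_samples: int = None, n_coils: int = 8,
                     noise_rel: float = 0.01, seed: int = 42
                     ) -> Tuple[KSpaceData, np.ndarray, PhantomSpec]:
    """Two-encoding phase-contrast acquisition of the flow toy phantom.

    Encoding 0 is the V=0 reference, encoding 1 the velocity-encoded
    measurement with V1 = pi/VENC; spokes of the two encodings interleave
    in angle.
    """
    kmax = grid_size / 2
    n_samples = n_samples or grid_size + 1
    ga = tiny_golden_angle(1)
    spec = builtin_phantoms("flow_vessel_toy")
    enc = VelocityEncoding(spec.extras["venc"])
    radii = np.linspace(-kmax, kmax, n_samples)
    angles = np.empty((2, n_spokes))
    for k in range(2):
        angles[k] = (ga * (2 * np.arange(n_spokes) + k)) % 360.0
    rad = np.deg2rad(angles)
    direction = np.stack([np.cos(rad), np.sin(rad)], axis=-1)
    coords = radii[None, None, :, None] * direction[:, :, None, :]
    from .trajectories import Trajectory
    traj = Trajectory(coords, angles, kmax)
    times = np.array([0.0, 1.0e-3])  # nominal encoding time stamps
    coils = circular_coil_model(n_coils)
    sigma = noise_rel * dc_magnitude(spec, coils)
    y = simulate_kspace(spec, coils, traj, times, noise_sigma=sigma,
                        seed=seed, enc=enc)
    data = KSpaceData(y, traj, times, "PC", sigma, seed,
                      meta={"venc": spec.extras["venc"],
                            "n_coils": n_coils})
    return data, coils.grid_maps(grid_size), spec
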