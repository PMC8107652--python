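"""Analytical MR signal models with exact partial derivatives.

Each model maps per-voxel physical parameter maps to a complex signal
series over a time grid (inversion times, echo times, or velocity
encodings).  Partial derivatives are analytic and are consumed by the
Gauss-Newton machinery in :mod:`mbqmri.encoding`.

Units: times in seconds, rates in 1/s, off-resonance in Hz, velocities in
cm/s.  Magnetization-type maps (Mss, M0, M0', W, F, rho) are complex;
rates, fields and velocities are real.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

GYROMAGNETIC_MHZ_PER_T = 42.576  # proton gamma/2pi

INVALID = np.nan  # marker for voxels where a derived map is undefined


@dataclass
class TimeGrid:
    """Strictly increasing, non-negative time points in seconds."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValueError("time grid must be non-empty")
        if np.any(self.values < 0):
            raise ValueError("times must be non-negative")
        if self.values.size > 1 and np.any(np.diff(self.values) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self):
        return self.values.size


def _as_maps(*arrays):
    arrs = [np.asarray(a) for a in arrays]
    shape = np.broadcast_shapes(*[a.shape for a in arrs])
    for a in arrs:
        if a.shape not in ((), shape) and a.shape != shape:
            # broadcasting scalars is fine; true mismatches raise here
            np.broadcast_shapes(a.shape, shape)
    return [np.broadcast_to(a, shape) for a in arrs], shape


@dataclass
class IRFlashParams:
    """Inversion-recovery FLASH: steady state, equilibrium, effective rate."""

    Mss: np.ndarray
    M0: np.ndarray
    R1s: np.ndarray

    def __post_init__(self):
        (self.Mss, self.M0, self.R1s), self.shape = _as_maps(
            np.asarray(self.Mss, complex), np.asarray(self.M0, complex),
            np.asarray(self.R1s, float))
        if np.any(self.R1s < 0) or not np.all(np.isfinite(self.R1s)):
            raise ValueError("R1* must be finite and >= 0")


@dataclass
class SpinEchoParams:
    M0p: np.ndarray
    R2: np.ndarray

    def __post_init__(self):
        (self.M0p, self.R2), self.shape = _as_maps(
            np.asarray(self.M0p, complex), np.asarray(self.R2, float))
        if np.any(self.R2 < 0):
            raise ValueError("R2 must be >= 0")


@dataclass
class WaterFatParams:
    W: np.ndarray
    F: np.ndarray
    R2s: np.ndarray
    fB0: np.ndarray

    def __post_init__(self):
        (self.W, self.F, self.R2s, self.fB0), self.shape = _as_maps(
            np.asarray(self.W, complex), np.asarray(self.F, complex),
            np.asarray(self.R2s, float), np.asarray(self.fB0, float))
        if np.any(self.R2s < 0):
            raise ValueError("R2* must be >= 0")


@dataclass
class FatSpectrum:
    """Multi-peak fat spectrum: frequencies in Hz, normalized amplitudes."""

    peak_freqs: np.ndarray
    peak_amps: np.ndarray

    def __post_init__(self):
        self.peak_freqs = np.atleast_1d(np.asarray(self.peak_freqs, float))
        self.peak_amps = np.atleast_1d(np.asarray(self.peak_amps, float))
        if self.peak_freqs.size != self.peak_amps.size:
            raise ValueError("peak frequency/amplitude lengths differ")
        if np.any(self.peak_amps < 0):
            raise ValueError("amplitudes must be >= 0")
        s = self.peak_amps.sum()
        if not np.isclose(s, 1.0, atol=1e-8):
            raise ValueError("amplitudes must sum to 1 (normalize first)")

    def phasor(self, times: np.ndarray) -> np.ndarray:
        """sum_p a_p exp(2i pi f_p t) for each time point."""
        t = np.atleast_1d(np.asarray(times, float))
        return (self.peak_amps[None, :]
                * np.exp(2j * np.pi * np.outer(t, self.peak_freqs))).sum(1)


# 6-peak liver fat spectrum: ppm offsets relative to water and relative
# amplitudes; amplitudes renormalized to sum to 1.
_FAT_PPM = np.array([-3.80, -3.40, -2.60, -1.94, -0.39, 0.60])
_FAT_AMP = np.array([0.087, 0.693, 0.128, 0.004, 0.039, 0.048])


def default_fat_spectrum(field_strength: float = 3.0) -> FatSpectrum:
    """Standard 6-peak fat spectrum at the given field strength (Tesla)."""
    if field_strength <= 0:
        raise ValueError("field strength must be positive")
    freqs = _FAT_PPM * GYROMAGNETIC_MHZ_PER_T * field_strength  # ppm * MHz -> Hz
    return FatSpectrum(freqs, _FAT_AMP / _FAT_AMP.sum())


@dataclass
class FlowParams:
    rho: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        (self.rho, self.v), self.shape = _as_maps(
            np.asarray(self.rho, complex), np.asarray(self.v, float))


@dataclass
class VelocityEncoding:
    """Velocity encodings V_k in rad s/cm; V_0 = 0, V_1 = pi/venc."""

    venc: float
    encodings: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.encodings is None:
            self.encodings = np.array([0.0, np.pi / self.venc])
        self.encodings = np.asarray(self.encodings, float)
        if self.encodings[0] != 0.0:
            raise ValueError("first encoding must be the V_0 = 0 reference")


# ---------------------------------------------------------------------------
# signal evaluations

def ir_flash_signal(params: IRFlashParams, times: TimeGrid,
                    with_jacobian: bool = False):
    """s(t) = Mss - (Mss + M0) exp(-t R1*) per voxel.

    Returns signal of shape ``(T,) + map_shape``; with ``with_jacobian``
    also a dict of partials w.r.t. Mss, M0, R1s of the same shape.
    """
    t = times.values.reshape((-1,) + (1,) * len(params.shape))
    E = np.exp(-t * params.R1s[None])
    s = params.Mss[None] - (params.Mss + params.M0)[None] * E
    if not with_jacobian:
        return s
    jac = {
        "Mss": 1.0 - E + 0j,
        "M0": -E + 0j,
        "R1s": t * (params.Mss + params.M0)[None] * E,
    }
    return s, jac


def se_signal(params: SpinEchoParams, times: TimeGrid,
              with_jacobian: bool = False):
    """s(t) = M0' exp(-t R2) per voxel."""
    t = times.values.reshape((-1,) + (1,) * len(params.shape))
    E = np.exp(-t * params.R2[None])
    s = params.M0p[None] * E
    if not with_jacobian:
        return s
    jac = {"M0p": E + 0j, "R2": -t * s}
    return s, jac


def megre_signal(params: WaterFatParams, echoes: TimeGrid,
                 spectrum: FatSpectrum = None, with_jacobian: bool = False):
    """Multi-echo gradient-echo water/fat signal.

    M_n = (W + F * cs_n) exp(-R2* TE_n) exp(2i pi fB0 TE_n)
    with cs_n the fat-spectrum phasor.  With F identically zero this is the
    single-compartment gradient-echo model.
    """
    if spectrum is None:
        if np.any(params.F != 0):
            raise ValueError("a fat spectrum is required when F != 0")
        cs = np.zeros(len(echoes), dtype=complex)
    else:
        cs = spectrum.phasor(echoes.values)
    t = echoes.values.reshape((-1,) + (1,) * len(params.shape))
    cs = cs.reshape(t.shape)
    decay = np.exp((-params.R2s + 2j * np.pi * params.fB0)[None] * t)
    s = (params.W[None] + params.F[None] * cs) * decay
    if not with_jacobian:
        return s
    jac = {
        "W": decay + 0j,
        "F": cs * decay,
        "R2s": -t * s,
        "fB0": 2j * np.pi * t * s,
    }
    return s, jac


def pc_signal(params: FlowParams, enc: VelocityEncoding,
              with_jacobian: bool = False):
    """Phase-contrast signal M_k = rho exp(i v V_k) per encoding."""
    V = enc.encodings.reshape((-1,) + (1,) * len(params.shape))
    ph = np.exp(1j * params.v[None] * V)
    s = params.rho[None] * ph
    if not with_jacobian:
        return s
    jac = {"rho": ph + 0j, "v": 1j * V * s}
    return s, jac


def t1_from_params(params: IRFlashParams, eps: float = 1e-12) -> np.ndarray:
    """T1 = |M0| / (|Mss| * R1*), invalid voxels marked NaN."""
    mss = np.abs(params.Mss)
    valid = (mss > eps) & (params.R1s > eps)
    out = np.full(params.shape, INVALID, dtype=float)
    out[valid] = np.abs(params.M0)[valid] / (mss[valid] * params.R1s[valid])
    return out


# ---------------------------------------------------------------------------
# model objects used by the encoding operator

class Model:
    """Signal model interface: maps dict-of-maps -> (T, *grid) series."""

    names: Tuple[str, ...]
    is_complex: Dict[str, bool]

    def signal(self, x: Dict[str, np.ndarray]) -> np.ndarray:
        raise NotImplementedError

    def signal_and_jac(self, x):
        raise NotImplementedError

    def jvp(self, x, dx):
        _, jac = self.signal_and_jac(x)
        out = 0.0
        for name in self.names:
            out = out + jac[name] * dx[name][None]
        return out

    def vjp(self, x, ybar):
        _, jac = self.signal_and_jac(x)
        out = {}
        for name in self.names:
            g = (np.conj(jac[name]) * ybar).sum(axis=0)
            out[name] = np.real(g) if not self.is_complex[name] else g
        return out


class IRFlashModel(Model):
    """Recon-path IR-FLASH model; tolerates transiently negative rates.

    With ``window`` set (seconds), the signal is averaged over the
    acquisition window of each frame (midpoint quadrature at ``n_quad``
    points) instead of evaluated at the window centre only.  This removes
    the curvature bias of frame binning for short T1* without changing the
    number of unknowns.
    """

    names = ("Mss", "M0", "R1s")
    is_complex = {"Mss": True, "M0": True, "R1s": False}

    def __init__(self, times: TimeGrid, window: float = None,
                 n_quad: int = 5):
        self.times = times
        self.window = window
        self.n_quad = n_quad

    def _t(self, x):
        shape = np.asarray(x["Mss"]).shape
        t = self.times.values.reshape((-1,) + (1,) * len(shape))
        if not self.window:
            return t[None]  # single quadrature node
        offs = (np.arange(self.n_quad) + 0.5) / self.n_quad - 0.5
        offs = offs.reshape((-1,) + (1,) * (t.ndim))
        return np.maximum(t[None] + self.window * offs, 0.0)

    def signal(self, x):
        t = self._t(x)
        E = np.exp(-t * np.real(x["R1s"])[None, None])
        s = x["Mss"][None, None] - (x["Mss"] + x["M0"])[None, None] * E
        return s.mean(axis=0)

    def signal_and_jac(self, x):
        t = self._t(x)
        E = np.exp(-t * np.real(x["R1s"])[None, None])
        s = x["Mss"][None, None] - (x["Mss"] + x["M0"])[None, None] * E
        jac = {"Mss": (1.0 - E).mean(axis=0) + 0j,
               "M0": (-E).mean(axis=0) + 0j,
               "R1s": (t * (x["Mss"] + x["M0"])[None, None] * E).mean(axis=0)}
        return s.mean(axis=0), jac

    def derived_map(self, x):
        return t1_from_params(
            IRFlashParams(x["Mss"], x["M0"],
                          np.clip(np.real(x["R1s"]), 0.0, None)))


class SpinEchoModel(Model):
    names = ("M0p", "R2")
    is_complex = {"M0p": True, "R2": False}

    def __init__(self, times: TimeGrid):
        self.times = times

    def _t(self, x):
        shape = np.asarray(x["M0p"]).shape
        return self.times.values.reshape((-1,) + (1,) * len(shape))

    def signal(self, x):
        t = self._t(x)
        return x["M0p"][None] * np.exp(-t * np.real(x["R2"])[None])

    def signal_and_jac(self, x):
        t = self._t(x)
        E = np.exp(-t * np.real(x["R2"])[None])
        s = x["M0p"][None] * E
        return s, {"M0p": E + 0j, "R2": -t * s}

    def derived_map(self, x, eps=1e-12):
        R2 = np.real(x["R2"])
        out = np.full(R2.shape, INVALID, dtype=float)
        out[R2 > eps] = 1.0 / R2[R2 > eps]
        return out


class MEGREModel(Model):
    names = ("W", "F", "R2s", "fB0")
    is_complex = {"W": True, "F": True, "R2s": False, "fB0": False}

    def __init__(self, echoes: TimeGrid, spectrum: FatSpectrum):
        self.times = echoes
        self.spectrum = spectrum

    def _parts(self, x):
        shape = np.asarray(x["W"]).shape
        t = self.times.values.reshape((-1,) + (1,) * len(shape))
        cs = self.spectrum.phasor(self.times.values).reshape(t.shape) \
            if self.spectrum is not None else np.zeros_like(t)
        decay = np.exp((-np.real(x["R2s"])
                        + 2j * np.pi * np.real(x["fB0"]))[None] * t)
        return t, cs, decay

    def signal(self, x):
        _, cs, decay = self._parts(x)
        return (x["W"][None] + x["F"][None] * cs) * decay

    def signal_and_jac(self, x):
        t, cs, decay = self._parts(x)
        s = (x["W"][None] + x["F"][None] * cs) * decay
        jac = {"W": decay + 0j, "F": cs * decay,
               "R2s": -t * s, "fB0": 2j * np.pi * t * s}
        return s, jac


class PCDiffModel(Model):
    """Phase-contrast model in (rho, dphi): M_0 = rho, M_1 = rho e^{i dphi}.

    dphi is the phase-difference map regularized directly; the velocity is
    v = dphi * VENC / pi.
    """

    names = ("rho", "dphi")
    is_complex = {"rho": True, "dphi": False}

    def __init__(self, enc: VelocityEncoding):
        self.enc = enc
        if len(enc.encodings) != 2:
            raise ValueError("phase-difference model needs exactly 2 encodings")

    def signal(self, x):
        rho, dphi = x["rho"], np.real(x["dphi"])
        return np.stack([rho + 0j, rho * np.exp(1j * dphi)])

    def signal_and_jac(self, x):
        rho, dphi = x["rho"], np.real(x["dphi"])
        ph = np.exp(1j * dphi)
        s = np.stack([rho + 0j, rho * ph])
        zeros = np.zeros_like(rho)
        jac = {
            "rho": np.stack([np.ones_like(rho), ph]),
            "dphi": np.stack([zeros, 1j * rho * ph]),
        }
        return s, jac

    def velocity(self, x):
        return np.real(x["dphi"]) * self.enc.venc / np.pi
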