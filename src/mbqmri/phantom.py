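"""Inverse-crime-free phantom simulation.

k-space data are synthesized from closed-form Fourier transforms of
ellipses, weighted by analytic coil sensitivities expressed as truncated
plane-wave expansions (so coil weighting stays analytic via the Fourier
shift theorem).  No rasterized image is ever gridded, which keeps the
simulation model distinct from the reconstruction's discretized forward
operator.

Geometry conventions: the FOV is [-0.5, 0.5) in both axes, ellipse centres
and semi-axes are in FOV units, rotations in degrees counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.special import j1

from . import signal_models as sm
from .trajectories import Trajectory


@dataclass
class Ellipse:
    centre: Tuple[float, float]
    semi_axes: Tuple[float, float]
    rotation: float = 0.0
    amplitude: complex = 1.0 + 0j

    def __post_init__(self):
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if max(abs(self.centre[0]), abs(self.centre[1])) > 0.5:
            raise ValueError("centre must lie within the FOV")

    @property
    def area(self) -> float:
        return np.pi * self.semi_axes[0] * self.semi_axes[1]

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        th = np.deg2rad(self.rotation)
        dx, dy = x - self.centre[0], y - self.centre[1]
        u = np.cos(th) * dx + np.sin(th) * dy
        v = -np.sin(th) * dx + np.cos(th) * dy
        return (u / self.semi_axes[0]) ** 2 + (v / self.semi_axes[1]) ** 2 <= 1


def ellipse_kspace(e: Ellipse, kpoints: np.ndarray) -> np.ndarray:
    """Closed-form 2D Fourier transform of the ellipse indicator.

    F(k) = amplitude * pi a b * 2 J1(2 pi r) / (2 pi r) * exp(-2i pi k.c)
    with r the axis-normalized radius of the rotated coordinates; the DC
    value is amplitude times the ellipse area.
    """
    k = np.asarray(kpoints, dtype=float)
    shape = k.shape[:-1]
    kf = k.reshape(-1, 2)
    th = np.deg2rad(e.rotation)
    kx = np.cos(th) * kf[:, 0] + np.sin(th) * kf[:, 1]
    ky = -np.sin(th) * kf[:, 0] + np.cos(th) * kf[:, 1]
    a, b = e.semi_axes
    r = np.sqrt((a * kx) ** 2 + (b * ky) ** 2)
    val = np.full(r.shape, np.pi * a * b)
    nz = r > 1e-12
    z = 2.0 * np.pi * r[nz]
    val[nz] = np.pi * a * b * 2.0 * j1(z) / z
    phase = np.exp(-2j * np.pi * (kf[:, 0] * e.centre[0]
                                  + kf[:, 1] * e.centre[1]))
    return (e.amplitude * val * phase).reshape(shape)


# ---------------------------------------------------------------------------
# coils

@dataclass
class CoilModel:
    """Per-coil truncated plane-wave expansion of a smooth sensitivity.

    c_j(r) = sum_m w_jm exp(2i pi d_jm . r), d in cycles/FOV.
    """

    weights: np.ndarray  # (n_coils, n_terms) complex
    dvecs: np.ndarray    # (n_coils, n_terms, 2) cycles/FOV

    def __post_init__(self):
        self.weights = np.asarray(self.weights, complex)
        self.dvecs = np.asarray(self.dvecs, float)
        if self.weights.ndim != 2 or self.weights.shape[0] < 1:
            raise ValueError("need at least one coil with a non-empty expansion")

    @property
    def n_coils(self) -> int:
        return self.weights.shape[0]

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Sensitivities at positions (x, y); returns (n_coils, *shape)."""
        ph = np.exp(2j * np.pi * (
            self.dvecs[..., 0][..., None] * x.ravel()[None, None, :]
            + self.dvecs[..., 1][..., None] * y.ravel()[None, None, :]))
        out = (self.weights[..., None] * ph).sum(axis=1)
        return out.reshape((self.n_coils,) + x.shape)

    def grid_maps(self, N: int) -> np.ndarray:
        """Sensitivity maps on the N x N pixel grid (coils, N, N)."""
        p = (np.arange(N) - N / 2) / N
        X, Y = np.meshgrid(p, p, indexing="ij")
        return self.evaluate(X, Y)


def circular_coil_model(n_coils: int = 8, order: int = 2,
                        gamma: float = 3.0) -> CoilModel:
    """Ring of circular receive coils with smooth complex sensitivities.

    Coil j looks along the unit vector u_j at angle 2 pi j / n; its profile
    is the (2*order+1)-term Fourier series of exp(gamma * u_j.r) on the FOV,
    which decays away from the coil and is analytic in k-space.  order=0
    returns uniform (identity) coils.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    ms = np.arange(-order, order + 1)
    # Fourier coefficients of exp(gamma s) on s in [-1/2, 1/2)
    w = ((-1.0) ** ms) * 2.0 * np.sinh(gamma / 2.0) / (gamma - 2j * np.pi * ms)
    if order == 0:
        w = np.ones(1, dtype=complex)
    angles = 2.0 * np.pi * np.arange(n_coils) / n_coils
    u = np.stack([np.cos(angles), np.sin(angles)], axis=-1)  # (C, 2)
    dvecs = ms[None, :, None] * u[:, None, :]
    weights = np.tile(w[None, :], (n_coils, 1))
    return CoilModel(weights, dvecs)


# ---------------------------------------------------------------------------
# phantom specs

@dataclass
class PhantomSpec:
    """Ellipse regions with per-model physical parameters.

    ``background`` is drawn first; tube regions punch out the background
    (its amplitude is subtracted under each tube), so every point carries
    exactly one parameter set.
    """

    model_id: str  # IR_FLASH | SE | MEGRE | PC | SSFP
    background: Tuple[Ellipse, Dict[str, complex]]
    regions: List[Tuple[Ellipse, Dict[str, complex]]]
    extras: Dict = field(default_factory=dict)

    def __post_init__(self):
        # approximate disjointness check on bounding circles
        for i, (ei, _) in enumerate(self.regions):
            for ej, _ in self.regions[i + 1:]:
                dist = np.hypot(ei.centre[0] - ej.centre[0],
                                ei.centre[1] - ej.centre[1])
                if dist < max(ei.semi_axes) + max(ej.semi_axes):
                    raise ValueError(
                        "tube regions must be (approximately) disjoint")

    def truth_maps(self, N: int) -> Dict[str, np.ndarray]:
        """Rasterized ground-truth parameter maps on an N x N grid."""
        p = (np.arange(N) - N / 2) / N
        X, Y = np.meshgrid(p, p, indexing="ij")
        names = sorted(self.background[1])
        maps = {n: np.zeros((N, N), dtype=complex) for n in names}
        for ell, pars in [self.background] + list(self.regions):
            mask = ell.contains(X, Y)
            for n in names:
                maps[n][mask] = pars[n] * ell.amplitude if n not in (
                    "R1s", "R2", "R2s", "fB0", "v") else pars[n]
        return maps


_TUBE_RING_RADIUS = 0.30
_TUBE_RADIUS = 0.055
_N_TUBES = 10


def _tube_centres(n: int = _N_TUBES):
    ang = np.deg2rad(90.0 - 360.0 * np.arange(n) / n)
    return np.stack([_TUBE_RING_RADIUS * np.cos(ang),
                     _TUBE_RING_RADIUS * np.sin(ang)], axis=-1)


def builtin_phantoms(name: str) -> PhantomSpec:
    """Documented phantom fixtures.

    ``t1_tubes``: 10 tubes, T1 = 200..2000 ms (step 200) on a ring, in a
    3000 ms background disc.  Simulated as IR-FLASH with M0 = 1,
    Mss = M0/2 and R1* = 2/T1 so that T1 = M0/(Mss R1*) holds exactly.

    ``t2_tubes``: 10 tubes, T2 = 20..200 ms (step 20), background 1000 ms;
    spin-echo model with M0' = 1, R2 = 1/T2.

    ``waterfat_liver_toy``: water background with a fat-dominant and a
    mixed (fat fraction 1/3) tube.  ``flow_vessel_toy``: static background
    with one constant-velocity vessel (VENC in ``extras``).
    """
    centres = _tube_centres()
    if name == "t1_tubes":
        bg_t1 = 3.0
        background = (Ellipse((0.0, 0.0), (0.44, 0.44)),
                      {"Mss": 0.5, "M0": 1.0, "R1s": 2.0 / bg_t1})
        regions = []
        for i in range(_N_TUBES):
            t1 = 0.2 * (i + 1)
            regions.append((Ellipse(tuple(centres[i]),
                                    (_TUBE_RADIUS, _TUBE_RADIUS)),
                            {"Mss": 0.5, "M0": 1.0, "R1s": 2.0 / t1}))
        return PhantomSpec("IR_FLASH", background, regions,
                           extras={"t1_ms": [200.0 * (i + 1)
                                             for i in range(_N_TUBES)],
                                   "background_t1_ms": 3000.0})
    if name == "t2_tubes":
        background = (Ellipse((0.0, 0.0), (0.44, 0.44)),
                      {"M0p": 1.0, "R2": 1.0})
        regions = []
        for i in range(_N_TUBES):
            t2 = 0.02 * (i + 1)
            regions.append((Ellipse(tuple(centres[i]),
                                    (_TUBE_RADIUS, _TUBE_RADIUS)),
                            {"M0p": 1.0, "R2": 1.0 / t2}))
        return PhantomSpec("SE", background, regions,
                           extras={"t2_ms": [20.0 * (i + 1)
                                             for i in range(_N_TUBES)],
                                   "background_t2_ms": 1000.0})
    if name == "waterfat_liver_toy":
        background = (Ellipse((0.0, 0.0), (0.42, 0.38)),
                      {"W": 1.0, "F": 0.0, "R2s": 30.0, "fB0": 0.0})
        regions = [
            (Ellipse((-0.18, 0.02), (0.10, 0.10)),
             {"W": 0.3, "F": 0.7, "R2s": 80.0, "fB0": 20.0}),
            (Ellipse((0.18, -0.02), (0.10, 0.10)),
             {"W": 1.0, "F": 0.5, "R2s": 50.0, "fB0": -30.0}),
        ]
        return PhantomSpec("MEGRE", background, regions,
                           extras={"field_strength": 3.0})
    if name == "flow_vessel_toy":
        venc = 150.0
        background = (Ellipse((0.0, 0.0), (0.42, 0.42)),
                      {"rho": 1.0, "v": 0.0})
        regions = [(Ellipse((0.12, 0.08), (0.08, 0.08)),
                    {"rho": 1.2, "v": 75.0})]
        return PhantomSpec("PC", background, regions,
                           extras={"venc": venc, "vessel_v": 75.0})
    raise ValueError(f"unknown phantom {name!r}")


def builtin_rois(name: str):
    """(label, centre, radius) ROI list matching the builtin fixtures."""
    rois = []
    if name in ("t1_tubes", "t2_tubes"):
        centres = _tube_centres()
        for i in range(_N_TUBES):
            rois.append((f"tube{i + 1}", tuple(centres[i]),
                         0.6 * _TUBE_RADIUS))
        rois.append(("background", (0.0, 0.0), 0.10))
    elif name == "waterfat_liver_toy":
        rois = [("fat_tube", (-0.18, 0.02), 0.06),
                ("mixed_tube", (0.18, -0.02), 0.06),
                ("water_bg", (0.0, -0.25), 0.06)]
    elif name == "flow_vessel_toy":
        rois = [("vessel", (0.12, 0.08), 0.05),
                ("background", (-0.15, -0.12), 0.10)]
    else:
        raise ValueError(f"unknown phantom {name!r}")
    return rois


# ---------------------------------------------------------------------------
# k-space synthesis

def _region_signal(model_id: str, pars: Dict, times: np.ndarray,
                   spectrum: sm.FatSpectrum = None,
                   enc: sm.VelocityEncoding = None) -> np.ndarray:
    """Temporal model signal of a homogeneous region; shape like times."""
    t = np.asarray(times, float)
    if model_id == "IR_FLASH":
        p = sm.IRFlashParams(pars["Mss"], pars["M0"], pars["R1s"])
        s = p.Mss - (p.Mss + p.M0) * np.exp(-t * p.R1s)
        return s
    if model_id == "SE":
        return pars["M0p"] * np.exp(-t * pars["R2"])
    if model_id == "MEGRE":
        cs = spectrum.phasor(t.ravel()).reshape(t.shape) \
            if spectrum is not None else 0.0
        return ((pars["W"] + pars["F"] * cs)
                * np.exp((-pars["R2s"] + 2j * np.pi * pars["fB0"]) * t))
    if model_id == "PC":
        return pars["rho"] * np.exp(1j * pars["v"] * enc.encodings.reshape(t.shape))
    if model_id == "SSFP":
        # frequency-swept balanced-SSFP magnitude profile over one period;
        # t is the sweep phase in [0, 1).  Approximation of the standard
        # off-resonance response: amp / (1 - b cos(2 pi t + theta)).
        return (pars["amp"]
                / (1.0 - pars["b"] * np.cos(2 * np.pi * t + pars["theta"])))
    raise ValueError(f"unknown model {model_id!r}")


def _effective_regions(spec: PhantomSpec):
    """(ellipse, params, subtract_params_or_None): tubes punch out background."""
    bg_ell, bg_pars = spec.background
    out = [(bg_ell, bg_pars, None)]
    for ell, pars in spec.regions:
        out.append((ell, pars, bg_pars))
    return out


def dc_magnitude(spec: PhantomSpec, coils: CoilModel) -> float:
    """Mean over coils of |y(k=0)| for a unit-amplitude static phantom."""
    vals = np.zeros(coils.n_coils, dtype=complex)
    for ell, _, _ in _effective_regions(spec):
        for j in range(coils.n_coils):
            shifted = -coils.dvecs[j]  # k=0 minus d
            vals[j] += (coils.weights[j]
                        * ellipse_kspace(ell, shifted)).sum()
    return float(np.mean(np.abs(vals)))


def simulate_kspace(spec: PhantomSpec, coils: CoilModel, traj: Trajectory,
                    times: np.ndarray, noise_sigma: float = 0.0,
                    seed: int = 42, spoke_times: np.ndarray = None,
                    spectrum: sm.FatSpectrum = None,
                    enc: sm.VelocityEncoding = None) -> np.ndarray:
    """Analytic multi-coil k-space of a phantom; (frames, spokes, samples, coils).

    ``times`` holds one time stamp per frame/echo; for continuously acquired
    sequences ``spoke_times`` (frames, spokes) overrides it so the model
    signal is evaluated per spoke rather than per frame.  Complex white
    Gaussian noise with standard deviation ``noise_sigma`` per complex
    sample (E|n|^2 = sigma^2) is added with the given seed.
    """
    F, S, ns = traj.n_frames, traj.n_spokes, traj.n_samples
    times = np.asarray(times, float)
    if spoke_times is not None:
        spoke_times = np.asarray(spoke_times, float)
        if spoke_times.shape != (F, S):
            raise ValueError("spoke_times must be (frames, spokes)")
        tgrid = spoke_times[:, :, None]  # broadcast over samples
    else:
        if times.shape[0] != F:
            raise ValueError("times length must equal the frame count")
        tgrid = times[:, None, None]
    if spec.model_id == "PC" and enc is None:
        venc = spec.extras.get("venc")
        enc = sm.VelocityEncoding(venc) if venc else None
    if spec.model_id == "MEGRE" and spectrum is None:
        spectrum = sm.default_fat_spectrum(spec.extras.get("field_strength", 3.0))

    kflat = traj.coords.reshape(-1, 2)  # (F*S*ns, 2)
    C = coils.n_coils
    dflat = coils.dvecs.reshape(-1, 2)  # (C*T, 2) shifts
    wflat = coils.weights.reshape(-1)
    y = np.zeros((F * S * ns, C), dtype=complex)
    for ell, pars, sub in _effective_regions(spec):
        sig = _region_signal(spec.model_id, pars, tgrid, spectrum, enc)
        if sub is not None:
            sig = sig - _region_signal(spec.model_id, sub, tgrid,
                                       spectrum, enc)
        sig = np.broadcast_to(sig, (F, S, ns)).reshape(-1)
        # ellipse spectrum at every (sample, coil-term) shifted coordinate
        shifted = kflat[:, None, :] - dflat[None, :, :]
        E = ellipse_kspace(ell, shifted)  # (n, C*T)
        Ew = E.reshape(len(kflat), C, -1) * coils.weights[None, :, :]
        y += sig[:, None] * Ew.sum(axis=2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        y = y + noise_sigma / np.sqrt(2.0) * noise
    return y.reshape(F, S, ns, C)
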