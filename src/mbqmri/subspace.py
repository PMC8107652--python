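"""Linear temporal-subspace reconstruction.

Signal time courses are approximated by a small orthonormal temporal
basis (SVD of a simulated dictionary, or low-order Fourier modes); the
coefficient maps solve a linear inverse problem in coefficient space.
Physical parameters are then obtained by back-projecting to an image
series and fitting the voxel-wise signal model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .data import KSpaceData
from .encoding import gridding_recon
from .nlrecon import RegSpec
from .nufft import Nufft
from .fitting import fit_ir_pixelwise
from .signal_models import TimeGrid
from .wavelets import dwt2, group_soft_threshold, idwt2


@dataclass
class Dictionary:
    """Simulated signal atoms (n_atoms, n_timepoints) with their parameters."""

    atoms: np.ndarray
    params: Dict[str, np.ndarray]
    times: np.ndarray

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms)
        if self.atoms.ndim != 2 or self.atoms.shape[0] < 1:
            raise ValueError("atoms must be a non-empty (n_atoms, T) matrix")
        if not np.all(np.isfinite(self.atoms)):
            raise ValueError("atoms must be finite")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]


@dataclass
class TemporalBasis:
    """Orthonormal temporal basis: columns of ``basis`` (T, n_coeff)."""

    basis: np.ndarray
    singvals: Optional[np.ndarray] = None
    orders: Optional[np.ndarray] = None  # Fourier mode orders, if applicable

    def __post_init__(self):
        self.basis = np.asarray(self.basis, complex)
        if self.basis.ndim != 2 or self.basis.shape[1] > self.basis.shape[0]:
            raise ValueError("basis must be (T, n_coeff) with n_coeff <= T")

    @property
    def n_coeff(self) -> int:
        return self.basis.shape[1]


def gen_ir_dictionary(times: TimeGrid, n_r1: int = 1000,
                      t1s_range=(0.005, 5.0), n_mss: int = 100,
                      mss_range=(0.01, 1.0)) -> Dictionary:
    """Inversion-recovery dictionary with M0 = 1.

    Effective times 1/R1* are linearly spaced over ``t1s_range`` (seconds)
    and Mss over ``mss_range``; defaults give 100 000 atoms.
    """
    if n_r1 < 1 or n_mss < 1:
        raise ValueError("grid sizes must be >= 1")
    t1s = np.linspace(t1s_range[0], t1s_range[1], n_r1)
    mss = np.linspace(mss_range[0], mss_range[1], n_mss)
    t = times.values
    E = np.exp(-t[None, :] / t1s[:, None])  # (n_r1, T)
    # atoms over the (mss, r1s) product grid, complex for uniformity
    atoms = (mss[:, None, None] - (mss[:, None, None] + 1.0) * E[None])
    atoms = atoms.reshape(-1, t.size).astype(complex)
    grid = {"Mss": np.repeat(mss, n_r1), "T1s": np.tile(t1s, n_mss)}
    return Dictionary(atoms, grid, t)


def gen_megre_dictionary(echoes: TimeGrid, n_t2s: int = 256,
                         t2s_range=(0.010, 0.100), n_fb0: int = 256,
                         fb0_range=(-200.0, 200.0)) -> Dictionary:
    """Multi-gradient-echo dictionary exp(-TE/T2*) exp(2i pi fB0 TE)."""
    if n_t2s < 1 or n_fb0 < 1:
        raise ValueError("grid sizes must be >= 1")
    t2s = np.linspace(t2s_range[0], t2s_range[1], n_t2s)
    fb0 = np.linspace(fb0_range[0], fb0_range[1], n_fb0)
    te = echoes.values
    mag = np.exp(-te[None, :] / t2s[:, None])  # (n_t2s, T)
    ph = np.exp(2j * np.pi * fb0[:, None] * te[None, :])  # (n_fb0, T)
    atoms = (mag[:, None, :] * ph[None, :, :]).reshape(-1, te.size)
    grid = {"T2s": np.repeat(t2s, n_fb0), "fB0": np.tile(fb0, n_t2s)}
    return Dictionary(atoms, grid, te)


def svd_basis(dictionary: Dictionary, n_coeff: int) -> TemporalBasis:
    """Top temporal singular vectors of the atom matrix."""
    T = dictionary.atoms.shape[1]
    if n_coeff > T:
        raise ValueError("n_coeff cannot exceed the number of time points")
    _, s, vh = np.linalg.svd(dictionary.atoms, full_matrices=False)
    return TemporalBasis(vh[:n_coeff].conj().T, singvals=s)


def truncation_error(dictionary: Dictionary, basis: TemporalBasis,
                     worst: bool = True) -> float:
    """Relative l2 error of projecting atoms onto the basis span."""
    B = basis.basis
    proj = (dictionary.atoms @ B) @ B.conj().T
    err = np.linalg.norm(dictionary.atoms - proj, axis=1)
    nrm = np.maximum(np.linalg.norm(dictionary.atoms, axis=1), 1e-30)
    rel = err / nrm
    return float(rel.max() if worst else rel.mean())


def fourier_basis(n_timepoints: int, n_modes: int = 4) -> TemporalBasis:
    """Lowest-order DFT modes, ordered 0, +1, -1, +2, -2, ...

    Columns are orthonormal; the mode orders are kept for synthesizing
    images at arbitrary virtual phase offsets.
    """
    if n_modes > n_timepoints:
        raise ValueError("n_modes cannot exceed the number of time points")
    orders = []
    k = 0
    while len(orders) < n_modes:
        if k == 0:
            orders.append(0)
        else:
            orders.append(k)
            if len(orders) < n_modes:
                orders.append(-k)
        k += 1
    orders = np.array(orders[:n_modes])
    t = np.arange(n_timepoints)
    B = np.exp(2j * np.pi * np.outer(t, orders) / n_timepoints)
    B /= np.sqrt(n_timepoints)
    return TemporalBasis(B, orders=orders)


# ---------------------------------------------------------------------------
# coefficient-space solver

@dataclass
class SubspaceConfig:
    solver: str = "CG"  # CG | FISTA
    iters: int = 50
    tol: float = 1e-8
    seed: int = 0
    power_iters: int = 10


class _SubspaceOperator:
    """a (S,N,N) -> samples (F, spokes, ns, C), basis folded per frame."""

    def __init__(self, traj, sens, basis: TemporalBasis, grid_size,
                 nufft_kwargs=None):
        if traj.n_frames != basis.basis.shape[0]:
            raise ValueError("basis rows must match the number of frames")
        self.traj = traj
        self.sens = np.asarray(sens, complex)
        self.B = basis.basis  # (F, S)
        self.N = grid_size
        kw = nufft_kwargs or {}
        self.nuffts = [Nufft((grid_size, grid_size), traj.coords[f], **kw)
                       for f in range(traj.n_frames)]

    def apply(self, a: np.ndarray) -> np.ndarray:
        F, S = self.B.shape
        out = np.empty((F, self.traj.n_spokes, self.traj.n_samples,
                        self.sens.shape[0]), complex)
        for f in range(F):
            img = np.tensordot(self.B[f], a, axes=(0, 0))
            out[f] = np.moveaxis(
                self.nuffts[f].forward(self.sens * img[None]), 0, -1)
        return out

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        F, S = self.B.shape
        a = np.zeros((S, self.N, self.N), complex)
        for f in range(F):
            coil_imgs = self.nuffts[f].adjoint(np.moveaxis(y[f], -1, 0))
            g = (np.conj(self.sens) * coil_imgs).sum(axis=0)
            a += np.conj(self.B[f])[:, None, None] * g[None]
        return a

    def normal(self, a):
        return self.adjoint(self.apply(a))


def _prox_llr(a: np.ndarray, threshold: float, block: int,
              rng: np.random.Generator) -> np.ndarray:
    """Singular-value soft threshold on local spatial blocks (random shift)."""
    S, N, _ = a.shape
    sx, sy = rng.integers(0, block, size=2)
    work = np.roll(a, (sx, sy), axis=(1, 2))
    nb = N // block
    mats = work[:, :nb * block, :nb * block].reshape(
        S, nb, block, nb, block).transpose(1, 3, 0, 2, 4).reshape(
        nb * nb, S, block * block)
    u, s, vh = np.linalg.svd(mats, full_matrices=False)
    s = np.maximum(s - threshold, 0.0)
    mats = u @ (s[..., None] * vh)
    work[:, :nb * block, :nb * block] = mats.reshape(
        nb, nb, S, block, block).transpose(2, 0, 3, 1, 4).reshape(
        S, nb * block, nb * block)
    return np.roll(work, (-sx, -sy), axis=(1, 2))


def subspace_solve(data: KSpaceData, sens: np.ndarray, basis: TemporalBasis,
                   regs: List[RegSpec] = None, cfg: SubspaceConfig = None,
                   nufft_kwargs: dict = None) -> np.ndarray:
    """Solve min_a ||P F C B a - y||^2 + sum_i lambda_i R_i(a).

    The data are normalized to unit image intensity before solving and the
    coefficients scaled back, so regularization strengths are comparable
    across datasets.  Returns coefficient maps (n_coeff, N, N).
    """
    cfg = cfg or SubspaceConfig()
    regs = regs or []
    N = int(2 * data.traj.kmax)
    if nufft_kwargs is None:  # single precision is ample for the solve
        nufft_kwargs = {"oversampling": 1.5, "dtype": np.complex64}
    op = _SubspaceOperator(data.traj, sens, basis, N, nufft_kwargs)
    img0 = gridding_recon(data.y[:1], data.traj, sens, N)[0]
    a_scale = float(np.percentile(np.abs(img0), 99))
    if a_scale <= 0:
        a_scale = 1.0
    y = data.y / a_scale
    aty = op.adjoint(y)

    lam_l2 = sum(r.strength for r in regs if r.type == "L2")
    prox_regs = [r for r in regs
                 if r.type in ("JOINT_L1_WAVELET", "LLR") and r.strength > 0]
    if cfg.solver == "CG" and not prox_regs:
        a = np.zeros_like(aty)
        res = aty - op.normal(a) - lam_l2 * a
        p = res.copy()
        rs = np.vdot(res, res).real
        rs0 = rs
        for _ in range(cfg.iters):
            if rs <= cfg.tol ** 2 * max(rs0, 1e-30):
                break
            Ap = op.normal(p) + lam_l2 * p
            alpha = rs / max(np.vdot(p, Ap).real, 1e-30)
            a = a + alpha * p
            res = res - alpha * Ap
            rs_new = np.vdot(res, res).real
            p = res + (rs_new / max(rs, 1e-30)) * p
            rs = rs_new
        return a * a_scale

    # FISTA with prox terms
    rng = np.random.default_rng(cfg.seed)
    v = rng.standard_normal(aty.shape) + 1j * rng.standard_normal(aty.shape)
    for _ in range(cfg.power_iters):
        w = op.normal(v)
        lam_max = np.vdot(v, w).real / max(np.vdot(v, v).real, 1e-30)
        v = w / max(np.linalg.norm(w), 1e-30)
    L = 2.0 * (lam_max + lam_l2) * 1.05
    tau = 1.0 / L
    a = np.zeros_like(aty)
    z = a.copy()
    t = 1.0
    for _ in range(cfg.iters):
        g = 2.0 * (op.normal(z) - aty + lam_l2 * z)
        step = z - tau * g
        for r in prox_regs:
            if r.type == "JOINT_L1_WAVELET":
                coeffs = dwt2(step, r.wavelet_levels)
                step = idwt2(group_soft_threshold(
                    coeffs, tau * r.strength), r.wavelet_levels)
            else:
                step = _prox_llr(step, tau * r.strength, r.block_size, rng)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = step + (t - 1.0) / t_new * (step - a)
        a, t = step, t_new
    return a * a_scale


# ---------------------------------------------------------------------------
# back-projection and pixel-wise fitting

def backproject(coeffs: np.ndarray, basis: TemporalBasis) -> np.ndarray:
    """Coefficient maps -> image time series (F, N, N)."""
    return np.tensordot(basis.basis, coeffs, axes=(1, 0))


def backproject_and_fit(coeffs: np.ndarray, basis: TemporalBasis,
                        times: TimeGrid, model: str = "IR_FLASH", **fit_kw):
    """Back-project coefficients and fit the voxel-wise IR model."""
    if model != "IR_FLASH":
        raise ValueError("only the IR_FLASH fit is supported")
    series = backproject(coeffs, basis)
    maps, t1 = fit_ir_pixelwise(series, times, **fit_kw)
    # mask values beyond the identifiable range of the acquisition
    cap = min(20.0 * float(times.values[-1]), 10.0)
    with np.errstate(invalid="ignore"):
        t1[(t1 < 1e-3) | (t1 > cap)] = np.nan
    return series, maps, t1


def composite_and_synthesize(coeffs: np.ndarray, basis: TemporalBasis,
                             offsets: Sequence[float] = ()):
    """Root-sum-squares composite and synthesized images at phase offsets.

    The composite sqrt(sum_s |a_s|^2) is invariant to per-voxel phase
    shifts of the modulation; synthesized images evaluate the Fourier-mode
    basis at virtual offsets theta (radians over one modulation period).
    """
    composite = np.sqrt((np.abs(coeffs) ** 2).sum(axis=0))
    synthesized = []
    if len(offsets):
        if basis.orders is None:
            raise ValueError("synthesis at offsets needs a Fourier basis")
        T = basis.basis.shape[0]
        for theta in offsets:
            bs = np.exp(1j * basis.orders * theta) / np.sqrt(T)
            synthesized.append(np.tensordot(bs, coeffs, axes=(0, 0)))
    return composite, np.array(synthesized)
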