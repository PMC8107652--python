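"""Forward operator  F = P o F o C o M  and its Gauss-Newton linearization.

The operator chains the voxel-wise signal model M, multiplication with the
coil sensitivities C, the non-uniform Fourier transform F, and sampling P
(the sampling pattern is baked into the per-frame NUFFT).  Coil maps are
either fixed, or appended to the unknowns as Sobolev-weighted Fourier
coefficients.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import scipy.fft as spfft

from ._dictvec import ddot, drandn_like, dscale
from .nufft import Nufft
from .signal_models import Model
from .trajectories import Trajectory

COIL_KEY = "coils"


def cfft2(x: np.ndarray) -> np.ndarray:
    """Unitary centered 2D FFT over the trailing two axes."""
    return spfft.fftshift(
        spfft.fft2(spfft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def cifft2(x: np.ndarray) -> np.ndarray:
    return spfft.fftshift(
        spfft.ifft2(spfft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def sobolev_weights(N: int, s: float = None, l: float = 16.0) -> np.ndarray:
    """w(k) = (1 + s |k|^2)^(-l) on the centered N x N Fourier grid."""
    if l <= 0:
        raise ValueError("exponent l must be positive")
    if s is None:
        s = 220.0 / N ** 2
    k = np.arange(N) - N / 2
    k2 = k[:, None] ** 2 + k[None, :] ** 2
    return (1.0 + s * k2) ** (-l)


def nufft_forward(image: np.ndarray, traj: Trajectory, frame: int = 0,
                  **kw) -> np.ndarray:
    """One-shot NUFFT of a single frame's samples (convenience wrapper)."""
    return Nufft(image.shape[-2:], traj.coords[frame], **kw).forward(image)


def nufft_adjoint(samples: np.ndarray, traj: Trajectory, grid_size: int,
                  frame: int = 0, **kw) -> np.ndarray:
    return Nufft((grid_size, grid_size), traj.coords[frame], **kw).adjoint(samples)


def apply_coils(image: np.ndarray, sens: np.ndarray) -> np.ndarray:
    """Pointwise coil weighting: (N,N) image -> (C,N,N) coil images."""
    if image.shape != sens.shape[-2:]:
        raise ValueError("image and sensitivity grids differ")
    return sens * image[None]


def combine_coils(coil_images: np.ndarray, sens: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`apply_coils`: conjugate-weighted sum over coils."""
    if coil_images.shape != sens.shape:
        raise ValueError("coil image and sensitivity stacks differ")
    return (np.conj(sens) * coil_images).sum(axis=0)


class LinearizedOperator:
    """DF at a fixed linearization point, with exact adjoint."""

    def __init__(self, op: "ParamOperator", x: Dict[str, np.ndarray]):
        self.op = op
        self.sens = op.current_sens(x)
        self.images, self.jac = op.model.signal_and_jac(x)
        self.estimate_coils = op.estimate_coils and COIL_KEY in x

    def apply(self, dx: Dict[str, np.ndarray]) -> np.ndarray:
        op = self.op
        dmod = 0.0
        for name in op.model.names:
            d = dx[name]
            if not op.model.is_complex[name]:
                d = np.real(d)
            dmod = dmod + self.jac[name] * d[None]
        y = op._encode_frames(dmod, self.sens)
        if self.estimate_coils:
            dsens = op.coil_transform(dx[COIL_KEY])
            y = y + op._encode_frames(self.images, dsens)
        return y

    def adjoint(self, dy: np.ndarray) -> Dict[str, np.ndarray]:
        op = self.op
        grad_img = op._decode_frames(dy, self.sens)  # (T, N, N)
        out = {}
        for name in op.model.names:
            g = (np.conj(self.jac[name]) * grad_img).sum(axis=0)
            out[name] = np.real(g) if not op.model.is_complex[name] else g
        if self.estimate_coils:
            gc = op._decode_frames_percoil(dy, self.images)
            out[COIL_KEY] = op.coil_transform_adjoint(gc)
        return out

    def normal(self, dx):
        return self.adjoint(self.apply(dx))


class ParamOperator:
    """Nonlinear forward model for one signal model on one trajectory.

    Parameters
    ----------
    model : signal model providing signal/jacobian per frame.
    traj : binned trajectory (frames, spokes, samples, 2).
    grid_size : reconstruction matrix size N.
    sens : fixed coil maps (C, N, N); required unless ``estimate_coils``.
    estimate_coils : append coil unknowns, parameterized as Fourier
        coefficients multiplied by Sobolev weights.
    """

    def __init__(self, model: Model, traj: Trajectory, grid_size: int,
                 sens: Optional[np.ndarray] = None,
                 estimate_coils: bool = False, n_coils: int = None,
                 sobolev_s: float = None, sobolev_l: float = 16.0,
                 nufft_kwargs: dict = None):
        self.model = model
        self.traj = traj
        self.N = int(grid_size)
        self.sens = None if sens is None else np.asarray(sens, complex)
        self.estimate_coils = estimate_coils
        if sens is None and not estimate_coils:
            raise ValueError("provide coil maps or enable coil estimation")
        self.n_coils = self.sens.shape[0] if self.sens is not None else n_coils
        self.sobolev = sobolev_weights(self.N, sobolev_s, sobolev_l)
        kw = nufft_kwargs or {}
        self.nuffts = [Nufft((self.N, self.N), traj.coords[f], **kw)
                       for f in range(traj.n_frames)]

    # -- coil parameterization -------------------------------------------
    def coil_transform(self, coeffs: np.ndarray) -> np.ndarray:
        """Weighted Fourier coefficients -> image-space coil maps."""
        return cifft2(self.sobolev[None] * coeffs)

    def coil_transform_adjoint(self, maps: np.ndarray) -> np.ndarray:
        return self.sobolev[None] * cfft2(maps)

    def current_sens(self, x: Dict[str, np.ndarray]) -> np.ndarray:
        if self.estimate_coils and COIL_KEY in x:
            return self.coil_transform(x[COIL_KEY])
        return self.sens

    # -- encode/decode helpers -------------------------------------------
    def _encode_frames(self, images: np.ndarray, sens: np.ndarray):
        """(T,N,N) model images -> (F,S,ns,C) samples."""
        F = self.traj.n_frames
        out = np.empty((F, self.traj.n_spokes, self.traj.n_samples,
                        sens.shape[0]), dtype=complex)
        for f in range(F):
            coil_imgs = sens * images[f][None]
            out[f] = np.moveaxis(self.nuffts[f].forward(coil_imgs), 0, -1)
        return out

    def _decode_frames(self, y: np.ndarray, sens: np.ndarray) -> np.ndarray:
        """Adjoint of `_encode_frames` in the model-image slot."""
        F = self.traj.n_frames
        out = np.empty((F, self.N, self.N), dtype=complex)
        for f in range(F):
            coil_imgs = self.nuffts[f].adjoint(np.moveaxis(y[f], -1, 0))
            out[f] = (np.conj(sens) * coil_imgs).sum(axis=0)
        return out

    def _decode_frames_percoil(self, y: np.ndarray,
                               images: np.ndarray) -> np.ndarray:
        """Adjoint in the coil slot: sum_f conj(M_f) * F_f^H y_f, per coil."""
        out = np.zeros((y.shape[-1], self.N, self.N), dtype=complex)
        for f in range(self.traj.n_frames):
            coil_imgs = self.nuffts[f].adjoint(np.moveaxis(y[f], -1, 0))
            out += np.conj(images[f])[None] * coil_imgs
        return out

    # -- public operator API ---------------------------------------------
    def forward(self, x: Dict[str, np.ndarray]) -> np.ndarray:
        images = self.model.signal(x)
        return self._encode_frames(images, self.current_sens(x))

    def linearize(self, x: Dict[str, np.ndarray]) -> LinearizedOperator:
        return LinearizedOperator(self, x)

    def jacobian_apply(self, x, dx):
        return self.linearize(x).apply(dx)

    def jacobian_adjoint(self, x, dy):
        return self.linearize(x).adjoint(dy)

    def adjoint_images(self, y: np.ndarray,
                       sens: np.ndarray = None) -> np.ndarray:
        """Coil-combined adjoint reconstruction per frame (T, N, N)."""
        return self._decode_frames(y, self.sens if sens is None else sens)


def radial_dcf(traj: Trajectory, frame: int) -> np.ndarray:
    """Ram-Lak style density compensation for one frame's radial samples.

    Each sample is weighted by its k-space area element |r| dr dtheta, so
    the density-compensated adjoint approximates the continuous inverse
    Fourier integral (used only for initialization and the two-step
    baseline, never inside the iterative operator).
    """
    coords = traj.coords[frame]
    r = np.linalg.norm(coords, axis=-1)
    dr = 2.0 * traj.kmax / (traj.n_samples - 1)
    dtheta = np.pi / traj.n_spokes
    w = r * dr * dtheta
    w[w == 0] = np.pi * (dr / 2.0) ** 2 / traj.n_spokes  # centre sample disc
    return w


def gridding_recon(y: np.ndarray, traj: Trajectory, sens: np.ndarray,
                   grid_size: int, nuffts=None) -> np.ndarray:
    """Density-compensated adjoint ('gridding') reconstruction per frame.

    Returns coil-combined images (frames, N, N), normalized by the coil
    sum-of-squares; this is the conventional two-step baseline.
    """
    N = grid_size
    sos = np.maximum((np.abs(sens) ** 2).sum(axis=0), 1e-8)
    n_frames = y.shape[0]  # may be a subset of the trajectory's frames
    out = np.empty((n_frames, N, N), dtype=complex)
    for f in range(n_frames):
        nft = nuffts[f] if nuffts is not None else Nufft((N, N),
                                                         traj.coords[f])
        dcf = radial_dcf(traj, f)
        coil_imgs = nft.adjoint(np.moveaxis(y[f], -1, 0) * dcf[None])
        out[f] = (np.conj(sens) * coil_imgs).sum(axis=0) / sos
    return out


def power_iteration_norm(lin: LinearizedOperator, x_template: Dict,
                         seed: int = 0, iters: int = 10) -> float:
    """Largest eigenvalue of DF^H DF, estimated by power iteration."""
    rng = np.random.default_rng(seed)
    v = drandn_like(x_template, rng)
    lam = 1.0
    for _ in range(iters):
        w = lin.normal(v)
        lam = ddot(v, w) / max(ddot(v, v), 1e-30)
        nrm = np.sqrt(max(ddot(w, w), 1e-30))
        v = dscale(1.0 / nrm, w)
    return float(lam)
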