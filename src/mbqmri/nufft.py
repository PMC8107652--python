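"""Non-uniform FFT on 2D grids via Kaiser-Bessel gridding.

Conventions
-----------
Image pixels ``x[i, j]`` sit at positions ``p_i = (i - N/2) / N`` in FOV
units, i.e. the FOV is ``[-0.5, 0.5)``.  k-space coordinates are given in
cycles/FOV with ``|k| <= N/2``.  The forward (type-2) transform is

    y(k) = (1/N) * sum_{i,j} x[i, j] * exp(-2i pi (kx p_i + ky p_j))

so that the operator has roughly unit norm; the adjoint is the exact
conjugate transpose of the discrete implementation (gridding interpolation
is realized as a precomputed sparse matrix, so forward/adjoint pass a
machine-precision dot test by construction).
"""

from __future__ import annotations

import numpy as np
import scipy.fft as spfft
import scipy.sparse as sp
from numpy.polynomial.legendre import leggauss
from scipy.special import i0


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel, normalized to kb(0)=1."""
    arg = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u, dtype=float)
    inside = arg > 0
    out[inside] = i0(beta * np.sqrt(arg[inside])) / i0(beta)
    return out


def _kb_ft(t: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the kernel at frequencies t (numeric)."""
    # 64-node Gauss-Legendre on [-width/2, width/2]; integrand is smooth.
    nodes, weights = leggauss(64)
    u = 0.5 * width * nodes
    ku = _kb_kernel(u, width, beta)
    t = np.asarray(t, dtype=float)
    phase = np.cos(2.0 * np.pi * np.outer(t, u))
    return 0.5 * width * (phase * (weights * ku)).sum(axis=1)


class Nufft:
    """Type-2/type-1 NUFFT pair for one fixed set of sample coordinates.

    Parameters
    ----------
    grid_shape : (N, N) image grid (square, N even).
    coords : (..., 2) k-space coordinates in cycles/FOV, |k| <= N/2.
    oversampling : grid oversampling factor (default 2).
    width : interpolation kernel width in oversampled grid units (default 8).
    """

    def __init__(self, grid_shape, coords, oversampling: float = 2.0,
                 width: int = 8, dtype=np.complex128):
        N = int(grid_shape[0])
        if grid_shape[0] != grid_shape[1] or N % 2:
            raise ValueError("grid must be square with even side")
        coords = np.asarray(coords, dtype=float)
        if coords.shape[-1] != 2:
            raise ValueError("coords must have a trailing axis of length 2")
        kmax = N / 2
        if np.max(np.abs(coords)) > kmax + 1e-9:
            raise ValueError(
                f"coordinates exceed kmax={kmax} of the {N}x{N} grid")
        self.N = N
        self.sample_shape = coords.shape[:-1]
        self.n_samples = int(np.prod(self.sample_shape)) if coords.ndim > 1 else 1
        M = int(round(oversampling * N))
        M += M % 2
        self.M = M
        self.width = width
        sigma = M / N
        # Beatty et al. choice of the shape parameter.
        self.beta = np.pi * np.sqrt(
            (width / sigma) ** 2 * (sigma - 0.5) ** 2 - 0.8)
        self.dtype = np.dtype(dtype)
        self._rdtype = np.float32 if self.dtype == np.complex64 \
            else np.float64
        self._build_interp(coords.reshape(-1, 2))
        t = (np.arange(N) - N / 2) / M
        apod1d = _kb_ft(t, width, self.beta)
        self.apod = np.outer(apod1d, apod1d).astype(self._rdtype)
        self.scale = 1.0 / N

    def _build_interp(self, kflat: np.ndarray) -> None:
        M, J = self.M, self.width
        kappa = 2.0 * (M / (2 * self.N)) * kflat  # oversampled-grid coords
        # J nearest integer grid points per axis around each coordinate
        base = np.floor(kappa).astype(np.int64) - J // 2 + 1
        offs = np.arange(J)
        mx = base[:, 0:1] + offs  # (n, J)
        my = base[:, 1:2] + offs
        wx = _kb_kernel(kappa[:, 0:1] - mx, J, self.beta)
        wy = _kb_kernel(kappa[:, 1:2] - my, J, self.beta)
        # periodic wrap onto the centered grid layout (index = m + M/2 mod M)
        ix = (mx + M // 2) % M
        iy = (my + M // 2) % M
        n = kflat.shape[0]
        cols = (ix[:, :, None] * M + iy[:, None, :]).reshape(n, -1)
        vals = (wx[:, :, None] * wy[:, None, :]).reshape(n, -1)
        rows = np.repeat(np.arange(n), J * J)
        self._P = sp.csr_matrix(
            (vals.ravel().astype(self.dtype), (rows, cols.ravel())),
            shape=(n, M * M))
        self._PH = self._P.conj().T.tocsr()

    # -- forward / adjoint ------------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        """Apply the NUFFT to one image (N,N) or a batch (..., N, N)."""
        image = np.asarray(image, dtype=self.dtype)
        batch = image.shape[:-2]
        x = image.reshape(-1, self.N, self.N) / self.apod
        M, N = self.M, self.N
        pad = np.zeros((x.shape[0], M, M), dtype=self.dtype)
        lo = (M - N) // 2
        pad[:, lo:lo + N, lo:lo + N] = x
        G = spfft.fftshift(
            spfft.fft2(spfft.ifftshift(pad, axes=(-2, -1))), axes=(-2, -1))
        y = (self._P @ G.reshape(x.shape[0], -1).T).T * self.scale
        return y.reshape(batch + self.sample_shape)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        samples = np.asarray(samples, dtype=self.dtype)
        nb = samples.ndim - len(self.sample_shape)
        batch = samples.shape[:nb]
        y = samples.reshape(np.prod(batch, dtype=int) if batch else 1, -1)
        M, N = self.M, self.N
        g = (self._PH @ y.T).T.reshape(-1, M, M)
        pad = spfft.fftshift(
            spfft.ifft2(spfft.ifftshift(g, axes=(-2, -1))),
            axes=(-2, -1)) * (M * M)
        lo = (M - N) // 2
        x = pad[:, lo:lo + N, lo:lo + N] / self.apod * self.scale
        return x.reshape(batch + (N, N))


def direct_dft(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Brute-force non-uniform DFT (oracle for small grids)."""
    N = image.shape[-1]
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    p = (np.arange(N) - N / 2) / N
    ex = np.exp(-2j * np.pi * np.outer(coords[:, 0], p))  # (n, N)
    ey = np.exp(-2j * np.pi * np.outer(coords[:, 1], p))
    # y_n = sum_ij x_ij ex[n,i] ey[n,j]
    return np.einsum("ij,ni,nj->n", image, ex, ey) / N


def direct_dft_adjoint(samples: np.ndarray, coords: np.ndarray,
                       N: int) -> np.ndarray:
    """Adjoint of :func:`direct_dft`."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    p = (np.arange(N) - N / 2) / N
    ex = np.exp(2j * np.pi * np.outer(coords[:, 0], p))
    ey = np.exp(2j * np.pi * np.outer(coords[:, 1], p))
    return np.einsum("n,ni,nj->ij", samples.reshape(-1), ex, ey) / N
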