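"""Orthonormal Daubechies-4 wavelet transform, periodic boundary.

Implemented as small orthogonal step matrices applied along both axes,
with the usual packed (Mallat) quadrant layout, so multi-map stacks can be
thresholded jointly per coefficient location.  Perfect reconstruction
holds to machine precision because the step matrices are exactly
orthogonal (for even sizes >= 4).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_SQRT3 = np.sqrt(3.0)
# Daubechies-4 (four-tap) analysis lowpass filter
_H = np.array([1.0 + _SQRT3, 3.0 + _SQRT3, 3.0 - _SQRT3, 1.0 - _SQRT3]) \
    / (4.0 * np.sqrt(2.0))
_G = np.array([_H[3], -_H[2], _H[1], -_H[0]])  # highpass


@lru_cache(maxsize=None)
def _step_matrix(n: int) -> np.ndarray:
    if n < 4 or n % 2:
        raise ValueError("transform size must be even and >= 4")
    A = np.zeros((n, n))
    half = n // 2
    for k in range(half):
        for m in range(4):
            A[k, (2 * k + m) % n] += _H[m]
            A[half + k, (2 * k + m) % n] += _G[m]
    return A


def max_levels(n: int) -> int:
    lv = 0
    while n % 2 == 0 and n // 2 >= 4:
        n //= 2
        lv += 1
    return lv


def dwt2(x: np.ndarray, levels: int = 3) -> np.ndarray:
    """2D periodic DWT of (..., N, N); packed quadrant layout, in a copy."""
    N = x.shape[-1]
    if x.shape[-2] != N:
        raise ValueError("trailing axes must be square")
    if levels > max_levels(N):
        raise ValueError(f"{levels} levels impossible for size {N}")
    y = np.array(x, dtype=complex if np.iscomplexobj(x) else float)
    n = N
    for _ in range(levels):
        A = _step_matrix(n)
        sub = np.ascontiguousarray(y[..., :n, :n])
        y[..., :n, :n] = (A @ sub) @ A.T
        n //= 2
    return y


def idwt2(y: np.ndarray, levels: int = 3) -> np.ndarray:
    """Inverse of :func:`dwt2`."""
    N = y.shape[-1]
    x = np.array(y, dtype=complex if np.iscomplexobj(y) else float)
    sizes = [N // 2 ** lv for lv in range(levels)]
    for n in reversed(sizes):
        A = _step_matrix(n)
        sub = np.ascontiguousarray(x[..., :n, :n])
        x[..., :n, :n] = (A.T @ sub) @ A
    return x


def group_soft_threshold(coeffs: np.ndarray, threshold: float) -> np.ndarray:
    """Soft-threshold the l2 norm across the leading (map) axis."""
    norm = np.sqrt((np.abs(coeffs) ** 2).sum(axis=0, keepdims=True))
    factor = np.maximum(1.0 - threshold / np.maximum(norm, 1e-30), 0.0)
    return coeffs * factor


def prox_joint_l1_wavelet(maps: np.ndarray, threshold: float,
                          levels: int = 3) -> np.ndarray:
    """Joint l1-wavelet proximal map on a (n_maps, N, N) stack.

    Each map is transformed, the coefficient vectors across the map axis
    are group-soft-thresholded, and the result is transformed back.
    """
    if threshold == 0:
        return np.array(maps, copy=True)
    coeffs = dwt2(maps, levels)
    return idwt2(group_soft_threshold(coeffs, threshold), levels)
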