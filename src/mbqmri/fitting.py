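"""Voxel-wise nonlinear least-squares fits of signal models.

Used to initialize the Gauss-Newton reconstruction and to map
subspace-reconstructed image series to physical parameters.
"""

from __future__ import annotations

import numpy as np

from .signal_models import IRFlashParams, TimeGrid, t1_from_params


def fit_ir_pixelwise(series: np.ndarray, times: TimeGrid,
                     n_grid: int = 64, r1s_range=(0.2, 50.0),
                     refine_iters: int = 20):
    """Voxel-wise 3-parameter IR fit: Mss, M0 complex, R1* real.

    Coarse R1* grid search with the closed-form linear subproblem for
    (Mss, M0), followed by Gauss-Newton refinement.  Voxels with (near)
    zero signal are marked invalid (NaN in the derived T1).
    """
    t = times.values
    T = t.size
    V = int(np.prod(series.shape[1:]))
    m = series.reshape(T, V)
    power = np.linalg.norm(m, axis=0)
    valid = power > 1e-8 * max(power.max(), 1e-30)

    r1s_grid = np.exp(np.linspace(np.log(r1s_range[0]),
                                  np.log(r1s_range[1]), n_grid))
    best_sse = np.full(V, np.inf)
    best = np.zeros((3, V), complex)  # Mss, M0, R1s
    for r1 in r1s_grid:
        E = np.exp(-t * r1)
        A = np.stack([1.0 - E, -E], axis=1)  # (T, 2) real
        pinv = np.linalg.pinv(A)
        p = pinv @ m  # (2, V)
        sse = np.linalg.norm(A @ p - m, axis=0) ** 2
        upd = sse < best_sse
        best_sse[upd] = sse[upd]
        best[0, upd] = p[0, upd]
        best[1, upd] = p[1, upd]
        best[2, upd] = r1

    mss, m0, r1s = best[0], best[1], np.real(best[2])
    # Gauss-Newton refinement over [Re/Im Mss, Re/Im M0, R1s]
    for _ in range(refine_iters):
        E = np.exp(-np.outer(t, r1s))  # (T, V)
        model = mss[None] - (mss + m0)[None] * E
        r = m - model
        J_mss = 1.0 - E  # d/dMss (complex-linear)
        J_m0 = -E
        J_r1 = np.outer(t, np.ones(V)) * (mss + m0)[None] * E
        # real-valued normal equations (5 unknowns per voxel)
        cols = [J_mss, 1j * J_mss, J_m0, 1j * J_m0, J_r1]
        Jr = np.stack([np.concatenate([c.real, c.imag]) for c in cols])  # (5, 2T, V)
        rr = np.concatenate([r.real, r.imag])  # (2T, V)
        H = np.einsum("itv,jtv->vij", Jr, Jr)
        g = np.einsum("itv,tv->vi", Jr, rr)
        H += 1e-12 * np.eye(5)[None]
        try:
            delta = np.linalg.solve(H, g[..., None])[..., 0]  # (V, 5)
        except np.linalg.LinAlgError:
            delta = np.einsum("vij,vj->vi", np.linalg.pinv(H), g)
        mss = mss + delta[:, 0] + 1j * delta[:, 1]
        m0 = m0 + delta[:, 2] + 1j * delta[:, 3]
        r1s = np.clip(r1s + delta[:, 4], r1s_range[0] / 10, r1s_range[1] * 10)

    shape = series.shape[1:]
    r1s = np.clip(np.real(r1s), r1s_range[0], r1s_range[1])
    mss = np.where(valid, mss, 0).reshape(shape)
    m0 = np.where(valid, m0, 0).reshape(shape)
    r1s = np.where(valid, r1s, 0).reshape(shape)
    maps = {"Mss": mss, "M0": m0, "R1s": np.real(r1s)}
    t1 = t1_from_params(IRFlashParams(mss, m0, np.clip(np.real(r1s), 0, None)))
    return maps, t1


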