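"""Small vector-space helpers for dict-of-arrays unknowns.

The Gauss-Newton unknowns are heterogeneous (complex magnetization maps,
real rate/field maps, optionally coil coefficients), stored as a dict of
ndarrays.  The inner product is the real inner product Re<x, y>, which
makes mixed real/complex adjoints consistent.
"""

from __future__ import annotations

import numpy as np


def ddot(a: dict, b: dict) -> float:
    return float(sum(np.real(np.vdot(a[k], b[k])) for k in a))


def dnorm(a: dict) -> float:
    return np.sqrt(ddot(a, a))


def daxpy(alpha, x: dict, y: dict) -> dict:
    return {k: alpha * x[k] + y[k] for k in x}


def dscale(alpha, x: dict) -> dict:
    return {k: alpha * x[k] for k in x}

def dadd(x: dict, y: dict) -> dict:
    return {k: x[k] + y[k] for k in x}


def dsub(x: dict, y: dict) -> dict:
    return {k: x[k] - y[k] for k in x}


def dcopy(x: dict) -> dict:
    return {k: np.array(v, copy=True) for k, v in x.items()}


def dzeros_like(x: dict) -> dict:
    return {k: np.zeros_like(v) for k, v in x.items()}


def drandn_like(x: dict, rng: np.random.Generator) -> dict:
    out = {}
    for k, v in x.items():
        r = rng.standard_normal(v.shape)
        if np.iscomplexobj(v):
            r = r + 1j * rng.standard_normal(v.shape)
        out[k] = r.astype(v.dtype)
    return out
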