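"""File I/O: HDF5 k-space/map containers, BART cfl/hdr dialect, NIfTI export.

HDF5 k-space container layout:
  datasets  "y"     complex128, (frames, spokes, samples, coils)
            "traj"  float64, (frames, spokes, samples, 2), cycles/FOV
            "times" float64, (frames,)
            "spoke_times" float64, (frames, spokes)  [optional]
            "angles" float64, (frames, spokes)
  attrs     model_id, sigma, seed, kmax, meta (JSON)
"""

from __future__ import annotations

import json
from typing import Dict

import h5py
import nibabel as nib
import numpy as np

from .data import KSpaceData
from .trajectories import Trajectory


def write_kspace(path: str, data: KSpaceData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("y", data=np.asarray(data.y, np.complex128))
        f.create_dataset("traj", data=np.asarray(data.traj.coords, np.float64))
        f.create_dataset("times", data=np.asarray(data.times, np.float64))
        f.create_dataset("angles", data=np.asarray(data.traj.angles,
                                                   np.float64))
        if data.spoke_times is not None:
            f.create_dataset("spoke_times",
                             data=np.asarray(data.spoke_times, np.float64))
        f.attrs["model_id"] = data.model_id
        f.attrs["sigma"] = float(data.sigma)
        f.attrs["seed"] = int(data.seed)
        f.attrs["kmax"] = float(data.traj.kmax)
        f.attrs["meta"] = json.dumps(data.meta)


def read_kspace(path: str) -> KSpaceData:
    with h5py.File(path, "r") as f:
        for name in ("y", "traj", "times", "angles"):
            if name not in f:
                raise KeyError(
                    f"k-space container is missing dataset {name!r}")
        for attr in ("model_id", "kmax"):
            if attr not in f.attrs:
                raise KeyError(
                    f"k-space container is missing attribute {attr!r}")
        traj = Trajectory(f["traj"][()], f["angles"][()],
                          float(f.attrs["kmax"]))
        spoke_times = f["spoke_times"][()] if "spoke_times" in f else None
        return KSpaceData(
            y=f["y"][()], traj=traj, times=f["times"][()],
            model_id=str(f.attrs["model_id"]),
            sigma=float(f.attrs.get("sigma", 0.0)),
            seed=int(f.attrs.get("seed", 0)),
            meta=json.loads(f.attrs.get("meta", "{}")),
            spoke_times=spoke_times)


def write_maps(path: str, maps: Dict[str, np.ndarray],
               attrs: Dict = None) -> None:
    """Full-precision complex map container."""
    with h5py.File(path, "w") as f:
        for k, v in maps.items():
            f.create_dataset(k, data=np.asarray(v, np.complex128))
        for k, v in (attrs or {}).items():
            f.attrs[k] = json.dumps(v) if isinstance(v, (dict, list)) else v


def read_maps(path: str) -> Dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {k: f[k][()] for k in f.keys()}


# ---------------------------------------------------------------------------
# BART cfl/hdr dialect

def write_cfl(basename: str, array: np.ndarray) -> None:
    """BART-compatible pair: <base>.hdr (dims line) + <base>.cfl (cfloat)."""
    arr = np.asarray(array, np.complex64)
    dims = list(arr.shape) + [1] * (16 - arr.ndim)
    with open(basename + ".hdr", "w") as f:
        f.write("# Dimensions\n")
        f.write(" ".join(str(d) for d in dims) + "\n")
    # column-major sample order, little-endian float32 pairs
    with open(basename + ".cfl", "wb") as f:
        arr.T.astype("<c8").tofile(f)


def read_cfl(basename: str) -> np.ndarray:
    with open(basename + ".hdr") as f:
        f.readline()
        dims = [int(d) for d in f.readline().split()]
    n = int(np.prod(dims))
    with open(basename + ".cfl", "rb") as f:
        arr = np.fromfile(f, dtype="<c8", count=n)
    return arr.reshape(dims, order="F").squeeze()


# ---------------------------------------------------------------------------
# NIfTI export

def write_nifti(path: str, map_: np.ndarray, fov: float = 1.0,
                complex_mode: str = "magnitude") -> None:
    """Float32 single-slice volume, FOV-scaled identity affine.

    ``complex_mode``: "magnitude" (default) stores |map|; "magphase"
    stores magnitude and phase as two volumes along the last axis.
    """
    arr = np.asarray(map_)
    if complex_mode == "magphase" and np.iscomplexobj(arr):
        vol = np.stack([np.abs(arr), np.angle(arr)], axis=-1)
    elif complex_mode == "magnitude":
        vol = np.abs(arr)[..., None] if arr.ndim == 2 else np.abs(arr)
    else:
        raise ValueError(f"unknown complex_mode {complex_mode!r}")
    vol = vol.astype(np.float32)
    N = vol.shape[0]
    affine = np.diag([fov / N, fov / N, 1.0, 1.0])
    affine[:2, 3] = -fov / 2
    nib.save(nib.Nifti1Image(vol, affine), path)


def read_nifti(path: str) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj)


def provenance_record(config: Dict, seed: int) -> Dict:
    """Structured provenance: config hash, seed, package versions."""
    import hashlib

    import h5py as _h5
    import numpy as _np
    import scipy as _sp

    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {"mbqmri": __version__, "numpy": _np.__version__,
                     "scipy": _sp.__version__, "h5py": _h5.__version__},
    }
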