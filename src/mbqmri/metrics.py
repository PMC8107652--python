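"""ROI statistics, error metrics and synthetic contrast generation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .signal_models import Model, TimeGrid


@dataclass
class ROI:
    label: str
    centre: Tuple[float, float]  # FOV units
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")

    def mask(self, N: int) -> np.ndarray:
        p = (np.arange(N) - N / 2) / N
        X, Y = np.meshgrid(p, p, indexing="ij")
        return (X - self.centre[0]) ** 2 + (Y - self.centre[1]) ** 2 \
            <= self.radius ** 2


def make_rois(rois: Sequence) -> List[ROI]:
    """Build an ROI set from (label, centre, radius) tuples; labels unique."""
    out = [r if isinstance(r, ROI) else ROI(*r) for r in rois]
    labels = [r.label for r in out]
    if len(set(labels)) != len(labels):
        raise ValueError("ROI labels must be unique")
    return out


def roi_stats(map_: np.ndarray, rois: Sequence) -> Dict[str, Dict]:
    """Per-ROI mean, population SD and voxel count.

    Statistics are taken on the magnitude for complex maps; NaN voxels
    (invalid markers) are ignored.  An ROI without any voxel on the grid
    is reported with count 0.
    """
    N = map_.shape[0]
    vals = np.abs(map_) if np.iscomplexobj(map_) else np.asarray(map_, float)
    out = {}
    for roi in make_rois(rois):
        m = roi.mask(N)
        sel = vals[m]
        sel = sel[np.isfinite(sel)]
        if sel.size == 0:
            out[roi.label] = {"mean": np.nan, "sd": np.nan, "count": 0}
        else:
            out[roi.label] = {"mean": float(sel.mean()),
                              "sd": float(sel.std()),  # population SD
                              "count": int(sel.size)}
    return out


def normalized_error(map_: np.ndarray, reference: np.ndarray,
                     mask: np.ndarray = None) -> float:
    """||map - reference||_2 / ||reference||_2 over an optional mask."""
    a = np.asarray(map_)
    b = np.asarray(reference)
    if mask is not None:
        a, b = a[mask], b[mask]
    denom = np.linalg.norm(b)
    if denom == 0:
        raise ValueError("reference has zero norm")
    return float(np.linalg.norm(a - b) / denom)


def synthesize_contrasts(model: Model, params: Dict[str, np.ndarray],
                         times: TimeGrid) -> np.ndarray:
    """Evaluate the signal model at arbitrary (not only acquired) times."""
    cls = type(model)
    if hasattr(model, "spectrum"):
        new = cls(times, model.spectrum)
    else:
        new = cls(times)
    return new.signal(params)
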