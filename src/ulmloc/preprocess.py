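"""Stack preprocessing: SVD clutter filtering, per-acquisition 0-1
normalization, low-intensity thresholding, and grid upsampling.

The clutter filter removes the lowest-order singular components of the
Casorati (pixels x time) matrix, which capture slowly varying tissue
signal; the moving microbubble signal survives in higher-order
components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .simulator import FrameStack


@dataclass
class PreprocessParams:
    svd_low_cut: int = 1
    svd_high_cut: int | None = None
    threshold: float = 0.15
    upsample_axial: float = 2.5
    upsample_lateral: float = 5.0

    def __post_init__(self):
        if self.svd_low_cut < 0:
            raise ValueError("svd_low_cut must be >= 0")
        if not (0 <= self.threshold <= 1):
            raise ValueError("threshold must be in [0, 1]")


def _as_array(stack) -> np.ndarray:
    return stack.data if isinstance(stack, FrameStack) else np.asarray(stack, dtype=np.float64)


def _rewrap(stack, data: np.ndarray, stage: str | None = None):
    if isinstance(stack, FrameStack):
        return FrameStack(data, stack.grid, stage or stack.stage)
    return data


def svd_filter(stack, low_cut: int, high_cut: int | None = None):
    """Zero singular components [0, low_cut) and [high_cut, end) of the
    Casorati matrix; return the magnitude of the reconstruction."""
    data = _as_array(stack)
    t, h, w = data.shape
    if t < 2:
        raise ValueError("need at least 2 frames")
    casorati = data.reshape(t, h * w).T          # pixels x time
    u, s, vt = np.linalg.svd(casorati, full_matrices=False)
    rank = s.size
    if low_cut >= rank:
        raise ValueError(f"low_cut {low_cut} >= rank {rank}")
    keep = np.ones(rank, dtype=bool)
    keep[:low_cut] = False
    if high_cut is not None:
        keep[high_cut:] = False
    recon = (u[:, keep] * s[keep]) @ vt[keep]
    return _rewrap(stack, np.abs(recon.T.reshape(t, h, w)), "preprocessed")


def normalize_acquisition(stack):
    """Affine map to [0, 1] using the global min/max of the acquisition."""
    data = _as_array(stack)
    lo, hi = data.min(), data.max()
    if hi <= lo:
        raise ValueError("constant stack: degenerate intensity range")
    return _rewrap(stack, (data - lo) / (hi - lo))


def threshold_background(stack, threshold: float = 0.15):
    """Zero out values strictly below ``threshold`` (boundary kept)."""
    data = _as_array(stack)
    return _rewrap(stack, np.where(data < threshold, 0.0, data))


def upsample(stack, ax_factor: float = 2.5, lat_factor: float = 5.0,
             order: int = 3):
    """Per-frame spline interpolation onto a finer grid; grid metadata
    pixel sizes are divided by the factors."""
    if ax_factor < 1 or lat_factor < 1:
        raise ValueError("upsampling factors must be >= 1")
    data = _as_array(stack)
    if ax_factor == 1 and lat_factor == 1:
        out = data.copy()
    else:
        t, h, w = data.shape
        oh, ow = int(round(h * ax_factor)), int(round(w * lat_factor))
        # corner-anchored grid: output (i, j) samples input (i/ax, j/lat),
        # so a feature at (r, c) lands at exactly (r*ax, c*lat)
        rr, cc = np.meshgrid(np.arange(oh) / ax_factor,
                             np.arange(ow) / lat_factor, indexing="ij")
        coords = np.stack([rr, cc])
        out = np.stack([
            np.maximum(ndimage.map_coordinates(frame, coords, order=order,
                                               mode="nearest"), 0.0)
            for frame in data])
    if isinstance(stack, FrameStack):
        grid = replace(stack.grid,
                       fine_pixel_um=stack.grid.fine_pixel_um / float(lat_factor))
        return FrameStack(out, grid, stack.stage)
    return out


def preprocess_stack(stack, params: PreprocessParams):
    """SVD filter -> 0-1 normalization -> background thresholding.

    Upsampling is kept separate because localizers differ in the grid
    they expect.
    """
    out = svd_filter(stack, params.svd_low_cut, params.svd_high_cut) \
        if params.svd_low_cut > 0 or params.svd_high_cut is not None else stack
    out = normalize_acquisition(out)
    return threshold_background(out, params.threshold)
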