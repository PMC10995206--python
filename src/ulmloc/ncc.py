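"""Conventional localization baseline: zero-normalized cross-correlation
against a bivariate-Gaussian point-spread template, regional maximum
search, and sub-pixel refinement of each peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage.feature import match_template

from .decode import Localization
from .templates import MBTemplate, TemplateBank, fit_template_moments, \
    make_gaussian_template


@dataclass
class NccParams:
    template: MBTemplate
    ncc_threshold: float = 0.6
    min_distance: int = 3
    refine: str = "paraboloid"          # or "centroid"

    def __post_init__(self):
        if not (0 < self.ncc_threshold < 1):
            raise ValueError("ncc_threshold must be in (0, 1)")
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")
        if self.refine not in ("paraboloid", "centroid"):
            raise ValueError("refine must be 'paraboloid' or 'centroid'")


def fit_psf_template(bank: TemplateBank, side: int | None = None) -> MBTemplate:
    """Empirical PSF: a bivariate Gaussian least-squares fitted to the
    mean of the bank's templates."""
    mean = np.mean([t.patch for t in bank.templates], axis=0)
    sr0, sc0, _ = fit_template_moments(mean)
    c = mean.shape[0] // 2
    r = np.arange(mean.shape[0], dtype=float) - c
    q = np.arange(mean.shape[1], dtype=float) - c

    def model(p):
        a, sr, sc = p
        return a * np.exp(-0.5 * (r[:, None] / sr) ** 2) * \
            np.exp(-0.5 * (q[None, :] / sc) ** 2)

    res = optimize.least_squares(
        lambda p: (model(p) - mean).ravel(),
        x0=[mean.max(), max(sr0, 0.5), max(sc0, 0.5)],
        bounds=([1e-6, 0.1, 0.1], [np.inf, mean.shape[0], mean.shape[1]]))
    _, sr, sc = res.x
    side = side if side is not None else mean.shape[0]
    if side % 2 == 0:
        side += 1
    side = max(side, int(np.ceil(5 * max(sr, sc))) | 1)
    return make_gaussian_template(sr, sc, side)


def ncc_map(frame: np.ndarray, template: MBTemplate | np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation at every fully valid displacement,
    embedded in a same-size map whose border is filled with -1."""
    patch = template.patch if isinstance(template, MBTemplate) else np.asarray(template)
    frame = np.asarray(frame, dtype=np.float64)
    if patch.shape[0] >= frame.shape[0] or patch.shape[1] >= frame.shape[1]:
        raise ValueError("template must be strictly smaller than the frame")
    valid = match_template(frame, patch.astype(np.float64), pad_input=False)
    out = np.full(frame.shape, -1.0)
    r0, c0 = patch.shape[0] // 2, patch.shape[1] // 2
    out[r0:r0 + valid.shape[0], c0:c0 + valid.shape[1]] = np.clip(valid, -1.0, 1.0)
    return out


def find_peaks(corr: np.ndarray, ncc_threshold: float = 0.6,
               min_distance: int = 3) -> list[tuple[int, int]]:
    """Strict local maxima above threshold, greedily suppressed within
    ``min_distance`` (higher value wins; ties broken row-major)."""
    corr = np.asarray(corr)
    h, w = corr.shape
    padded = np.full((h + 2, w + 2), -np.inf)
    padded[1:-1, 1:-1] = corr
    neigh = np.full(corr.shape, -np.inf)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            np.maximum(neigh, padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w],
                       out=neigh)
    rows, cols = np.nonzero((corr > neigh) & (corr >= ncc_threshold))
    if rows.size == 0:
        return []
    order = np.lexsort((cols, rows, -corr[rows, cols]))
    kept: list[tuple[int, int]] = []
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_distance ** 2
               for kr, kc in kept):
            kept.append((r, c))
    return kept


def _paraboloid_vertex(patch3: np.ndarray) -> tuple[float, float]:
    """Vertex of the least-squares 2D quadratic through a 3x3 neighbourhood,
    clamped to +-0.5 px."""
    y, x = np.mgrid[-1:2, -1:2]
    A = np.stack([np.ones(9), x.ravel(), y.ravel(), x.ravel() ** 2,
                  y.ravel() ** 2, (x * y).ravel()], axis=1)
    coef, *_ = np.linalg.lstsq(A, patch3.ravel(), rcond=None)
    _, b, c, d, e, f = coef
    H = np.array([[2 * d, f], [f, 2 * e]])
    try:
        dx, dy = np.linalg.solve(H, [-b, -c])
    except np.linalg.LinAlgError:
        return (0.0, 0.0)
    return (float(np.clip(dy, -0.5, 0.5)), float(np.clip(dx, -0.5, 0.5)))


def subpixel_refine(surface: np.ndarray, peaks: list[tuple[int, int]],
                    refine: str = "paraboloid", frame: int = 0,
                    intensity: np.ndarray | None = None) -> list[Localization]:
    """Refine integer peaks to continuous coordinates.

    ``paraboloid`` fits a quadratic to the 3x3 correlation neighbourhood;
    ``centroid`` takes the intensity-weighted centroid of the 5x5
    neighbourhood of ``intensity`` (falling back to ``surface``).  Border
    peaks are returned unrefined.
    """
    surface = np.asarray(surface)
    img = surface if intensity is None else np.asarray(intensity)
    h, w = surface.shape
    locs: list[Localization] = []
    for (r, c) in peaks:
        margin = 1 if refine == "paraboloid" else 2
        if r < margin or c < margin or r >= h - margin or c >= w - margin:
            dr = dc = 0.0          # border peak: unrefined
        elif refine == "paraboloid":
            dr, dc = _paraboloid_vertex(surface[r - 1:r + 2, c - 1:c + 2])
        else:
            win = img[r - 2:r + 3, c - 2:c + 3]
            tot = win.sum()
            if tot <= 0:
                dr = dc = 0.0
            else:
                g = np.mgrid[-2:3, -2:3]
                dr = float((win * g[0]).sum() / tot)
                dc = float((win * g[1]).sum() / tot)
        value = float(img[r, c])
        locs.append(Localization(frame=frame, row=r + dr, col=c + dc,
                                 brightness=value,
                                 prob=float(np.clip(surface[r, c], 1e-6, 1.0)),
                                 sigma_row=0.0, sigma_col=0.0, sigma_I=0.0))
    return locs


def ncc_localize(frame_img: np.ndarray, params: NccParams,
                 frame: int = 0) -> list[Localization]:
    """Full conventional pipeline on one frame: correlate, search regional
    maxima, refine sub-pixel."""
    corr = ncc_map(frame_img, params.template)
    peaks = find_peaks(corr, params.ncc_threshold, params.min_distance)
    return subpixel_refine(corr, peaks, refine=params.refine, frame=frame,
                           intensity=np.asarray(frame_img))


def ncc_localize_stack(stack, params: NccParams) -> list[Localization]:
    data = stack.data if hasattr(stack, "data") else np.asarray(stack)
    locs: list[Localization] = []
    for t in range(data.shape[0]):
        locs.extend(ncc_localize(data[t], params, frame=t))
    return locs
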