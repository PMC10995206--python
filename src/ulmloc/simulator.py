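"""Ground-truth microbubble simulator.

Bubbles are seeded uniformly over the field of view at a target areal
concentration (bubbles per squared wavelength), carry a constant speed
drawn from U(5, 25) mm/s, a lifetime of U{1..20} frames, a brightness
drawn from N(mu_Imax, sigma_Imax) truncated at zero, and a direction that
is perturbed by Gaussian noise each frame.  Expired or exited bubbles are
replaced by fresh draws so the expected density is stationary.  Each
bubble keeps one template from the bank for its whole lifetime (temporal
coherence that a context-aware localizer can exploit).

Frames are rendered on the fine grid by bilinearly shifting each bubble's
peak-normalized template to its sub-pixel position, scaling by its
brightness, summing overlaps, then block-averaging down to the network
input grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ImagingConfig, SimulationParams
from .noise import NoiseModel, add_rician_noise
from .templates import MBTemplate, TemplateBank


@dataclass
class MBState:
    """One live bubble on the fine grid."""

    id: int
    pos: np.ndarray            # (row, col), continuous fine px
    dir: np.ndarray            # unit 2-vector
    speed: float               # mm/s
    brightness: float
    birth: int                 # frame index
    lifetime: int              # frames present
    template_idx: int = 0


@dataclass
class GroundTruth:
    """Per-frame list of (id, row_fine, col_fine, brightness) records."""

    frames: list[list[tuple[int, float, float, float]]] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        return np.array([len(f) for f in self.frames])

    def coords(self, t: int) -> np.ndarray:
        """(n, 2) array of fine-grid coordinates at frame ``t``."""
        if not self.frames[t]:
            return np.empty((0, 2))
        return np.array([(r, c) for (_, r, c, _) in self.frames[t]])

    def to_records(self) -> list[tuple[int, int, float, float, float]]:
        return [(t, i, r, c, b)
                for t, frame in enumerate(self.frames)
                for (i, r, c, b) in frame]


@dataclass
class FrameStack:
    """T x H x W non-negative image stack with grid metadata."""

    data: np.ndarray
    grid: ImagingConfig
    stage: str = "input"       # fine | input | preprocessed

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("frame stack must be finite")


# ---------------------------------------------------------------------
# Population dynamics
# ---------------------------------------------------------------------

def _draw_brightness(params: SimulationParams, rng: np.random.Generator) -> float:
    for _ in range(100):
        b = rng.normal(params.mu_imax, params.sigma_imax)
        if b > 0:
            return float(b)
    return float(abs(rng.normal(params.mu_imax, params.sigma_imax))) or params.mu_imax


def _spawn(cfg: ImagingConfig, params: SimulationParams,
           rng: np.random.Generator, mb_id: int, frame: int,
           n_templates: int) -> MBState:
    h, w = cfg.fov_fine
    pos = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
    theta = rng.uniform(0, 2 * np.pi)
    lo, hi = params.lifetime_range_frames
    return MBState(
        id=mb_id,
        pos=pos,
        dir=np.array([math.cos(theta), math.sin(theta)]),
        speed=float(rng.uniform(*params.speed_range_mm_s)),
        brightness=_draw_brightness(params, rng),
        birth=frame,
        lifetime=int(rng.integers(lo, hi + 1)),
        template_idx=int(rng.integers(0, max(n_templates, 1))),
    )


def init_population(cfg: ImagingConfig, params: SimulationParams,
                    rng: np.random.Generator, frame: int = 0,
                    n_templates: int = 1, start_id: int = 0) -> list[MBState]:
    """Poisson-distributed count with mean concentration x FOV area (in
    squared wavelengths); positions uniform over the field of view."""
    if params.concentration_per_lambda2 <= 0:
        raise ValueError("concentration must be positive")
    area = cfg.fov_area_lambda2
    if area < 1.0:
        raise ValueError("FOV smaller than one squared wavelength")
    n = rng.poisson(params.concentration_per_lambda2 * area)
    return [_spawn(cfg, params, rng, start_id + i, frame, n_templates)
            for i in range(n)]


def step_motion(states: list[MBState], cfg: ImagingConfig,
                params: SimulationParams, rng: np.random.Generator,
                next_frame: int, next_id: int,
                n_templates: int = 1) -> tuple[list[MBState], int]:
    """Advance all bubbles one frame; replace expired/exited ones.

    Returns the new state list and the updated id counter.
    """
    h, w = cfg.fov_fine
    out: list[MBState] = []
    for s in states:
        d = s.dir + rng.normal(0.0, params.perturb_sd, size=2)
        norm = np.linalg.norm(d)
        d = s.dir if norm < 1e-12 else d / norm
        step = cfg.fine_px_per_frame(s.speed)
        pos = s.pos + d * step
        expired = (next_frame - s.birth) >= s.lifetime
        exited = not (0 <= pos[0] <= h - 1 and 0 <= pos[1] <= w - 1)
        if expired or exited:
            out.append(_spawn(cfg, params, rng, next_id, next_frame, n_templates))
            next_id += 1
        else:
            out.append(MBState(s.id, pos, d, s.speed, s.brightness,
                               s.birth, s.lifetime, s.template_idx))
    return out, next_id


# ---------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------

_DELTA = MBTemplate(np.ones((1, 1)))


def _stamp(canvas: np.ndarray, patch: np.ndarray, row: float, col: float,
           amp: float) -> None:
    """Add ``amp * patch`` with its center at continuous (row, col), using
    a bilinear split over the four neighbouring integer placements."""
    half = patch.shape[0] // 2
    tr = row - half
    tc = col - half
    r0 = math.floor(tr)
    c0 = math.floor(tc)
    fr = tr - r0
    fc = tc - c0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            wgt = wr * wc
            if wgt == 0:
                continue
            rr = r0 + dr
            cc = c0 + dc
            rlo = max(0, rr)
            clo = max(0, cc)
            rhi = min(canvas.shape[0], rr + patch.shape[0])
            chi = min(canvas.shape[1], cc + patch.shape[1])
            if rlo >= rhi or clo >= chi:
                continue
            canvas[rlo:rhi, clo:chi] += amp * wgt * \
                patch[rlo - rr:rhi - rr, clo - cc:chi - cc]


def block_average(frame: np.ndarray, factor: int) -> np.ndarray:
    h, w = frame.shape
    return frame.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def render_frame(states: list[MBState], bank: TemplateBank | None,
                 cfg: ImagingConfig) -> tuple[np.ndarray, list]:
    """Render one noise-free input-grid frame and its ground-truth entry."""
    h, w = cfg.fov_fine
    if h % cfg.downsample or w % cfg.downsample:
        raise ValueError("fov_fine must be divisible by downsample")
    templates = bank.templates if bank is not None else [_DELTA]
    if templates[0].side > min(h, w):
        raise ValueError("template larger than FOV")
    fine = np.zeros((h, w))
    gt = []
    for s in states:
        tpl = templates[s.template_idx % len(templates)]
        off = tpl.peak_offset
        _stamp(fine, tpl.patch, s.pos[0] - off[0], s.pos[1] - off[1], s.brightness)
        gt.append((s.id, float(s.pos[0]), float(s.pos[1]), float(s.brightness)))
    return block_average(fine, cfg.downsample), gt


def simulate_sequence(cfg: ImagingConfig, params: SimulationParams,
                      bank: TemplateBank | None,
                      noise_model: NoiseModel | None,
                      n_frames: int, seed: int = 0) -> tuple[FrameStack, GroundTruth]:
    """Full simulation chain: seeding, motion, rendering, Rician noise."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    n_templates = len(bank) if bank is not None else 1
    states = init_population(cfg, params, rng, frame=0, n_templates=n_templates)
    next_id = len(states)
    frames = []
    gt = GroundTruth()
    for t in range(n_frames):
        if t > 0:
            states, next_id = step_motion(states, cfg, params, rng, t,
                                          next_id, n_templates)
        frame, entry = render_frame(states, bank, cfg)
        if noise_model is not None:
            frame = add_rician_noise(frame, noise_model, rng)
        frames.append(frame)
        gt.frames.append(entry)
    return FrameStack(np.stack(frames), cfg, stage="input"), gt
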