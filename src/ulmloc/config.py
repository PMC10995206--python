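"""Imaging geometry, run configuration and deterministic seed fan-out.

All stochastic stages draw from generators derived from one master seed
via (seed, stage-name) pairs, so adding or reordering pipeline stages
never perturbs another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import difflib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage."""
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry of a simulated or measured frame stack.

    The fine grid is the simulation / ground-truth grid; the network input
    grid is the fine grid block-averaged by ``downsample``.
    """

    center_frequency_hz: float = 20e6
    frame_rate_hz: float = 1000.0
    sound_speed_m_s: float = 1540.0
    fine_pixel_um: float = 12.3
    downsample: int = 2
    fov_fine: tuple[int, int] = (80, 80)

    def __post_init__(self):
        # coerce YAML-sourced scalars (e.g. "15.625e6" parses as str)
        for name in ("center_frequency_hz", "frame_rate_hz", "sound_speed_m_s",
                     "fine_pixel_um"):
            object.__setattr__(self, name, float(getattr(self, name)))
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "downsample", int(self.downsample))
        object.__setattr__(self, "fov_fine", tuple(int(v) for v in self.fov_fine))
        if self.downsample < 1 or self.fov_fine[0] <= 0 or self.fov_fine[1] <= 0:
            raise ValueError("downsample and fov_fine must be positive")

    @property
    def wavelength_um(self) -> float:
        return self.sound_speed_m_s / self.center_frequency_hz * 1e6

    @property
    def input_pixel_um(self) -> float:
        return self.fine_pixel_um * self.downsample

    @property
    def fov_input(self) -> tuple[int, int]:
        return (self.fov_fine[0] // self.downsample,
                self.fov_fine[1] // self.downsample)

    @property
    def fov_area_lambda2(self) -> float:
        """Field-of-view area in squared wavelengths."""
        h, w = self.fov_fine
        return (h * self.fine_pixel_um / self.wavelength_um) * \
               (w * self.fine_pixel_um / self.wavelength_um)

    def fine_px_per_frame(self, speed_mm_s: float) -> float:
        """Displacement per frame, in fine-grid pixels, at a given speed."""
        return speed_mm_s * 1000.0 / self.frame_rate_hz / self.fine_pixel_um


@dataclass
class SimulationParams:
    """Microbubble population statistics used by the simulator."""

    concentration_per_lambda2: float = 0.05
    speed_range_mm_s: tuple[float, float] = (5.0, 25.0)
    lifetime_range_frames: tuple[int, int] = (1, 20)
    perturb_sd: float = 0.2
    mu_imax: float = 1.0
    sigma_imax: float = 0.2


@dataclass
class RunConfig:
    """Full scenario: geometry, simulation, noise, model and tracking knobs."""

    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    noise_sigma_frac: float = 0.1       # sigma as a fraction of mu_imax when no recording
    svd_low_cut: int = 1
    threshold: float = 0.15
    ncc_threshold: float = 0.6
    p_thresh: float = 0.6
    uncertainty_reject_frac: float = 0.05
    min_persistence: int = 10
    max_gap: int = 2
    max_angle_deg: float = 45.0
    seed: int = 0
    output_dir: str = "."
    log_level: str = "info"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["imaging"]["fov_fine"] = list(self.imaging.fov_fine)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _check_keys(given: dict, allowed: set[str], where: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        msgs = []
        for key in sorted(unknown):
            hint = difflib.get_close_matches(key, allowed, n=1)
            msgs.append(f"'{key}'" + (f" (did you mean '{hint[0]}'?)" if hint else ""))
        raise ValueError(f"unknown {where} keys: " + ", ".join(msgs))


def _tupled(d: dict, key: str, cast=float) -> None:
    if key in d:
        d[key] = tuple(cast(v) for v in d[key])


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML scenario; defaults fill missing fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    top = {f.name for f in dataclasses.fields(RunConfig)}
    _check_keys(raw, top, "config")
    img_raw = raw.pop("imaging", {}) or {}
    _check_keys(img_raw, {f.name for f in dataclasses.fields(ImagingConfig)}, "imaging")
    _tupled(img_raw, "fov_fine", int)
    sim_raw = raw.pop("simulation", {}) or {}
    _check_keys(sim_raw, {f.name for f in dataclasses.fields(SimulationParams)}, "simulation")
    _tupled(sim_raw, "speed_range_mm_s", float)
    _tupled(sim_raw, "lifetime_range_frames", int)
    return RunConfig(imaging=ImagingConfig(**img_raw),
                     simulation=SimulationParams(**sim_raw), **raw)
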