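"""Rician background-noise model for B-mode magnitude images.

Electronic noise enters the in-phase/quadrature (IQ) channels as
independent additive Gaussians of scale sigma, so the recorded magnitude
of a noise-free signal nu follows a Rician distribution (Rayleigh when
nu = 0).  The per-pixel sigma map is estimated from a noise-only
recording: the temporal mean of a Rayleigh field equals sigma*sqrt(pi/2),
so scaling the mean by sqrt(2/pi) recovers sigma without bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import special


@dataclass
class NoiseModel:
    """Per-pixel noise scale (sigma, intensity units) and the number of
    frames it was estimated from."""

    sigma_map: np.ndarray
    n_samples: int = 0

    def __post_init__(self):
        self.sigma_map = np.asarray(self.sigma_map, dtype=np.float64)
        if np.any(self.sigma_map < 0):
            raise ValueError("sigma_map must be non-negative")

    @classmethod
    def constant(cls, sigma: float, shape: tuple[int, int]) -> "NoiseModel":
        """Spatially uniform model (synthetic-data convention)."""
        return cls(np.full(shape, float(sigma)), n_samples=0)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, sigma_map=self.sigma_map, n_samples=self.n_samples)

    @classmethod
    def load(cls, path: str | Path) -> "NoiseModel":
        with np.load(path) as z:
            return cls(z["sigma_map"], int(z["n_samples"]))


def estimate_sigma(noise_stack: np.ndarray) -> NoiseModel:
    """Estimate sigma per pixel from a noise-only magnitude stack:
    sigma = sqrt(2/pi) * temporal mean."""
    stack = np.asarray(noise_stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a T x H x W stack with T >= 2")
    if np.any(stack < 0):
        raise ValueError("noise stack must be non-negative")
    sigma = np.sqrt(2.0 / np.pi) * stack.mean(axis=0)
    return NoiseModel(sigma, n_samples=stack.shape[0])


def add_rician_noise(frame: np.ndarray, model: NoiseModel,
                     rng: np.random.Generator) -> np.ndarray:
    """Corrupt a non-negative frame nu with Rician noise:
    out = |nu + n_r + i*n_i|, n_r, n_i ~ N(0, sigma^2) per pixel."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != model.sigma_map.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs "
                         f"sigma_map {model.sigma_map.shape}")
    n_r = rng.standard_normal(frame.shape) * model.sigma_map
    n_i = rng.standard_normal(frame.shape) * model.sigma_map
    return np.hypot(frame + n_r, n_i)


def rician_pdf(intensity, nu, sigma):
    """Rician density (I/sigma^2) exp(-(I^2+nu^2)/(2 sigma^2)) I0(I nu/sigma^2).

    Evaluated with the exponentially scaled Bessel function so that large
    arguments stay finite: the product collapses to
    (I/sigma^2) exp(-(I-nu)^2 / (2 sigma^2)) i0e(I nu / sigma^2).
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    nu = np.asarray(nu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    s2 = sigma ** 2
    out = (intensity / s2) * np.exp(-(intensity - nu) ** 2 / (2 * s2)) \
        * special.i0e(intensity * nu / s2)
    return np.where(intensity < 0, 0.0, out)
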