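"""Microbubble template banks: parametric Gaussians, patch extraction,
and an adversarially trained (least-squares GAN) template generator.

A template is the image of one isolated microbubble — the system's
point-spread signature on the fine grid — stored peak-normalized so that
brightness can be modelled independently.  The simulator stamps templates
from a bank at sub-pixel ground-truth positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

log = logging.getLogger(__name__)


@dataclass
class MBTemplate:
    """One point-spread patch; ``peak_offset`` is the sub-pixel location of
    the continuous peak relative to the patch center, in fine-grid pixels."""

    patch: np.ndarray
    peak_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.patch = np.asarray(self.patch, dtype=np.float64)
        if self.patch.ndim != 2:
            raise ValueError("patch must be 2D")
        if np.any(self.patch < 0):
            raise ValueError("patch must be non-negative")

    @property
    def side(self) -> int:
        return self.patch.shape[0]


@dataclass
class TemplateBank:
    """Ordered collection of templates plus the pre-normalization peak
    statistics (mu/sigma of patch maxima) used to model brightness."""

    templates: list[MBTemplate]
    mu_imax: float = 1.0
    sigma_imax: float = 0.0
    source: str = "gaussian"

    def __post_init__(self):
        if not self.templates:
            raise ValueError("empty template bank")
        if self.sigma_imax < 0:
            raise ValueError("sigma_imax must be >= 0")
        sides = {t.side for t in self.templates}
        if len(sides) != 1:
            raise ValueError("all templates must share one side length")

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def side(self) -> int:
        return self.templates[0].side

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            patches=np.stack([t.patch for t in self.templates]),
            offsets=np.array([t.peak_offset for t in self.templates]),
            mu_imax=self.mu_imax, sigma_imax=self.sigma_imax,
            source=self.source)

    @classmethod
    def load(cls, path: str | Path) -> "TemplateBank":
        with np.load(path, allow_pickle=False) as z:
            temps = [MBTemplate(p, tuple(o)) for p, o in zip(z["patches"], z["offsets"])]
            return cls(temps, float(z["mu_imax"]), float(z["sigma_imax"]),
                       str(z["source"]))


def make_gaussian_template(sigma_axial: float, sigma_lateral: float,
                           side: int = 65,
                           peak_offset: tuple[float, float] = (0.0, 0.0)) -> MBTemplate:
    """Discretized bivariate Gaussian with continuous peak value 1 at
    patch center + ``peak_offset`` (rows = axial, cols = lateral)."""
    if sigma_axial <= 0 or sigma_lateral <= 0:
        raise ValueError("sigmas must be positive")
    if side % 2 == 0:
        raise ValueError("side must be odd")
    if side < 5 * max(sigma_axial, sigma_lateral):
        raise ValueError("side must be at least 5x the largest sigma")
    c = side // 2
    r = np.arange(side, dtype=np.float64) - (c + peak_offset[0])
    q = np.arange(side, dtype=np.float64) - (c + peak_offset[1])
    patch = np.exp(-0.5 * (r[:, None] / sigma_axial) ** 2) * \
        np.exp(-0.5 * (q[None, :] / sigma_lateral) ** 2)
    return MBTemplate(patch, tuple(peak_offset))


def extract_templates(stack: np.ndarray, peaks: list[list[tuple[int, int]]],
                      side: int = 65) -> TemplateBank:
    """Crop one patch per detected peak; the peak pixel becomes the patch
    center (the detector's peak is taken as the true bubble position, so
    ``peak_offset`` is zero).  Peak statistics are computed before the
    per-patch peak normalization."""
    stack = np.asarray(stack, dtype=np.float64)
    if np.any(stack < 0):
        raise ValueError("stack must be non-negative")
    half = side // 2
    temps, maxima = [], []
    for t, frame_peaks in enumerate(peaks):
        frame = stack[t]
        for (r, c) in frame_peaks:
            r, c = int(round(r)), int(round(c))
            if (r - half < 0 or c - half < 0 or
                    r + half >= frame.shape[0] or c + half >= frame.shape[1]):
                log.warning("peak (%d, %d) in frame %d too close to border; skipped",
                            r, c, t)
                continue
            patch = frame[r - half:r + half + 1, c - half:c + half + 1].copy()
            peak = patch.max()
            if peak <= 0:
                log.warning("zero patch at (%d, %d) in frame %d; skipped", r, c, t)
                continue
            maxima.append(peak)
            temps.append(MBTemplate(patch / peak))
    if not temps:
        raise ValueError("no patches survived extraction (empty bank)")
    maxima = np.asarray(maxima)
    return TemplateBank(temps, mu_imax=float(maxima.mean()),
                        sigma_imax=float(maxima.std()),  # population SD
                        source="extracted")


def fit_template_moments(patch: np.ndarray) -> tuple[float, float, float]:
    """Intensity-weighted (center-of-mass) moments of a patch.

    Returns (sigma_row, sigma_col, eccentricity); for a discretized
    Gaussian the weighted SDs recover its sigmas.
    """
    p = np.asarray(patch, dtype=np.float64)
    tot = p.sum()
    if tot <= 0:
        return (0.0, 0.0, 1.0)
    r = np.arange(p.shape[0])[:, None]
    c = np.arange(p.shape[1])[None, :]
    mr = (p * r).sum() / tot
    mc = (p * c).sum() / tot
    vr = (p * (r - mr) ** 2).sum() / tot
    vc = (p * (c - mc) ** 2).sum() / tot
    sr, sc = np.sqrt(vr), np.sqrt(vc)
    ecc = max(sr, sc) / max(min(sr, sc), 1e-12)
    return (float(sr), float(sc), float(ecc))


# ---------------------------------------------------------------------
# LSGAN
# ---------------------------------------------------------------------

class _Generator:
    """Latent vector -> template patch, via dense projection then two
    upsample+conv stages; sigmoid output keeps patches in [0, 1]."""

    def __init__(self, latent_dim: int, side: int, width: int,
                 rng: np.random.Generator):
        self.latent_dim = latent_dim
        self.side = side
        self.s4 = (side + 3) // 4
        self.width = width
        self.fc = nn.Linear(latent_dim, self.s4 * self.s4 * 4 * width, rng)
        self.c1 = nn.Conv2d(4 * width, 2 * width, 3, rng)
        self.c2 = nn.Conv2d(2 * width, width, 3, rng)
        self.out = nn.Conv2d(width, 1, 3, rng)

    def __call__(self, z: nn.Tensor) -> nn.Tensor:
        n = z.shape[0]
        h = self.fc(z).elu().reshape(n, self.s4, self.s4, 4 * self.width)
        h = self.c1(nn.upsample2(h)).elu()
        h = self.c2(nn.upsample2(h)).elu()
        h = self.out(h).sigmoid()
        return nn.crop2d(h, self.side, self.side)

    @property
    def params(self):
        return nn.collect_params(self.fc, self.c1, self.c2, self.out)


class _Discriminator:
    """Patch -> scalar score (no squashing; least-squares adversarial loss)."""

    def __init__(self, side: int, width: int, rng: np.random.Generator):
        self.side = side
        self.s8 = ((side + 7) // 8)
        self.c1 = nn.Conv2d(1, width, 3, rng)
        self.c2 = nn.Conv2d(width, 2 * width, 3, rng)
        self.c3 = nn.Conv2d(2 * width, 4 * width, 3, rng)
        self.fc = nn.Linear(self.s8 * self.s8 * 4 * width, 1, rng)
        self.fc.w.data[:] = 0.0        # untrained D scores every patch 0

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        x = nn.pad2d_to(x, 8)
        h = nn.avg_pool2(self.c1(x).elu())
        h = nn.avg_pool2(self.c2(h).elu())
        h = nn.avg_pool2(self.c3(h).elu())
        n = h.shape[0]
        return self.fc(h.reshape(n, -1))

    @property
    def params(self):
        return nn.collect_params(self.c1, self.c2, self.c3, self.fc)


@dataclass
class GanModels:
    generator: _Generator
    discriminator: _Discriminator
    latent_dim: int
    training_log: list[tuple[float, float]] = field(default_factory=list)
    mu_imax: float = 1.0
    sigma_imax: float = 0.0

    def save(self, path: str | Path) -> None:
        meta = dict(latent_dim=self.latent_dim, side=self.generator.side,
                    g_width=self.generator.width,
                    d_width=self.discriminator.c1.w.data.shape[3],
                    mu_imax=self.mu_imax, sigma_imax=self.sigma_imax)
        state = {f"g_{k}": v for k, v in nn.state_dict(self.generator.params).items()}
        state.update({f"d_{k}": v for k, v in nn.state_dict(self.discriminator.params).items()})
        np.savez_compressed(path, training_log=np.asarray(self.training_log),
                            **meta, **state)

    @classmethod
    def load(cls, path: str | Path) -> "GanModels":
        with np.load(path, allow_pickle=False) as z:
            rng = np.random.default_rng(0)  # shapes only; weights overwritten
            gen = _Generator(int(z["latent_dim"]), int(z["side"]),
                             int(z["g_width"]), rng)
            disc = _Discriminator(int(z["side"]), int(z["d_width"]), rng)
            nn.load_state(gen.params,
                          {k[2:]: z[k] for k in z.files if k.startswith("g_")})
            nn.load_state(disc.params,
                          {k[2:]: z[k] for k in z.files if k.startswith("d_")})
            return cls(gen, disc, int(z["latent_dim"]),
                       [tuple(row) for row in z["training_log"]],
                       float(z["mu_imax"]), float(z["sigma_imax"]))


def lsgan_d_loss(d_real: nn.Tensor, d_fake: nn.Tensor) -> nn.Tensor:
    """0.5 E[(D(x)-1)^2] + 0.5 E[D(G(z))^2]."""
    return 0.5 * ((d_real - 1.0) ** 2).mean() + 0.5 * (d_fake ** 2).mean()


def lsgan_g_loss(d_fake: nn.Tensor) -> nn.Tensor:
    """0.5 E[(D(G(z))-1)^2]."""
    return 0.5 * ((d_fake - 1.0) ** 2).mean()


def train_lsgan(bank: TemplateBank, epochs: int = 200, batch: int = 32,
                latent_dim: int = 64, seed: int = 0, width: int = 16,
                lr: float = 2e-4) -> GanModels:
    """Adversarial training with least-squares losses, alternating one
    discriminator and one generator step per batch."""
    if len(bank) < batch:
        raise ValueError("bank smaller than one batch")
    rng = np.random.default_rng(seed)
    side = bank.side
    gen = _Generator(latent_dim, side, width, rng)
    disc = _Discriminator(side, width, rng)
    opt_g = nn.Adam(gen.params, lr=lr, beta1=0.5)
    opt_d = nn.Adam(disc.params, lr=lr, beta1=0.5)
    data = np.stack([t.patch for t in bank.templates]).astype(np.float32)[..., None]
    models = GanModels(gen, disc, latent_dim, [],
                       mu_imax=bank.mu_imax, sigma_imax=bank.sigma_imax)
    n_batches = max(1, len(bank) // batch)
    for epoch in range(epochs):
        order = rng.permutation(len(bank))
        ld_sum = lg_sum = 0.0
        for bi in range(n_batches):
            real = data[order[bi * batch:(bi + 1) * batch]]
            z = rng.standard_normal((real.shape[0], latent_dim)).astype(np.float32)
            # discriminator step (generator output treated as constant)
            with nn.no_grad():
                fake = gen(nn.Tensor(z)).data
            d_loss = lsgan_d_loss(disc(nn.Tensor(real)), disc(nn.Tensor(fake)))
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            # generator step
            z = rng.standard_normal((real.shape[0], latent_dim)).astype(np.float32)
            g_loss = lsgan_g_loss(disc(gen(nn.Tensor(z))))
            opt_g.zero_grad()
            g_loss.backward()
            opt_g.step()
            ld = float(d_loss.data)
            lg = float(g_loss.data)
            if not (np.isfinite(ld) and np.isfinite(lg)):
                raise FloatingPointError(
                    f"non-finite LSGAN loss at epoch {epoch} (lr={lr}): "
                    f"L(D)={ld}, L(G)={lg}")
            ld_sum += ld
            lg_sum += lg
        models.training_log.append((ld_sum / n_batches, lg_sum / n_batches))
    return models


def sample_templates(gan: GanModels, n: int, seed: int = 0) -> TemplateBank:
    """Draw ``n`` synthetic templates from a trained generator.

    Patches are clamped to be non-negative and re-normalized to unit peak;
    the brightness statistics are copied from the training bank since
    brightness is modelled separately by the simulator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    temps: list[MBTemplate] = []
    with nn.no_grad():
        while len(temps) < n:
            want = n - len(temps)
            retries = 0
            z = rng.standard_normal((want, gan.latent_dim)).astype(np.float32)
            patches = gan.generator(nn.Tensor(z)).data[..., 0]
            for p in patches:
                p = np.maximum(p.astype(np.float64), 0.0)
                while p.max() <= 1e-9:
                    retries += 1
                    if retries > 10:
                        raise RuntimeError("generator produced only all-zero patches")
                    z1 = rng.standard_normal((1, gan.latent_dim)).astype(np.float32)
                    p = np.maximum(
                        gan.generator(nn.Tensor(z1)).data[0, :, :, 0].astype(np.float64),
                        0.0)
                temps.append(MBTemplate(p / p.max()))
    return TemplateBank(temps[:n], mu_imax=gan.mu_imax,
                        sigma_imax=gan.sigma_imax, source="lsgan")
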