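"""Context-aware probabilistic localization network.

A 2D DECODE-style model: a frame-analysis U-Net extracts features from
each of three consecutive frames, a temporal-context U-Net fuses the
three feature maps, and a convolutional head emits nine per-pixel
channels for the center frame — detection probability p, sub-pixel
offsets (dy, dx), brightness I, uncertainties (sigma_y, sigma_x,
sigma_I), background B and a passive background-scale channel (the
background term of the loss is disabled; background is handled by the
explicit noise model).

Training minimizes a joint objective:

* a count loss — the Gaussian approximation to the Poisson-binomial
  likelihood of the true bubble count E given the per-pixel Bernoulli
  probabilities p_k; and
* a localization loss — the negative log-likelihood of each ground-truth
  (y, x, I) triple under a Gaussian mixture with one diagonal component
  per pixel, weighted by p_k / sum(p).

Training data are simulated on the fly; no frame is ever reused.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .config import ImagingConfig, SimulationParams
from .noise import NoiseModel
from .simulator import FrameStack, GroundTruth, simulate_sequence
from .templates import TemplateBank

log = logging.getLogger(__name__)

SIGMA_FLOOR = 0.01       # px / intensity units; keeps mixture covariances SPD
SIGMA_CAP = 3.0          # upper bound; an unbounded sigma admits a degenerate
                         # optimum where one huge component covers every bubble
COUNT_VAR_FLOOR = 1e-6


@dataclass
class DecodeOutput:
    """Per-pixel channel maps for one frame (output grid = input grid)."""

    p: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    I_hat: np.ndarray
    sigma_x: np.ndarray
    sigma_y: np.ndarray
    sigma_I: np.ndarray
    B: np.ndarray


@dataclass
class GmmTarget:
    """Ground truth for one frame in output-grid coordinates: an (E, 3)
    array of (row, col, brightness)."""

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)

    @property
    def E(self) -> int:
        return self.coords.shape[0]


@dataclass
class Localization:
    frame: int
    row: float
    col: float
    brightness: float
    prob: float
    sigma_row: float
    sigma_col: float
    sigma_I: float


# ---------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------

def _as_tensor(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x))


def count_loss(p, E: int) -> nn.Tensor:
    """Gaussian-approximated Poisson-binomial negative log-likelihood of
    the true count: 0.5 (E - mu)^2 / var + 0.5 log(2 pi var), with
    mu = sum(p), var = sum(p (1 - p)) floored at 1e-6."""
    p = _as_tensor(p)
    flat = p.reshape(-1)
    mu = flat.sum()
    var = (flat * (1.0 - flat)).sum() + COUNT_VAR_FLOOR
    return 0.5 * ((float(E) - mu) ** 2) / var + 0.5 * (2.0 * np.pi * var).log()


def localization_loss(p, dx, dy, I_hat, sigma_x, sigma_y, sigma_I,
                      target: GmmTarget) -> nn.Tensor:
    """Negative mean log-likelihood of ground-truth (row, col, I) triples
    under the probability-weighted Gaussian mixture (log-sum-exp form).

    Channel maps are (H, W); pixel centers sit at integer coordinates.
    """
    if target.E == 0:
        raise ValueError("localization loss undefined for E = 0")
    p = _as_tensor(p)
    dtype = p.data.dtype
    h, w = p.data.shape[-2], p.data.shape[-1]
    rows, cols = np.meshgrid(np.arange(h, dtype=dtype),
                             np.arange(w, dtype=dtype), indexing="ij")
    pk = p.reshape(-1)
    total = pk.sum()
    if float(total.data) <= 0:
        raise ValueError("all detection probabilities are zero (no mixture support)")
    log_w = (pk + 1e-30).log() - (total + 1e-30).log()

    mu_r = (_as_tensor(dy) + nn.Tensor(rows)).reshape(-1)
    mu_c = (_as_tensor(dx) + nn.Tensor(cols)).reshape(-1)
    mu_i = _as_tensor(I_hat).reshape(-1)
    sr = _as_tensor(sigma_y).reshape(-1)
    sc = _as_tensor(sigma_x).reshape(-1)
    si = _as_tensor(sigma_I).reshape(-1)

    gt = target.coords.astype(dtype)                # (E, 3)
    gr = nn.Tensor(gt[:, 0:1])                      # (E, 1) broadcast vs (K,)
    gc = nn.Tensor(gt[:, 1:2])
    gi = nn.Tensor(gt[:, 2:3])
    e = gt.shape[0]

    def norm2(diff, s):
        return (diff / s) ** 2

    quad = norm2(gr - mu_r.reshape(1, -1), sr.reshape(1, -1)) + \
        norm2(gc - mu_c.reshape(1, -1), sc.reshape(1, -1)) + \
        norm2(gi - mu_i.reshape(1, -1), si.reshape(1, -1))
    log_norm = sr.log() + sc.log() + si.log() + 1.5 * np.log(2.0 * np.pi)
    log_pdf = -0.5 * quad - log_norm.reshape(1, -1)
    log_mix = (log_pdf + log_w.reshape(1, -1)).logsumexp(axis=1)   # (E,)
    return -(1.0 / e) * log_mix.sum()


def total_loss(p, dx, dy, I_hat, sigma_x, sigma_y, sigma_I,
               target: GmmTarget) -> nn.Tensor:
    """count + localization; empty frames contribute the count term only
    (the mixture likelihood is undefined at E = 0). Background loss is 0."""
    loss = count_loss(p, target.E)
    if target.E > 0:
        loss = loss + localization_loss(p, dx, dy, I_hat, sigma_x, sigma_y,
                                        sigma_I, target)
    return loss


# ---------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------

class _UNet:
    """Two-level U-Net: filters (f, 2f, 4f), 3x3 convs + ELU, average-pool
    downsampling, nearest-neighbour upsampling with skip concatenation."""

    def __init__(self, c_in: int, f: int, rng: np.random.Generator):
        self.c1a = nn.Conv2d(c_in, f, 3, rng)
        self.c1b = nn.Conv2d(f, f, 3, rng)
        self.c2a = nn.Conv2d(f, 2 * f, 3, rng)
        self.c2b = nn.Conv2d(2 * f, 2 * f, 3, rng)
        self.c3a = nn.Conv2d(2 * f, 4 * f, 3, rng)
        self.c3b = nn.Conv2d(4 * f, 4 * f, 3, rng)
        self.u1a = nn.Conv2d(6 * f, 2 * f, 3, rng)
        self.u1b = nn.Conv2d(2 * f, 2 * f, 3, rng)
        self.u2a = nn.Conv2d(3 * f, f, 3, rng)
        self.u2b = nn.Conv2d(f, f, 3, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        c1 = self.c1b(self.c1a(x).elu()).elu()
        c2 = self.c2b(self.c2a(nn.avg_pool2(c1)).elu()).elu()
        c3 = self.c3b(self.c3a(nn.avg_pool2(c2)).elu()).elu()
        u1 = self.u1b(self.u1a(nn.concat([nn.upsample2(c3), c2], axis=3)).elu()).elu()
        u2 = self.u2b(self.u2a(nn.concat([nn.upsample2(u1), c1], axis=3)).elu()).elu()
        return u2

    @property
    def params(self):
        return nn.collect_params(self.c1a, self.c1b, self.c2a, self.c2b,
                                 self.c3a, self.c3b, self.u1a, self.u1b,
                                 self.u2a, self.u2b)


class DecodeModel:
    """Frame-analysis U-Net(s) + temporal-context U-Net + 9-channel head."""

    def __init__(self, base_filters: int = 48, share_frame_weights: bool = True,
                 seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0DEC0DE]))
        self.base_filters = base_filters
        self.share_frame_weights = share_frame_weights
        f = base_filters
        n_frame_nets = 1 if share_frame_weights else 3
        self.frame_nets = [_UNet(1, f, rng) for _ in range(n_frame_nets)]
        self.context_net = _UNet(3 * f, f, rng)
        self.head = nn.Conv2d(f, 9, 3, rng)
        self.head.b.data[0] = -2.0     # start from a sparse detection prior
        self.train_log: list[float] = []

    @property
    def params(self) -> list[nn.Tensor]:
        out: list[nn.Tensor] = []
        for net in self.frame_nets:
            out.extend(net.params)
        out.extend(self.context_net.params)
        out.extend(self.head.params)
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def forward(self, windows: np.ndarray) -> nn.Tensor:
        """(N, 3, H, W) window batch -> raw (N, H, W, 9) head output."""
        windows = np.asarray(windows, dtype=np.float32)
        if windows.ndim != 4 or windows.shape[1] != 3:
            raise ValueError("expected (N, 3, H, W) three-frame windows")
        n, _, h, w = windows.shape
        if h % 4 or w % 4:
            raise ValueError("frame size must be divisible by 4")
        f = self.base_filters
        if self.share_frame_weights:
            x = nn.Tensor(windows.reshape(n * 3, h, w, 1))
            feat = self.frame_nets[0](x)
            feat = feat.reshape(n, 3, h, w, f).transpose(0, 2, 3, 1, 4) \
                .reshape(n, h, w, 3 * f)
        else:
            feats = [net(nn.Tensor(windows[:, i, :, :, None]))
                     for i, net in enumerate(self.frame_nets)]
            feat = nn.concat(feats, axis=3)
        return self.head(self.context_net(feat))

    @staticmethod
    def split_raw(raw: nn.Tensor) -> dict[str, nn.Tensor]:
        """Map raw head channels to constrained quantities."""
        def sigma(ch):
            return ch.sigmoid() * SIGMA_CAP + SIGMA_FLOOR
        return {
            "p": raw[..., 0].sigmoid(),
            "dy": raw[..., 1].tanh() * 0.5,
            "dx": raw[..., 2].tanh() * 0.5,
            "I_hat": raw[..., 3].softplus(),
            "sigma_y": sigma(raw[..., 4]),
            "sigma_x": sigma(raw[..., 5]),
            "sigma_I": sigma(raw[..., 6]),
            "B": raw[..., 7].softplus(),
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, **nn.state_dict(self.params))
        sidecar = dict(base_filters=self.base_filters,
                       share_frame_weights=self.share_frame_weights,
                       train_log=self.train_log)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DecodeModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(meta["base_filters"], meta["share_frame_weights"])
        with np.load(path) as z:
            nn.load_state(model.params, dict(z))
        model.train_log = list(meta.get("train_log", []))
        return model


def build_network(base_filters: int = 48, share_frame_weights: bool = True,
                  seed: int = 0) -> DecodeModel:
    return DecodeModel(base_filters, share_frame_weights, seed)


# ---------------------------------------------------------------------
# Training on freshly simulated data
# ---------------------------------------------------------------------

def gt_to_target(gt_frame: list, cfg: ImagingConfig,
                 scale: float = 1.0) -> GmmTarget:
    """Map fine-grid ground truth to output-grid coordinates.

    The input (= output) pixel i spans fine pixels [d*i, d*(i+1)), so its
    center sits at fine coordinate d*i + (d-1)/2.
    """
    d = cfg.downsample
    coords = [((r - (d - 1) / 2) / d, (c - (d - 1) / 2) / d, b * scale)
              for (_, r, c, b) in gt_frame]
    return GmmTarget(np.asarray(coords).reshape(-1, 3))


def output_to_fine(row: float, col: float, cfg: ImagingConfig) -> tuple[float, float]:
    d = cfg.downsample
    return (row * d + (d - 1) / 2, col * d + (d - 1) / 2)


def _make_training_windows(cfg, params, bank, noise_model, n_windows,
                           seq_len, rng):
    """Simulate fresh sequences and cut them into normalized 3-frame
    windows with matched output-grid targets."""
    windows, targets = [], []
    while len(windows) < n_windows:
        seed = int(rng.integers(0, 2 ** 31 - 1))
        stack, gt = simulate_sequence(cfg, params, bank, noise_model,
                                      seq_len, seed=seed)
        lo, hi = stack.data.min(), stack.data.max()
        scale = 1.0 / (hi - lo) if hi > lo else 1.0
        data = (stack.data - lo) * scale
        for t in range(1, seq_len - 1):
            windows.append(data[t - 1:t + 2])
            targets.append(gt_to_target(gt.frames[t], cfg, scale))
            if len(windows) >= n_windows:
                break
    return np.asarray(windows, dtype=np.float32), targets


def train_decode(cfg: ImagingConfig, params: SimulationParams,
                 bank: TemplateBank, noise_model: NoiseModel | None,
                 epochs: int = 5, frames_per_epoch: int = 10000,
                 batch: int = 16, base_filters: int = 48,
                 lr: float = 6e-4, seed: int = 0, seq_len: int = 12,
                 share_frame_weights: bool = True,
                 checkpoint: str | Path | None = None,
                 model: DecodeModel | None = None) -> DecodeModel:
    """Train on on-the-fly simulated data (each frame used exactly once).

    The learning rate is halved whenever an epoch fails to improve the
    running mean loss (simple plateau schedule).  Deterministic given
    ``seed`` on fixed hardware.
    """
    if model is None:
        model = build_network(base_filters, share_frame_weights, seed=seed)
    opt = nn.Adam(model.params, lr=lr)
    data_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDA7A]))
    prev_epoch_loss = np.inf
    for epoch in range(epochs):
        windows, targets = _make_training_windows(
            cfg, params, bank, noise_model, frames_per_epoch, seq_len, data_rng)
        order = data_rng.permutation(len(windows))
        epoch_loss = 0.0
        n_batches = 0
        for b0 in range(0, len(order), batch):
            idx = order[b0:b0 + batch]
            raw = model.forward(windows[idx])
            ch = model.split_raw(raw)
            losses = []
            for j, i in enumerate(idx):
                losses.append(total_loss(
                    ch["p"][j], ch["dx"][j], ch["dy"][j], ch["I_hat"][j],
                    ch["sigma_x"][j], ch["sigma_y"][j], ch["sigma_I"][j],
                    targets[i]))
            loss = sum(losses[1:], losses[0]) * (1.0 / len(losses))
            lval = float(loss.data)
            if not np.isfinite(lval):
                if checkpoint is not None:
                    model.save(checkpoint)
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={lval})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += lval
            n_batches += 1
        epoch_loss /= max(n_batches, 1)
        model.train_log.append(epoch_loss)
        log.info("epoch %d/%d: mean loss %.4f (lr %.2e)",
                 epoch + 1, epochs, epoch_loss, opt.lr)
        if epoch_loss >= prev_epoch_loss:
            opt.lr = max(opt.lr * 0.5, 1e-5)
        prev_epoch_loss = epoch_loss
        if checkpoint is not None:
            model.save(checkpoint)
    return model


# ---------------------------------------------------------------------
# Inference and post-processing
# ---------------------------------------------------------------------

def infer(model: DecodeModel, stack: FrameStack | np.ndarray,
          chunk: int = 32) -> list[DecodeOutput]:
    """One DecodeOutput per interior frame t = 1 .. T-2 (sliding window of
    three consecutive frames)."""
    data = stack.data if isinstance(stack, FrameStack) else np.asarray(stack)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 frames for temporal context")
    t_out = data.shape[0] - 2
    outputs: list[DecodeOutput] = []
    with nn.no_grad():
        for c0 in range(0, t_out, chunk):
            c1 = min(c0 + chunk, t_out)
            windows = np.stack([data[t:t + 3] for t in range(c0, c1)])
            ch = DecodeModel.split_raw(model.forward(windows))
            arr = {k: v.data for k, v in ch.items()}
            for j in range(c1 - c0):
                outputs.append(DecodeOutput(
                    p=arr["p"][j], dx=arr["dx"][j], dy=arr["dy"][j],
                    I_hat=arr["I_hat"][j], sigma_x=arr["sigma_x"][j],
                    sigma_y=arr["sigma_y"][j], sigma_I=arr["sigma_I"][j],
                    B=arr["B"][j]))
    return outputs


def decode_detections(out: DecodeOutput, frame: int = 0, p_thresh: float = 0.6,
                      agg_radius: int = 1,
                      uncertainty_reject_frac: float = 0.05) -> list[Localization]:
    """Discretize the probability field into localizations.

    Candidate pixels are local maxima of p whose probability mass summed
    over the (2r+1)^2 neighbourhood reaches ``p_thresh`` (summing
    neighbourhoods approximates per-bubble probability mass).  After
    collection the highest-positional-uncertainty fraction is discarded.
    """
    p = out.p
    size = 2 * agg_radius + 1
    neigh = ndimage.uniform_filter(p, size=size, mode="constant") * size ** 2
    maxf = ndimage.maximum_filter(p, size=size, mode="constant")
    cand = (p >= maxf) & (neigh >= p_thresh)
    # break plateau ties: keep the first pixel in row-major order
    rows, cols = np.nonzero(cand)
    taken = np.zeros_like(cand)
    locs: list[Localization] = []
    for r, c in zip(rows, cols):
        if taken[max(0, r - agg_radius):r + agg_radius + 1,
                 max(0, c - agg_radius):c + agg_radius + 1].any():
            continue
        taken[r, c] = True
        locs.append(Localization(
            frame=frame,
            row=float(r + out.dy[r, c]),
            col=float(c + out.dx[r, c]),
            brightness=float(out.I_hat[r, c]),
            prob=float(min(1.0, neigh[r, c])),
            sigma_row=float(out.sigma_y[r, c]),
            sigma_col=float(out.sigma_x[r, c]),
            sigma_I=float(out.sigma_I[r, c])))
    if uncertainty_reject_frac > 0 and locs:
        n_drop = int(np.floor(uncertainty_reject_frac * len(locs)))
        if n_drop > 0:
            locs.sort(key=lambda l: np.hypot(l.sigma_row, l.sigma_col))
            locs = locs[:len(locs) - n_drop]
    return locs


def localize_stack(model: DecodeModel, stack: FrameStack,
                   p_thresh: float = 0.6, agg_radius: int = 1,
                   uncertainty_reject_frac: float = 0.05) -> list[Localization]:
    """Run inference over a stack and collect localizations for interior
    frames (frame indices refer to the original stack)."""
    outs = infer(model, stack)
    locs: list[Localization] = []
    for t, out in enumerate(outs, start=1):
        locs.extend(decode_detections(out, frame=t, p_thresh=p_thresh,
                                      agg_radius=agg_radius,
                                      uncertainty_reject_frac=uncertainty_reject_frac))
    return locs
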