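# ulmloc

Simulation-trained probabilistic microbubble localization for
super-resolution **ultrasound localization microscopy (ULM)**.

ULM reconstructs microvascular maps an order of magnitude below the
acoustic diffraction limit by localizing and tracking intravenously
injected microbubbles across thousands of contrast-enhanced ultrasound
frames. Its central trade-off is bubble concentration: sparse bubbles
localize precisely but fill vessels slowly; dense bubbles overlap and
defeat conventional template-matching localization. `ulmloc` addresses
the dense regime with a context-aware probabilistic localization
network trained purely on simulated data with known ground truth, and
ships every stage needed to study it at desk scale on one CPU:

* **simulator** — stochastic bubble flow (Poisson seeding at a target
  density in bubbles/λ², speeds 5–25 mm/s, lifetimes 1–20 frames,
  brightness ~ N(µ, σ), per-frame direction perturbation), sub-pixel
  template rendering, Rician background noise;
* **templates** — parametric bivariate-Gaussian banks, patch extraction
  around detected peaks, and a least-squares GAN that learns and samples
  realistic bubble signatures;
* **decode-style localizer** — two cascaded U-Nets over three-frame
  temporal windows emitting per-pixel detection probability, sub-pixel
  offsets, brightness and uncertainties, trained with a joint
  count + Gaussian-mixture localization loss (on a compact numpy
  autodiff engine included in the package);
* **ncc baseline** — zero-normalized cross-correlation against a fitted
  Gaussian PSF with regional-maximum search and paraboloid refinement;
* **preprocess / tracking / reconstruct** — SVD clutter filtering,
  per-acquisition normalization, linear-assignment tracking with a 45°
  linking-angle gate and 10-frame persistence, λ/5 density and
  directional maps, and functional ULM activation maps (Pearson r of
  per-pixel bubble-count series against a stimulation pattern, r > 0.2);
* **metrics** — optimal-assignment matching, detection accuracy
  TP/(TP+FP), miss rate FN/(TP+FN), the averaged RMS localization error
  √(Σ((Δx²+Δy²)/2)/TP), vessel filling, and a concentration-sweep
  benchmark.

The model and its losses: with per-pixel Bernoulli probabilities p_k the
count loss is the Gaussian approximation to the Poisson-binomial
likelihood of the true bubble count E,

    L_count = (E − µ)² / (2σ²) + log(√(2π) σ),   µ = Σ p_k,  σ² = Σ p_k(1−p_k),

and the localization loss is the negative log-likelihood of each ground
truth u = (y, x, I) under the mixture with one diagonal Gaussian per
pixel, weighted by w_k = p_k / Σp:

    L_loc = −(1/E) Σ_e log Σ_k w_k · N(u_e ; (y_k+Δy_k, x_k+Δx_k, I_k), diag(σ_y², σ_x², σ_I²)).

See `docs/methods.md` for grids, parameterizations and design choices.

## Worked example

```python
import numpy as np
from ulmloc import (ImagingConfig, SimulationParams, NoiseModel,
                    simulate_sequence, train_decode, localize_stack,
                    normalize_acquisition, gaussian_bank)
from ulmloc.decode import output_to_fine
from ulmloc.metrics import evaluate_frames

cfg = ImagingConfig()                      # 20 MHz, 12.3 um fine px, 80x80 -> 40x40
params = SimulationParams(concentration_per_lambda2=0.05)
bank = gaussian_bank(seed=0)               # 32 Gaussian bubble templates
noise = NoiseModel.constant(0.1, cfg.fov_input)

model = train_decode(cfg, params, bank, noise, epochs=5,
                     frames_per_epoch=2000, batch=8, base_filters=16, seed=1)

stack, gt = simulate_sequence(cfg, params, bank, noise, 202, seed=999)
locs = localize_stack(model, normalize_acquisition(stack))
pred = {}
for p in locs:
    pred.setdefault(p.frame, []).append(output_to_fine(p.row, p.col, cfg))
pred = {t: np.asarray(v) for t, v in pred.items()}
df = evaluate_frames(pred, gt, range(1, 201), radius=10.0)
print(f"accuracy {df['accuracy'].mean():.3f}  miss {df['miss'].mean():.3f}  "
      f"error {df['error'].mean() * cfg.fine_pixel_um:.2f} um")
```

Output from this exact run (one CPU core, ~11 minutes, dominated by
training):

```
accuracy 1.000  miss 0.137  error 6.54 um
```

meaning: every detection the network reported sat within the matching
radius of a true bubble (no false positives), 13.7% of bubbles went
undetected at 0.05 bubbles/λ², and matched detections were off by
6.5 µm RMS — about λ/12 at 20 MHz, an order of magnitude below the
diffraction limit. On the same frames the conventional NCC baseline
misses 57%; at a high density of 0.30 bubbles/λ² the network misses 65%
versus 89% for NCC.

A command-line surface wraps the same functions:

```bash
ulmloc simulate --seed 1 --frames 200 --out sim/
ulmloc train --epochs 5 --frames-per-epoch 2000 --out model.npz
ulmloc localize sim/stack.tif --method decode --model model.npz --out det.csv
ulmloc track det.csv sim/stack.tif --out tracks.csv
ulmloc reconstruct tracks.csv sim/stack.tif --out maps/
ulmloc evaluate det.csv sim/ground_truth.csv
```

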