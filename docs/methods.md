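# Methods

`ulmloc` implements a desk-scale, fully synthetic pipeline for
super-resolution ultrasound localization microscopy (ULM): it simulates
contrast-enhanced frame stacks with known microbubble ground truth,
trains a context-aware probabilistic localization network on them,
benchmarks it against a conventional normalized-cross-correlation (NCC)
localizer, links detections into tracks, and reconstructs super-resolved
density, direction and functional activation maps.

## Imaging geometry

Everything is expressed on three grids tied to the acoustic wavelength
λ = c / f₀ (sound speed c = 1540 m/s):

* **fine grid** — the simulation / ground-truth grid (default 12.3 µm
  pixels, 80 × 80);
* **input grid** — the network grid, the fine grid block-averaged ×2
  (40 × 40);
* **reconstruction grids** — localizations are rounded to λ/10 and maps
  accumulated at λ/5 (98.56 µm wavelength at 15.625 MHz gives 9.856 and
  19.712 µm; 77 µm at 20 MHz gives 7.7 and 15.4 µm).

Coordinates are (row = axial, col = lateral), 0-based, with pixel
centers at integers. Input pixel *i* spans fine pixels {2i, 2i+1}, so
fine coordinate r maps to output coordinate (r − 0.5)/2. This convention
makes the ×2 block-average mapping exact and is used consistently by the
simulator, the loss targets and the evaluation.

## Simulator

Bubble count per field of view is Poisson with mean `concentration ×
area(λ²)`; the benchmark sweep spans 0.02–0.37 bubbles/λ². Each bubble
draws speed ~ U(5, 25) mm/s, lifetime ~ U{1..20} frames, brightness ~
N(µ_Imax, σ_Imax) truncated at zero, and a uniform initial direction.
Per frame the direction unit vector is perturbed by N(0, 0.2²) per
component and renormalized. Design points the source protocol leaves
open, fixed here once:

* **Respawning.** Expired or exited bubbles are replaced by fresh draws,
  so the bubble count of a sequence is conserved exactly and the
  expected density is stationary. The time average of a sequence
  therefore equals its initial Poisson draw; statistical checks average
  over independent seeds.
* **Template coherence.** Each bubble keeps one bank template for its
  whole lifetime — the temporal coherence a context-aware network can
  exploit.
* **Rendering.** Templates are peak-normalized; a bubble is stamped by
  bilinearly shifting its template to the sub-pixel position and scaling
  by brightness; overlaps add linearly; the fine frame is block-averaged
  to the input grid (which conserves the spatial integral of intensity).

The default synthetic bank contains bivariate Gaussian templates with
axial/lateral σ drawn from U(1.5, 3.0) fine px (FWHM ≈ 0.6–0.9 λ),
µ_Imax = 1, σ_Imax = 0.2. These are stand-ins for templates learned from
real data; they reproduce overlap and brightness-variation effects but
not the asymmetric, depth-dependent point-spread shapes of in vivo
recordings — results on this bank therefore measure the pipeline, not
in vivo performance.

## Noise model

Additive Gaussian noise of scale σ on both IQ channels makes the
recorded magnitude Rician: p(I | ν, σ) = (I/σ²) exp(−(I²+ν²)/(2σ²))
I₀(Iν/σ²), evaluated with the exponentially scaled Bessel function for
stability. The printed form of this density elsewhere sometimes carries
a σ̂ (un-squared) in the leading fraction; the sampling construction
uniquely determines the standard I/σ² form, which is what the sampler
and density here implement — the χ² sampler-vs-density consistency test
enforces it. The per-pixel σ is estimated from noise-only recordings as
σ̂ = √(2/π) × temporal mean (unbiased for Rayleigh data). Without a
recording, a constant σ = 0.1 µ_Imax is used — a synthetic-data
convention giving peak SNR ≈ 10.

## Localization network

A 2D DECODE-style architecture: one frame-analysis U-Net (3×3 convs,
ELU, two average-pool/upsample levels, filters f–2f–4f, f = 48 by
default) applied to each of three consecutive frames with shared weights
(a config switch instantiates three separate nets), a temporal-context
U-Net over the concatenated features, and a 3×3 head emitting nine
channels for the center frame: detection probability p (sigmoid),
offsets Δy, Δx ∈ (−0.5, 0.5) (tanh/2), brightness I (softplus),
uncertainties σ_y, σ_x, σ_I, background B and a passive background-scale
channel.

**Bounded uncertainties.** σ = 0.01 + 3·sigmoid(raw). The bound matters:
with an unbounded (softplus) σ the joint loss has a strong degenerate
optimum in which all probability mass sits at one border pixel whose
component inflates to σ ≈ 30 px and "covers" every bubble; desk-scale
training reliably falls into it. Capping σ at 3 px removes that optimum.
The p-channel head bias starts at −2 (a sparse detection prior).

**Losses.** The count loss is the Gaussian approximation to the
Poisson-binomial count likelihood, ½(E−µ)²/σ² + log(√(2π)σ) with
µ = Σp_k, σ² = Σp_k(1−p_k) floored at 10⁻⁶. The localization loss is the
negative mean log-likelihood of each ground-truth (y, x, I) triple under
a Gaussian mixture with one diagonal 3D component per pixel, weighted by
p_k/Σp, computed with log-sum-exp. Frames with E = 0 contribute the
count term only; the background loss is identically zero because
background is modelled by the explicit noise model. Both losses are
verified against independent scalar-loop implementations at 10⁻⁶.

**Training.** Data are simulated on the fly (sequences of 12 frames cut
into 3-frame windows; every frame used exactly once), normalized per
sequence to [0, 1] with the ground-truth brightness scaled by the same
factor. Adam at 6·10⁻⁴ (higher rates collapse the detection field into
the no-detection optimum before features form), learning rate halved
when an epoch fails to improve. The desk profile used by the tests and
the acceptance script is 5 epochs × 2000 frames at base width 16, batch
8, on 40 × 40 inputs — batch 8 doubles the number of optimizer steps at
the same data budget, which at this small scale converges markedly
further than batch 16; the profile is sized so a training run fits in
minutes on one CPU core; the default width 48 and
10 000 frames/epoch reproduce the reference regime when more compute is
available. Networks run on a small numpy reverse-mode autodiff engine
written for this package (im2col-free convolutions as one GEMM per layer
plus shifted adds); float32 weights, gradients verified against finite
differences.

**Detection.** Candidate pixels are local maxima of p whose probability
mass summed over a (2r+1)² neighbourhood (r = 1) reaches `p_thresh`
(default 0.6) — neighbourhood summing approximates per-bubble
probability mass when the network spreads a detection over adjacent
pixels. Position = pixel center + (Δy, Δx). The highest 5% by positional
uncertainty √(σ_x²+σ_y²) are rejected, mirroring uncertainty-based
filtering at inference.

## Conventional baseline

Zero-normalized cross-correlation of each frame against a bivariate
Gaussian PSF (least-squares fitted to the bank mean), computed at fully
valid displacements and embedded in a same-size map with a −1 border.
Peaks are strict local maxima above threshold (default 0.6), greedily
suppressed within `min_distance` (higher wins, ties row-major). Sub-pixel
refinement fits a quadratic to the 3×3 correlation neighbourhood and
clamps the vertex to ±0.5 px (a 5×5 intensity centroid is available; it
carries the usual truncation bias toward the window center). On
noise-free isolated bubbles this baseline reaches RMSE < 0.25 fine px.

## Preprocessing

SVD clutter filtering zeroes the lowest `low_cut` singular components of
the pixels × time Casorati matrix (default 1 for synthetic data —
adaptive cutoff selection is out of scope), followed by per-acquisition
0–1 normalization and thresholding (values < 0.15 zeroed; the boundary
value survives). Upsampling uses spline interpolation on a
corner-anchored grid so a feature at (r, c) lands at exactly
(r·f_ax, c·f_lat).

## Tracking

A simplified two-step linear-assignment tracker, deliberately lighter
than full uTrack: frame-to-frame minimum-total-distance assignment gated
at `max_dist` (1.5 × the fastest bubble's per-frame displacement), then
gap closing between segment ends and starts (gap ≤ 2 frames, distance ≤
gap × max_dist) with the linking angle between the segment's terminal
velocity (displacement over its last ≤3 steps) and the end-to-start
displacement gated at 45°. Tracks spanning fewer than 10 frames are
discarded. Birth/death costs and motion models are not modelled.

## Reconstruction and functional mapping

Track points are rounded to λ/10, binned at λ/5; density maps count
points per pixel (mass = number of accumulated points). Direction maps
accumulate ±1 by the axial velocity sign, +1 toward the transducer
(decreasing row). The per-pixel bubble-count series s_MB(t) counts
*distinct tracks* per pixel per 1-s window. Functional activation is the
Pearson correlation r between s_MB(t) and the stimulation pattern over
the analysis mask — stimulation seconds (0–30 of each 70-s cycle) and
stable rest (40–70); the 10-s transition is excluded — with r > 0.2
defining activation. Zero-variance pixels are flagged and set to r = 0.
The synthetic validation drives Poisson counts whose rate doubles during
stimulation (base 3 s⁻¹) across 15 cycles; modulated pixels activate
with probability ≥ 0.95 while null pixels stay ≤ 5%.

## Template GAN

The learned-template path trains a least-squares GAN on extracted
patches: D minimizes ½E[(D(x)−1)²] + ½E[D(G(z))²], G minimizes
½E[(D(G(z))−1)²], alternating one step each per batch (Adam, lr 2·10⁻⁴,
β₁ = 0.5). The generator maps a 64-d latent through a dense projection
and two upsample+conv stages to a sigmoid patch; the discriminator is a
conv/average-pool stack with a zero-initialized linear head, so an
untrained D scores 0 everywhere and the generator loss starts near its
ceiling and falls as training progresses. Sampled patches are clamped
non-negative and peak-normalized; brightness statistics are copied from
the training bank. A moment check (intensity-weighted widths within 3 SD
of the training bank) guards against gross mode collapse; finer
collapse diagnostics are out of scope.

## Evaluation metrics

Predictions and ground truth are matched one-to-one by
minimum-total-distance optimal assignment restricted to pairs within the
radius (default 5 output px; greedy matching is available for
sensitivity checks but inflates accuracy at high density). Detection
accuracy = TP/(TP+FP), miss rate = FN/(TP+FN), and the localization
error is √(mean over TP of ((Δx² + Δy²)/2)) — the per-pair halving
inside the root follows the metric as conventionally printed. Metrics
are computed per frame and then aggregated (mean ± SD).

## Known limitations

* Synthetic banks and white Rician noise omit speckle/clutter texture,
  depth-dependent PSF variation and beamforming artefacts; passing
  benchmarks demonstrate the pipeline's correctness, not in vivo
  accuracy.
* The desk training profile (width 16, 10 000 total frames) is far
  below the reference regime; the trained network's absolute accuracy
  and miss numbers are specific to that profile.
* Training is deterministic for a fixed seed on fixed hardware, but
  float32 reductions can differ across BLAS builds; thresholds in tests
  carry margins for this.
* The tracker has no motion model and no merge/split handling; crossing
  vessels can swap identities.
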