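# Methods

`padenoise` implements single-pulse photoacoustic (PA) B-scan denoising
with a conditional GAN, alongside the classical baselines, the
no-reference image-quality metrics, the noise-characterization tools, and
a synthetic phantom/photobleaching simulator that makes every component
trainable and testable from code alone. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic experiments do and do not demonstrate.

## The denoising model

The generator `G` maps a noisy single-pulse image `x` to an estimate of
the clean (many-pulse-average) image `y`. It is a Pix2Pix-style
encoder–decoder: kernel-4 stride-2 convolutions halve the resolution per
level on the way down and transposed convolutions mirror the path up,
with skip concatenations between matching levels so fine spatial detail
bypasses the bottleneck. Blocks are conv → batch norm → ReLU; the first
encoder block carries no normalization, encoder blocks beyond the first
three and decoder blocks except the last three carry dropout (p = 0.5).
Dropout is also the model's only stochastic input: there is no explicit
noise tensor (the usual Pix2Pix convention). Weights are he-normal
(truncated at two standard deviations). The final layer is a tanh;
images in `[0, 1]` are rescaled to `[-1, 1]` at the network boundary and
back afterwards.

Depth adapts to the image side: 8 levels at 256 px (1×1 bottleneck,
where normalization is skipped because single-sample 1×1 statistics are
degenerate), `log2(side) − 1` levels below that (2×2 bottleneck at
64 px). Channel widths double per level from `base_filters` and cap at
8×.

The discriminator is a PatchGAN: a fully convolutional kernel-4 stack
with strides (2, 2, 2, 1, 1), widths (64, 128, 256, 512) plus a
1-channel head, run on the channel-concatenated (condition, candidate)
pair. Each output unit scores one 70×70 patch of the input —
`r ← r·s + (k − s)` layer by layer gives 4, 10, 16, 34, 70 — and a
256×256 input yields a 30×30 score map. The first block has no
normalization; hidden activations are plain ReLU with a leaky ReLU
(slope 0.2) only after the final convolution. Both facts are also
measured empirically: a gradient-footprint probe backpropagates an
impulse from one central output unit through absolute-valued kernels
with identity activations and counts the nonzero input pixels, so the
connectivity is verified independently of the arithmetic.

### Objective

With binary cross-entropy `BCE` over the patch map (computed from logits
for stability; at chance the two-term discriminator loss equals
`2 ln 2`):

```
L_D     = BCE(D(x, y), 1) + BCE(D(x, G(x)), 0)
L_adv   = BCE(D(x, G(x)), 1)                     (non-saturating)
L_G     = L_adv + λ_DL · (L_huber + L_SSIM),     λ_DL = 100
```

The Huber term is quadratic for residuals below δ = 1 and linear beyond
(continuous value and slope at the kink); on `[0, 1]`-scaled images the
δ = 1 threshold means in-range residuals stay in the quadratic regime and
the linear branch only engages for outliers. The SSIM term is
`mean(1 − SSIM(y, G(x)))` with the standard constants
`C1 = (0.01 L)², C2 = (0.03 L)²` and an 11×11 Gaussian window
(σ = 1.5), averaged over the window-valid interior. Both reconstruction
terms are evaluated on the `[0, 1]` scale so their magnitudes refer to
storage units. The SSIM gradient is analytic: the chain rule runs
through the five Gaussian blurs, with the blur adjoint approximated by
the blur itself (exact away from the reflected boundary; the residual
error within half a window of the border is negligible for a training
signal and was checked against numerical differentiation).

### Optimization

Adam for both players: learning rate 1e-4 (constant; no decay), β1 = 0.5,
β2 = 0.999, ε = 1e-7, batch size 1. Each step performs one discriminator
update (one real and one fake pair) then one generator update. With
batch size 1 the batch-norm statistics are per-image, i.e.
instance-normalization behavior. Data order is a fresh random
permutation per epoch drawn from the run seed; everything (weights,
dropout, data order, synthetic data) derives from that one seed, so runs
are bit-reproducible. Training aborts with a diagnostic if any loss
goes non-finite.

Two profiles ship: the full-scale schedule (256×256, 64 base filters,
40,000 steps) and a desk profile (64×64, 32 base filters, 2,000 steps)
sized for a single CPU. The desk discriminator uses strides
(2, 2, 1, 1) — receptive field 34 — because the full 70-pixel field
cannot fit a 64-pixel image (the builder rejects inputs smaller than the
receptive field by contract).

The supervised baseline uses the identical skip-connected
encoder–decoder trained with mean absolute error only (no adversary),
same optimizer settings.

All networks run on a small numpy layer stack written for this package
(im2col/col2im convolutions, explicit backprop, Adam); every layer's
gradient is verified against numerical differentiation in the test
suite, and the transposed convolution is additionally checked as the
exact adjoint of the convolution.

## Classical baselines

* Savitzky–Golay, order 3, frame 9, applied per column — the axial
  (A-line) direction, since PA signals are depth profiles. Whether the
  original use was 1-D or separable 2-D is not determinable; a
  `bivariate` flag provides the separable variant. Edges use mirror
  padding; interior samples are the exact local least-squares polynomial
  fit, so cubics pass through unchanged.
* Pixel-wise adaptive Wiener, 5×5 window:
  `out = μ + max(σ² − ν², 0)/max(σ², ν²) · (in − μ)` with the noise power
  ν² estimated as the mean of all local variances. Local statistics use
  reflect padding so a constant image is a strict pass-through (zero
  padding would perturb borders).
* BM3D with estimated σ and all stages (hard-thresholding + Wiener).
  BM3D itself is an optional external dependency: when the `bm3d`
  package is absent the call raises an explicit "optional baseline
  missing" error, never a silent fallback. The σ front end — a
  single-channel wavelet-diagonal median-absolute-deviation estimator —
  is always available. A requested σ = 0 returns the input (nothing to
  remove).

## Image-quality metrics

Over user-declared rectangular boxes (0-based, half-open):
`SNR = μ_ROI/σ_BG` (plain ratio, not dB), `CNR = σ_ROI/σ_BG`, and
`GCNR = 1 − Σ_b min(p1_b, p2_b)` from histograms over 256 shared bins
spanning the pooled range (bin count configurable; a convergence check
is in the tests). GCNR is invariant under common monotone intensity
remappings when the bins are recomputed on the remapped range; SNR/CNR
are invariant under positive scaling but SNR shifts under offsets.
Pixels are measured as-is — no absolute value — so filters that go
negative are measured faithfully. A zero-variance background raises a
"degenerate background" error; a zero-width pooled range in GCNR counts
as complete overlap (0) with a warning.

For synthetic studies, `phantoms.suggest_roi` places the signal box on
the window of the *clean* phantom with the highest mean intensity
(trying both orientations of the requested box shape) and the background
box in the darkest disjoint corner. This is harness plumbing: boxes
placed blindly (e.g. image-center) straddle dark interior for ring-like
objects and make GCNR measure the wrong thing. On real data the boxes
are user inputs.

## Noise models and characterization

Four corruptions, none of which clips (clipping happens only at file
write so residual statistics stay unbiased): additive Gaussian
(σ, default 0.1); scaled-count Poisson `Poisson(img·s)/s` (the original
parameterization is unspecified, so the scale is exposed; variance per
pixel is mean/s); salt & pepper destroying an exact `round(p·N)` pixels
(default 10%) to the range extremes with a fair salt/pepper split; and
multiplicative speckle `img·(1 + u)` with `u ~ Uniform(−a, a)`,
`a = √(3v)` so `var(u) = v` (default 0.1).

Noise profiles are `log(1 + |FFT2|²)`, DC-centered, optionally divided
by their maximum. The `log(1+·)` form avoids `log 0`; normalization is
applied post-log for dynamic-range comparability (the pre/post choice is
not determinable from the published description). No window function is
applied before the FFT. Cross-power spectra are
`log(1 + |F_a · conj(F_b)|)` on the same grid, and profile similarity is
the Pearson correlation of the two flattened (row-major) log-power
arrays; dissimilar acquisition platforms land well below 0.8.

## Synthetic data

The phantom generator replaces unavailable instrument data with three
object families on dark background: a tube cross-section (two bright
wall arcs at the acoustic poles, since PA detection favors interfaces
normal to the transducer axis), thin fibers at arbitrary orientation
(Gaussian profile with FWHM equal to the nominal thickness), and seeded
random vessel trees. Peak amplitude is normalized exactly to the spec's
amplitude. Every generator is a pure function of (arguments, seed);
paired datasets derive per-sample seeds counter-style from
`(master_seed, index)` so they are order-independent and extensible.

Two pairing modes: frame-average pairs (input residual `σ/√F_in`, label
residual `σ/√F_label`, e.g. 128 vs 25,600 averages, sampled directly at
the averaged scale) and the Gaussian benchmark (clean target, input +
N(0, σ²), default σ = 0.1) used for the efficacy studies.

### Photobleaching

The dye model is mono-exponential per-pulse decay: each pulse delivered
at lateral position `x_j` multiplies the local concentration at `u` by
`1 − β·g(u − x_j)`, with `g` the unit-peak Gaussian lateral beam profile
(`exp(−2d²/w²)`, `w` the 1/e² radius, default 2× the 100-µm scan step —
acoustic-resolution systems illuminate broadly, and the beam overlap is
what pre-bleaches positions before their own scan). β is a free
parameter; nothing is hard-coded to reproduce any particular published
percentage. A point exposure gives `A_k = A_0(1 − β)^k` exactly — the
simplest kinetics consistent with a steady decline under repeated
exposure (true dye photochemistry, triplet states and oxygen dependence
are out of scope). Within an n-pulse average, bleaching applies between
pulses, so averaged frames reflect mid-decay amplitudes: averaging buys
SNR at the price of dose.

Bleaching percentage is `100·(1 − A_k/A_ref)` against the first scanned
position, floored at 0 (noise can push the raw comparison negative; the
raw value is retained). Per-position amplitude is the maximum over the
object mask (clean-phantom half-maximum support), optionally after 3×3
median smoothing. In the three-way experiment (single pulse / n-pulse
average / denoised single pulse) the denoised mode reuses the
single-pulse acquisition, so its bleaching curve equals the single-pulse
curve *identically* — denoising changes image quality, not delivered
dose — while its SNR is reported separately. Statistical annotations
(ANOVA) are out of scope; the per-group arrays are exported for any
stats package.

## Problem sizes in the test suite

The efficacy property is checked at desk scale: 200 training pairs,
64×64, Gaussian σ = 0.1, 2,000 steps, 32 base filters, five independent
seeds, 20 held-out images, passing when the trained model beats the
noisy input in mean SNR and GCNR and the Savitzky–Golay and Wiener rows
in mean SNR for at least 4 of 5 seeds. Unit tests use smaller networks
(3 levels, 4–8 filters, 32×32 images) chosen so numerical gradient
checks and determinism checks stay fast.

## What passing tests do and do not show

The synthetic phantoms share the real data's geometry class (bright
sparse structures on dark background) and its additive-noise character,
but not speckle texture, depth-dependent attenuation, reconstruction
artifacts, system-specific colored noise spectra, or tissue
heterogeneity. Efficacy on this benchmark demonstrates that the
architecture, objective and optimization are wired correctly and can
learn a strong denoiser; it does not certify performance on any real
scanner's data, and absolute SNR/CNR values here are not comparable to
values measured on instrument data. Likewise the photobleaching
simulation demonstrates the dose/SNR trade-off mechanism, not ICG
chemistry: β and the beam radius are knobs, and only the qualitative
pattern (averaging bleaches several-fold more than single-pulse;
denoised single-pulse keeps single-pulse dose at high SNR) is asserted.

## Known limitations

* CPU-only numpy training: the full-scale 256×256/40,000-step schedule
  is configuration-selectable but slow off-GPU; the desk profile is the
  practical default here.
* Batch size is fixed at 1 in practice (batch norm then behaves as
  instance norm, which is the intended regime); larger batches work but
  change normalization semantics.
* The SSIM gradient's boundary approximation (see above).
* GCNR depends on bin count at small samples; 256 bins is the default
  and the convergence test documents the sensitivity.
* No acoustic forward model: phantoms are drawn in image space.
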