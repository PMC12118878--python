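# padenoise

Denoising single-pulse photoacoustic (PA) B-scans with a conditional GAN,
so that imaging with exogenous dyes doesn't have to pay for signal-to-noise
with photobleaching dose.

## The problem

Acoustic-resolution PA microscopy normally averages 20–30 laser pulses per
scan position to reach usable SNR. With photobleachable contrast agents
such as indocyanine green, every extra pulse degrades the dye: repeated
exposure at one point steadily destroys signal amplitude, and a raster scan
with per-position averaging pre-bleaches neighboring positions through beam
overlap before they are even scanned. The alternative — single-pulse
acquisition — keeps the dose minimal but produces badly noisy images.

`padenoise` targets researchers working on PA image enhancement: it
restores single-pulse image quality computationally, and quantifies the
bleaching/SNR trade-off in simulation.

## The model

A Pix2Pix-style conditional GAN. The generator G is a skip-connected
encoder–decoder (kernel-4 stride-2 convolutions, batch norm, ReLU, dropout
0.5) mapping the noisy image x to a clean estimate; the discriminator D is
a 70×70 PatchGAN whose kernel-4 stack (strides 2,2,2,1,1) scores a 30×30
patch map on 256×256 conditional pairs. The generator objective augments
the adversarial term with Huber and structural-similarity distances:

    G* = arg min_G max_D  L_cGAN(G, D) + λ_DL L_h(G) + λ_DL L_SSIM(G)

with λ_DL = 100, Huber threshold δ = 1, and L_SSIM = mean(1 − SSIM(y, G(x))).
Both networks train with Adam (lr 1e-4, β1 = 0.5, β2 = 0.999, ε = 1e-7) at
batch size 1. The networks run on a compact numpy layer stack included in
the package (gradient-checked in the test suite), so nothing beyond the
scientific Python stack is required.

Alongside the cGAN: a U-Net baseline trained with mean absolute error;
Savitzky–Golay (order 3, frame 9, axial), adaptive Wiener (5×5) and
optional BM3D classical baselines; SNR/CNR/GCNR no-reference metrics over
declared ROI boxes; FFT noise-profile characterization; and a synthetic
phantom + raster-scan photobleaching simulator that makes the whole
pipeline runnable without instrument data.

## Worked example

Train the desk-scale cGAN (64×64 phantoms, 2,000 steps, ~3 min on one CPU)
and compare it with the classical filters on held-out images:

```python
import numpy as np
from padenoise.phantoms import default_phantom_suite, make_gaussian_pairs, suggest_roi
from padenoise.networks import GeneratorSpec, DiscriminatorSpec
from padenoise.training import TrainConfig, train_cgan
from padenoise.filters import savitzky_golay, wiener_adaptive
from padenoise.metrics import evaluate_image

specs = default_phantom_suite((64, 64))
train = make_gaussian_pairs(specs, 200, sigma=0.1, seed=10, shape=(64, 64))
test = make_gaussian_pairs(specs, 20, sigma=0.1, seed=99, shape=(64, 64))

model, log = train_cgan(train, GeneratorSpec(base_filters=32),
                        DiscriminatorSpec(base_filters=32, strides=(2, 2, 1, 1)),
                        TrainConfig(steps=2000, seed=0))

for name, fn in [("one pulse", lambda im: im), ("SG", savitzky_golay),
                 ("Wiener", wiener_adaptive), ("cGAN", model.denoise)]:
    ms = [evaluate_image(fn(p.input), suggest_roi(p.target)) for p in test]
    print(f"{name:9s} SNR {np.mean([m.snr for m in ms]):8.2f}"
          f"   GCNR {np.mean([m.gcnr for m in ms]):.3f}")
```

Output:

```
one pulse SNR     6.89   GCNR 0.947
SG        SNR    12.59   GCNR 0.985
Wiener    SNR    35.90   GCNR 0.988
cGAN      SNR  1187.88   GCNR 0.991
```

The noisy input's background (σ = 0.1) caps its SNR near 7; the classical
filters shrink the noise floor a few-fold; the trained generator pushes the
background residual below 1e-3 while preserving the bright structure, hence
the large SNR ratio and the highest distribution-separability (GCNR).

Point-exposure bleaching kinetics are closed-form — a dye with per-pulse
bleaching fraction β = 0.001 keeps `0.999^430 ≈ 0.650` of its amplitude
after 430 pulses (a ~35% drop):

```python
from padenoise.phantoms import BleachModel, simulate_point_exposure
simulate_point_exposure(BleachModel(beta=0.001), 430)[-1]   # 0.65037
```

The same mechanism drives the raster-scan experiment
(`padenoise.evaluation.bleaching_experiment`): 30-pulse averaging bleaches
the far end of a scanned tube several-fold more than single-pulse
acquisition, while cGAN-denoised single-pulse frames keep the single-pulse
dose *identically* and recover the SNR.

A `padenoise` CLI wraps the library for shell use
(`generate`, `corrupt`, `denoise`, `train`, `evaluate`, `benchmark`,
`bleach-sim`, `characterize-noise`, `noise-sweep`); every run writes a
manifest (config hash, seed, version) so artifacts are reproducible.

See `docs/methods.md` for the full model description, parameter defaults,
and the limits of what the synthetic benchmarks demonstrate.

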