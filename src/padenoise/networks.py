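"""Network architectures and objectives for the denoising cGAN.

The generator is a Pix2Pix-style encoder–decoder with skip concatenations
(the "U-Net generator"); the discriminator is a PatchGAN: a fully
convolutional stack whose scalar outputs each judge one receptive-field
patch of the (condition, candidate) input pair. With the default kernel-4
stack and strides [2, 2, 2, 1, 1] each output unit sees a 70x70 patch and
a 256x256 input yields a 30x30 score map.

The generator objective combines the adversarial term with Huber and SSIM
reconstruction terms::

    total_G = l_adv + lambda_dl * (l_huber + l_ssim),   lambda_dl = 100

with Huber threshold delta = 1. The discriminator keeps the standard
conditional-GAN binary cross-entropy against per-patch real/fake labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn.layers import (
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    Dropout,
    Layer,
    LeakyReLU,
    ReLU,
    Sequential,
    Tanh,
    _col2im,
)
from .nn import ssim as _ssim

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossTerms",
    "UNetGenerator",
    "build_generator",
    "build_discriminator",
    "build_unet_baseline",
    "huber_loss",
    "huber_grad",
    "mae_loss",
    "mae_grad",
    "ssim_loss",
    "ssim_loss_and_grad",
    "bce_with_logits",
    "bce_grad",
    "generator_objective",
    "discriminator_objective",
    "adversarial_generator_loss",
    "receptive_field",
    "discriminator_output_shape",
    "gradient_footprint",
]


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class GeneratorSpec:
    """Geometry and regularization of the encoder–decoder generator.

    ``n_levels=None`` derives the depth from the input side: 8 levels at
    256 and above (1x1 bottleneck, the canonical full-scale geometry),
    otherwise ``log2(side) - 1`` so the bottleneck stays 2x2 on small
    desk-scale images.

    Dropout placement follows the stated recipe: encoder blocks beyond the
    first three carry dropout, decoder blocks except the last three carry
    dropout (``encoder_dropout="none"`` switches to the canonical
    decoder-only placement). Dropout doubles as the generator's stochastic
    input: there is no explicit noise tensor.
    """

    n_levels: int | None = None
    base_filters: int = 64
    kernel: int = 4
    stride: int = 2
    dropout_p: float = 0.5
    encoder_dropout: str = "paper"  # "paper" (blocks 4..L) or "none"
    max_filter_mult: int = 8

    def resolve_levels(self, side: int) -> int:
        if self.n_levels is not None:
            n = self.n_levels
        elif side >= 256:
            n = 8
        else:
            n = max(3, int(math.log2(side)) - 1)
        if 2**n > side:
            raise ValueError(f"2^n_levels={2**n} exceeds image side {side}")
        return n


@dataclass(frozen=True)
class DiscriminatorSpec:
    """PatchGAN geometry: kernel-4 convolutions with the given strides.

    Channel widths are ``base_filters * (1, 2, 4, ...)`` for the body plus
    a single-channel head. The default strides ``(2, 2, 2, 1, 1)`` give the
    70-pixel receptive field and the 30x30 map on 256x256 input. The first
    block carries no normalization; hidden activations are plain
    rectifiers and the final layer uses a leaky rectifier (slope 0.2).
    """

    base_filters: int = 64
    kernel: int = 4
    strides: tuple[int, ...] = (2, 2, 2, 1, 1)
    leaky_slope: float = 0.2


@dataclass
class LossTerms:
    """Per-step loss components of the adversarial objective."""

    l_adv: float = 0.0
    l_huber: float = 0.0
    l_ssim: float = 0.0
    l_disc: float = 0.0
    lambda_dl: float = 100.0
    delta: float = 1.0

    @property
    def total_g(self) -> float:
        return generator_objective(self)


def generator_objective(terms: LossTerms) -> float:
    """Combined generator loss: ``l_adv + lambda_dl * (l_huber + l_ssim)``."""
    return float(terms.l_adv + terms.lambda_dl * (terms.l_huber + terms.l_ssim))


# --------------------------------------------------------------------------
# generator


class UNetGenerator(Layer):
    """Encoder–decoder with skip concatenations and explicit backprop."""

    def __init__(self, enc_blocks: list[Sequential], dec_blocks: list[Sequential]):
        if len(enc_blocks) != len(dec_blocks):
            raise ValueError("encoder and decoder must have equal depth")
        self.enc = enc_blocks
        self.dec = dec_blocks
        self._splits: list[int] = []

    def params(self):
        out = []
        for b in self.enc + self.dec:
            out.extend(b.params())
        return out

    def forward(self, x, training=False):
        feats = []
        for b in self.enc:
            x = b.forward(x, training)
            feats.append(x)
        self._feat_count = len(feats)
        self._splits = []
        y = feats[-1]
        L = len(self.enc)
        for i, b in enumerate(self.dec):
            if i > 0:
                skip = feats[L - 1 - i]
                self._splits.append(y.shape[1])
                y = np.concatenate([y, skip], axis=1)
            y = b.forward(y, training)
        return y

    def backward(self, gy):
        L = len(self.enc)
        gfeats: list[np.ndarray | None] = [None] * L
        g = gy
        for i in reversed(range(len(self.dec))):
            g = self.dec[i].backward(g)
            if i > 0:
                split = self._splits[i - 1]
                gfeats[L - 1 - i] = g[:, split:]
                g = g[:, :split]
        # g is now the gradient at the bottleneck feature; walk the encoder
        # back down, folding in each skip-connection gradient where it taps off
        for j in reversed(range(L)):
            g = self.enc[j].backward(g)
            if j >= 1 and gfeats[j - 1] is not None:
                g = g + gfeats[j - 1]
        return g


def _enc_channels(spec: GeneratorSpec, n: int) -> list[int]:
    return [min(spec.base_filters * 2**i, spec.base_filters * spec.max_filter_mult) for i in range(n)]


def build_generator(spec: GeneratorSpec, in_shape: tuple[int, int],
                    rng: np.random.Generator | None = None,
                    in_channels: int = 1, out_channels: int = 1) -> UNetGenerator:
    """Build the encoder–decoder generator for square ``in_shape`` images."""
    h, w = in_shape
    if h != w:
        raise ValueError(f"generator expects square inputs, got {in_shape}")
    n = spec.resolve_levels(h)
    if h % (2**n) != 0:
        raise ValueError(f"image side {h} not divisible by 2^{n}")
    rng = rng or np.random.default_rng()
    ch = _enc_channels(spec, n)
    k, s = spec.kernel, spec.stride

    enc: list[Sequential] = []
    side = h
    for i in range(n):
        side //= 2
        layers: list[Layer] = [
            Conv2D(in_channels if i == 0 else ch[i - 1], ch[i], k, s, 1, rng, name=f"enc{i}")
        ]
        # no norm in the first block, and none where the map is degenerate (1x1)
        if i > 0 and side > 1:
            layers.append(BatchNorm2D(ch[i], name=f"enc{i}.bn"))
        layers.append(ReLU())
        if spec.encoder_dropout == "paper" and i >= 3 and spec.dropout_p > 0:
            layers.append(Dropout(spec.dropout_p, rng))
        enc.append(Sequential(layers))

    dec: list[Sequential] = []
    for i in range(n):
        last = i == n - 1
        in_c = ch[n - 1] if i == 0 else ch[n - 1 - i] + ch[n - 1 - i]
        out_c = out_channels if last else ch[n - 2 - i]
        layers = [ConvTranspose2D(in_c, out_c, k, s, 1, rng, name=f"dec{i}")]
        if not last:
            layers.append(BatchNorm2D(out_c, name=f"dec{i}.bn"))
            layers.append(ReLU())
            if i < n - 3 and spec.dropout_p > 0:
                layers.append(Dropout(spec.dropout_p, rng))
        else:
            layers.append(Tanh())
        dec.append(Sequential(layers))
    return UNetGenerator(enc, dec)


def build_unet_baseline(spec: GeneratorSpec, in_shape: tuple[int, int],
                        rng: np.random.Generator | None = None) -> UNetGenerator:
    """Supervised baseline: the same skip-connected encoder–decoder skeleton.

    Identical wiring to the generator; the difference is entirely in the
    objective (mean absolute error only, no adversary) applied by the
    training loop.
    """
    return build_generator(spec, in_shape, rng)


# --------------------------------------------------------------------------
# discriminator


def build_discriminator(spec: DiscriminatorSpec, in_shape: tuple[int, int],
                        rng: np.random.Generator | None = None,
                        in_channels: int = 2) -> Sequential:
    """Build the PatchGAN over channel-concatenated (condition, candidate)."""
    h, w = in_shape
    rf = receptive_field(spec)
    if min(h, w) < rf:
        raise ValueError(f"input {in_shape} smaller than the {rf}-pixel receptive field")
    rng = rng or np.random.default_rng()
    n_body = len(spec.strides) - 1
    widths = [min(spec.base_filters * 2**i, spec.base_filters * 8) for i in range(n_body)]
    layers: list[Layer] = []
    prev = in_channels
    for i, width in enumerate(widths):
        layers.append(Conv2D(prev, width, spec.kernel, spec.strides[i], 1, rng, name=f"disc{i}"))
        if i > 0:
            layers.append(BatchNorm2D(width, name=f"disc{i}.bn"))
        layers.append(ReLU())
        prev = width
    layers.append(Conv2D(prev, 1, spec.kernel, spec.strides[-1], 1, rng, name="disc_head"))
    layers.append(LeakyReLU(spec.leaky_slope))
    return Sequential(layers)


def receptive_field(spec: DiscriminatorSpec) -> int:
    """One-sided receptive field by kernel/stride composition.

    Walking from the output back to the input, ``r <- r*s + (k - s)`` per
    layer. For kernel 4 and strides (2, 2, 2, 1, 1) this yields 70.
    """
    r = 1
    for s in reversed(spec.strides):
        r = r * s + (spec.kernel - s)
    return r


def discriminator_output_shape(spec: DiscriminatorSpec, in_shape: tuple[int, int]) -> tuple[int, int]:
    """Spatial size of the patch score map (padding 1 throughout)."""
    h, w = in_shape
    for s in spec.strides:
        h = (h + 2 - spec.kernel) // s + 1
        w = (w + 2 - spec.kernel) // s + 1
    return h, w


def gradient_footprint(disc: Sequential, in_shape: tuple[int, int],
                       in_channels: int = 2) -> int:
    """Receptive field measured by a gradient-footprint probe.

    Backpropagates an impulse from one central output unit through the
    discriminator's convolution stack using absolute-valued kernels and
    identity activations (a structural linearization, so no activation can
    hide a connection), and returns the side length of the nonzero input
    footprint. Edge clipping is avoided by probing the central unit.
    """
    convs = [l for l in disc.layers if isinstance(l, Conv2D)]
    h, w = in_shape
    shapes = [(h, w)]
    for cv in convs:
        shapes.append(cv.out_shape(*shapes[-1]))
    oh, ow = shapes[-1]
    g = np.zeros((1, 1, oh, ow), dtype=np.float64)
    g[0, 0, oh // 2, ow // 2] = 1.0
    for cv, (ih, iw) in zip(reversed(convs), reversed(shapes[:-1])):
        n, oc, gh, gw = g.shape
        w_abs = np.abs(cv.w.value.astype(np.float64))
        gmat = g.reshape(1, oc, gh * gw)
        gcols = (w_abs.T @ gmat[0])[None]
        g = _col2im(gcols, (1, cv.in_c, ih, iw), cv.k, cv.s, cv.p)
    footprint = np.abs(g[0]).sum(axis=0) > 0
    rows = np.flatnonzero(footprint.any(axis=1))
    cols = np.flatnonzero(footprint.any(axis=0))
    return int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))


# --------------------------------------------------------------------------
# losses


def _flat(a: np.ndarray) -> np.ndarray:
    return np.asarray(a, dtype=float)


def huber_loss(pred: np.ndarray, target: np.ndarray, delta: float = 1.0) -> float:
    """Mean Huber penalty: quadratic within ``delta``, linear beyond.

    ``0.5 r^2`` for ``|r| <= delta`` else ``delta * (|r| - 0.5 delta)``;
    continuous with continuous slope at the transition.
    """
    pred, target = _flat(pred), _flat(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.abs(pred - target)
    quad = 0.5 * r**2
    lin = delta * (r - 0.5 * delta)
    return float(np.where(r <= delta, quad, lin).mean())


def huber_grad(pred: np.ndarray, target: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Gradient of :func:`huber_loss` w.r.t. ``pred``."""
    pred, target = _flat(pred), _flat(target)
    r = pred - target
    return np.clip(r, -delta, delta) / r.size


def mae_loss(pred: np.ndarray, target: np.ndarray) -> float:
    pred, target = _flat(pred), _flat(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.abs(pred - target).mean())


def mae_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    pred, target = _flat(pred), _flat(target)
    return np.sign(pred - target) / pred.size


def _batched(x: np.ndarray) -> np.ndarray:
    """Normalize (H,W) / (N,H,W) / (N,1,H,W) to (N,H,W)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        return x[None]
    if x.ndim == 4 and x.shape[1] == 1:
        return x[:, 0]
    if x.ndim == 3:
        return x
    raise ValueError(f"expected 2D/3D/4D single-channel batch, got shape {x.shape}")


def ssim_loss(pred: np.ndarray, target: np.ndarray, data_range: float = 1.0) -> float:
    """Mean over the batch of ``1 - SSIM(target, pred)``; lies in [0, 2]."""
    p, t = _batched(pred), _batched(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    vals = [_ssim.ssim_value(pi, ti, data_range) for pi, ti in zip(p, t)]
    return float(np.mean([1.0 - v for v in vals]))


def ssim_loss_and_grad(pred: np.ndarray, target: np.ndarray, data_range: float = 1.0):
    """(loss, dloss/dpred) for the batch-mean SSIM distance."""
    p, t = _batched(pred), _batched(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    n = p.shape[0]
    grads = np.empty_like(p)
    total = 0.0
    for i in range(n):
        v, g = _ssim.ssim_and_grad(p[i], t[i], data_range)
        total += 1.0 - v
        grads[i] = -g / n
    return total / n, grads.reshape(np.asarray(pred, dtype=float).shape)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0)


def bce_with_logits(logits: np.ndarray, target: float) -> float:
    """Mean binary cross-entropy of a score map against a constant label."""
    z = np.asarray(logits, dtype=float)
    return float((_softplus(z) - target * z).mean())


def bce_grad(logits: np.ndarray, target: float) -> np.ndarray:
    z = np.asarray(logits, dtype=float)
    return (1.0 / (1.0 + np.exp(-z)) - target) / z.size


def discriminator_objective(real_logits: np.ndarray, fake_logits: np.ndarray) -> float:
    """Patch BCE: real map against ones plus fake map against zeros.

    At chance (sigmoid score 0.5 everywhere) this equals ``2 ln 2``.
    """
    return bce_with_logits(real_logits, 1.0) + bce_with_logits(fake_logits, 0.0)


def adversarial_generator_loss(fake_logits: np.ndarray) -> float:
    """Non-saturating generator term: fake map scored against ones."""
    return bce_with_logits(fake_logits, 1.0)
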