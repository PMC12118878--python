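"""cGAN and supervised U-Net training with the benchmark hyperparameters.

The optimization recipe: Adam for both players with learning rate 1e-4,
beta1 0.5, beta2 0.999, epsilon 1e-7, batch size 1; each step performs one
discriminator update (patch BCE on a real and a fake pair) followed by one
generator update on ``l_adv + lambda_dl * (l_huber + l_ssim)`` with
``lambda_dl = 100`` and Huber ``delta = 1``. The full-scale schedule is
40,000 steps; a desk-scale profile (64x64 images, 2,000 steps, 32 base
filters) ships for CPU-sized runs.

Networks see images rescaled to [-1, 1] (tanh output); the Huber and SSIM
terms are evaluated on the [0, 1] scale so their magnitudes and the
``delta = 1`` threshold refer to storage units.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass

import numpy as np

from .image import Image2D, PairedSample
from .networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    LossTerms,
    UNetGenerator,
    adversarial_generator_loss,
    bce_grad,
    bce_with_logits,
    build_discriminator,
    build_generator,
    discriminator_objective,
    generator_objective,
    huber_grad,
    huber_loss,
    mae_grad,
    mae_loss,
    ssim_loss_and_grad,
)
from .nn.layers import BatchNorm2D
from .nn.optim import Adam

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "DenoisingModel",
    "train_cgan",
    "train_unet",
    "denoise",
    "desk_profile",
    "paper_profile",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule hyperparameters."""

    lr: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 1
    steps: int = 40000
    seed: int = 0
    checkpoint_every: int = 0  # 0: only the final checkpoint
    lambda_dl: float = 100.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1/beta2 must be in [0, 1)")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


def desk_profile(seed: int = 0) -> tuple[GeneratorSpec, DiscriminatorSpec, TrainConfig]:
    """CPU-sized default: 64x64 images, 32 base filters, 2,000 steps.

    The discriminator drops to strides (2, 2, 1, 1) so its 34-pixel
    receptive field fits inside a 64-pixel image.
    """
    return (
        GeneratorSpec(base_filters=32),
        DiscriminatorSpec(base_filters=32, strides=(2, 2, 1, 1)),
        TrainConfig(steps=2000, seed=seed),
    )


def paper_profile(seed: int = 0) -> tuple[GeneratorSpec, DiscriminatorSpec, TrainConfig]:
    """Full-scale settings: 256x256, 64 base filters, 40,000 steps."""
    return GeneratorSpec(), DiscriminatorSpec(), TrainConfig(seed=seed)


class DenoisingModel:
    """A trained generator plus the I/O conventions it was trained with."""

    def __init__(self, gen: UNetGenerator, gen_spec: GeneratorSpec, side: int,
                 kind: str = "cgan", step: int = 0, seed: int = 0):
        self.gen = gen
        self.gen_spec = gen_spec
        self.side = side
        self.kind = kind
        self.step = step
        self.seed = seed

    @property
    def down_factor(self) -> int:
        return 2 ** self.gen_spec.resolve_levels(self.side)

    def denoise(self, image, stochastic: bool = False):
        """Denoise one image; pads and crops to the network grid if needed.

        Dropout is inactive unless ``stochastic=True``. Output is clipped
        to [0, 1]. Per-frame latency is logged at debug level
        (informational only; it is hardware-dependent).
        """
        from .image import as_pixels, like

        px = as_pixels(image)
        h, w = px.shape
        f = self.down_factor
        ph = (-h) % f
        pw = (-w) % f
        t0 = time.perf_counter()
        padded = np.pad(px, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else px
        x = (padded.astype(np.float32) * 2.0 - 1.0)[None, None]
        y = self.gen.forward(x, training=stochastic)
        out = (y[0, 0].astype(float) + 1.0) / 2.0
        out = np.clip(out[:h, :w], 0.0, 1.0)
        logger.debug("denoise latency: %.1f ms for %dx%d", 1e3 * (time.perf_counter() - t0), h, w)
        return like(image, out)

    # -- persistence --------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for p in self.gen.params():
            state[p.name] = p.value
        for blk in self.gen.enc + self.gen.dec:
            for layer in blk.layers:
                if isinstance(layer, BatchNorm2D):
                    base = layer.gamma.name.rsplit(".", 1)[0]
                    state[f"{base}.running_mean"] = layer.running_mean
                    state[f"{base}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for p in self.gen.params():
            p.value[...] = state[p.name]
        for blk in self.gen.enc + self.gen.dec:
            for layer in blk.layers:
                if isinstance(layer, BatchNorm2D):
                    base = layer.gamma.name.rsplit(".", 1)[0]
                    layer.running_mean = np.asarray(state[f"{base}.running_mean"])
                    layer.running_var = np.asarray(state[f"{base}.running_var"])


def save_checkpoint(model: DenoisingModel, path) -> None:
    """Write weights (npz) plus a JSON metadata sidecar."""
    import pathlib

    path = pathlib.Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_arrays())
    meta = {
        "kind": model.kind,
        "side": model.side,
        "step": model.step,
        "seed": model.seed,
        "gen_spec": asdict(model.gen_spec),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> DenoisingModel:
    import pathlib

    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = GeneratorSpec(**meta["gen_spec"])
    side = int(meta["side"])
    gen = build_generator(spec, (side, side), np.random.default_rng(0))
    model = DenoisingModel(gen, spec, side, kind=meta["kind"], step=int(meta["step"]),
                           seed=int(meta["seed"]))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_arrays({k: data[k] for k in data.files})
    return model


# --------------------------------------------------------------------------
# training loops


def _to_tensor(img: Image2D) -> np.ndarray:
    return (img.pixels.astype(np.float32) * 2.0 - 1.0)[None, None]


def _check_dataset(dataset: list[PairedSample]) -> int:
    if not dataset:
        raise ValueError("dataset must be non-empty")
    shapes = {p.input.shape for p in dataset}
    if len(shapes) != 1:
        raise ValueError(f"all pairs must share one shape, got {shapes}")
    h, w = next(iter(shapes))
    if h != w:
        raise ValueError("training expects square images")
    return h


def _epoch_order(rng: np.random.Generator, n: int, steps: int) -> np.ndarray:
    """Random shuffle per epoch; with batch 1 this is the step sequence."""
    reps = int(np.ceil(steps / n))
    return np.concatenate([rng.permutation(n) for _ in range(reps)])[:steps]


def _finite_or_raise(step: int, **losses: float) -> None:
    for name, v in losses.items():
        if not np.isfinite(v):
            raise RuntimeError(
                f"training diverged at step {step}: {name} = {v}; "
                f"all losses: {losses}"
            )


def train_cgan(
    dataset: list[PairedSample],
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
    cfg: TrainConfig = TrainConfig(),
    out_dir=None,
) -> tuple[DenoisingModel, list[dict]]:
    """Alternating cGAN optimization; returns the generator and a loss log.

    Per step: one discriminator update (BCE on one real and one fake
    conditional pair), then one generator update on the combined
    objective. The log records every loss component per step; the final
    checkpoint (and periodic ones, if configured) are written to
    ``out_dir`` when given.
    """
    side = _check_dataset(dataset)
    gen_spec = gen_spec or GeneratorSpec(base_filters=32)
    disc_spec = disc_spec or DiscriminatorSpec(base_filters=32, strides=(2, 2, 1, 1))
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(gen_spec, (side, side), rng)
    disc = build_discriminator(disc_spec, (side, side), rng)
    opt_g = Adam(gen.params(), cfg.lr, cfg.beta1, cfg.beta2, cfg.epsilon)
    opt_d = Adam(disc.params(), cfg.lr, cfg.beta1, cfg.beta2, cfg.epsilon)
    order = _epoch_order(rng, len(dataset), cfg.steps)
    log: list[dict] = []

    model = DenoisingModel(gen, gen_spec, side, kind="cgan", seed=cfg.seed)
    for step, idx in enumerate(order, start=1):
        pair = dataset[int(idx)]
        x = _to_tensor(pair.input)
        y = _to_tensor(pair.target)

        fake = gen.forward(x, training=True)

        # -- discriminator update ------------------------------------
        opt_d.zero_grad()
        real_logits = disc.forward(np.concatenate([x, y], axis=1), training=True)
        disc.backward(bce_grad(real_logits, 1.0).astype(np.float32))
        l_real = bce_with_logits(real_logits, 1.0)
        fake_logits = disc.forward(np.concatenate([x, fake], axis=1), training=True)
        disc.backward(bce_grad(fake_logits, 0.0).astype(np.float32))
        l_disc = l_real + bce_with_logits(fake_logits, 0.0)
        opt_d.step()

        # -- generator update ----------------------------------------
        opt_g.zero_grad()
        fake_logits = disc.forward(np.concatenate([x, fake], axis=1), training=True)
        l_adv = adversarial_generator_loss(fake_logits)
        g_at_disc_input = disc.backward(bce_grad(fake_logits, 1.0).astype(np.float32))
        g_fake = g_at_disc_input[:, 1:2]  # candidate channel only

        pred01 = (fake.astype(float) + 1.0) / 2.0
        targ01 = (y.astype(float) + 1.0) / 2.0
        l_huber = huber_loss(pred01, targ01, cfg.delta)
        g_h = huber_grad(pred01, targ01, cfg.delta)
        l_ssim, g_s = ssim_loss_and_grad(pred01, targ01, data_range=1.0)
        # chain rule through the [-1,1] -> [0,1] map: d pred01/d fake = 1/2
        g_fake = g_fake + 0.5 * cfg.lambda_dl * (g_h + g_s)
        gen.backward(g_fake.astype(np.float32))
        opt_g.step()

        terms = LossTerms(l_adv=l_adv, l_huber=l_huber, l_ssim=l_ssim, l_disc=l_disc,
                          lambda_dl=cfg.lambda_dl, delta=cfg.delta)
        _finite_or_raise(step, l_disc=l_disc, l_adv=l_adv, l_huber=l_huber, l_ssim=l_ssim)
        log.append({"step": step, "l_disc": l_disc, "l_adv": l_adv, "l_huber": l_huber,
                    "l_ssim": l_ssim, "total_G": generator_objective(terms)})
        model.step = step
        if out_dir is not None and cfg.checkpoint_every and step % cfg.checkpoint_every == 0:
            save_checkpoint(model, _ckpt_path(out_dir, f"cgan_step{step:06d}"))
    if out_dir is not None:
        save_checkpoint(model, _ckpt_path(out_dir, "cgan_final"))
        _write_log_csv(out_dir, log)
    return model, log


def train_unet(
    dataset: list[PairedSample],
    spec: GeneratorSpec | None = None,
    cfg: TrainConfig = TrainConfig(),
    out_dir=None,
) -> tuple[DenoisingModel, list[dict]]:
    """Supervised baseline: mean-absolute-error descent, no adversary."""
    side = _check_dataset(dataset)
    spec = spec or GeneratorSpec(base_filters=32)
    rng = np.random.default_rng(cfg.seed)
    net = build_generator(spec, (side, side), rng)
    opt = Adam(net.params(), cfg.lr, cfg.beta1, cfg.beta2, cfg.epsilon)
    order = _epoch_order(rng, len(dataset), cfg.steps)
    log: list[dict] = []
    model = DenoisingModel(net, spec, side, kind="unet", seed=cfg.seed)
    for step, idx in enumerate(order, start=1):
        pair = dataset[int(idx)]
        x = _to_tensor(pair.input)
        y = _to_tensor(pair.target)
        pred = net.forward(x, training=True)
        l_mae = mae_loss(pred, y)
        _finite_or_raise(step, l_mae=l_mae)
        opt.zero_grad()
        net.backward(mae_grad(pred, y).astype(np.float32))
        opt.step()
        log.append({"step": step, "l_mae": l_mae})
        model.step = step
        if out_dir is not None and cfg.checkpoint_every and step % cfg.checkpoint_every == 0:
            save_checkpoint(model, _ckpt_path(out_dir, f"unet_step{step:06d}"))
    if out_dir is not None:
        save_checkpoint(model, _ckpt_path(out_dir, "unet_final"))
        _write_log_csv(out_dir, log)
    return model, log


def denoise(image, model: DenoisingModel, stochastic: bool = False):
    """Inference wrapper: shape-preserving denoising of one image."""
    return model.denoise(image, stochastic=stochastic)


def _ckpt_path(out_dir, stem: str):
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out / stem


def _write_log_csv(out_dir, log: list[dict]) -> None:
    import csv
    import pathlib

    if not log:
        return
    path = pathlib.Path(out_dir) / "training_log.csv"
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=list(log[0].keys()))
        writer.writeheader()
        writer.writerows(log)
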