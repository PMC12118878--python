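"""Synthetic noise injection and noise-profile characterization.

Corruption operators
--------------------
Four standard models used to probe denoiser robustness:

* Gaussian: ``out = img + N(0, sigma^2)`` i.i.d. per pixel.
* Poisson: ``out = Poisson(img * scale) / scale`` — shot noise whose
  variance per pixel equals ``mean / scale``.
* Salt & pepper: an exact fraction of pixels (uniformly chosen without
  replacement) destroyed to the range extremes, salt/pepper 50/50.
* Speckle: ``out = img * (1 + u)`` with ``u ~ Uniform(-a, a)``,
  ``a = sqrt(3 v)`` so ``var(u) = v``.

No operator clips its output; clipping to the storage range happens only
at file write so that measured residual statistics stay unbiased.

Noise profiles
--------------
The spectral fingerprint of an imaging system's noise: the log-compressed
squared FFT magnitude ``log(1 + |F|^2)``, DC-centered, optionally
normalized to its maximum. Cross-power spectra and the Pearson
correlation of two flattened log-power spectra quantify how similar two
systems' noise floors are (dissimilar platforms fall well below 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .image import Image2D, as_pixels, like

__all__ = [
    "NoiseSpec",
    "NoiseProfile",
    "add_gaussian",
    "add_poisson",
    "add_salt_pepper",
    "add_speckle",
    "apply_noise",
    "log_power_spectrum",
    "cross_power_spectrum",
    "spectrum_correlation",
    "estimate_noise_sigma",
]

NOISE_KINDS = ("gaussian", "poisson", "salt_pepper", "speckle")


@dataclass(frozen=True)
class NoiseSpec:
    """A named corruption with its parameters and seed.

    params: gaussian -> {"sigma"}, poisson -> {"scale"},
    salt_pepper -> {"density"}, speckle -> {"variance"}.
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        p = dict(self.params)
        if self.kind == "gaussian" and p.get("sigma", 0.1) < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "poisson" and p.get("scale", 100.0) <= 0:
            raise ValueError("scale must be > 0")
        if self.kind == "salt_pepper" and not 0 <= p.get("density", 0.1) <= 1:
            raise ValueError("density must be in [0, 1]")
        if self.kind == "speckle" and p.get("variance", 0.1) < 0:
            raise ValueError("variance must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, "params": dict(self.params), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "NoiseSpec":
        return cls(kind=d["kind"], params=dict(d.get("params", {})), seed=int(d.get("seed", 0)))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def add_gaussian(img, sigma: float, seed=0):
    """Additive i.i.d. Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    px = as_pixels(img)
    if sigma == 0:
        return like(img, px.copy())
    return like(img, px + _rng(seed).normal(0.0, sigma, px.shape))


def add_poisson(img, scale: float = 100.0, seed=0):
    """Scaled-count shot noise: ``Poisson(img * scale) / scale``."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    px = as_pixels(img)
    if np.any(px < 0):
        raise ValueError("Poisson noise requires a non-negative image")
    return like(img, _rng(seed).poisson(px * scale) / scale)


def add_salt_pepper(img, density: float = 0.1, seed=0):
    """Destroy an exact ``round(density * N)`` pixels to the range extremes."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    px = as_pixels(img).copy()
    if isinstance(img, Image2D):
        lo, hi = img.value_range
    else:
        lo, hi = 0.0, 1.0
    n = px.size
    n_hit = int(round(density * n))
    if n_hit:
        rng = _rng(seed)
        flat_idx = rng.choice(n, size=n_hit, replace=False)
        salt = rng.random(n_hit) < 0.5
        flat = px.reshape(-1)
        flat[flat_idx[salt]] = hi
        flat[flat_idx[~salt]] = lo
    return like(img, px)


def add_speckle(img, variance: float = 0.1, seed=0):
    """Multiplicative speckle: ``img * (1 + Uniform(-a, a))``, ``a = sqrt(3 v)``."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    px = as_pixels(img)
    if variance == 0:
        return like(img, px.copy())
    a = np.sqrt(3.0 * variance)
    u = _rng(seed).uniform(-a, a, px.shape)
    return like(img, px * (1.0 + u))


def apply_noise(img, spec: NoiseSpec):
    """Dispatch a :class:`NoiseSpec` onto an image."""
    p = dict(spec.params)
    if spec.kind == "gaussian":
        return add_gaussian(img, p.get("sigma", 0.1), spec.seed)
    if spec.kind == "poisson":
        return add_poisson(img, p.get("scale", 100.0), spec.seed)
    if spec.kind == "salt_pepper":
        return add_salt_pepper(img, p.get("density", 0.1), spec.seed)
    return add_speckle(img, p.get("variance", 0.1), spec.seed)


# --------------------------------------------------------------------------
# noise-profile characterization


@dataclass
class NoiseProfile:
    """Log-compressed, DC-centered power spectrum of one image.

    ``log_power = log(1 + |FFT2|^2)`` after a quadrant swap so the zero
    frequency sits at the array center. ``spectrum`` keeps the centered
    complex FFT so cross-power spectra can be formed later.
    """

    log_power: np.ndarray
    normalized: bool
    source_id: str = ""
    spectrum: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.log_power.shape  # type: ignore[return-value]


def log_power_spectrum(img, normalize: bool = True, source_id: str = "") -> NoiseProfile:
    """Log-squared-magnitude FFT spectrum, optionally peak-normalized.

    Normalization divides the log-compressed spectrum by its maximum so
    profiles from different systems share a [0, 1]-topped dynamic range.
    """
    px = as_pixels(img)
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite values")
    F = np.fft.fftshift(np.fft.fft2(px))
    P = np.log1p(np.abs(F) ** 2)
    if normalize:
        m = P.max()
        if m == 0:
            raise ValueError("degenerate spectrum: all-zero image cannot be normalized")
        P = P / m
    return NoiseProfile(log_power=P, normalized=normalize, source_id=source_id, spectrum=F)


def cross_power_spectrum(a: NoiseProfile, b: NoiseProfile) -> np.ndarray:
    """``log(1 + |F_a conj(F_b)|)`` on the same centered frequency grid."""
    if a.spectrum is None or b.spectrum is None:
        raise ValueError("cross power requires profiles built by log_power_spectrum")
    if a.spectrum.shape != b.spectrum.shape:
        raise ValueError(f"shape mismatch: {a.spectrum.shape} vs {b.spectrum.shape}")
    return np.log1p(np.abs(a.spectrum * np.conj(b.spectrum)))


def spectrum_correlation(a: NoiseProfile, b: NoiseProfile) -> float:
    """Pearson correlation of the two flattened log-power spectra."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    x = a.log_power.ravel()
    y = b.log_power.ravel()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance spectrum has no defined correlation")
    return float(np.corrcoef(x, y)[0, 1])


def estimate_noise_sigma(img) -> float:
    """Robust additive-noise std estimate (wavelet-diagonal MAD).

    Single-channel wavelet median-absolute-deviation estimator; the
    finest-scale diagonal detail coefficients of a smooth image are
    dominated by the noise, and the MAD of a Gaussian rescales to its std.
    """
    px = as_pixels(img)
    if min(px.shape) < 8:
        raise ValueError("image too small for noise estimation (need >= 8x8)")
    from skimage.restoration import estimate_sigma

    return float(estimate_sigma(px))
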