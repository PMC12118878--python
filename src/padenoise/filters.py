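"""Classical denoising baselines: Savitzky–Golay, adaptive Wiener, BM3D.

The parameter defaults are the benchmark settings: third-order SG with a
9-sample frame applied along the axial (A-line) direction, a 5x5
pixel-wise adaptive Wiener filter, and BM3D run with an estimated noise
std and all stages (hard thresholding + Wiener refinement). BM3D itself
is an optional external baseline; only its sigma-estimation front end and
stage configuration live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import savgol_filter

from .image import as_pixels, like
from .noise import estimate_noise_sigma

__all__ = [
    "FilterConfig",
    "OptionalBaselineError",
    "savitzky_golay",
    "wiener_adaptive",
    "bm3d_denoise",
]


class OptionalBaselineError(RuntimeError):
    """Raised when an optional external baseline is not installed."""


@dataclass(frozen=True)
class FilterConfig:
    """Classical-filter parameters (defaults are the benchmark settings)."""

    sg_order: int = 3
    sg_frame: int = 9
    sg_bivariate: bool = False
    wiener_window: tuple[int, int] = (5, 5)
    bm3d_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.sg_frame % 2 == 0 or self.sg_frame <= self.sg_order:
            raise ValueError("sg_frame must be odd and greater than sg_order")
        if any(w % 2 == 0 for w in self.wiener_window):
            raise ValueError("wiener window must be odd in both dimensions")


def savitzky_golay(img, order: int = 3, frame: int = 9, bivariate: bool = False):
    """Savitzky–Golay smoothing along the axial (row) direction.

    Each column — one A-line — is convolved with the least-squares
    polynomial kernel of the given order and frame; interior samples equal
    the local polynomial fit, so polynomials up to ``order`` pass through
    unchanged. Edges use mirror padding. ``bivariate=True`` additionally
    filters along the lateral axis (separable application).
    """
    if frame % 2 == 0 or frame <= order:
        raise ValueError("frame must be odd and greater than order")
    px = as_pixels(img)
    if px.shape[0] <= frame:
        raise ValueError(f"frame {frame} must be smaller than image height {px.shape[0]}")
    out = savgol_filter(px, frame, order, axis=0, mode="mirror")
    if bivariate:
        if px.shape[1] <= frame:
            raise ValueError(f"frame {frame} must be smaller than image width {px.shape[1]}")
        out = savgol_filter(out, frame, order, axis=1, mode="mirror")
    return like(img, out)


def wiener_adaptive(img, window: tuple[int, int] = (5, 5)):
    """Pixel-wise adaptive Wiener filter with local mean/variance statistics.

    Per pixel: ``out = mu + max(var - nu2, 0) / max(var, nu2) * (in - mu)``
    where ``mu``/``var`` are the window mean and variance (reflect padding,
    so a constant image is a strict pass-through) and the noise power
    ``nu2`` is the average of all local variances (the standard
    adaptive-filter default when no noise power is supplied). Windows
    flatter than the noise floor collapse to their local mean.
    """
    wh, ww = window
    if wh % 2 == 0 or ww % 2 == 0:
        raise ValueError("window must be odd in both dimensions")
    px = as_pixels(img)
    if wh > px.shape[0] or ww > px.shape[1]:
        raise ValueError(f"window {window} larger than image {px.shape}")
    size = (wh, ww)
    mu = uniform_filter(px, size=size, mode="reflect")
    mu2 = uniform_filter(px * px, size=size, mode="reflect")
    var = mu2 - mu * mu
    nu2 = var.mean()
    denom = np.maximum(var, nu2)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(denom > 0, np.maximum(var - nu2, 0.0) / np.where(denom > 0, denom, 1.0), 0.0)
    return like(img, mu + gain * (px - mu))


def bm3d_denoise(img, sigma: float | None = None):
    """BM3D with estimated sigma and all stages (optional external baseline).

    ``sigma=None`` estimates the noise std from the image first. A
    requested ``sigma=0`` returns the input unchanged (documented
    convention: nothing to remove). If the ``bm3d`` package is not
    installed this raises :class:`OptionalBaselineError` — never a silent
    fallback to another filter.
    """
    px = as_pixels(img)
    if sigma is None:
        sigma = estimate_noise_sigma(px)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return like(img, px.copy())
    try:
        import bm3d as _bm3d
    except ImportError as exc:  # pragma: no cover - exercised when bm3d absent
        raise OptionalBaselineError(
            "optional baseline missing: the 'bm3d' package is not installed; "
            "install it to run the BM3D baseline (pip install bm3d)"
        ) from exc
    out = _bm3d.bm3d(px, sigma_psd=sigma, stage_arg=_bm3d.BM3DStages.ALL_STAGES)
    return like(img, np.asarray(out, dtype=float))
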