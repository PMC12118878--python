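"""Structural similarity (SSIM) with an analytic gradient.

The forward pass follows the standard definition: local means, variances
and covariance taken with an 11x11 Gaussian window (sigma 1.5), stability
constants C1 = (0.01 L)^2 and C2 = (0.03 L)^2 for dynamic range L, and the
mean SSIM taken over the window-valid interior (edges cropped by half the
window). The backward pass chain-rules through the five Gaussian blurs;
the blur adjoint is approximated by the blur itself (the Gaussian kernel
is symmetric, so the approximation is exact away from the reflected
boundary and only slightly off within half a window of it — irrelevant
for a training signal).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["ssim_map", "ssim_value", "ssim_and_grad"]

WIN_SIZE = 11
SIGMA = 1.5
# truncate chosen so the Gaussian kernel has exactly WIN_SIZE taps per axis
_TRUNCATE = (WIN_SIZE - 1) / 2 / SIGMA
_PAD = (WIN_SIZE - 1) // 2


def _blur(x: np.ndarray) -> np.ndarray:
    return gaussian_filter(x, sigma=SIGMA, truncate=_TRUNCATE, mode="reflect")


def _terms(x: np.ndarray, y: np.ndarray, data_range: float):
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    ux, uy = _blur(x), _blur(y)
    uxx, uyy, uxy = _blur(x * x), _blur(y * y), _blur(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    a1 = 2 * ux * uy + c1
    a2 = 2 * vxy + c2
    b1 = ux * ux + uy * uy + c1
    b2 = vx + vy + c2
    return ux, uy, vx, vy, vxy, a1, a2, b1, b2


def ssim_map(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> np.ndarray:
    """Pixelwise SSIM map of two equal-shape 2D arrays."""
    *_, a1, a2, b1, b2 = _terms(np.asarray(x, float), np.asarray(y, float), data_range)
    return (a1 * a2) / (b1 * b2)


def ssim_value(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    """Mean SSIM over the window-valid interior (edge-cropped)."""
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape) < WIN_SIZE:
        raise ValueError(f"image smaller than the {WIN_SIZE}x{WIN_SIZE} SSIM window")
    s = ssim_map(x, y, data_range)
    return float(s[_PAD:-_PAD, _PAD:-_PAD].mean())


def ssim_and_grad(x: np.ndarray, y: np.ndarray, data_range: float = 1.0):
    """Mean SSIM and its gradient with respect to ``x``.

    Returns ``(value, grad)`` where ``grad`` has the shape of ``x``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape) < WIN_SIZE:
        raise ValueError(f"image smaller than the {WIN_SIZE}x{WIN_SIZE} SSIM window")
    ux, uy, vx, vy, vxy, a1, a2, b1, b2 = _terms(x, y, data_range)
    s = (a1 * a2) / (b1 * b2)
    value = float(s[_PAD:-_PAD, _PAD:-_PAD].mean())

    # d(mean over crop)/dS
    gs = np.zeros_like(s)
    interior = gs[_PAD:-_PAD, _PAD:-_PAD]
    interior += 1.0 / interior.size

    denom = b1 * b2
    g_a1 = gs * a2 / denom
    g_a2 = gs * a1 / denom
    g_b1 = -gs * s / b1
    g_b2 = -gs * s / b2

    # gradients w.r.t. the blurred statistics
    g_ux = 2 * uy * g_a1 + 2 * ux * g_b1 - 2 * ux * g_b2 - uy * 2 * g_a2
    g_uxx = g_b2
    g_uxy = 2 * g_a2
    # chain through the blurs (adjoint ~ blur, symmetric kernel)
    grad = _blur(g_ux) + 2 * x * _blur(g_uxx) + y * _blur(g_uxy)
    return value, grad
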