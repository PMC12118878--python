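"""No-reference image-quality metrics over declared ROI/background boxes.

* ``SNR = mu_ROI / sigma_BG`` — mean signal amplitude over background
  noise std, reported as a plain ratio (arbitrary units, not dB).
* ``CNR = sigma_ROI / sigma_BG`` — ROI variability over background std.
* ``GCNR = 1 - integral min(p1, p2) dI`` — one minus the overlap of the
  two regions' intensity distributions, estimated from histograms over
  shared bin edges; bounded in [0, 1], invariant under any common
  monotone intensity remapping (bins recomputed on the remapped range).

Values are computed on pixel values as-is (no absolute value), so images
that go negative after filtering are measured faithfully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image import ROISpec

__all__ = ["MetricResult", "snr", "cnr", "gcnr", "evaluate_image"]

DEFAULT_GCNR_BINS = 256


@dataclass(frozen=True)
class MetricResult:
    snr: float
    cnr: float
    gcnr: float


def _sigma_bg(img, roi: ROISpec) -> float:
    s = float(np.std(roi.background(img)))
    if s == 0:
        raise ValueError("degenerate background: zero variance in background box")
    return s


def snr(img, roi: ROISpec) -> float:
    """Mean of the signal box over the std of the background box."""
    return float(np.mean(roi.signal(img))) / _sigma_bg(img, roi)


def cnr(img, roi: ROISpec) -> float:
    """Std of the signal box over the std of the background box."""
    return float(np.std(roi.signal(img))) / _sigma_bg(img, roi)


def gcnr(img, roi: ROISpec, bins: int = DEFAULT_GCNR_BINS) -> float:
    """Generalized CNR: 1 minus the histogram overlap of the two regions.

    Histograms share bin edges spanning the pooled value range and are
    normalized to unit mass, so the overlap approximates
    ``integral min(p1, p2) dI``. Identical distributions give 0, fully
    separated ones give 1. A zero-width pooled range (both regions one
    constant) counts as complete overlap and returns 0 with a warning.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    s = np.ravel(roi.signal(img))
    b = np.ravel(roi.background(img))
    lo = min(s.min(), b.min())
    hi = max(s.max(), b.max())
    if hi == lo:
        warnings.warn("gcnr: zero-width pooled intensity range; returning 0 (identical distributions)")
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    h1, _ = np.histogram(s, bins=edges)
    h2, _ = np.histogram(b, bins=edges)
    p1 = h1 / h1.sum()
    p2 = h2 / h2.sum()
    ovl = np.minimum(p1, p2).sum()
    return float(np.clip(1.0 - ovl, 0.0, 1.0))


def evaluate_image(img, roi: ROISpec, bins: int = DEFAULT_GCNR_BINS) -> MetricResult:
    """SNR, CNR and GCNR of one image over one ROI spec."""
    return MetricResult(snr=snr(img, roi), cnr=cnr(img, roi), gcnr=gcnr(img, roi, bins=bins))
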