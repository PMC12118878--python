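"""Core image containers for the photoacoustic denoising pipeline.

Conventions
-----------
* An image is a single-channel 2D float array: rows are axial (z, depth),
  columns are lateral (x, scan direction).
* Generated images live in the nominal ``[0, 1]`` storage range; any
  rescaling required by a neural network is owned by the network wrapper,
  not by the container.
* Float32 TIFF is the canonical on-disk format (lossless for our data).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "Image2D",
    "PairedSample",
    "ROISpec",
    "ScanSeries",
    "as_pixels",
    "read_image",
    "write_image",
]

MIN_SIDE = 16


@dataclass
class Image2D:
    """Single-channel float image with spacing and range metadata.

    Parameters
    ----------
    pixels:
        2D float array, rows = axial (z), cols = lateral (x).
    value_range:
        Declared nominal storage range. Generation clamps to this range;
        intermediate processing (e.g. additive noise before measurement)
        may exceed it and is clipped only at file write.
    pixel_spacing_mm:
        ``(dz, dx)`` spacing in millimetres.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)
    pixel_spacing_mm: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < MIN_SIDE:
            raise ValueError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        lo, hi = self.value_range
        if not hi > lo:
            raise ValueError("value_range must be (lo, hi) with hi > lo")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """Copy of this image with new pixel data, same metadata."""
        return dataclasses.replace(self, pixels=np.asarray(pixels, dtype=float))

    def clipped(self) -> "Image2D":
        lo, hi = self.value_range
        return self.with_pixels(np.clip(self.pixels, lo, hi))


def as_pixels(img: "Image2D | np.ndarray") -> np.ndarray:
    """Pixel array of an :class:`Image2D` or a bare ndarray (pass-through)."""
    if isinstance(img, Image2D):
        return img.pixels
    return np.asarray(img, dtype=float)


def like(template: "Image2D | np.ndarray", pixels: np.ndarray):
    """Wrap ``pixels`` in the same container kind as ``template``."""
    if isinstance(template, Image2D):
        return template.with_pixels(pixels)
    return np.asarray(pixels, dtype=float)


@dataclass
class PairedSample:
    """A (noisy input, clean target) training pair with provenance.

    ``meta`` records how the pair was made (noise model and parameters or
    frame-average counts, plus the seed), so the pair is reproducible.
    """

    input: Image2D
    target: Image2D
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input.shape != self.target.shape:
            raise ValueError(
                f"input/target shape mismatch: {self.input.shape} vs {self.target.shape}"
            )


@dataclass(frozen=True)
class ROISpec:
    """Rectangular signal and background regions, 0-based half-open bounds.

    ``signal_box`` and ``background_box`` are ``(row0, col0, row1, col1)``.
    The signal box is where SNR's mean and CNR's std are taken; the
    background box supplies the noise std for both ratios.
    """

    signal_box: tuple[int, int, int, int]
    background_box: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for name, box in (("signal_box", self.signal_box), ("background_box", self.background_box)):
            r0, c0, r1, c1 = box
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"{name} is empty: {box}")
            if (r1 - r0) * (c1 - c0) < 4:
                raise ValueError(f"{name} must contain at least 4 pixels: {box}")
        if self._overlaps(self.signal_box, self.background_box):
            raise ValueError("signal and background boxes must be disjoint")

    @staticmethod
    def _overlaps(a, b) -> bool:
        ar0, ac0, ar1, ac1 = a
        br0, bc0, br1, bc1 = b
        return ar0 < br1 and br0 < ar1 and ac0 < bc1 and bc0 < ac1

    def validate_for(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for name, (r0, c0, r1, c1) in (
            ("signal_box", self.signal_box),
            ("background_box", self.background_box),
        ):
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError(f"{name} {self.signal_box} outside image of shape {shape}")

    def signal(self, img: "Image2D | np.ndarray") -> np.ndarray:
        px = as_pixels(img)
        self.validate_for(px.shape)
        r0, c0, r1, c1 = self.signal_box
        return px[r0:r1, c0:c1]

    def background(self, img: "Image2D | np.ndarray") -> np.ndarray:
        px = as_pixels(img)
        self.validate_for(px.shape)
        r0, c0, r1, c1 = self.background_box
        return px[r0:r1, c0:c1]


@dataclass
class ScanSeries:
    """Ordered raster-scan B-scan sequence over a (possibly bleaching) target.

    One frame per lateral scan position; ``pulses_per_position`` pulses were
    averaged into each frame; ``peak_amplitudes[k]`` is the per-position peak
    signal used by the photobleaching quantification.
    """

    frames: list[Image2D]
    positions_mm: np.ndarray
    pulses_per_position: int
    peak_amplitudes: np.ndarray
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        n = len(self.frames)
        if not (len(self.positions_mm) == n and len(self.peak_amplitudes) == n):
            raise ValueError("frames, positions_mm and peak_amplitudes must have equal length")
        if n >= 2 and not np.all(np.diff(self.positions_mm) > 0):
            raise ValueError("positions_mm must be strictly increasing")
        if self.pulses_per_position < 1:
            raise ValueError("pulses_per_position must be >= 1")

    def __len__(self) -> int:
        return len(self.frames)


def write_image(path, img: "Image2D | np.ndarray", clip: bool = True) -> None:
    """Write an image as 32-bit float TIFF (clipped to its declared range)."""
    import tifffile

    px = as_pixels(img)
    if clip and isinstance(img, Image2D):
        lo, hi = img.value_range
        px = np.clip(px, lo, hi)
    tifffile.imwrite(str(path), px.astype(np.float32))


def read_image(path, pixel_spacing_mm=(0.1, 0.1)) -> Image2D:
    """Read a float TIFF (or any single-channel image tifffile can open)."""
    import tifffile

    px = np.asarray(tifffile.imread(str(path)), dtype=float)
    if px.ndim != 2:
        raise ValueError(f"expected a single-channel 2D image in {path}, got shape {px.shape}")
    lo = min(0.0, float(px.min()))
    hi = max(1.0, float(px.max()))
    return Image2D(px, value_range=(lo, hi), pixel_spacing_mm=pixel_spacing_mm)


def save_series_hdf5(path, series: ScanSeries) -> None:
    """Persist a :class:`ScanSeries` (frames/positions/peaks + meta attrs)."""
    import h5py

    with h5py.File(str(path), "w") as f:
        f.create_dataset("frames", data=np.stack([fr.pixels for fr in series.frames]).astype(np.float32))
        f.create_dataset("positions_mm", data=series.positions_mm)
        f.create_dataset("peak_amplitudes", data=series.peak_amplitudes)
        f.attrs["pulses_per_position"] = series.pulses_per_position
        for k, v in series.meta.items():
            if isinstance(v, (int, float, str, bool)):
                f.attrs[k] = v


def load_series_hdf5(path) -> ScanSeries:
    import h5py

    with h5py.File(str(path), "r") as f:
        frames = [Image2D(fr) for fr in np.asarray(f["frames"], dtype=float)]
        series = ScanSeries(
            frames=frames,
            positions_mm=np.asarray(f["positions_mm"]),
            pulses_per_position=int(f.attrs["pulses_per_position"]),
            peak_amplitudes=np.asarray(f["peak_amplitudes"]),
            meta={k: f.attrs[k] for k in f.attrs if k != "pulses_per_position"},
        )
    return series
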