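"""Turn a normalized (unwrapped) iris image into the spectral pipeline's vector.

The chain is: complex 2-D Gabor filtering -> keep the radial half of the
rows adjacent to the pupil (where iris texture concentrates) -> JPEG-style
zigzag scan of the real and imaginary parts -> concatenate -> remove the
overall mean.  The zigzag traversal suppresses the strong row/column
periodicity that a raster scan would imprint on the estimated spectrum.

Segmentation and rubber-sheet normalization are upstream concerns: inputs
here are already rectangular, grayscale, pupil-at-one-edge rasters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "NormalizedIrisImage",
    "GaborParams",
    "VectorizedIris",
    "gabor_kernel",
    "gabor_filter",
    "inner_half_crop",
    "zigzag_indices",
    "zigzag_scan",
    "inverse_zigzag",
    "vectorize",
    "preprocess_image",
    "load_normalized_image",
]

PupilSide = Literal["top", "bottom"]


@dataclass(frozen=True)
class NormalizedIrisImage:
    """Rectangular grayscale iris raster with the pupil along one edge."""

    pixels: np.ndarray
    pupil_side: PupilSide = "top"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("pixels must be an H x W matrix with H, W >= 2")
        if not np.isfinite(px).all():
            raise ValueError("pixels must be finite")
        if self.pupil_side not in ("top", "bottom"):
            raise ValueError("pupil_side must be 'top' or 'bottom'")


@dataclass(frozen=True)
class GaborParams:
    """Complex Gabor filter parameters.

    f0 is the center frequency in cycles/pixel (horizontal, i.e. angular,
    modulation); sigma is the envelope bandwidth expressed as a fraction of
    the wavelength 1/f0, so the Gaussian envelope standard deviation is
    sigma/f0 pixels.  kernel_size=None truncates at +/- 3 envelope SDs.
    Defaults f0 = 1/9, sigma = 0.5 follow common iris-encoding practice.
    """

    f0: float = 1.0 / 9.0
    sigma: float = 0.5
    kernel_size: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.f0 < 0.5:
            raise ValueError("f0 must lie in (0, 0.5) cycles/pixel")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel_size is not None:
            if self.kernel_size < 1 or self.kernel_size % 2 == 0:
                raise ValueError("kernel_size must be a positive odd integer")

    @property
    def envelope_sd(self) -> float:
        """Gaussian envelope standard deviation in pixels."""
        return self.sigma / self.f0


@dataclass(frozen=True)
class VectorizedIris:
    """Zero-mean real vector feeding the AR/spectral stages."""

    values: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "source_shape", tuple(int(s) for s in self.source_shape))
        if vals.ndim != 1 or vals.size % 2:
            raise ValueError("values must be a 1-D vector of even length")
        if abs(float(vals.mean())) > 1e-9:
            raise ValueError("values must be zero-mean")

    def __len__(self) -> int:
        return self.values.size

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, fmt="%.17g", header="value", comments="")


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Complex 2-D Gabor kernel, DC-compensated so a constant image maps to ~0.

    Gaussian envelope (isotropic, SD = sigma/f0 pixels) times a horizontal
    complex exponential at f0 cycles/pixel.  DC compensation subtracts a
    scaled copy of the envelope so the kernel integrates to exactly zero.
    """
    sd = params.envelope_sd
    half = (params.kernel_size // 2) if params.kernel_size else max(1, int(np.ceil(3 * sd)))
    coords = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    envelope = np.exp(-(xx**2 + yy**2) / (2 * sd**2))
    kern = envelope * np.exp(2j * np.pi * params.f0 * xx)
    kern = kern - envelope * (kern.sum() / envelope.sum())
    return kern


def gabor_filter(
    image: NormalizedIrisImage | np.ndarray, params: GaborParams = GaborParams()
) -> np.ndarray:
    """Convolve the image with the complex Gabor kernel (reflect padding)."""
    pixels = image.pixels if isinstance(image, NormalizedIrisImage) else np.asarray(image, float)
    if not np.isfinite(pixels).all():
        raise ValueError("image contains non-finite pixels")
    kern = gabor_kernel(params)
    real = ndimage.convolve(pixels, kern.real, mode="reflect")
    imag = ndimage.convolve(pixels, kern.imag, mode="reflect")
    return real + 1j * imag


def inner_half_crop(filtered: np.ndarray, pupil_side: PupilSide) -> np.ndarray:
    """Keep the ceil(H/2) rows adjacent to the pupil edge."""
    if pupil_side not in ("top", "bottom"):
        raise ValueError("pupil_side must be 'top' or 'bottom'")
    h = filtered.shape[0]
    keep = (h + 1) // 2
    return filtered[:keep] if pupil_side == "top" else filtered[h - keep :]


def zigzag_indices(rows: int, cols: int) -> list[tuple[int, int]]:
    """JPEG-style anti-diagonal traversal order starting at (0, 0)."""
    order: list[tuple[int, int]] = []
    for s in range(rows + cols - 1):
        if s % 2 == 0:  # walk up-right: row index descending
            for i in range(min(s, rows - 1), max(-1, s - cols), -1):
                order.append((i, s - i))
        else:  # walk down-left: column index descending
            for j in range(min(s, cols - 1), max(-1, s - rows), -1):
                order.append((s - j, j))
    return order


def zigzag_scan(m: np.ndarray) -> np.ndarray:
    """Flatten a matrix in zigzag order (a bijective, energy-preserving reorder)."""
    m = np.asarray(m)
    idx = zigzag_indices(*m.shape)
    ii, jj = zip(*idx)
    return m[np.asarray(ii), np.asarray(jj)]


def inverse_zigzag(seq: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Invert :func:`zigzag_scan` back to a matrix of the given shape."""
    seq = np.asarray(seq)
    if seq.size != shape[0] * shape[1]:
        raise ValueError("sequence length does not match target shape")
    out = np.empty(shape, dtype=seq.dtype)
    idx = zigzag_indices(*shape)
    ii, jj = zip(*idx)
    out[np.asarray(ii), np.asarray(jj)] = seq
    return out


def vectorize(filtered_half: np.ndarray) -> VectorizedIris:
    """Concatenate zigzag scans of real and imaginary parts, then center.

    The overall mean is removed once, after concatenation, so the output is
    the zero-mean real vector the AR stage models.
    """
    filtered_half = np.asarray(filtered_half)
    flat = np.concatenate(
        [zigzag_scan(filtered_half.real), zigzag_scan(filtered_half.imag)]
    ).astype(float)
    flat -= flat.mean()
    # guard against accumulated rounding in the mean removal
    flat -= flat.mean()
    return VectorizedIris(values=flat, source_shape=filtered_half.shape)


def preprocess_image(
    image: NormalizedIrisImage, params: GaborParams = GaborParams()
) -> VectorizedIris:
    """Full chain: Gabor filter -> pupil-side half crop -> zigzag vectorize."""
    filtered = gabor_filter(image, params)
    half = inner_half_crop(filtered, image.pupil_side)
    return vectorize(half)


def load_normalized_image(path, pupil_side: PupilSide = "top") -> NormalizedIrisImage:
    """Read a grayscale PNG/TIFF/BMP raster (RGB inputs are channel-averaged)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return NormalizedIrisImage(pixels=arr, pupil_side=pupil_side)
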