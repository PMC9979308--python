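"""Image preprocessing operators: wavelet denoising, top-hats, enhancement.

Acquired MR magnitude images arrive noisy and low-contrast; before any
quantitative use they are typically (1) denoised in a shift-tolerant wavelet
frame, (2) probed for small bright/dark features with morphological top-hat
residues, and (3) contrast-enhanced either pointwise in the spatial domain
or with a radial gain profile in the frequency domain.  All operators map
[0, 1] grayscale images to images of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology

from . import dtwavelet
from .fourier import dc_index, fft2c, ifft2c


# ---------------------------------------------------------------------------
# wavelet denoising

@dataclass(frozen=True)
class WaveletSpec:
    levels: int = 3
    threshold: float = 0.0
    threshold_mode: str = "soft"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError("threshold_mode must be 'soft' or 'hard'")


def dtcwt_denoise(image: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> np.ndarray:
    """Dual-tree wavelet denoising: magnitude-threshold highpass bands.

    Forward dual-tree transform, joint magnitude thresholding of the detail
    coefficients (soft shrinkage or hard keep/kill), inverse transform.
    Threshold 0 is the identity up to filter-bank round-off.
    """
    img = np.asarray(image, dtype=float)
    trees = dtwavelet.forward(img, spec.levels)
    trees = dtwavelet.threshold_magnitude(trees, spec.threshold, spec.threshold_mode)
    out = dtwavelet.inverse(trees)
    return out[: img.shape[0], : img.shape[1]]


# ---------------------------------------------------------------------------
# morphology

@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: boolean footprint anchored at its center."""

    footprint: np.ndarray

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2 or not fp.any():
            raise ValueError("footprint must be a nonempty 2-D boolean array")
        anchor = (fp.shape[0] // 2, fp.shape[1] // 2)
        if not fp[anchor]:
            raise ValueError("footprint must contain its center anchor")
        object.__setattr__(self, "footprint", fp)

    @classmethod
    def square(cls, size: int) -> "StructuringElement":
        return cls(np.ones((size, size), dtype=bool))

    @classmethod
    def disc(cls, radius: int) -> "StructuringElement":
        return cls(morphology.disk(radius).astype(bool))


def opening(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Grayscale opening (erosion then dilation), reflect-padded borders."""
    return ndimage.grey_opening(
        np.asarray(image, dtype=float), footprint=se.footprint, mode="reflect"
    )


def closing(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Grayscale closing (dilation then erosion), reflect-padded borders."""
    return ndimage.grey_closing(
        np.asarray(image, dtype=float), footprint=se.footprint, mode="reflect"
    )


def white_top_hat(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """f - opening(f): bright features smaller than the SE; >= 0 everywhere."""
    img = np.asarray(image, dtype=float)
    return img - opening(img, se)


def black_top_hat(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """closing(f) - f: dark features smaller than the SE; >= 0 everywhere."""
    img = np.asarray(image, dtype=float)
    return closing(img, se) - img


# ---------------------------------------------------------------------------
# spatial (pointwise) enhancement

class PointTransform:
    """Monotone intensity map on [0, 1]."""

    def __call__(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class GammaTransform(PointTransform):
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return np.clip(image, 0.0, 1.0) ** self.gamma


@dataclass(frozen=True)
class LinearStretch(PointTransform):
    """Affine rescale of [min, max] to [0, 1] (constant images map to 0)."""

    def __call__(self, image: np.ndarray) -> np.ndarray:
        lo, hi = float(image.min()), float(image.max())
        if hi <= lo:
            return np.zeros_like(image)
        return (image - lo) / (hi - lo)


@dataclass(frozen=True)
class HistogramEqualization(PointTransform):
    """Rank-preserving histogram equalization (sort-preserving, hence monotone)."""

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return exposure.equalize_hist(np.clip(image, 0.0, 1.0))


@dataclass(frozen=True)
class CustomMonotone(PointTransform):
    """User map, validated to be monotone non-decreasing on a [0, 1] grid."""

    fn: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        grid = np.linspace(0.0, 1.0, 257)
        vals = np.asarray(self.fn(grid), dtype=float)
        if vals.shape != grid.shape or np.any(np.diff(vals) < -1e-12):
            raise ValueError("custom transform must be monotone non-decreasing on [0, 1]")

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return np.asarray(self.fn(image), dtype=float)


def enhance_spatial(image: np.ndarray, transform: PointTransform) -> np.ndarray:
    """Apply a monotone pointwise transform; output clipped to [0, 1]."""
    if not isinstance(transform, PointTransform):
        raise TypeError("transform must be a PointTransform")
    return np.clip(transform(np.asarray(image, dtype=float)), 0.0, 1.0)


# ---------------------------------------------------------------------------
# frequency-domain enhancement

class FrequencyFilter:
    """Radially symmetric nonnegative gain profile over normalized radius."""

    def gain(self, r: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class FlatGain(FrequencyFilter):
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("gain must be nonnegative")

    def gain(self, r: np.ndarray) -> np.ndarray:
        return np.full_like(r, self.value)


@dataclass(frozen=True)
class GaussianHighBoost(FrequencyFilter):
    """gain = 1 + boost * (1 - exp(-r^2 / (2 sigma^2))): unity at DC."""

    sigma: float = 0.25
    boost: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.boost < 0:
            raise ValueError("sigma must be positive and boost nonnegative")

    def gain(self, r: np.ndarray) -> np.ndarray:
        return 1.0 + self.boost * (1.0 - np.exp(-(r**2) / (2 * self.sigma**2)))


@dataclass(frozen=True)
class ButterworthHighPass(FrequencyFilter):
    """gain = offset + (1 - 1 / (1 + (r/cutoff)^(2 order)))."""

    cutoff: float = 0.2
    order: int = 2
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.order < 1 or self.offset < 0:
            raise ValueError("invalid Butterworth parameters")

    def gain(self, r: np.ndarray) -> np.ndarray:
        return self.offset + 1.0 - 1.0 / (1.0 + (r / self.cutoff) ** (2 * self.order))


@dataclass(frozen=True)
class DCOnly(FrequencyFilter):
    """Zero gain everywhere except the DC sample (unit gain there)."""

    def gain(self, r: np.ndarray) -> np.ndarray:
        return (r == 0).astype(float)


def enhance_frequency(image: np.ndarray, filter_spec: FrequencyFilter) -> np.ndarray:
    """fft -> multiply by the radial gain -> ifft -> real part, clip [0, 1]."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    cy, cx = dc_index(img.shape)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot((yy - cy) / (h / 2.0), (xx - cx) / (w / 2.0))
    g = np.asarray(filter_spec.gain(r), dtype=float)
    if (g < 0).any():
        raise ValueError("negative gains are not allowed")
    out = np.real(ifft2c(fft2c(img) * g))
    return np.clip(out, 0.0, 1.0)
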