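"""Centered unitary 2-D Fourier operators shared by all reconstructors.

MR data live in k-space, the 2-D Fourier domain of the image.  Every
reconstructor in this package phrases its data-fidelity term through the
pair below, which is normalized so that ``ifft2c(fft2c(x)) == x`` and
``norm(fft2c(x)) == norm(x)`` (Parseval).  The zero frequency (DC) sits at
the array center.
"""

from __future__ import annotations

import numpy as np


def _check_2d(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got ndim={a.ndim}")
    return a


def fft2c(image: np.ndarray) -> np.ndarray:
    """Centered, unitary 2-D FFT (image -> k-space)."""
    x = _check_2d(image, "image")
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Centered, unitary 2-D inverse FFT (k-space -> image, complex)."""
    y = _check_2d(kspace, "kspace")
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(y), norm="ortho"))


def dc_index(shape: tuple[int, int]) -> tuple[int, int]:
    """Index of the zero-frequency sample in the centered k-space layout."""
    return (shape[0] // 2, shape[1] // 2)


def zero_filled(kspace: np.ndarray) -> np.ndarray:
    """Zero-filled reconstruction: real part of the inverse transform.

    The baseline every reconstructor must beat: missing k-space entries are
    left at zero, which manifests as aliasing/blurring in image space.
    """
    return np.real(ifft2c(kspace))
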