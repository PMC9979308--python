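"""Dual-tree wavelet frame used by the denoising front end.

A dual-tree transform runs two wavelet filter banks whose outputs form the
real and imaginary parts of approximately analytic complex coefficients;
thresholding the coefficient *magnitude* is far more shift-tolerant than
thresholding a single critically-sampled DWT.

This implementation realizes the second tree as a one-sample-delayed copy of
the first (the classic first-level construction, applied at every level via
a circular shift of the input), in both image axes — four sub-transforms in
total, each a perfectly reconstructing `pywt` decomposition in
periodization mode.  The four trees are combined into a per-position
coefficient magnitude for thresholding.  Perfect reconstruction is exact;
near-analyticity is approximate (an integer-shift stand-in for the
quarter-sample-delay filter pair).
"""

from __future__ import annotations

import numpy as np
import pywt

_WAVELET = "sym4"  # near-symmetric orthonormal filters
_SHIFTS = ((0, 0), (0, 1), (1, 0), (1, 1))


def max_levels(shape: tuple[int, int]) -> int:
    return int(np.floor(np.log2(min(shape))))


def forward(image: np.ndarray, levels: int) -> list:
    """Four shifted wavelet decompositions of the image (the 'trees')."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if levels < 1 or levels > max_levels(img.shape):
        raise ValueError(f"levels must lie in [1, {max_levels(img.shape)}] for {img.shape}")
    trees = []
    for sy, sx in _SHIFTS:
        shifted = np.roll(img, (sy, sx), axis=(0, 1))
        trees.append(pywt.wavedec2(shifted, _WAVELET, mode="periodization", level=levels))
    return trees


def inverse(trees: list) -> np.ndarray:
    """Average of the four unshifted synthesis transforms."""
    out = None
    for (sy, sx), coeffs in zip(_SHIFTS, trees):
        rec = pywt.waverec2(coeffs, _WAVELET, mode="periodization")
        rec = np.roll(rec, (-sy, -sx), axis=(0, 1))
        out = rec if out is None else out + rec
    return out / len(_SHIFTS)


def threshold_magnitude(trees: list, threshold: float, mode: str = "soft") -> list:
    """Threshold highpass coefficients on their cross-tree magnitude.

    The per-position magnitude is the root-mean-square of the four trees'
    coefficients; each tree's coefficient is scaled by the same attenuation
    factor, so the joint (complex-like) magnitude is what gets shrunk.
    Lowpass (approximation) coefficients are never touched.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if mode not in ("soft", "hard"):
        raise ValueError("mode must be 'soft' or 'hard'")
    if threshold == 0:
        return trees
    n_trees = len(trees)
    n_scales = len(trees[0])
    out = [[trees[t][0]] for t in range(n_trees)]  # keep approximations
    for s in range(1, n_scales):
        scaled = [[] for _ in range(n_trees)]
        for band in range(3):  # horizontal / vertical / diagonal details
            stack = np.stack([trees[t][s][band] for t in range(n_trees)])
            mag = np.sqrt(np.mean(stack**2, axis=0))
            if mode == "soft":
                factor = np.maximum(0.0, 1.0 - threshold / np.maximum(mag, 1e-300))
            else:
                factor = (mag >= threshold).astype(float)
            for t in range(n_trees):
                scaled[t].append(stack[t] * factor)
        for t in range(n_trees):
            out[t].append(tuple(scaled[t]))
    return out
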