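"""Image-quality metrics: PSNR and SSIM.

PSNR is implemented directly (the package needs a distinguished +infinity
sentinel for identical images, which library versions raise or warn on).
SSIM delegates to scikit-image configured with the de-facto standard
parameters of the original structural-similarity index: 11x11 Gaussian
window with sigma 1.5, K1=0.01, K2=0.03, population covariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

PSNR_INF = np.inf  # sentinel for identical images (MSE == 0)


@dataclass(frozen=True)
class QualityReport:
    """One evaluation cell: a method at a sampling rate."""

    psnr_db: float
    ssim: float
    method_label: str = ""
    sampling_rate: float = float("nan")


def _pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    return ref, tst


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical.

    ``10 * log10(data_range**2 / MSE)``.  Images here are normalized to
    [0, 1], hence the default ``data_range`` of 1.0.
    """
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    ref, tst = _pair(reference, test)
    mse = float(np.mean((ref - tst) ** 2))
    if mse <= 1e-24:  # identical to double precision
        return PSNR_INF
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity index (standard stabilized form)."""
    ref, tst = _pair(reference, test)
    win = 11
    if min(ref.shape) < win:
        raise ValueError(f"images smaller than the {win}x{win} SSIM window")
    return float(
        structural_similarity(
            ref,
            tst,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            win_size=win,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def evaluate(
    reference: np.ndarray,
    test: np.ndarray,
    method_label: str = "",
    sampling_rate: float = float("nan"),
    data_range: float = 1.0,
) -> QualityReport:
    return QualityReport(
        psnr_db=psnr(reference, test, data_range),
        ssim=ssim(reference, test, data_range),
        method_label=method_label,
        sampling_rate=sampling_rate,
    )
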