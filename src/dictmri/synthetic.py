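"""Synthetic inputs: phantoms, sampling masks, k-space acquisition, cohorts.

Everything the reconstruction and staging machinery consumes can be generated
here, deterministically from a spec + seed:

* **phantoms** — piecewise-constant compositions of ellipses (anatomy-like
  cross-sections) with small bright discs mimicking nodular features; the
  structure TV and patch dictionaries exploit;
* **sampling masks** — uniform-random, variable-density (radial power-law)
  or radial-line k-space undersampling patterns hitting an exact target rate;
* **acquisition** — the forward model ``y = M (F x + noise)`` with complex
  circular Gaussian k-space noise (the standard MR noise model);
* **cohorts** — staging contingency tables drawn from a stage prior and a
  row-stochastic misclassification matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fourier import dc_index, fft2c
from .staging import StagingTable

MASK_PATTERNS = ("uniform_random", "variable_density", "radial_lines")


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class PhantomSpec:
    height: int = 64
    width: int = 64
    n_ellipses: int = 4
    nodule_count: int = 3
    nodule_radius_px: float = 2.5
    intensity_range: tuple[float, float] = (0.15, 0.95)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom dimensions must be at least 16x16")
        lo, hi = self.intensity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("intensity_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_ellipses < 1:
            raise ValueError("need at least one ellipse")
        if self.nodule_count < 0 or self.nodule_radius_px <= 0:
            raise ValueError("invalid nodule parameters")


@dataclass(frozen=True)
class MaskSpec:
    pattern: str = "variable_density"
    sampling_rate: float = 0.4
    keep_dc: bool = True
    seed: int = 0
    density_decay: float = 2.0  # power-law exponent for variable density

    def __post_init__(self) -> None:
        if self.pattern not in MASK_PATTERNS:
            raise ValueError(f"pattern must be one of {MASK_PATTERNS}")
        if not (0.0 < self.sampling_rate <= 1.0):
            raise ValueError("sampling_rate must lie in (0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    stage_labels: tuple[str, ...]
    stage_prior: tuple[float, ...]
    misclassification: np.ndarray  # row j: P(imaging stage | true stage j)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.stage_labels)
        prior = np.asarray(self.stage_prior, dtype=float)
        mis = np.asarray(self.misclassification, dtype=float)
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if prior.shape != (k,) or mis.shape != (k, k):
            raise ValueError("prior / misclassification shape mismatch with labels")
        if abs(prior.sum() - 1.0) > 1e-12:
            raise ValueError("stage prior must sum to 1")
        if np.any(np.abs(mis.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("each misclassification row must sum to 1")
        if (prior < 0).any() or (mis < 0).any():
            raise ValueError("probabilities must be nonnegative")
        object.__setattr__(self, "stage_prior", tuple(prior))
        object.__setattr__(self, "misclassification", mis)


@dataclass(frozen=True)
class KSpaceSample:
    """Undersampled complex k-space plus its sampling mask."""

    data: np.ndarray
    mask: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=complex)
        mask = np.asarray(self.mask, dtype=bool)
        if data.shape != mask.shape:
            raise ValueError("k-space and mask shapes differ")
        data = np.where(mask, data, 0.0)  # enforce: unsampled entries are zero
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# phantoms

def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Piecewise-constant ellipse phantom with bright disc nodules.

    The first ellipse is a large centered body; subsequent ellipses are
    internal structures painted over it (later regions overwrite earlier
    ones, keeping the image piecewise constant with values in [0, 1]).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    lo, hi = spec.intensity_range

    img = np.full((h, w), 0.0)

    # main body: large centered ellipse at the low end of the intensity range
    body_a, body_b = 0.42 * h, 0.42 * w
    body = ((yy - cy0) / body_a) ** 2 + ((xx - cx0) / body_b) ** 2 <= 1.0
    img[body] = lo

    for _ in range(spec.n_ellipses - 1):
        cy = cy0 + rng.uniform(-0.25, 0.25) * h
        cx = cx0 + rng.uniform(-0.25, 0.25) * w
        a = rng.uniform(0.06, 0.22) * h
        b = rng.uniform(0.06, 0.22) * w
        theta = rng.uniform(0, np.pi)
        val = rng.uniform(lo, hi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        region = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[region & body] = val

    r = spec.nodule_radius_px
    for _ in range(spec.nodule_count):
        cy = cy0 + rng.uniform(-0.3, 0.3) * h
        cx = cx0 + rng.uniform(-0.3, 0.3) * w
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[disc & body] = hi

    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal((h, w))
    return img


# ---------------------------------------------------------------------------
# masks

def make_mask(spec: MaskSpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean k-space sampling mask hitting round(rate * n_pixels) exactly."""
    h, w = shape
    n = h * w
    target = int(round(spec.sampling_rate * n))
    target = max(1, min(n, target))
    rng = np.random.default_rng(spec.seed)
    dc_flat = np.ravel_multi_index(dc_index(shape), shape)

    if spec.pattern == "uniform_random":
        chosen = rng.choice(n, size=target, replace=False)
    elif spec.pattern == "variable_density":
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = dc_index(shape)
        r = np.hypot((yy - cy) / (h / 2.0), (xx - cx) / (w / 2.0)).ravel()
        weights = (1.0 + 8.0 * r) ** (-spec.density_decay)
        p = weights / weights.sum()
        chosen = rng.choice(n, size=target, replace=False, p=p)
    else:  # radial_lines
        chosen = _radial_line_indices(shape, target, rng)

    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    if spec.keep_dc and not mask[dc_flat]:
        # swap one retained non-DC sample for DC so the count is unchanged
        drop = rng.choice(np.flatnonzero(mask))
        mask[drop] = False
        mask[dc_flat] = True
    return mask.reshape(shape)


def _radial_line_indices(shape: tuple[int, int], target: int, rng) -> np.ndarray:
    h, w = shape
    cy, cx = dc_index(shape)
    selected: set[int] = set()
    n_radius = int(np.ceil(np.hypot(h, w)))
    angle = rng.uniform(0, np.pi)
    golden = np.pi * (3 - np.sqrt(5.0))
    while len(selected) < target:
        t = np.linspace(-1, 1, 2 * n_radius)
        ys = np.clip(np.round(cy + t * n_radius * np.sin(angle)), 0, h - 1).astype(int)
        xs = np.clip(np.round(cx + t * n_radius * np.cos(angle)), 0, w - 1).astype(int)
        selected.update(np.ravel_multi_index((ys, xs), shape).tolist())
        angle = (angle + golden) % np.pi
    chosen = np.fromiter(selected, dtype=int)
    if len(chosen) > target:
        dc_flat = np.ravel_multi_index((cy, cx), shape)
        keep = chosen[chosen == dc_flat]
        rest = chosen[chosen != dc_flat]
        rng.shuffle(rest)
        chosen = np.concatenate([keep, rest])[:target]
    return chosen


# ---------------------------------------------------------------------------
# acquisition

def simulate_acquisition(
    image: np.ndarray,
    mask: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> KSpaceSample:
    """Forward model: ``y = mask * (F x + eps)`` with complex Gaussian eps.

    ``noise_sigma`` is the standard deviation of each of the real and
    imaginary noise components in (unitary) k-space.  Unsampled entries are
    stored as zero; the mask travels with the sample.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    y = fft2c(image)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sigma * (
            rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        )
    rate = float(mask.mean())
    return KSpaceSample(data=np.where(mask, y, 0.0), mask=mask, sampling_rate=rate)


# ---------------------------------------------------------------------------
# cohorts

def simulate_cohort(spec: CohortSpec) -> StagingTable:
    """Draw a staging contingency table: true stage from the prior, then the
    imaging call from that stage's misclassification row."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.stage_labels)
    true_counts = rng.multinomial(spec.n_patients, np.asarray(spec.stage_prior))
    counts = np.zeros((k, k), dtype=np.int64)
    for j in range(k):  # true stage j fills column j
        counts[:, j] = rng.multinomial(true_counts[j], spec.misclassification[j])
    return StagingTable(counts=counts, labels=spec.stage_labels)
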