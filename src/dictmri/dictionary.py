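"""Synthetic-dictionary reconstruction: K-SVD learning + OMP sparse coding.

The synthetic route models each (vectorized) image patch y_i as a sparse
combination of learned atoms, ``y_i ~ D x_i`` with ``||x_i||_0 <= T``.
Learning alternates:

* **sparse coding** — orthogonal matching pursuit (OMP) per patch: greedily
  pick the atom most correlated with the residual, re-project the target
  onto the selected atoms, repeat up to T times;
* **atom update** — for each atom in turn, a rank-1 refit (SVD of the
  restricted residual) over the patches currently using it, K-SVD style.

Reconstruction from undersampled k-space interleaves dictionary denoising of
the current image estimate with a hard data-consistency step that restores
the measured k-space samples exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fourier import fft2c, ifft2c, zero_filled
from .synthetic import KSpaceSample


@dataclass(frozen=True)
class PatchConfig:
    patch_size: int = 8
    stride: int = 2
    remove_mean: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.stride <= self.patch_size):
            raise ValueError("require 1 <= stride <= patch_size")


@dataclass
class PatchDictionary:
    """Unit-norm atom matrix (patch_dim x n_atoms) with coding parameters."""

    atoms: np.ndarray
    sparsity_T: int
    train_iters: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("every atom must have unit l2 norm")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def patch_dim(self) -> int:
        return self.atoms.shape[0]


def _grid_starts(extent: int, patch: int, stride: int) -> np.ndarray:
    """Start offsets covering [0, extent-patch] with the last patch clamped."""
    starts = list(range(0, extent - patch + 1, stride))
    if starts[-1] != extent - patch:
        starts.append(extent - patch)
    return np.asarray(starts)


def extract_patches(image: np.ndarray, cfg: PatchConfig) -> np.ndarray:
    """Vectorized overlapping patches as columns, raster order.

    Returns a (patch_size**2, n_patches) matrix.  When ``remove_mean`` is
    set the caller is expected to subtract means itself (see
    ``reconstruct_dict``); extraction is always raw.
    """
    img = np.asarray(image, dtype=float)
    p = cfg.patch_size
    if img.shape[0] < p or img.shape[1] < p:
        raise ValueError("patch larger than image")
    rows = _grid_starts(img.shape[0], p, cfg.stride)
    cols = _grid_starts(img.shape[1], p, cfg.stride)
    out = np.empty((p * p, len(rows) * len(cols)))
    idx = 0
    for r in rows:
        for c in cols:
            out[:, idx] = img[r : r + p, c : c + p].ravel()
            idx += 1
    return out


def reassemble_patches(
    patches: np.ndarray, image_shape: tuple[int, int], cfg: PatchConfig
) -> np.ndarray:
    """Average overlapping patches back into an image (uniform weights)."""
    p = cfg.patch_size
    rows = _grid_starts(image_shape[0], p, cfg.stride)
    cols = _grid_starts(image_shape[1], p, cfg.stride)
    acc = np.zeros(image_shape)
    weight = np.zeros(image_shape)
    idx = 0
    for r in rows:
        for c in cols:
            acc[r : r + p, c : c + p] += patches[:, idx].reshape(p, p)
            weight[r : r + p, c : c + p] += 1.0
            idx += 1
    return acc / weight


def omp_code(y: np.ndarray, dictionary: PatchDictionary, T: int | None = None) -> np.ndarray:
    """Orthogonal matching pursuit for a single target vector."""
    codes = omp_code_batch(np.asarray(y, dtype=float).reshape(-1, 1), dictionary, T)
    return codes[:, 0]


def omp_code_batch(
    Y: np.ndarray, dictionary: PatchDictionary, T: int | None = None
) -> np.ndarray:
    """OMP for every column of ``Y``; returns the (n_atoms x n_cols) codes.

    Greedy selection with full orthogonal re-projection after each pick, so
    the residual stays orthogonal to the selected atoms and its norm is
    non-increasing per step.  Stops early when the residual is numerically
    zero.
    """
    D = dictionary.atoms
    if T is None:
        T = dictionary.sparsity_T
    if T > dictionary.n_atoms:
        warnings.warn("sparsity T exceeds atom count; clipping", stacklevel=2)
        T = dictionary.n_atoms
    Y = np.asarray(Y, dtype=float)
    n_cols = Y.shape[1]
    X = np.zeros((dictionary.n_atoms, n_cols))
    if T == 0:
        return X
    for j in range(n_cols):
        y = Y[:, j]
        resid = y.copy()
        support: list[int] = []
        for _ in range(T):
            corr = D.T @ resid
            corr[support] = 0.0
            k = int(np.argmax(np.abs(corr)))
            if abs(corr[k]) < 1e-12:
                break
            support.append(k)
            coef, *_ = np.linalg.lstsq(D[:, support], y, rcond=None)
            resid = y - D[:, support] @ coef
            if np.linalg.norm(resid) < 1e-12:
                break
        if support:
            X[support, j] = coef
    return X


def _swap_refine(
    y: np.ndarray, D: np.ndarray, support: list[int], max_rounds: int = 8
) -> tuple[list[int], np.ndarray, float]:
    """Single-atom swap descent on the support (subspace-pursuit flavored)."""
    support = list(support)
    coef, *_ = np.linalg.lstsq(D[:, support], y, rcond=None)
    best = float(np.linalg.norm(y - D[:, support] @ coef))
    n_atoms = D.shape[1]
    for _ in range(max_rounds):
        if best < 1e-12:
            break
        improved = False
        for i in range(len(support)):
            for j in range(n_atoms):
                if j in support:
                    continue
                cand = support.copy()
                cand[i] = j
                c, *_ = np.linalg.lstsq(D[:, cand], y, rcond=None)
                r = float(np.linalg.norm(y - D[:, cand] @ c))
                if r < best - 1e-12:
                    best, support = r, cand
                    improved = True
        if not improved:
            break
    coef, *_ = np.linalg.lstsq(D[:, support], y, rcond=None)
    return support, coef, best


class _ExhaustiveCoder:
    """Best T-support coding by enumeration; viable only at toy scale.

    Precomputes an orthonormal basis Q for every size-T support of the
    current dictionary, then scores each candidate support on a target via
    ``||y||^2 - ||Q^T y||^2`` in one einsum.
    """

    def __init__(self, D: np.ndarray, T: int):
        from itertools import combinations

        self.supports = list(combinations(range(D.shape[1]), T))
        qs = np.empty((len(self.supports), D.shape[0], T))
        for i, sup in enumerate(self.supports):
            qs[i], _ = np.linalg.qr(D[:, sup])
        self.qs = qs
        self.D = D

    def code(self, y: np.ndarray) -> tuple[list[int], np.ndarray]:
        proj = np.einsum("sdt,d->st", self.qs, y)
        scores = np.einsum("st,st->s", proj, proj)
        best = int(np.argmax(scores))
        sup = list(self.supports[best])
        coef, *_ = np.linalg.lstsq(self.D[:, sup], y, rcond=None)
        return sup, coef


#: largest number of candidate supports for which exhaustive coding is used
EXACT_CODING_BUDGET = 20000


def code_batch(
    Y: np.ndarray,
    dictionary: PatchDictionary,
    refine: bool = False,
    refine_tol: float = 1e-8,
) -> np.ndarray:
    """Sparse-code every column: OMP, optionally polished per stuck column.

    With ``refine`` on, columns whose OMP residual exceeds ``refine_tol``
    get a single-atom swap descent, and — when the number of size-T
    supports is within ``EXACT_CODING_BUDGET`` — an exhaustive best-support
    search.  Intended for near-exactly-sparse data at toy scale; for image
    patches leave it off.
    """
    X = omp_code_batch(Y, dictionary)
    if not refine:
        return X
    from math import comb

    D = dictionary.atoms
    T = min(dictionary.sparsity_T, dictionary.n_atoms)
    resid2 = np.sum((Y - D @ X) ** 2, axis=0)
    stuck = np.flatnonzero(resid2 > refine_tol)
    if stuck.size == 0:
        return X
    exhaustive = None
    if T >= 1 and comb(dictionary.n_atoms, T) <= EXACT_CODING_BUDGET:
        exhaustive = _ExhaustiveCoder(D, T)
    for j in stuck:
        y = Y[:, j]
        if exhaustive is not None:
            sup, coef = exhaustive.code(y)
        else:
            sup = list(np.flatnonzero(X[:, j]))
            if not sup:
                continue
            sup, coef, _ = _swap_refine(y, D, sup)
        new = np.zeros(dictionary.n_atoms)
        new[sup] = coef
        if np.sum((y - D @ new) ** 2) <= resid2[j]:
            X[:, j] = new
    return X


def _init_atoms(Y: np.ndarray, n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """Seed atoms from random training patches, normalized; degenerate
    (near-zero) picks are replaced by random unit vectors."""
    n = Y.shape[1]
    pick = rng.choice(n, size=n_atoms, replace=n < n_atoms)
    atoms = Y[:, pick].astype(float).copy()
    norms = np.linalg.norm(atoms, axis=0)
    bad = norms < 1e-10
    if bad.any():
        atoms[:, bad] = rng.standard_normal((Y.shape[0], int(bad.sum())))
        norms = np.linalg.norm(atoms, axis=0)
    return atoms / norms


def learn_dictionary(
    Y: np.ndarray,
    n_atoms: int = 256,
    T: int = 8,
    iters: int = 10,
    seed: int = 0,
    refine: bool = False,
    restarts: int = 1,
    stop_rel: float | None = None,
) -> tuple[PatchDictionary, np.ndarray, list[float]]:
    """K-SVD style dictionary learning minimizing ||Y - D X||_F^2, ||x_i||_0 <= T.

    Returns ``(dictionary, codes, objective_trace)``.  The trace starts at
    the objective of the initial dictionary with its OMP codes and, in the
    default mode, is non-increasing: the recoding step keeps, per column,
    whichever of the old and new codes has the smaller residual, and each
    rank-1 atom refit is a best approximation on that atom's support.  Atoms
    that fall out of use are re-seeded from the worst-represented patches.

    ``refine=True`` switches to a recovery mode for (near-)exactly sparse
    data: near-duplicate and barely-used atoms are actively retired and the
    late coding sweeps are polished by swap/exhaustive search.  That escape
    pressure can make the trace transiently non-monotone.  ``restarts`` runs
    independent seeds and keeps the best final objective; ``stop_rel`` stops
    early once ``||Y - DX||_F / ||Y||_F`` falls below it.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.any(Y):
        raise ValueError("cannot learn a dictionary from all-zero data")
    if Y.shape[1] < n_atoms:
        raise ValueError("need at least as many patches as atoms")
    y_norm2 = float(np.linalg.norm(Y) ** 2)
    best: tuple[PatchDictionary, np.ndarray, list[float]] | None = None
    for r in range(max(1, restarts)):
        run = _learn_once(Y, n_atoms, T, iters, seed + 9973 * r, refine, stop_rel)
        if best is None or run[2][-1] < best[2][-1]:
            best = run
        if stop_rel is not None and best[2][-1] <= (stop_rel**2) * y_norm2:
            break
    return best


def _learn_once(
    Y: np.ndarray,
    n_atoms: int,
    T: int,
    iters: int,
    seed: int,
    refine: bool,
    stop_rel: float | None,
) -> tuple[PatchDictionary, np.ndarray, list[float]]:
    rng = np.random.default_rng(seed)
    atoms = _init_atoms(Y, n_atoms, rng)
    dic = PatchDictionary(atoms=atoms, sparsity_T=T, train_iters=iters, seed=seed)
    y_norm2 = float(np.linalg.norm(Y) ** 2)
    # polishing (swap/exhaustive coding) only pays off once the dictionary is
    # close; restrict it to the last third of the refine-mode schedule
    polish_from = (2 * iters) // 3 if refine else iters + 1
    X = omp_code_batch(Y, dic)
    trace = [float(np.linalg.norm(Y - dic.atoms @ X) ** 2)]
    for it in range(iters):
        # --- atom update sweep (K-SVD rank-1 refits)
        D = dic.atoms
        R = Y - D @ X
        for k in range(n_atoms):
            users = np.flatnonzero(X[k])
            if users.size == 0:
                # re-seed toward the worst-represented patch's residual: the
                # direction the current dictionary explains worst
                worst = int(np.argmax(np.sum(R**2, axis=0)))
                d_new = R[:, worst]
                if np.linalg.norm(d_new) < 1e-10:
                    d_new = Y[:, worst]
                nrm = np.linalg.norm(d_new)
                if nrm > 1e-10:
                    D[:, k] = d_new / nrm
                continue
            # restricted residual including atom k's own contribution
            Ek = R[:, users] + np.outer(D[:, k], X[k, users])
            U, s, Vt = np.linalg.svd(Ek, full_matrices=False)
            D[:, k] = U[:, 0]
            X[k, users] = s[0] * Vt[0]
            R[:, users] = Ek - np.outer(D[:, k], X[k, users])
        if refine:
            # maintenance: retire near-duplicate and barely-used atoms toward
            # the worst-represented residual directions; escapes the local
            # minima exact-sparse data is prone to (transiently non-monotone)
            _maintain_atoms(Y, D, X)
        dic = PatchDictionary(atoms=D, sparsity_T=T, train_iters=iters, seed=seed)
        # --- sparse coding sweep, guarded to never increase the objective
        X_new = code_batch(Y, dic, refine=refine and it >= polish_from)
        old_res = np.sum((Y - D @ X) ** 2, axis=0)
        new_res = np.sum((Y - D @ X_new) ** 2, axis=0)
        worse = new_res > old_res
        if worse.any():
            X_new[:, worse] = X[:, worse]
        X = X_new
        trace.append(float(np.linalg.norm(Y - D @ X) ** 2))
        if stop_rel is not None and trace[-1] <= (stop_rel**2) * y_norm2:
            break
    return dic, X, trace


def _maintain_atoms(
    Y: np.ndarray,
    D: np.ndarray,
    X: np.ndarray,
    coherence_max: float = 0.99,
    usage_min: int = 3,
) -> None:
    """Replace redundant atoms in place (refine mode only).

    An atom nearly parallel to another, or used by fewer than ``usage_min``
    patches, is re-seeded from the residual of the worst-represented patch
    and its code row cleared.
    """
    n_atoms = D.shape[1]
    R = Y - D @ X
    err2 = np.sum(R**2, axis=0)
    G = np.abs(D.T @ D)
    np.fill_diagonal(G, 0.0)
    usage = (X != 0).sum(axis=1)
    for k in range(n_atoms):
        if G[k].max() > coherence_max or usage[k] < usage_min:
            worst = int(np.argmax(err2))
            d_new = R[:, worst]
            if np.linalg.norm(d_new) < 1e-10:
                d_new = Y[:, worst]
            nrm = np.linalg.norm(d_new)
            if nrm <= 1e-10:
                continue
            D[:, k] = d_new / nrm
            X[k, :] = 0.0
            err2[worst] = 0.0
            G = np.abs(D.T @ D)
            np.fill_diagonal(G, 0.0)


@dataclass(frozen=True)
class DictReconSpec:
    n_atoms: int = 128
    sparsity_T: int = 6
    train_iters: int = 5
    outer_iters: int = 3
    seed: int = 0
    train_on: str = "self"  # "self": corrupted image's own patches; or "corpus"
    corpus: np.ndarray | None = None  # training patch matrix when train_on="corpus"


@dataclass
class DictReconLog:
    objective_traces: list[list[float]] = field(default_factory=list)
    outer_iterations: int = 0


def reconstruct_dict(
    sample: KSpaceSample,
    cfg: PatchConfig = PatchConfig(),
    spec: DictReconSpec = DictReconSpec(),
) -> tuple[np.ndarray, DictReconLog]:
    """Dictionary-learning reconstruction with hard k-space data consistency.

    Each outer iteration: learn (or reuse) a dictionary on the current
    estimate's mean-removed patches, sparse-code and reassemble them by
    uniform overlap averaging, then overwrite the sampled k-space entries of
    the result with the measured values.  The returned image is complex (see
    ``data_consistency``); its sampled spectrum equals the measurements
    exactly, and ``np.real`` of it is the image estimate.
    """
    x = zero_filled(sample.data).astype(complex)
    log = DictReconLog()
    dic: PatchDictionary | None = None
    for outer in range(spec.outer_iters):
        patches = extract_patches(np.real(x), cfg)
        means = patches.mean(axis=0, keepdims=True) if cfg.remove_mean else 0.0
        centered = patches - means
        if spec.train_on == "corpus" and spec.corpus is not None:
            if dic is None:
                dic, _, trace = learn_dictionary(
                    spec.corpus, spec.n_atoms, spec.sparsity_T, spec.train_iters, spec.seed
                )
                log.objective_traces.append(trace)
        else:
            dic, _, trace = learn_dictionary(
                centered, spec.n_atoms, spec.sparsity_T, spec.train_iters,
                spec.seed + outer,
            )
            log.objective_traces.append(trace)
        codes = omp_code_batch(centered, dic)
        approx = dic.atoms @ codes + means
        x = reassemble_patches(approx, x.shape, cfg)
        x = data_consistency(x, sample)
        log.outer_iterations = outer + 1
    # no clipping/realification after the final consistency step: the
    # sampled k-space entries of the returned image are exactly the data
    return x, log


def data_consistency(image: np.ndarray, sample: KSpaceSample) -> np.ndarray:
    """Replace the sampled k-space entries of ``image`` with the measured y.

    Returns a complex-valued image: because the sampling mask is not
    Hermitian-symmetric, projecting back to a real image would perturb the
    sampled spectrum again.  ``F(out)[mask] == y[mask]`` holds exactly for
    the returned array; its real part is the image estimate.
    """
    k = fft2c(np.real(np.asarray(image)))
    k = np.where(sample.mask, sample.data, k)
    return ifft2c(k)
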