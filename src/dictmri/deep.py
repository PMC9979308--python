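"""Deep-dictionary reconstruction: a small convolutional restoration network.

The third route replaces explicit dictionaries with a convolutional network
h(x) trained to map zero-filled (aliased) reconstructions to clean images.
Training minimizes mean squared error plus an L2 weight-decay penalty,

    H(W, b) = (1/n) sum_i  (1/2) ||h(x_i) - y_i||^2  +  (lambda/2) sum W^2,

by plain (mini-batch) gradient descent:  W <- W - alpha dH/dW,
b <- b - alpha dH/db.  The per-sample data term uses the per-pixel mean
inside the squared norm, so costs are comparable across image sizes; the
decay term excludes biases.  All convolutions are "same" zero-padded, so
spatial shape is preserved through the net.

Everything is numpy: convolutions via im2col (sliding windows + one BLAS
matmul), gradients hand-derived and checked against finite differences in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dictionary import data_consistency
from .fourier import zero_filled
from .synthetic import KSpaceSample

#: (kernel, in_channels, out_channels) of the default restoration net
DEFAULT_ARCH = ((9, 1, 64), (1, 64, 32), (5, 32, 1))


class DivergenceError(RuntimeError):
    """Raised when training produces non-finite gradients or exploding cost."""


@dataclass
class ConvNetParams:
    """Weights/biases of the conv stack plus its training hyperparameters.

    ``weights[l]`` has shape (k, k, c_in, c_out); ReLU is applied after
    every layer except the last (linear output).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    learning_rate: float = 0.1
    weight_decay: float = 0.0
    seed: int = 0
    residual: bool = False  # global skip: h(x) = x + net(x), DnCNN-style

    @property
    def n_params(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    def copy(self) -> "ConvNetParams":
        return ConvNetParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            seed=self.seed,
            residual=self.residual,
        )


def init_net(
    arch: tuple[tuple[int, int, int], ...] = DEFAULT_ARCH,
    learning_rate: float = 0.1,
    weight_decay: float = 0.0,
    seed: int = 0,
    residual: bool = False,
) -> ConvNetParams:
    """He-initialized network; channel chain must be consistent."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    prev_out = arch[0][1]
    for k, cin, cout in arch:
        if cin != prev_out:
            raise ValueError(f"channel mismatch: layer expects {cin}, got {prev_out}")
        fan_in = k * k * cin
        weights.append(rng.standard_normal((k, k, cin, cout)) * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(cout))
        prev_out = cout
    return ConvNetParams(weights, biases, learning_rate, weight_decay, seed, residual)


# ---------------------------------------------------------------------------
# convolution primitives (batched, NHWC)

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W, k*k*C) patch matrix with same zero padding."""
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    win = np.moveaxis(win, 3, 5)
    n, h, w = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, h, w, k * k * win.shape[5])


def conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Same-padded 2-D correlation: (N,H,W,Cin) x (k,k,Cin,Cout) -> (N,H,W,Cout)."""
    k, _, cin, cout = w.shape
    cols = _im2col(x, k)
    out = cols @ w.reshape(k * k * cin, cout)
    if b is not None:
        out = out + b
    return out


def forward(net: ConvNetParams, image: np.ndarray) -> np.ndarray:
    """Network output for one image (H, W) -> (H, W); deterministic."""
    out = forward_batch(net, np.asarray(image, dtype=float)[None])
    return out[0]


def forward_batch(net: ConvNetParams, images: np.ndarray) -> np.ndarray:
    """Forward pass for a stack of images (N, H, W) -> (N, H, W)."""
    x = np.asarray(images, dtype=float)
    a = x[..., None]  # NHWC with C=1
    n_layers = len(net.weights)
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        z = conv_same(a, w, b)
        a = np.maximum(z, 0.0) if l < n_layers - 1 else z
    out = a[..., 0]
    return out + x if net.residual else out


def _forward_cached(net: ConvNetParams, images: np.ndarray):
    x = np.asarray(images, dtype=float)
    a = x[..., None]
    acts = [a]
    n_layers = len(net.weights)
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        z = conv_same(a, w, b)
        a = np.maximum(z, 0.0) if l < n_layers - 1 else z
        acts.append(a)
    if net.residual:
        # the skip path carries no parameters; only the output value changes
        acts.append(acts[-1] + x[..., None])
    return acts


def cost(
    net: ConvNetParams, inputs: np.ndarray, targets: np.ndarray
) -> tuple[float, float, float]:
    """(total, data, decay): exact decomposition of the training objective."""
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim == 2:
        x, y = x[None], y[None]
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    h = forward_batch(net, x)
    per_sample = 0.5 * np.mean((h - y) ** 2, axis=(1, 2))
    data = float(per_sample.mean())
    decay = float(0.5 * net.weight_decay * sum(np.sum(w**2) for w in net.weights))
    return data + decay, data, decay


def gradients(
    net: ConvNetParams, inputs: np.ndarray, targets: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backprop gradients of the full cost (data + decay) w.r.t. W and b."""
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim == 2:
        x, y = x[None], y[None]
    n, hh, ww = x.shape
    acts = _forward_cached(net, x)
    h_out = acts[-1][..., 0]
    # d(data)/d(h) with the (1/n) * (1/2) * per-pixel-mean normalization
    delta = ((h_out - y) / (n * hh * ww))[..., None]
    dWs: list[np.ndarray] = [None] * len(net.weights)
    dbs: list[np.ndarray] = [None] * len(net.weights)
    for l in range(len(net.weights) - 1, -1, -1):
        w = net.weights[l]
        k, _, cin, cout = w.shape
        a_prev = acts[l]
        cols = _im2col(a_prev, k).reshape(-1, k * k * cin)
        dz = delta.reshape(-1, cout)
        dWs[l] = (cols.T @ dz).reshape(w.shape) + net.weight_decay * w
        dbs[l] = dz.sum(axis=0)
        if l > 0:
            # propagate: same-padded correlation with the flipped kernel,
            # in/out channels swapped
            w_flip = w[::-1, ::-1].transpose(0, 1, 3, 2)
            delta = conv_same(delta, w_flip)
            delta = delta * (acts[l] > 0)  # ReLU gate of the previous layer
    return dWs, dbs


def sgd_step(
    net: ConvNetParams,
    inputs: np.ndarray,
    targets: np.ndarray,
    learning_rate: float | None = None,
    weight_decay: float | None = None,
) -> ConvNetParams:
    """One gradient-descent update on every weight and bias (out of place)."""
    alpha = net.learning_rate if learning_rate is None else learning_rate
    if alpha < 0:
        raise ValueError("learning rate must be nonnegative")
    work = net.copy()
    if weight_decay is not None:
        work.weight_decay = weight_decay
    dWs, dbs = gradients(work, inputs, targets)
    for w, b, dw, db in zip(work.weights, work.biases, dWs, dbs):
        if not (np.isfinite(dw).all() and np.isfinite(db).all()):
            raise DivergenceError("non-finite gradient encountered")
        w -= alpha * dw
        b -= alpha * db
    return work


@dataclass
class TrainLog:
    total: list[float] = field(default_factory=list)
    data: list[float] = field(default_factory=list)
    decay: list[float] = field(default_factory=list)
    train_psnr: list[float] = field(default_factory=list)
    test_psnr: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_deep(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    n_train: int,
    n_test: int,
    epochs: int = 100,
    net: ConvNetParams | None = None,
    batch_size: int = 8,
    seed: int = 0,
    momentum: float = 0.0,
) -> tuple[ConvNetParams, TrainLog]:
    """Mini-batch gradient descent on (degraded, clean) pairs.

    The first ``n_train`` pairs train, the next ``n_test`` evaluate; the
    checkpoint with the best test PSNR is returned.  With ``n_test = 0`` the
    final-epoch parameters are returned and the test column stays empty.
    The default update is the plain gradient step; ``momentum`` enables a
    classical heavy-ball accumulator on top of it.
    """
    from .metrics import psnr  # local import to avoid a cycle at module load

    if n_train < 1 or n_train + n_test > len(pairs):
        raise ValueError("invalid train/test split")
    if not (0.0 <= momentum < 1.0):
        raise ValueError("momentum must lie in [0, 1)")
    if net is None:
        net = init_net(seed=seed)
    x_tr = np.stack([p[0] for p in pairs[:n_train]])
    y_tr = np.stack([p[1] for p in pairs[:n_train]])
    x_te = np.stack([p[0] for p in pairs[n_train : n_train + n_test]]) if n_test else None
    y_te = np.stack([p[1] for p in pairs[n_train : n_train + n_test]]) if n_test else None
    rng = np.random.default_rng(seed)
    log = TrainLog()
    best_net, best_psnr = net.copy(), -np.inf
    vel_w = [np.zeros_like(w) for w in net.weights]
    vel_b = [np.zeros_like(b) for b in net.biases]
    for epoch in range(epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, batch_size):
            idx = order[start : start + batch_size]
            if momentum == 0.0:
                net = sgd_step(net, x_tr[idx], y_tr[idx])
            else:
                dWs, dbs = gradients(net, x_tr[idx], y_tr[idx])
                net = net.copy()
                for w, b, dw, db, vw, vb in zip(
                    net.weights, net.biases, dWs, dbs, vel_w, vel_b
                ):
                    if not (np.isfinite(dw).all() and np.isfinite(db).all()):
                        raise DivergenceError("non-finite gradient encountered")
                    vw *= momentum
                    vw += dw
                    vb *= momentum
                    vb += db
                    w -= net.learning_rate * vw
                    b -= net.learning_rate * vb
        total, data, decay = cost(net, x_tr, y_tr)
        if not np.isfinite(total) or total > 1e6:
            raise DivergenceError(f"training cost diverged at epoch {epoch}: {total}")
        log.total.append(total)
        log.data.append(data)
        log.decay.append(decay)
        log.train_psnr.append(_mean_psnr(psnr, forward_batch(net, x_tr), y_tr))
        if n_test:
            te = _mean_psnr(psnr, forward_batch(net, x_te), y_te)
            log.test_psnr.append(te)
            if te > best_psnr:
                best_psnr, best_net, log.best_epoch = te, net.copy(), epoch
        else:
            best_net, log.best_epoch = net, epoch
    return best_net, log


def _mean_psnr(psnr_fn, preds: np.ndarray, refs: np.ndarray) -> float:
    vals = [psnr_fn(r, np.clip(p, 0, 1)) for p, r in zip(preds, refs)]
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("inf")


def reconstruct_deep(
    sample: KSpaceSample,
    net: ConvNetParams,
    apply_data_consistency: bool = True,
) -> np.ndarray:
    """Forward pass on the zero-filled input, then optional hard consistency.

    With the projection on (the default) the returned image is complex and
    its sampled k-space entries equal the measurements exactly (take
    ``np.real`` for the image estimate); without it the clipped real network
    output is returned.
    """
    x = zero_filled(sample.data)
    out = forward(net, x)
    if apply_data_consistency:
        return data_consistency(out, sample)
    return np.clip(out, 0.0, 1.0)
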