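"""Numerical primitives for the fuzzy dilated-convolution network.

Everything here is plain numpy and dimension-agnostic (2D images or 3D
volumes): dilated (atrous) convolution as shifted-slice accumulation,
strided pooling over dilated windows (max and stochastic), Gaussian
membership functions, the affine fuzzy-fusion transfer, and the small
radial-basis regression head trained by gradient descent on the
half-sum-of-squares error E = 1/2 sum |t_i - y_i|^2.
"""

from __future__ import annotations

from itertools import product
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "gaussian_basis",
    "rbf_forward",
    "training_error",
    "RBFHead",
    "gradient_step",
    "fuzzy_fusion_forward",
    "max_pool",
    "stochastic_pool",
    "dilated_offsets",
]


# ---------------------------------------------------------------------------
# Gaussian basis / RBF head (Eqs. 22-24 style training)
# ---------------------------------------------------------------------------

def gaussian_basis(v, center, sigma: float) -> float:
    """phi = exp(-||v - center||^2 / (2 sigma^2)), in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v = np.asarray(v, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    r2 = float(np.sum((v - center) ** 2))
    return float(np.exp(-r2 / (2.0 * sigma * sigma)))


def rbf_forward(v, weights, centers, sigma: float) -> float:
    """f(v) = sum_i w_i phi(||v - C_i||); linear in the weights."""
    weights = np.asarray(weights, dtype=np.float64).ravel()
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    if weights.size != centers.shape[0]:
        raise ValueError("weights and centers must have matching counts")
    phis = np.array([gaussian_basis(v, c, sigma) for c in centers])
    return float(weights @ phis)


def training_error(targets, outputs) -> Tuple[np.ndarray, float]:
    """Residuals e_i = t_i - y_i and total error E = 1/2 sum |e_i|^2."""
    t = np.asarray(targets, dtype=np.float64).ravel()
    y = np.asarray(outputs, dtype=np.float64).ravel()
    if t.size != y.size:
        raise ValueError("targets and outputs must have the same length")
    e = t - y
    return e, float(0.5 * np.sum(e * e))


class RBFHead:
    """Gaussian-basis regression head, linear in its weights.

    Centers and width are fixed at construction; only the weights are
    trained, by plain gradient descent on E.  For sufficiently small
    learning rate the loss is non-increasing (the problem is convex
    quadratic in the weights).
    """

    def __init__(self, centers, sigma: float = 1.0, weights=None,
                 random_state: Optional[int] = None):
        self.centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.sigma = float(sigma)
        n = self.centers.shape[0]
        if weights is None:
            rng = np.random.default_rng(random_state)
            weights = rng.normal(0.0, 0.1, size=n)
        self.weights = np.asarray(weights, dtype=np.float64).ravel()
        if self.weights.size != n:
            raise ValueError("one weight per center required")

    def design_matrix(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.sigma ** 2))

    def forward(self, X) -> np.ndarray:
        return self.design_matrix(X) @ self.weights

    def loss(self, X, t) -> float:
        _, E = training_error(t, self.forward(X))
        return E

    def gradient(self, X, t) -> np.ndarray:
        """Analytic dE/dw = -Phi^T e."""
        Phi = self.design_matrix(X)
        e, _ = training_error(t, Phi @ self.weights)
        return -Phi.T @ e

    def step(self, X, t, lr: float) -> "RBFHead":
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        g = self.gradient(X, t)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite gradient encountered: |g|max={np.abs(g).max()}"
            )
        self.weights = self.weights - lr * g
        return self

    def fit(self, X, t, lr: float = 0.1, epochs: int = 500,
            loss_threshold: float = 0.0) -> List[float]:
        """Gradient-descent epochs; stops early once E < loss_threshold."""
        history: List[float] = []
        for _ in range(epochs):
            self.step(X, t, lr)
            E = self.loss(X, t)
            history.append(E)
            if E < loss_threshold:
                break
        return history


def gradient_step(head: RBFHead, batch, lr: float) -> RBFHead:
    """One descent step on (X, t) = batch; returns the updated head."""
    X, t = batch
    return head.step(X, t, lr)


# ---------------------------------------------------------------------------
# Fuzzy fusion transfer
# ---------------------------------------------------------------------------

def fuzzy_fusion_forward(y_d, y_f, w_d, w_f, b) -> np.ndarray:
    """x = tanh(w_d * y_d + w_f * y_f + b); elementwise, output in (-1, 1)."""
    y_d = np.asarray(y_d, dtype=np.float64)
    y_f = np.asarray(y_f, dtype=np.float64)
    if y_d.shape != y_f.shape:
        raise ValueError("deep and fuzzy activations must share a shape")
    return np.tanh(w_d * y_d + w_f * y_f + b)


# ---------------------------------------------------------------------------
# Scalar pooling operators
# ---------------------------------------------------------------------------

def max_pool(window) -> float:
    """Window maximum."""
    w = np.asarray(window, dtype=np.float64).ravel()
    if w.size == 0:
        raise ValueError("pooling window must be non-empty")
    return float(w.max())


def stochastic_pool(window, mode: str = "inference",
                    rng: Optional[np.random.Generator] = None) -> float:
    """Activation-proportional pooling.

    Probabilities are proportional to the window activations (shifted
    up if any are negative).  ``training`` samples one element;
    ``inference`` returns the probability-weighted average of the
    original values.  A flat (or all-zero) window yields uniform
    probabilities, hence the constant itself.
    """
    w = np.asarray(window, dtype=np.float64).ravel()
    if w.size == 0:
        raise ValueError("pooling window must be non-empty")
    shifted = w - min(w.min(), 0.0)
    total = shifted.sum()
    p = shifted / total if total > 0 else np.full(w.size, 1.0 / w.size)
    if mode == "inference":
        return float(p @ w)
    if mode == "training":
        rng = rng or np.random.default_rng()
        return float(w[rng.choice(w.size, p=p)])
    raise ValueError(f"unknown pooling mode: {mode}")


# ---------------------------------------------------------------------------
# Dilated convolution / pooling over batched feature maps
# (internal helpers used by the network; shapes are (B, C, *spatial))
# ---------------------------------------------------------------------------

def dilated_offsets(kernel: int, rate: int, ndim: int) -> np.ndarray:
    """Tap offsets of a dilated kernel: k per axis, spaced ``rate`` apart."""
    if kernel < 1 or rate < 1:
        raise ValueError("kernel and rate must be >= 1")
    axis = [(i - kernel // 2) * rate for i in range(kernel)]
    return np.array(list(product(axis, repeat=ndim)), dtype=np.intp)


def receptive_extent(kernel: int, rate: int) -> int:
    """Spatial extent spanned by a dilated kernel: (k-1)*rate + 1."""
    return (kernel - 1) * rate + 1


def _pad_spatial(x: np.ndarray, pad: Sequence[int]) -> np.ndarray:
    width = [(0, 0), (0, 0)] + [(p, p) for p in pad]
    return np.pad(x, width)


def _shift_slices(off, pad, shape) -> Tuple[slice, ...]:
    return (slice(None), slice(None)) + tuple(
        slice(p + int(o), p + int(o) + s) for p, o, s in zip(pad, off, shape)
    )


def conv_dilated_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                         offsets: np.ndarray):
    """Same-size dilated convolution.

    x : (B, Cin, *S); W : (Cout, Cin, n_off); b : (Cout,).
    Returns (y, cache) with y : (B, Cout, *S).
    """
    spatial = x.shape[2:]
    pad = tuple(int(np.abs(offsets[:, d]).max()) for d in range(len(spatial)))
    xp = _pad_spatial(x, pad)
    y = np.zeros((x.shape[0], W.shape[0]) + spatial, dtype=x.dtype)
    for i, off in enumerate(offsets):
        xs = xp[_shift_slices(off, pad, spatial)]
        y += np.einsum("oc,bc...->bo...", W[:, :, i], xs, optimize=True)
    y += b.reshape((1, -1) + (1,) * len(spatial))
    return y, (xp, pad, spatial)


def conv_dilated_backward(dy: np.ndarray, cache, W: np.ndarray,
                          offsets: np.ndarray, need_dx: bool = True):
    """Gradients of the dilated convolution; returns (dx, dW, db)."""
    xp, pad, spatial = cache
    dW = np.zeros_like(W)
    db = dy.sum(axis=(0,) + tuple(range(2, dy.ndim)))
    dxp = np.zeros_like(xp) if need_dx else None
    for i, off in enumerate(offsets):
        sl = _shift_slices(off, pad, spatial)
        xs = xp[sl]
        dW[:, :, i] = np.einsum("bo...,bc...->oc", dy, xs, optimize=True)
        if need_dx:
            dxp[sl] += np.einsum("oc,bo...->bc...", W[:, :, i], dy,
                                 optimize=True)
    dx = None
    if need_dx:
        crop = (slice(None), slice(None)) + tuple(
            slice(p, p + s) for p, s in zip(pad, spatial)
        )
        dx = dxp[crop]
    return dx, dW, db


def _pool_geometry(spatial, offsets, stride):
    out = tuple(int(np.ceil(s / stride)) for s in spatial)
    pad = tuple(int(np.abs(offsets[:, d]).max()) for d in range(len(spatial)))
    return out, pad


def _pool_slices(off, pad, out_shape, stride):
    return (slice(None), slice(None)) + tuple(
        slice(p + int(o), p + int(o) + (n - 1) * stride + 1, stride)
        for p, o, n in zip(pad, off, out_shape)
    )


def pool_windows(a: np.ndarray, offsets: np.ndarray, stride: int):
    """Gather dilated pooling windows: (n_off, B, C, *Sout)."""
    spatial = a.shape[2:]
    out_shape, pad = _pool_geometry(spatial, offsets, stride)
    ap = _pad_spatial(a, pad)
    w = np.stack([ap[_pool_slices(off, pad, out_shape, stride)]
                  for off in offsets])
    return w, (pad, out_shape, spatial)


def pool_scatter(dsel: np.ndarray, offsets: np.ndarray, stride: int,
                 cache) -> np.ndarray:
    """Scatter per-tap gradients back to the (B, C, *S) input grid."""
    pad, out_shape, spatial = cache
    lead = dsel.shape[1:3]
    ap = np.zeros(lead + tuple(s + 2 * p for s, p in zip(spatial, pad)),
                  dtype=dsel.dtype)
    for i, off in enumerate(offsets):
        ap[_pool_slices(off, pad, out_shape, stride)] += dsel[i]
    crop = (slice(None), slice(None)) + tuple(
        slice(p, p + s) for p, s in zip(pad, spatial)
    )
    return ap[crop]


def stochastic_pool_map(a: np.ndarray, offsets: np.ndarray, stride: int,
                        mode: str, rng: Optional[np.random.Generator] = None):
    """Batched stochastic pooling over dilated windows.

    Returns (out, sel, cache); ``sel`` is the one-hot tap selection used
    for gradient routing in training mode (None at inference).
    """
    w, cache = pool_windows(a, offsets, stride)
    n = w.shape[0]
    shifted = w - np.minimum(w.min(axis=0, keepdims=True), 0.0)
    total = shifted.sum(axis=0, keepdims=True)
    safe = np.where(total > 0, total, 1.0)
    p = np.where(total > 0, shifted / safe, 1.0 / n)
    if mode == "inference":
        return (p * w).sum(axis=0), None, (cache, None)
    if mode != "training":
        raise ValueError(f"unknown pooling mode: {mode}")
    rng = rng or np.random.default_rng()
    u = rng.random(size=w.shape[1:])
    cum = np.cumsum(p, axis=0)
    idx = np.minimum((cum < u[None]).sum(axis=0), n - 1)
    sel = (np.arange(n).reshape((-1,) + (1,) * (w.ndim - 1)) == idx[None])
    out = (sel * w).sum(axis=0)
    return out, sel, (cache, None)


def max_pool_map(a: np.ndarray, offsets: np.ndarray, stride: int):
    """Batched max pooling over dilated windows; first tap wins ties."""
    w, cache = pool_windows(a, offsets, stride)
    idx = w.argmax(axis=0)
    n = w.shape[0]
    sel = (np.arange(n).reshape((-1,) + (1,) * (w.ndim - 1)) == idx[None])
    return w.max(axis=0), sel, cache
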