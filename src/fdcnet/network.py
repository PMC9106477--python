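"""The fuzzy dilated-convolution classifier (FDCNet).

Architecture (2D or 3D inputs), in forward order:

1. dilated convolution, ``conv_channels`` filters of ``filter_size`` per
   axis at atrous rate ``rate_conv``;
2. fuzzy layer: per-pixel Gaussian membership functions over the
   channel vector of conv activations (``fuzzy_units`` units with
   learnable centers and widths), mixed back to ``conv_channels`` maps
   by a 3x3 convolution at rate ``rate_fuzzy``, then fused with the
   deep branch through x = tanh(w_d * y_d + w_f * y_f + b);
3. pooling: a stochastic-pooling stage then a max-pooling stage, both
   over 3x3 windows dilated at rate ``rate_pool`` with stride 2 (extra
   plain max stages when more pooling layers are configured);
4. a fully connected head over the flattened maps concatenated with any
   auxiliary feature columns (eigenimage projections), softmax over the
   tumor classes.

Training is plain mini-batch gradient descent on the softmax
cross-entropy; all gradients are analytic and implemented here.
Setting the fusion weight w_f to zero makes the network output
identical to the same-parameter plain dilated CNN (the fuzzy branch
contributes exactly nothing), which is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .nn_ops import (
    conv_dilated_backward,
    conv_dilated_forward,
    dilated_offsets,
    max_pool_map,
    pool_scatter,
    receptive_extent,
    stochastic_pool_map,
)

__all__ = [
    "FDCNetConfig",
    "TrainConfig",
    "FDCNetClassifier",
    "build_network",
    "train",
    "predict",
    "ConfigurationError",
]

CLASS_NAMES = ("benign", "malignant", "suspicious")


class ConfigurationError(ValueError):
    """Raised when an architecture cannot be built for the given input."""


@dataclass
class FDCNetConfig:
    """Architecture constants of the network."""

    input_shape: Tuple[int, ...] = (64, 64)
    conv_channels: int = 20
    filter_size: int = 3
    rate_conv: int = 3
    rate_fuzzy: int = 7
    rate_pool: int = 11
    fuzzy_units: int = 10
    pool_layers: int = 2
    pooling: Tuple[str, ...] = ("max", "stochastic")
    n_classes: int = 3
    connected_budget: float = 1.0

    def __post_init__(self):
        if min(self.rate_conv, self.rate_fuzzy, self.rate_pool) < 1:
            raise ValueError("all atrous rates must be >= 1")
        if self.fuzzy_units < 1:
            raise ValueError("fuzzy_units must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (2 <= self.pool_layers <= 5):
            raise ValueError("pool_layers must lie in [2, 5]")


@dataclass
class TrainConfig:
    """Gradient-descent training parameters."""

    learning_rate: float = 0.05
    epochs: int = 50
    batch_size: int = 32
    train_fraction: float = 0.7
    seed: int = 42
    loss_threshold: float = 1e-4

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FDCNetClassifier(ClassifierMixin, BaseEstimator):
    """Fuzzy dilated-convolution classifier with an sklearn interface.

    ``X`` rows are flattened images (row-major, ``prod(image_shape)``
    pixels); any columns beyond the image length are treated as
    auxiliary feature inputs to the fully connected head (e.g.
    eigenimage projections).
    """

    def __init__(self, image_shape: Tuple[int, ...] = (64, 64),
                 conv_channels: int = 20, filter_size: int = 3,
                 rate_conv: int = 3, rate_fuzzy: int = 7, rate_pool: int = 11,
                 fuzzy_units: int = 10, pool_layers: int = 2,
                 learning_rate: float = 0.05, epochs: int = 50,
                 batch_size: int = 32, loss_threshold: float = 1e-4,
                 weight_decay: float = 1e-3, random_state: int = 0):
        self.image_shape = image_shape
        self.conv_channels = conv_channels
        self.filter_size = filter_size
        self.rate_conv = rate_conv
        self.rate_fuzzy = rate_fuzzy
        self.rate_pool = rate_pool
        self.fuzzy_units = fuzzy_units
        self.pool_layers = pool_layers
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.loss_threshold = loss_threshold
        self.weight_decay = weight_decay
        self.random_state = random_state

    # -- architecture geometry ------------------------------------------

    def _ndim(self) -> int:
        return len(self.image_shape)

    def _offsets(self):
        nd = self._ndim()
        k = self.filter_size
        return (dilated_offsets(k, self.rate_conv, nd),
                dilated_offsets(k, self.rate_fuzzy, nd),
                dilated_offsets(k, self.rate_pool, nd),
                dilated_offsets(2, 1, nd))

    def _pool_plan(self, spatial: Tuple[int, ...]):
        """Pooling stage list [(kind, offsets, stride, out_shape), ...]."""
        _, _, offs_pool, offs_small = self._offsets()
        plan = []
        cur = spatial
        kinds = ["max", "stochastic"] + ["max"] * (self.pool_layers - 2)
        for i, kind in enumerate(kinds):
            offs = offs_pool if i < 2 else offs_small
            out = tuple(int(np.ceil(s / 2)) for s in cur)
            plan.append((kind, offs, 2, cur))
            cur = out
        return plan, cur

    def _validate_size(self, spatial: Tuple[int, ...]) -> None:
        k = self.filter_size
        stages = [("conv", receptive_extent(k, self.rate_conv), spatial),
                  ("fuzzy", receptive_extent(k, self.rate_fuzzy), spatial)]
        plan, _ = self._pool_plan(spatial)
        for i, (kind, offs, _, cur) in enumerate(plan):
            ext = int(offs.max() - offs.min() + 1)
            stages.append((f"pool{i + 1}:{kind}", ext, cur))
        bad = [(n, e, c) for n, e, c in stages if min(c) < e]
        if bad:
            raise ConfigurationError(
                "input %s smaller than dilated receptive field of %s; "
                "minimum input size per axis is %d"
                % (spatial, ", ".join(n for n, _, _ in bad),
                   self.min_input_size())
            )

    def min_input_size(self) -> int:
        """Smallest per-axis input size admitting every receptive field."""
        for s in range(1, 4096):
            try:
                trial = (s,) * self._ndim()
                k = self.filter_size
                if min(trial) < max(receptive_extent(k, self.rate_conv),
                                    receptive_extent(k, self.rate_fuzzy)):
                    continue
                plan, _ = self._pool_plan(trial)
                ok = all(min(cur) >= int(offs.max() - offs.min() + 1)
                         for _, offs, _, cur in plan)
                if ok:
                    return s
            except ConfigurationError:
                continue
        raise ConfigurationError("no feasible input size below 4096")

    def _flat_dim(self) -> int:
        _, out = self._pool_plan(tuple(self.image_shape))
        return self.conv_channels * int(np.prod(out))

    def n_parameters(self, n_extra_features: int = 0,
                     n_classes: Optional[int] = None) -> int:
        """Deterministic parameter count from the configuration alone."""
        k_taps = self.filter_size ** self._ndim()
        C, U = self.conv_channels, self.fuzzy_units
        K = n_classes if n_classes is not None else 3
        count = C * k_taps + C                     # conv weights + bias
        count += U * C + U                         # centers + widths
        count += C * U * k_taps                    # fuzzy mixing conv
        count += 3 * C                             # w_d, w_f, fusion bias
        count += K * (self._flat_dim() + n_extra_features) + K
        return count

    # -- parameters ------------------------------------------------------

    def _init_params(self, rng: np.random.Generator, n_extra: int,
                     n_classes: int) -> Dict[str, np.ndarray]:
        nd = self._ndim()
        k_taps = self.filter_size ** nd
        C, U = self.conv_channels, self.fuzzy_units
        f32 = np.float32
        W1 = rng.normal(0, 1.0 / np.sqrt(k_taps), size=(C, 1, k_taps))
        W1 -= W1.mean(axis=2, keepdims=True)  # zero-DC: band-pass filters
        p = {
            "W1": W1.astype(f32),
            "b1": np.zeros(C, f32),
            # membership units start as radial magnitude-band detectors:
            # centers near the origin of activation space, widths log-spaced
            "centers": rng.normal(0, 0.1, size=(U, C)).astype(f32),
            "sigmas": np.logspace(np.log10(0.5), np.log10(8.0), U).astype(f32),
            "W2": rng.normal(0, 1.0 / np.sqrt(U * k_taps),
                             size=(C, U, k_taps)).astype(f32),
            "w_d": np.ones(C, f32),
            "w_f": np.ones(C, f32),
            # a spread of fusion biases breaks tanh's odd symmetry so mean
            # pooling becomes sensitive to activation magnitude
            "b_fuse": rng.uniform(-0.5, 0.5, C).astype(f32),
            "Wfc": rng.normal(0, 1.0 / np.sqrt(self._flat_dim() + n_extra),
                              size=(n_classes, self._flat_dim() + n_extra)
                              ).astype(f32),
            "bfc": np.zeros(n_classes, f32),
        }
        return p

    # -- forward / backward ---------------------------------------------

    def _split_columns(self, X: np.ndarray):
        d_img = int(np.prod(self.image_shape))
        if X.shape[1] < d_img:
            raise ValueError(
                f"X has {X.shape[1]} columns; expected at least {d_img} "
                f"image pixels for image_shape={self.image_shape}"
            )
        imgs = X[:, :d_img].reshape((-1, 1) + tuple(self.image_shape))
        extra = X[:, d_img:]
        return imgs.astype(np.float32), extra.astype(np.float32)

    def _forward(self, imgs, extra, mode="inference", rng=None,
                 skip_fuzzy=False):
        p = self.params_
        offs1, offs2, _, _ = self._offsets()
        cache: Dict[str, object] = {}
        nd = self._ndim()

        y_d, c1 = conv_dilated_forward(imgs, p["W1"], p["b1"], offs1)
        cache["c1"] = c1
        cache["y_d"] = y_d

        if skip_fuzzy:
            y_f = np.zeros_like(y_d)
        else:
            V = y_d
            centers, sigmas = p["centers"], p["sigmas"]
            V2 = (V * V).sum(axis=1)                        # (B, *S)
            cross = np.einsum("uc,bc...->bu...", centers, V, optimize=True)
            c2 = (centers * centers).sum(axis=1)
            d2 = V2[:, None] - 2.0 * cross + c2.reshape((1, -1) + (1,) * nd)
            np.clip(d2, 0.0, None, out=d2)
            sig = sigmas.reshape((1, -1) + (1,) * nd)
            m = np.exp(-d2 / (2.0 * sig * sig))
            y_f, c2cache = conv_dilated_forward(
                m, p["W2"], np.zeros(p["W2"].shape[0], np.float32), offs2)
            cache.update(m=m, d2=d2, c2=c2cache)
        cache["y_f"] = y_f

        shape_c = (1, -1) + (1,) * nd
        z = (p["w_d"].reshape(shape_c) * y_d
             + p["w_f"].reshape(shape_c) * y_f
             + p["b_fuse"].reshape(shape_c))
        a = np.tanh(z)
        cache["a"] = a

        plan, _ = self._pool_plan(tuple(self.image_shape))
        cur = a
        pool_caches = []
        for kind, offs, stride, _ in plan:
            if kind == "stochastic":
                out, sel, (pc, _) = stochastic_pool_map(cur, offs, stride,
                                                        mode, rng)
            else:
                out, sel, pc = max_pool_map(cur, offs, stride)
            pool_caches.append((kind, offs, stride, sel, pc, cur.shape))
            cur = out
        cache["pools"] = pool_caches

        flat = cur.reshape(cur.shape[0], -1)
        h = np.concatenate([flat, extra], axis=1)
        cache["h"] = h
        cache["pooled_shape"] = cur.shape
        logits = h @ p["Wfc"].T + p["bfc"]
        return logits, cache

    def _backward(self, cache, probs, y_idx):
        p = self.params_
        offs1, offs2, _, _ = self._offsets()
        nd = self._ndim()
        B = probs.shape[0]
        g: Dict[str, np.ndarray] = {}

        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits /= B

        h = cache["h"]
        g["Wfc"] = dlogits.T @ h
        g["bfc"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wfc"]
        flat_dim = int(np.prod(cache["pooled_shape"][1:]))
        dflat = dh[:, :flat_dim].astype(np.float32)
        dcur = dflat.reshape(cache["pooled_shape"])

        for kind, offs, stride, sel, pc, in_shape in reversed(cache["pools"]):
            dsel = sel * dcur[None]
            dcur = pool_scatter(dsel.astype(np.float32), offs, stride, pc)

        a = cache["a"]
        dz = dcur * (1.0 - a * a)
        spatial_axes = (0,) + tuple(range(2, 2 + nd))
        y_d, y_f = cache["y_d"], cache["y_f"]
        g["w_d"] = (dz * y_d).sum(axis=spatial_axes)
        g["w_f"] = (dz * y_f).sum(axis=spatial_axes)
        g["b_fuse"] = dz.sum(axis=spatial_axes)
        shape_c = (1, -1) + (1,) * nd
        dy_d = dz * p["w_d"].reshape(shape_c)

        if "m" in cache:
            dy_f = dz * p["w_f"].reshape(shape_c)
            dm, dW2, _ = conv_dilated_backward(dy_f, cache["c2"], p["W2"],
                                               offs2, need_dx=True)
            g["W2"] = dW2
            m, d2 = cache["m"], cache["d2"]
            sig = p["sigmas"].reshape((1, -1) + (1,) * nd)
            dmm = dm * m
            dd2 = dmm * (-0.5 / (sig * sig))
            g["sigmas"] = (dmm * d2).sum(
                axis=(0,) + tuple(range(2, 2 + nd))) / p["sigmas"] ** 3
            V = y_d
            sum_dd2 = dd2.sum(axis=1)                       # (B, *S)
            g["centers"] = -2.0 * (
                np.einsum("bu...,bc...->uc", dd2, V, optimize=True)
                - p["centers"] * dd2.sum(
                    axis=(0,) + tuple(range(2, 2 + nd)))[:, None])
            dV = 2.0 * (V * sum_dd2[:, None]
                        - np.einsum("bu...,uc->bc...", dd2, p["centers"],
                                    optimize=True))
            dy_d = dy_d + dV
        else:
            g["W2"] = np.zeros_like(p["W2"])
            g["centers"] = np.zeros_like(p["centers"])
            g["sigmas"] = np.zeros_like(p["sigmas"])

        _, dW1, db1 = conv_dilated_backward(dy_d, cache["c1"], p["W1"],
                                            offs1, need_dx=False)
        g["W1"], g["b1"] = dW1, db1
        return g

    # -- sklearn API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_samples, n_features)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training requires at least two classes")
        self._validate_size(tuple(self.image_shape))

        imgs, extra = self._split_columns(X)
        self.img_mean_ = float(imgs.mean())
        self.img_std_ = float(max(imgs.std(), 1e-8))
        self.extra_mean_ = extra.mean(axis=0) if extra.size else np.zeros(0)
        self.extra_std_ = (np.maximum(extra.std(axis=0), 1e-8)
                           if extra.size else np.ones(0))
        imgs = (imgs - self.img_mean_) / self.img_std_
        extra = ((extra - self.extra_mean_) / self.extra_std_
                 if extra.size else extra)

        rng = np.random.default_rng(self.random_state)
        self.n_extra_features_ = extra.shape[1]
        self.params_ = self._init_params(rng, extra.shape[1],
                                         self.classes_.size)
        n = X.shape[0]
        lr = self.learning_rate
        self.history_ = []
        for _ in range(self.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                logits, cache = self._forward(imgs[idx], extra[idx],
                                              mode="training", rng=rng)
                probs = _softmax(logits)
                ll = -np.log(np.clip(probs[np.arange(len(idx)),
                                           y_idx[idx]], 1e-12, None))
                losses.append(float(ll.mean()) * len(idx))
                grads = self._backward(cache, probs, y_idx[idx])
                wd = self.weight_decay
                for k, gk in grads.items():
                    if wd > 0 and k in ("W1", "W2", "Wfc"):
                        gk = gk + wd * self.params_[k]
                    self.params_[k] = (self.params_[k]
                                       - lr * gk).astype(np.float32)
                np.maximum(self.params_["sigmas"], 0.1,
                           out=self.params_["sigmas"])
            E = float(np.sum(losses) / n)
            self.history_.append(E)
            if E < self.loss_threshold:
                break
        return self

    def decision_function(self, X, skip_fuzzy: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        imgs, extra = self._split_columns(X)
        imgs = (imgs - self.img_mean_) / self.img_std_
        extra = ((extra - self.extra_mean_) / self.extra_std_
                 if extra.size else extra)
        logits, _ = self._forward(imgs, extra, mode="inference",
                                  skip_fuzzy=skip_fuzzy)
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def build_network(config: FDCNetConfig, **train_kw) -> FDCNetClassifier:
    """Instantiate a classifier from an architecture config.

    Raises :class:`ConfigurationError` when the input is smaller than a
    stage's dilated receptive field (the message reports the computed
    minimum feasible size).
    """
    clf = FDCNetClassifier(
        image_shape=tuple(config.input_shape),
        conv_channels=config.conv_channels,
        filter_size=config.filter_size,
        rate_conv=config.rate_conv,
        rate_fuzzy=config.rate_fuzzy,
        rate_pool=config.rate_pool,
        fuzzy_units=config.fuzzy_units,
        pool_layers=config.pool_layers,
        **train_kw,
    )
    clf._validate_size(tuple(config.input_shape))
    return clf


def train(model: FDCNetClassifier, X, y, cfg: Optional[TrainConfig] = None):
    """Stratified split + gradient-descent training.

    Returns ``(model, info)`` where ``info`` carries the per-epoch loss
    history and the (disjoint, seed-reproducible) train/test indices.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training requires at least two classes")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=cfg.train_fraction, random_state=cfg.seed,
        stratify=y)
    model.set_params(learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                     batch_size=cfg.batch_size,
                     loss_threshold=cfg.loss_threshold)
    X = np.asarray(X, dtype=np.float64)
    model.fit(X[train_idx], y[train_idx])
    info = {"history": list(model.history_),
            "train_idx": train_idx, "test_idx": test_idx}
    return model, info


def predict(model: FDCNetClassifier, image, eigen_features=None):
    """Classify one image (+ optional eigen features).

    Returns ``(label, scores)``; ties resolve to the lowest class index.
    """
    row = np.asarray(image, dtype=np.float64).ravel()
    if eigen_features is not None:
        row = np.concatenate([row, np.asarray(eigen_features,
                                              dtype=np.float64).ravel()])
    probs = model.predict_proba(row[None, :])[0]
    return model.classes_[int(np.argmax(probs))], probs
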